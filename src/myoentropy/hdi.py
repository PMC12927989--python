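"""Fiber-level homeostatic dysregulation index (HDI_M).

The index treats each fiber as a point in a three-feature space — fiber
cross-sectional area, fiber-type heterogeneity, and node-specific average
path length — z-scored within sex x fiber-type strata (up to six strata).
The reference centroid is the zero vector (the stratified mean), and the
covariance matrix S is fitted once on the entire pooled fiber population.
A fiber's Mahalanobis distance

    D_M = sqrt((x - mu)^T S^{-1} (x - mu))

is natural-log transformed without offset to give the fiber-level HDI_M;
the participant-level HDI_M is the arithmetic mean of a sample's
fiber-level values. Because ln(D^2) = 2 ln(D), reporting the squared
distance instead (``squared=True``) only rescales HDI_M by 2 and leaves
every rank-based or correlation result unchanged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURES",
    "ReferenceModel",
    "StratumError",
    "SingularCovarianceError",
    "ZeroDistanceError",
    "stratified_zscore",
    "fit_reference_model",
    "fiber_hdi",
    "participant_hdi",
]

#: feature column -> z-scored column
FEATURES = {"area_um2": "z_area", "heterogeneity": "z_het", "apl": "z_apl"}
Z_COLS = tuple(FEATURES.values())


class StratumError(ValueError):
    """A sex x fiber-type stratum is too small or degenerate."""


class SingularCovarianceError(ValueError):
    """Pooled covariance matrix is numerically singular."""


class ZeroDistanceError(ValueError):
    """A fiber sits exactly at the reference centroid (ln 0 undefined)."""


def stratified_zscore(
    fibers: pd.DataFrame,
    min_stratum_n: int = 10,
    on_small_stratum: str = "error",
) -> pd.DataFrame:
    """Z-score the three features within each sex x fiber-type stratum.

    Strata are the cross of sex {F, M} and fiber type {I, IIA, IIX}; only
    strata actually present contribute. Each feature is centered and
    scaled by the stratum sample mean and (n-1)-denominator standard
    deviation, computed over non-missing values. Missing features stay
    missing. Returns a copy with z_area/z_het/z_apl and ``stratum`` added.

    ``on_small_stratum``: 'error' (default) rejects strata with fewer than
    ``min_stratum_n`` complete rows; 'pool' falls back to pooled
    (unstratified) statistics for those strata with a warning.
    """
    if on_small_stratum not in {"error", "pool"}:
        raise ValueError("on_small_stratum must be 'error' or 'pool'")
    out = fibers.copy()
    out["stratum"] = out["sex"].astype(str) + "/" + out["fiber_type"].astype(str)
    for raw, zc in FEATURES.items():
        vals = out[raw].astype(float)
        z = pd.Series(np.nan, index=out.index)
        for key, sub in vals.groupby(out["stratum"]):
            present = sub.dropna()
            if len(present) < min_stratum_n:
                if on_small_stratum == "error":
                    raise StratumError(
                        f"stratum {key!r} has {len(present)} values for "
                        f"{raw!r} (< {min_stratum_n})"
                    )
                logger.warning(
                    "stratum %r below min size for %r; using pooled statistics",
                    key,
                    raw,
                )
                pooled = vals.dropna()
                mu, sd = pooled.mean(), pooled.std(ddof=1)
            else:
                mu, sd = present.mean(), present.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                raise StratumError(
                    f"stratum {key!r} has zero variance in {raw!r}"
                )
            z.loc[sub.index] = (sub - mu) / sd
        out[zc] = z
    return out


@dataclass
class ReferenceModel:
    """Zero centroid plus pooled covariance over the z-scored features."""

    covariance: np.ndarray
    features: tuple[str, ...] = Z_COLS
    n: int = 0
    condition_number: float = dc_field(default=np.nan)

    def subset(self, features: Sequence[str]) -> "ReferenceModel":
        idx = [self.features.index(f) for f in features]
        return ReferenceModel(
            self.covariance[np.ix_(idx, idx)], tuple(features), self.n
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "features": list(self.features),
                    "covariance": self.covariance.tolist(),
                    "n": self.n,
                    "condition_number": float(self.condition_number),
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            np.asarray(d["covariance"]),
            tuple(d["features"]),
            d["n"],
            d.get("condition_number", np.nan),
        )


def fit_reference_model(
    features: pd.DataFrame, z_cols: Sequence[str] = Z_COLS
) -> ReferenceModel:
    """Fit the pooled (n-1)-denominator covariance of the z-features.

    Rows with any missing feature are excluded. The centroid is fixed at
    zero by construction of the stratified z-scores.
    """
    X = features.loc[:, list(z_cols)].dropna().to_numpy(dtype=float)
    if len(X) < 4:
        raise ValueError("need at least 4 complete fibers to fit covariance")
    S = np.cov(X, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    cond = float(np.linalg.cond(S))
    if not np.isfinite(cond) or cond > 1e12:
        raise SingularCovarianceError(
            f"covariance matrix is singular (condition number {cond:.3g})"
        )
    return ReferenceModel(S, tuple(z_cols), len(X), cond)


def fiber_hdi(
    features: pd.DataFrame,
    model: ReferenceModel,
    feature_subset: Sequence[str] | None = None,
    squared: bool = False,
    on_zero_distance: str = "error",
) -> pd.DataFrame:
    """Mahalanobis distance and HDI_M per fiber.

    ``feature_subset`` (names from the model's feature tuple) restricts
    both the vectors and the covariance to a subset — e.g. excluding
    ``z_area`` gives the modified, area-free HDI_M. Fibers with any
    missing feature are dropped with a logged count. A fiber exactly at
    the centroid raises by default (natural log without offset);
    ``on_zero_distance='drop'`` removes such fibers instead.

    Returns a DataFrame indexed like the retained rows of ``features``
    with columns ``mahalanobis`` and ``hdi``.
    """
    if on_zero_distance not in {"error", "drop"}:
        raise ValueError("on_zero_distance must be 'error' or 'drop'")
    cols = tuple(feature_subset) if feature_subset else model.features
    if not cols:
        raise ValueError("feature subset must be nonempty")
    sub = model.subset(cols)
    X = features.loc[:, list(cols)].astype(float)
    complete = X.dropna()
    n_dropped = len(X) - len(complete)
    if n_dropped:
        logger.info("%d fibers dropped: missing features", n_dropped)
    x = complete.to_numpy()
    Sinv = np.linalg.inv(sub.covariance)
    q = np.einsum("ij,jk,ik->i", x, Sinv, x)
    q = np.maximum(q, 0.0)
    zero = q == 0.0
    if zero.any():
        if on_zero_distance == "error":
            raise ZeroDistanceError(
                f"{int(zero.sum())} fibers at zero Mahalanobis distance; "
                "ln(0) undefined without offset"
            )
        logger.warning("%d fibers at zero distance dropped", int(zero.sum()))
        complete = complete.loc[~zero]
        q = q[~zero]
    d = q if squared else np.sqrt(q)
    return pd.DataFrame(
        {"mahalanobis": d, "hdi": np.log(d)}, index=complete.index
    )


def participant_hdi(
    hdi: pd.Series, participant_ids: pd.Series
) -> pd.DataFrame:
    """Participant-level HDI_M: mean of the sample's fiber-level values.

    Returns one row per participant with mean, SD, and fiber count; fibers
    lacking a participant id raise.
    """
    pid = participant_ids.reindex(hdi.index)
    if pid.isna().any():
        raise ValueError("every fiber must map to a participant")
    g = hdi.groupby(pid)
    out = pd.DataFrame(
        {"hdi": g.mean(), "hdi_sd": g.std(ddof=1), "n_fibers": g.size()}
    )
    out.index.name = "participant_id"
    return out
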