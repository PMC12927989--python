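"""Synthetic muscle histology and cohort generator.

Produces seeded, fully characterized stand-ins for segmented muscle
cross-sections: Voronoi tessellations of jittered lattice points rasterized
to label images (one region per fiber), myosin-heavy-chain fiber types with
tunable spatial clustering, right-skewed (log-normal) fiber cross-sectional
areas, optional 3-channel immunofluorescence renders, and a participant
cohort whose outcomes are linear in a planted per-participant
disorganization parameter ``theta`` plus covariates and noise.

``theta`` in [0, 1] drives both fiber-area dispersion (log-normal sigma)
and fiber-type clustering, so that downstream dysregulation indices should
rise monotonically with it. Every random draw descends from a single
integer seed through ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "Tessellation",
    "Cohort",
    "generate_tessellation",
    "assign_fiber_types",
    "sample_fiber_areas",
    "render_histology_image",
    "generate_cohort",
    "write_cohort",
    "DEFAULT_TYPE_PROPORTIONS",
    "DEFAULT_MEAN_AREA_BY_TYPE",
    "DEFAULT_OUTCOME_BETAS",
    "DEFAULT_COVARIATE_MODEL",
    "FIBER_TYPES",
]

FIBER_TYPES = ("I", "IIA", "IIX")

# Type shares approximate the cohort-median fiber-type proportions of the
# target population, renormalized over the three pure MHC isoforms.
DEFAULT_TYPE_PROPORTIONS = (0.41, 0.35, 0.24)

# Median cross-sectional areas (um^2) by type in older-adult vastus lateralis.
DEFAULT_MEAN_AREA_BY_TYPE = {"I": 4535.0, "IIA": 3134.0, "IIX": 2238.0}

# Planted standardized effects of theta on each outcome analogue (negative:
# more disorganization, worse function).
DEFAULT_OUTCOME_BETAS = {
    "walk_speed": -0.16,
    "sppb": -0.14,
    "vo2peak": -0.16,
    "grip": -0.09,
    "leg_power": -0.10,
    "oxphos": -0.27,
    "atpmax": -0.15,
}

# Standardized covariate effects shared by all outcomes.
DEFAULT_COVARIATE_EFFECTS = {"age": -0.15, "sex": 0.25, "bmi": -0.10}

# (mean, sd) per covariate; heights are sex-specific.
DEFAULT_COVARIATE_MODEL = {
    "age": (76.4, 5.3),
    "bmi": (27.9, 4.8),
    "height_f": (161.5, 6.2),
    "height_m": (175.5, 6.8),
    "muscle_volume_index_z": (-0.8, 1.0),
    "adipose_index": (4.4, 1.7),
}

# Output scale (mean, sd) per outcome, so the tables look like real units.
OUTCOME_SCALES = {
    "walk_speed": (1.0, 0.2),
    "sppb": (2.1, 0.5),
    "vo2peak": (20.2, 4.4),
    "grip": (30.2, 10.1),
    "leg_power": (4.8, 1.8),
    "oxphos": (57.83, 17.04),
    "atpmax": (0.55, 0.15),
}

# theta -> log-normal sigma and neighbor-copy probability, linear maps.
SIGMA_RANGE = (0.1, 0.8)
CLUSTERING_RANGE = (0.0, 0.9)

DEFAULT_CHANNEL_MEANS = np.array(
    [[200.0, 30.0, 30.0], [30.0, 200.0, 30.0], [30.0, 30.0, 200.0]]
)


class SizingError(ValueError):
    """Field too small to hold the requested number of fibers."""


@dataclass
class Tessellation:
    """A rasterized Voronoi tessellation standing in for a segmented section.

    ``label_image`` holds integer labels 1..n with 0 reserved for the 1-px
    background border at the field edge; ``truth`` is a per-region table of
    pixel area, centroid and rook-contact neighbor sets (the ground truth a
    perfect extractor should recover).
    """

    field_size: tuple[int, int]
    seed_points: np.ndarray
    label_image: np.ndarray
    truth: pd.DataFrame

    @property
    def n_fibers(self) -> int:
        return len(self.truth)


def _lattice_shape(n_fibers: int, field_size: tuple[int, int]) -> tuple[int, int]:
    rows, cols = field_size
    aspect = cols / rows
    nc = max(1, int(round(np.sqrt(n_fibers * aspect))))
    nr = int(np.ceil(n_fibers / nc))
    return nr, nc


def rook_adjacency_pairs(label_image: np.ndarray) -> set[tuple[int, int]]:
    """Pairs of distinct nonzero labels sharing an edge-adjacent pixel pair."""
    pairs: set[tuple[int, int]] = set()
    lab = np.asarray(label_image)
    for a, b in ((lab[:, :-1], lab[:, 1:]), (lab[:-1, :], lab[1:, :])):
        m = (a > 0) & (b > 0) & (a != b)
        if m.any():
            lo = np.minimum(a[m], b[m])
            hi = np.maximum(a[m], b[m])
            pairs.update(zip(lo.tolist(), hi.tolist()))
    return pairs


def generate_tessellation(
    n_fibers: int,
    field_size: tuple[int, int] = (256, 256),
    jitter: float = 0.35,
    seed: int | np.random.SeedSequence = 0,
) -> Tessellation:
    """Rasterize a Voronoi tessellation of jittered lattice points.

    Parameters
    ----------
    n_fibers : number of regions (labels 1..n_fibers).
    field_size : (rows, cols) of the label image, including the 1-px border.
    jitter : seed-point displacement as a fraction of the lattice pitch;
        0 gives a regular grid.
    seed : integer seed or a ``SeedSequence`` (for splittable use).
    """
    rows, cols = int(field_size[0]), int(field_size[1])
    if n_fibers < 1:
        raise ValueError("n_fibers must be >= 1")
    if not 0 <= jitter:
        raise ValueError("jitter must be >= 0")
    interior = (rows - 2) * (cols - 2)
    if interior < n_fibers:
        raise SizingError(
            f"field {rows}x{cols} has {interior} interior pixels, "
            f"cannot host {n_fibers} fibers"
        )
    rng = np.random.default_rng(seed)

    nr, nc = _lattice_shape(n_fibers, (rows, cols))
    pitch_r = (rows - 2) / nr
    pitch_c = (cols - 2) / nc
    ii, jj = np.divmod(np.arange(n_fibers), nc)
    pts_r = 1.0 + (ii + 0.5) * pitch_r
    pts_c = 1.0 + (jj + 0.5) * pitch_c
    if jitter > 0:
        pts_r = pts_r + rng.uniform(-0.5, 0.5, n_fibers) * jitter * pitch_r
        pts_c = pts_c + rng.uniform(-0.5, 0.5, n_fibers) * jitter * pitch_c
    pts_r = np.clip(pts_r, 1.0, rows - 2.0)
    pts_c = np.clip(pts_c, 1.0, cols - 2.0)
    points = np.column_stack([pts_r, pts_c])

    rr, cc = np.meshgrid(
        np.arange(1, rows - 1, dtype=float),
        np.arange(1, cols - 1, dtype=float),
        indexing="ij",
    )
    pix = np.column_stack([rr.ravel(), cc.ravel()])
    _, nearest = cKDTree(points).query(pix, k=1)
    label = np.zeros((rows, cols), dtype=np.int32)
    label[1:-1, 1:-1] = (nearest + 1).reshape(rows - 2, cols - 2)

    counts = np.bincount(label.ravel(), minlength=n_fibers + 1)
    if (counts[1:] == 0).any():
        missing = int((counts[1:] == 0).sum())
        raise SizingError(
            f"{missing} of {n_fibers} regions rasterized to zero pixels; "
            "enlarge the field or reduce n_fibers"
        )

    ids = np.arange(1, n_fibers + 1)
    csum_r = np.bincount(label.ravel(), weights=np.repeat(np.arange(rows), cols))
    csum_c = np.bincount(label.ravel(), weights=np.tile(np.arange(cols), rows))
    neighbor_sets: dict[int, set[int]] = {int(i): set() for i in ids}
    for a, b in rook_adjacency_pairs(label):
        neighbor_sets[a].add(b)
        neighbor_sets[b].add(a)
    truth = pd.DataFrame(
        {
            "fiber_id": ids,
            "area_px": counts[1:],
            "centroid_row": csum_r[1:] / counts[1:],
            "centroid_col": csum_c[1:] / counts[1:],
            "neighbors": [frozenset(neighbor_sets[int(i)]) for i in ids],
        }
    )
    return Tessellation((rows, cols), points, label, truth)


def assign_fiber_types(
    tess: Tessellation,
    proportions: Sequence[float] = DEFAULT_TYPE_PROPORTIONS,
    clustering: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
) -> pd.Series:
    """Assign fiber types I/IIA/IIX, optionally spatially clustered.

    With ``clustering`` = 0 types are i.i.d. draws from ``proportions``.
    With ``clustering`` = c > 0, fibers are visited in random order and each
    copies the type of a random already-typed neighbor with probability c
    (falling back to an i.i.d. draw when no neighbor is typed yet),
    mimicking the same-type fiber grouping of denervation-reinnervation.
    """
    p = np.asarray(proportions, dtype=float)
    if p.shape != (3,) or (p < 0).any():
        raise ValueError("proportions must be 3 non-negative values")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("proportions must sum to 1")
    if not 0.0 <= clustering <= 1.0:
        raise ValueError("clustering must be in [0, 1]")
    rng = np.random.default_rng(seed)

    ids = tess.truth["fiber_id"].to_numpy()
    if clustering == 0.0:
        draws = rng.choice(3, size=len(ids), p=p)
        return pd.Series(
            [FIBER_TYPES[d] for d in draws], index=ids, name="fiber_type"
        )
    neighbors = dict(zip(ids, tess.truth["neighbors"]))
    order = rng.permutation(ids)
    types: dict[int, str] = {}
    for fid in order:
        fid = int(fid)
        typed_nb = [n for n in neighbors[fid] if n in types]
        if typed_nb and clustering > 0 and rng.random() < clustering:
            types[fid] = types[int(typed_nb[rng.integers(len(typed_nb))])]
        else:
            types[fid] = FIBER_TYPES[rng.choice(3, p=p)]
    return pd.Series([types[int(i)] for i in ids], index=ids, name="fiber_type")


def sample_fiber_areas(
    types: pd.Series,
    mean_area_by_type: Mapping[str, float] = DEFAULT_MEAN_AREA_BY_TYPE,
    sigma: float = 0.35,
    seed: int | np.random.SeedSequence = 0,
) -> pd.Series:
    """Draw log-normal fiber areas with exact type means.

    area = mean_type * exp(sigma*Z - sigma^2/2), so E[area] equals the type
    mean for every sigma and the coefficient of variation is
    sqrt(exp(sigma^2) - 1). sigma = 0 returns the type means exactly.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    for t, m in mean_area_by_type.items():
        if m <= 0:
            raise ValueError(f"mean area for type {t} must be positive")
    rng = np.random.default_rng(seed)
    means = types.map(mean_area_by_type).to_numpy(dtype=float)
    if np.isnan(means).any():
        raise ValueError("types contain a label absent from mean_area_by_type")
    z = rng.standard_normal(len(types))
    areas = means * np.exp(sigma * z - 0.5 * sigma**2)
    return pd.Series(areas, index=types.index, name="area_um2")


def render_histology_image(
    tess: Tessellation,
    types: pd.Series,
    channel_means: np.ndarray = DEFAULT_CHANNEL_MEANS,
    noise_sd: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a 3-channel MHC-like intensity image plus the label mask.

    ``channel_means`` rows index the true type (I, IIA, IIX order), columns
    the image channel; a diagonally dominant matrix keeps types
    identifiable. Pixel intensities are the fiber's type means plus
    Gaussian noise, clipped at zero. Background pixels are zero.
    """
    cm = np.asarray(channel_means, dtype=float)
    if cm.shape != (3, 3):
        raise ValueError("channel_means must be 3x3 (type x channel)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    lab = tess.label_image
    type_idx = {t: i for i, t in enumerate(FIBER_TYPES)}
    # per-label row of channel means; label 0 -> zeros
    lut = np.zeros((tess.n_fibers + 1, 3))
    for fid, t in types.items():
        lut[int(fid)] = cm[type_idx[str(t)]]
    img = lut[lab]
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
        img[lab == 0] = 0.0
    img = np.clip(img, 0.0, None).astype(np.float32)
    return img, lab.copy()


def theta_to_sigma(theta: np.ndarray) -> np.ndarray:
    lo, hi = SIGMA_RANGE
    return lo + (hi - lo) * np.asarray(theta, dtype=float)


def theta_to_clustering(theta: np.ndarray) -> np.ndarray:
    lo, hi = CLUSTERING_RANGE
    return lo + (hi - lo) * np.asarray(theta, dtype=float)


@dataclass
class Cohort:
    """A generated cohort: participant table, pooled fiber table, truths."""

    participants: pd.DataFrame
    fibers: pd.DataFrame
    true_betas: dict[str, float]
    seed: int
    tessellations: dict[str, Tessellation] = field(default_factory=dict)


def _draw_covariates(
    n: int, model: Mapping[str, tuple[float, float]], rng: np.random.Generator
) -> pd.DataFrame:
    for name, (_, sd) in model.items():
        if sd <= 0:
            raise ValueError(f"covariate {name!r} has non-positive sd (degenerate)")
    sex = np.where(rng.random(n) < 0.512, "F", "M")
    age = np.clip(rng.normal(*model["age"], n), 70.0, 95.0)
    bmi = np.clip(rng.normal(*model["bmi"], n), 18.0, 40.0)
    hf = rng.normal(*model["height_f"], n)
    hm = rng.normal(*model["height_m"], n)
    height = np.where(sex == "F", hf, hm)
    mvz = rng.normal(*model["muscle_volume_index_z"], n)
    adip = np.clip(rng.normal(*model["adipose_index"], n), 0.5, None)
    return pd.DataFrame(
        {
            "sex": sex,
            "age": age,
            "bmi": bmi,
            "height": height,
            "muscle_volume_index_z": mvz,
            "adipose_index": adip,
        }
    )


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:  # constant predictor: no between-participant contrast to plant
        return np.zeros_like(v, dtype=float)
    return (v - v.mean()) / sd


def generate_cohort(
    n_participants: int = 299,
    fibers_per_participant: tuple[int, int] = (346, 590),
    theta_distribution: str = "uniform",
    covariate_model: Mapping[str, tuple[float, float]] = DEFAULT_COVARIATE_MODEL,
    outcome_betas: Mapping[str, float] = DEFAULT_OUTCOME_BETAS,
    covariate_effects: Mapping[str, float] = DEFAULT_COVARIATE_EFFECTS,
    noise_sd: float | None = None,
    jitter: float = 0.35,
    pitch_px: int = 10,
    seed: int = 0,
    keep_tessellations: bool = False,
) -> Cohort:
    """Generate a full synthetic cohort with planted structure.

    Each participant receives a disorganization parameter theta (default
    Uniform(0,1)) that maps linearly to fiber-area log-normal sigma in
    [0.1, 0.8] and type-clustering probability in [0, 0.9]. Outcomes are
    ``beta * z(theta) + covariate effects + noise`` on the standardized
    scale, then rescaled to realistic units. ``noise_sd=None`` picks the
    residual sd so each standardized outcome has unit total variance.
    """
    if n_participants < 2:
        raise ValueError("n_participants must be >= 2")
    lo, hi = fibers_per_participant
    if not 1 <= lo <= hi:
        raise ValueError("fibers_per_participant must be a valid (lo, hi) range")

    root = np.random.SeedSequence(seed)
    ss_cohort, ss_fibers, ss_outcomes = root.spawn(3)
    rng = np.random.default_rng(ss_cohort)

    cov = _draw_covariates(n_participants, covariate_model, rng)
    if theta_distribution == "uniform":
        theta = rng.uniform(0.0, 1.0, n_participants)
    elif theta_distribution == "beta":
        theta = rng.beta(2.0, 2.0, n_participants)
    elif isinstance(theta_distribution, (tuple, list)) and len(theta_distribution) == 2:
        t_lo, t_hi = float(theta_distribution[0]), float(theta_distribution[1])
        if not 0.0 <= t_lo <= t_hi <= 1.0:
            raise ValueError("theta range must satisfy 0 <= lo <= hi <= 1")
        theta = rng.uniform(t_lo, t_hi, n_participants)
    else:
        raise ValueError(f"unknown theta_distribution {theta_distribution!r}")
    n_fib = rng.integers(lo, hi + 1, n_participants)

    pids = [f"P{i:04d}" for i in range(1, n_participants + 1)]
    participants = cov.copy()
    participants.insert(0, "participant_id", pids)
    participants["theta"] = theta
    participants["n_fibers_true"] = n_fib

    # outcomes: standardized linear predictor, rescaled to printed units
    orng = np.random.default_rng(ss_outcomes)
    z_theta = _zscore(theta)
    z_age = _zscore(cov["age"].to_numpy())
    z_bmi = _zscore(cov["bmi"].to_numpy())
    sex_m = (cov["sex"] == "M").to_numpy(dtype=float)
    lin_cov = (
        covariate_effects.get("age", 0.0) * z_age
        + covariate_effects.get("sex", 0.0) * sex_m
        + covariate_effects.get("bmi", 0.0) * z_bmi
    )
    var_cov = sum(v**2 for v in covariate_effects.values())
    for name, beta in outcome_betas.items():
        if noise_sd is None:
            resid_sd = float(np.sqrt(max(0.05, 1.0 - beta**2 - var_cov)))
        else:
            resid_sd = noise_sd
        y_std = beta * z_theta + lin_cov + orng.normal(0.0, resid_sd, n_participants)
        mean, sd = OUTCOME_SCALES.get(name, (0.0, 1.0))
        participants[name] = mean + sd * y_std

    sigma = theta_to_sigma(theta)
    clustering = theta_to_clustering(theta)
    fiber_seeds = ss_fibers.spawn(n_participants)
    tessellations: dict[str, Tessellation] = {}
    frames: list[pd.DataFrame] = []
    for i, pid in enumerate(pids):
        ss_t, ss_ty, ss_a = fiber_seeds[i].spawn(3)
        nf = int(n_fib[i])
        nr, nc = _lattice_shape(nf, (1, 1))  # aspect 1
        fs = (nr * pitch_px + 2, nc * pitch_px + 2)
        tess = generate_tessellation(nf, fs, jitter=jitter, seed=ss_t)
        types = assign_fiber_types(tess, clustering=float(clustering[i]), seed=ss_ty)
        areas = sample_fiber_areas(types, sigma=float(sigma[i]), seed=ss_a)
        tab = tess.truth[["fiber_id", "centroid_row", "centroid_col", "neighbors"]].copy()
        tab.insert(0, "participant_id", pid)
        tab["sex"] = cov["sex"].iloc[i]
        tab["fiber_type"] = types.to_numpy()
        tab["area_um2"] = areas.to_numpy()
        frames.append(tab)
        if keep_tessellations:
            tessellations[pid] = tess
    fibers = pd.concat(frames, ignore_index=True)
    return Cohort(participants, fibers, dict(outcome_betas), seed, tessellations)


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, str]:
    """Write participant/fiber CSVs and a truth JSON; return written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fib = cohort.fibers.copy()
    fib["neighbors"] = fib["neighbors"].map(
        lambda s: ";".join(str(i) for i in sorted(s))
    )
    paths = {
        "participants": str(outdir / "participants.csv"),
        "fibers": str(outdir / "fibers.csv"),
        "truth": str(outdir / "truth.json"),
    }
    cohort.participants.to_csv(paths["participants"], index=False)
    fib.to_csv(paths["fibers"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "seed": cohort.seed,
                "true_betas": cohort.true_betas,
                "theta": dict(
                    zip(
                        cohort.participants["participant_id"],
                        cohort.participants["theta"].round(10),
                    )
                ),
            },
            fh,
            indent=1,
        )
    return paths
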