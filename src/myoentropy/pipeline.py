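"""End-to-end pipeline: simulate -> extract -> graph -> HDI -> entropy -> associate.

One seeded config drives every stage; outputs (fiber table with z-scores
and HDI_M, participant table, group entropies, regression results, run
report JSON) are written to the output directory. Identical seed and
config produce byte-identical CSV outputs. Fiber bookkeeping is exact:
fibers_in = fibers_retained + dropped for missing heterogeneity/APL
+ dropped at zero distance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, entropy, graph, hdi, synthetic
from .extraction import compute_type_heterogeneity

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "compute_fiber_metrics"]

DEFAULT_OUTCOMES = tuple(synthetic.DEFAULT_OUTCOME_BETAS)


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    seed: int = 0
    out_dir: str = "myoentropy_run"
    # simulation (used when fibers_csv is not given)
    n_participants: int = 299
    fibers_per_participant: tuple[int, int] = (346, 590)
    theta_distribution: str = "uniform"
    # inputs (bypass simulation)
    fibers_csv: str | None = None
    participants_csv: str | None = None
    # analysis parameters
    pixel_size: float = 0.65
    gap_tolerance: int = 1
    min_stratum_n: int = 10
    on_small_stratum: str = "error"
    k_groups: int = 300
    feature_subset: tuple[str, ...] | None = None
    squared: bool = False
    outcomes: tuple[str, ...] = DEFAULT_OUTCOMES

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.k_groups < 1:
            raise ValueError("k_groups must be >= 1")
        if self.gap_tolerance < 0:
            raise ValueError("gap_tolerance must be >= 0")


def _parse_neighbors(val) -> frozenset[int]:
    if isinstance(val, frozenset):
        return val
    if isinstance(val, (set, list, tuple)):
        return frozenset(int(x) for x in val)
    if val is None or (isinstance(val, float) and np.isnan(val)) or val == "":
        return frozenset()
    return frozenset(int(x) for x in str(val).split(";"))


def compute_fiber_metrics(fibers: pd.DataFrame) -> pd.DataFrame:
    """Add heterogeneity and node-specific APL to a fiber table.

    Expects columns participant_id, fiber_id, fiber_type, and neighbors
    (a collection or semicolon-joined id string, local per participant).
    """
    fibers = fibers.copy()
    fibers["neighbors"] = fibers["neighbors"].map(_parse_neighbors)
    het = np.full(len(fibers), np.nan)
    for _, block in fibers.groupby("participant_id", sort=False):
        edges = set()
        for fid, nbs in zip(block["fiber_id"], block["neighbors"]):
            for nb in nbs:
                edges.add((min(int(fid), int(nb)), max(int(fid), int(nb))))
        types = dict(zip(block["fiber_id"].astype(int), block["fiber_type"].astype(str)))
        h = compute_type_heterogeneity(types, edges)
        het[fibers.index.get_indexer(block.index)] = [
            h[int(i)] for i in block["fiber_id"]
        ]
    fibers["heterogeneity"] = het
    fibers["apl"] = graph.apl_for_samples(fibers)
    return fibers


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write outputs; return the run report dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _jsonable(asdict(config)), "stages": {}}

    # stage 1: simulate or load
    if config.fibers_csv:
        fibers = pd.read_csv(config.fibers_csv)
        participants = (
            pd.read_csv(config.participants_csv) if config.participants_csv else None
        )
        true_betas = None
    else:
        cohort = synthetic.generate_cohort(
            n_participants=config.n_participants,
            fibers_per_participant=config.fibers_per_participant,
            theta_distribution=config.theta_distribution,
            seed=config.seed,
        )
        fibers, participants = cohort.fibers, cohort.participants
        true_betas = cohort.true_betas
    n_in = len(fibers)
    report["stages"]["input"] = {
        "n_fibers": n_in,
        "n_participants": int(fibers["participant_id"].nunique()),
    }

    # stage 2: per-sample metrics
    fibers = compute_fiber_metrics(fibers)
    n_missing_het = int(fibers["heterogeneity"].isna().sum())
    n_missing_apl = int(fibers["apl"].isna().sum() - n_missing_het)

    # stage 3: stratified z-scores, reference model, HDI
    fibers = hdi.stratified_zscore(
        fibers, config.min_stratum_n, config.on_small_stratum
    )
    model = hdi.fit_reference_model(fibers)
    res = hdi.fiber_hdi(
        fibers,
        model,
        feature_subset=config.feature_subset,
        squared=config.squared,
        on_zero_distance="drop",
    )
    fibers["mahalanobis"] = res["mahalanobis"]
    fibers["hdi"] = res["hdi"]
    n_retained = len(res)
    n_zero = n_in - n_missing_het - n_missing_apl - n_retained
    report["stages"]["hdi"] = {
        "fibers_in": n_in,
        "fibers_retained": n_retained,
        "dropped_missing_heterogeneity": n_missing_het,
        "dropped_missing_apl": n_missing_apl,
        "dropped_zero_distance": n_zero,
        "n_strata": int(fibers["stratum"].nunique()),
        "covariance_condition_number": model.condition_number,
        "mean_fiber_hdi": float(res["hdi"].mean()),
        "sd_fiber_hdi": float(res["hdi"].std(ddof=1)),
    }

    part_hdi = hdi.participant_hdi(res["hdi"], fibers["participant_id"])
    if participants is not None:
        participants = participants.merge(
            part_hdi.reset_index(), on="participant_id", how="left"
        )
    else:
        participants = part_hdi.reset_index()

    # stage 4: entropy of HDI-stratified groups
    retained = fibers.loc[res.index]
    groups = entropy.stratify_by_hdi(
        pd.Series(retained["hdi"].to_numpy(), index=retained["fiber_id"].to_numpy()),
        min(config.k_groups, len(retained)),
    )
    corr_report = {}
    for comp, col in (("area", "z_area"), ("heterogeneity", "z_het"), ("apl", "z_apl")):
        c = entropy.entropy_hdi_correlation(
            groups, comp, retained[col].to_numpy(), standardize=True
        )
        corr_report[comp] = {
            "r": c.r,
            "p": c.p,
            "k": c.k_groups,
            "n_bins": c.n_bins,
            "bin_width": c.bin_width,
        }
    report["stages"]["entropy"] = corr_report
    groups_df = pd.DataFrame(
        {
            "group_id": [g.group_id for g in groups],
            "size": [g.size for g in groups],
            "median_hdi": [g.median_hdi for g in groups],
            **{
                f"H_{comp}": [g.entropies.get(comp, np.nan) for g in groups]
                for comp in ("area", "heterogeneity", "apl")
            },
        }
    )

    # stage 5: associations
    outcomes = [o for o in config.outcomes if o in participants.columns]
    assoc_results = []
    interactions = {}
    if outcomes and "hdi" in participants:
        assoc_results = association.fit_outcome_models(participants, outcomes)
        for o in outcomes:
            coef, p = association.sex_interaction_test(participants, o)
            interactions[o] = {"coef": coef, "p": p}
    report["stages"]["association"] = {
        "results": [asdict(r) for r in assoc_results],
        "sex_interaction": interactions,
        "true_betas": true_betas,
    }

    # outputs
    fib_out = fibers.copy()
    fib_out["neighbors"] = fib_out["neighbors"].map(
        lambda s: ";".join(str(i) for i in sorted(s))
    )
    fib_out.to_csv(out / "fibers_hdi.csv", index=False)
    participants.to_csv(out / "participants_hdi.csv", index=False)
    groups_df.to_csv(out / "groups.csv", index=False)
    association.results_table(assoc_results).to_csv(out / "associations.csv", index=False)
    model.to_json(out / "reference_model.json")
    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=1, sort_keys=True)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
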