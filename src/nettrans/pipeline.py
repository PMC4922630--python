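"""End-to-end pipeline: classification -> prevalence -> nets -> bootstrap -> extrapolation.

`run_pipeline` strings the stages together per sex-by-group stratum, writes
the standard CSV artifacts to an output directory and records a JSON run
log (config hash, library versions, seed, exclusion counts) so a run is
reproducible from its artifacts alone.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bootstrap import BootstrapConfig, bootstrap_nets
from .classification import GrowthReference, classify_records
from .extrapolation import extrapolate_counts, validate_population
from .prevalence import SplineSpec, combine_cycles, fit_prevalence
from .transport import CostMatrix


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; hashable for the run log."""

    records_path: str
    output_dir: str
    growth_reference_path: str | None = None
    population_path: str | None = None
    cycle_mode: str = "pooled"
    stratify_by: tuple = ("sex", "group")
    spline: SplineSpec = field(default_factory=SplineSpec)
    cost_constants: tuple = (0.0, 6.0, 17.0)
    bootstrap_replicates: int = 1000
    ci_level: float = 0.95
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full estimation pipeline; returns paths of the artifacts."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "nettrans": __version__,
        },
        "seed": cfg.seed,
    }

    try:
        records = pd.read_csv(cfg.records_path)
    except Exception as e:  # noqa: BLE001
        raise StageError("read_records", e) from e

    ref = None
    if (records["age"] < 20).any():
        if cfg.growth_reference_path is None:
            raise StageError(
                "classify",
                FileNotFoundError(
                    "records contain child ages (<20) but no growth reference file was given"
                ),
            )
        try:
            ref = GrowthReference.from_csv(cfg.growth_reference_path)
        except Exception as e:  # noqa: BLE001
            raise StageError("read_growth_reference", e) from e

    try:
        classified, excl = classify_records(records, ref=ref)
    except Exception as e:  # noqa: BLE001
        raise StageError("classify", e) from e
    log["exclusions"] = excl.counts
    log["underweight_folded"] = excl.underweight_folded

    try:
        classified = combine_cycles(classified, cfg.cycle_mode) if "cycle" in classified else classified
    except Exception as e:  # noqa: BLE001
        raise StageError("combine_cycles", e) from e

    cost = CostMatrix(constants=tuple(cfg.cost_constants))
    boot = BootstrapConfig(replicates=cfg.bootstrap_replicates, seed=cfg.seed, ci_level=cfg.ci_level)

    strat_cols = [c for c in cfg.stratify_by if c in classified.columns]
    groups = classified.groupby(list(strat_cols)) if strat_cols else [("all", classified)]

    prev_frames, net_frames, extra_frames = [], [], []
    pop = None
    if cfg.population_path is not None:
        pop = validate_population(pd.read_csv(cfg.population_path))
    for key, sub in groups:
        name = "_".join(map(str, key if isinstance(key, tuple) else (key,)))
        try:
            curve = fit_prevalence(sub, stratum=name, spec=cfg.spline)
        except Exception as e:  # noqa: BLE001
            raise StageError(f"prevalence[{name}]", e) from e
        prev_frames.append(curve.to_frame())
        side = out / "coefficients"
        side.mkdir(exist_ok=True)
        pd.DataFrame({"coef": curve.coef}).to_csv(side / f"{name}_coef.csv", index=False)
        pd.DataFrame(curve.vcov).to_csv(side / f"{name}_vcov.csv", index=False)
        (side / f"{name}_basis.json").write_text(
            json.dumps(
                {
                    "n_interior_knots": cfg.spline.n_interior_knots,
                    "degree": cfg.spline.degree,
                    "penalty_order": cfg.spline.penalty_order,
                    "lambda": curve.lambda_,
                    "edf": curve.edf,
                    "reference_category": curve.ref_cat,
                    "estimated_categories": list(curve.cat_index),
                }
            )
        )
        try:
            table = bootstrap_nets(curve, cost, boot)
        except Exception as e:  # noqa: BLE001
            raise StageError(f"bootstrap[{name}]", e) from e
        net_frames.append(table)
        if pop is not None:
            sex = sub["sex"].iloc[0] if "sex" in sub else None
            grp = sub["group"].iloc[0] if "group" in sub else None
            try:
                extra_frames.append(extrapolate_counts(table, curve, pop, sex=sex, group=grp))
            except Exception as e:  # noqa: BLE001
                raise StageError(f"extrapolate[{name}]", e) from e

    artifacts = {}
    prev_path = out / "prevalence.csv"
    pd.concat(prev_frames, ignore_index=True).to_csv(prev_path, index=False, float_format="%.10g")
    artifacts["prevalence"] = str(prev_path)
    net_path = out / "net_transitions.csv"
    pd.concat(net_frames, ignore_index=True).to_csv(net_path, index=False, float_format="%.10g")
    artifacts["net_transitions"] = str(net_path)
    if extra_frames:
        ex_path = out / "net_transition_counts.csv"
        pd.concat(extra_frames, ignore_index=True).to_csv(ex_path, index=False, float_format="%.10g")
        artifacts["net_transition_counts"] = str(ex_path)
    excl_path = out / "exclusions.json"
    excl_path.write_text(excl.to_json())
    artifacts["exclusions"] = str(excl_path)

    log["artifacts"] = artifacts
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, default=str))
    artifacts["run_log"] = str(log_path)
    return artifacts
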