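"""Cost-constant calibration against longitudinal data, and stability validation.

Two supporting analyses surround the cross-sectional estimator.  First, the
"economy of movement" cost constants are calibrated by comparing
LP-estimated net transition probabilities with the net transitions counted
directly in longitudinal weight-category trajectories; because the net
flows of the optimal plan are invariant across all valid cost triples, the
calibration profile is expected to be essentially flat among them — the
grid search mainly documents that insensitivity and rejects invalid
candidates.  Second, the stationarity assumption that justifies reading
one-year transitions out of cross-sections is checked by projecting an
earlier survey cycle's prevalence forward and comparing it with later,
independently sampled cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bootstrap import bootstrap_surfaces
from .prevalence import PrevalenceCurve
from .transport import (
    BOUNDARIES,
    CostMatrix,
    _constants_valid,
    net_probabilities,
    nets_from_prevalence,
    project_forward,
    solve_transport,
)


def validate_longitudinal(df: pd.DataFrame) -> pd.DataFrame:
    """Check the longitudinal trajectory schema (id, age, category)."""
    required = {"id", "age", "category"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"longitudinal records missing columns: {sorted(missing)}")
    for pid, sub in df.groupby("id"):
        ages = sub["age"].to_numpy()
        if not (np.diff(ages) > 0).all():
            raise ValueError(f"ages not strictly increasing for individual {pid!r}")
    return df


def empirical_net_from_longitudinal(df: pd.DataFrame, age: int) -> pd.DataFrame:
    """Net transitions counted from paired observations at ages (a, a+1).

    Among individuals observed at both ages, the signed net flow across a
    boundary is (#upward crossings - #downward crossings); the favored
    direction's probability divides by the count in its origin category at
    age ``a`` (e.g. 10 of 100 normal-weight participants moving up and 3
    moving down gives a net of 7 and a net transition probability of 7%).
    Returns an empty frame when no paired observations span the ages.
    """
    pairs = (
        df[df["age"].isin([age, age + 1])]
        .pivot_table(index="id", columns="age", values="category", aggfunc="first")
        .dropna()
    )
    if pairs.empty or pairs.shape[1] < 2:
        return pd.DataFrame()
    start = pairs[age].to_numpy(int)
    end = pairs[age + 1].to_numpy(int)
    n = len(start)
    counts = np.array([(start == c).sum() for c in (1, 2, 3)], float)
    nets = np.empty(2)
    for b in (1, 2):  # boundary below category b+1
        up = ((start <= b) & (end > b)).sum()
        down = ((start > b) & (end <= b)).sum()
        nets[b - 1] = up - down
    table = net_probabilities(nets / n, counts / n, age=age)
    table["n_pairs"] = n
    table["net_count"] = table["net_flow"] * n
    return table


def empirical_net_table(df: pd.DataFrame, ages=None) -> pd.DataFrame:
    """Empirical nets for every age with paired observations."""
    validate_longitudinal(df)
    if ages is None:
        ages = range(int(df["age"].min()), int(df["age"].max()))
    frames = [t for a in ages if not (t := empirical_net_from_longitudinal(df, a)).empty]
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


@dataclass
class CalibrationResult:
    best: CostMatrix | None
    profile: pd.DataFrame

    @property
    def best_constants(self):
        return None if self.best is None else self.best.constants


def calibrate_costs(
    empirical: pd.DataFrame,
    ages: np.ndarray,
    P: np.ndarray,
    grid,
    c0: float = 0.0,
) -> CalibrationResult:
    """Grid search for cost constants (c0 fixed, candidates over (c1, c2)).

    Each valid candidate's LP nets — computed from the cross-sectional
    prevalence surface ``P`` on ``ages`` — are scored by mean squared
    difference against the empirical longitudinal net probabilities on the
    ages/boundaries where both exist.  Invalid candidates (violating
    c0 < c1 or 2*c1 < c2) are flagged in the profile and never fitted.
    Ties (the expected case, by cost-invariance of the nets) go to the first
    valid candidate in grid order.
    """
    ages = np.asarray(ages)
    rows = []
    best = None
    best_mse = np.inf
    emp = empirical.set_index(["age", "boundary", "direction"])["net_prob"]
    for c1, c2 in grid:
        constants = (c0, float(c1), float(c2))
        if not _constants_valid(constants):
            rows.append({"c0": c0, "c1": c1, "c2": c2, "valid": False, "mse": np.nan})
            continue
        cost = CostMatrix(constants=constants)
        se = []
        for t in range(len(ages) - 1):
            plan = solve_transport(P[t], P[t + 1], cost, age=int(ages[t]))
            table = net_probabilities(plan.net_flows(), P[t], age=int(ages[t]))
            for row in table.itertuples(index=False):
                key = (row.age, row.boundary, row.direction)
                if key in emp.index:
                    se.append((row.net_prob - emp.loc[key]) ** 2)
        mse = float(np.mean(se)) if se else np.nan
        rows.append({"c0": c0, "c1": c1, "c2": c2, "valid": True, "mse": mse})
        if np.isfinite(mse) and mse < best_mse - 1e-9:
            best, best_mse = cost, mse
    profile = pd.DataFrame(rows)
    if best is None:
        raise ValueError("no valid cost-constant candidates in the grid")
    return CalibrationResult(best=best, profile=profile)


def project_surface(P: np.ndarray, nets: np.ndarray, horizon: int) -> np.ndarray:
    """Chain one-year projections: predicted prevalence after ``horizon`` years.

    Entry ``t`` of the result is the prediction for age ``ages[t + horizon]``
    obtained by starting from ``P[t]`` and applying the net flows at ages
    ``t .. t+horizon-1``.  Result has ``len(P) - horizon`` rows.
    """
    if horizon == 0:
        return P.copy()
    cur = P[:-horizon].copy()
    for h in range(horizon):
        n_rows = cur.shape[0]
        step = nets[h : h + n_rows]
        nxt = np.empty_like(cur)
        nxt[:, 0] = cur[:, 0] - step[:, 0]
        nxt[:, 2] = cur[:, 2] + step[:, 1]
        nxt[:, 1] = 1.0 - nxt[:, 0] - nxt[:, 2]
        cur = nxt
    return cur


@dataclass
class StabilityReport:
    """Observed-vs-predicted comparison for one or more later cycles."""

    horizon: int
    details: pd.DataFrame  # cycle, age, category, observed, predicted, discrepancy, se, exceeds
    summary: pd.DataFrame  # cycle, max_abs_error, mean_abs_error, frac_exceeding, stable

    @property
    def stable(self) -> bool:
        return bool(self.summary["stable"].all())


def validate_stability(
    earlier: PrevalenceCurve,
    later: dict,
    horizon: int = 2,
    *,
    n_boot: int = 200,
    seed: int = 0,
    z: float = 3.0,
    flag_fraction: float = 0.10,
) -> StabilityReport:
    """Test transition-regime stability across survey cycles.

    The earlier cycle's net flows age its own prevalence forward ``horizon``
    years; under stationarity the projection should match each later cycle's
    independently estimated prevalence up to sampling noise.  A cell (age,
    category) is discrepant when |predicted - observed| exceeds ``z`` times
    the combined bootstrap standard error; a cycle is flagged unstable when
    more than ``flag_fraction`` of its cells are discrepant.
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    rng = np.random.default_rng(seed)
    nets = nets_from_prevalence(earlier.P)
    pred = project_surface(earlier.P, nets, horizon)
    pred_ages = earlier.ages[horizon:]

    # uncertainty of the projection: bootstrap the earlier curve, re-project
    reps_e = bootstrap_surfaces(earlier, n_boot, rng)
    pred_reps = np.stack(
        [project_surface(s, nets_from_prevalence(s), horizon) for s in reps_e]
    )
    se_pred = pred_reps.std(axis=0, ddof=1)

    detail_frames = []
    summary_rows = []
    from .classification import CATEGORY_LABELS

    for label, curve in later.items():
        if not np.array_equal(curve.ages, earlier.ages):
            raise ValueError(f"cycle {label!r} is on a different age grid")
        obs = curve.P[horizon:]
        se_obs = prevalence_se_cached(curve, n_boot, rng)[horizon:]
        se = np.sqrt(se_pred**2 + se_obs**2)
        disc = pred - obs
        exceeds = np.abs(disc) > z * np.clip(se, 1e-12, None)
        df = pd.DataFrame(
            {
                "cycle": label,
                "age": np.repeat(pred_ages, 3),
                "category": CATEGORY_LABELS * len(pred_ages),
                "observed": obs.ravel(),
                "predicted": pred.ravel(),
                "discrepancy": disc.ravel(),
                "se": se.ravel(),
                "exceeds": exceeds.ravel(),
            }
        )
        frac = float(exceeds.mean())
        summary_rows.append(
            {
                "cycle": label,
                "max_abs_error": float(np.abs(disc).max()),
                "mean_abs_error": float(np.abs(disc).mean()),
                "frac_exceeding": frac,
                "stable": frac <= flag_fraction,
            }
        )
        detail_frames.append(df)
    return StabilityReport(
        horizon=horizon,
        details=pd.concat(detail_frames, ignore_index=True),
        summary=pd.DataFrame(summary_rows),
    )


def prevalence_se_cached(curve: PrevalenceCurve, n_boot: int, rng) -> np.ndarray:
    return bootstrap_surfaces(curve, n_boot, rng).std(axis=0, ddof=1)
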