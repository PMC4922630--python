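"""Reusable simulation studies over the pipeline.

Each function runs one self-contained computational experiment — the
textbook worked example, the LP-vs-closed-form agreement sweep, truth
recovery on synthetic cross-sections, bootstrap interval calibration, and
the operating characteristics of the stability check — and returns plain
dictionaries/frames.  The analysis drivers and the acceptance machinery are
thin wrappers around these.

Default problem sizes are chosen to finish on a single CPU in minutes:
recovery uses one stratum of n = 50,000 records through the full
classification path; interval calibration uses 200 replicate datasets of
n = 20,000 classified records with 400 bootstrap draws each; the stability
study uses paired cycles of n = 7,000 with a two-year projection horizon.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bootstrap import bootstrap_surfaces
from .calibration import empirical_net_from_longitudinal, validate_stability
from .classification import classify_records
from .prevalence import fit_prevalence
from .synthetic import SurveyDesignSpec, make_truth, sample_cross_section, toy_growth_reference
from .transport import (
    CostMatrix,
    closed_form_net,
    net_prob_array,
    net_probabilities,
    solve_transport,
)

DEFAULT_COST_TRIPLES = ((0.0, 6.0, 17.0), (0.0, 1.0, 3.0), (0.0, 10.0, 25.0))


def worked_example() -> dict:
    """The illustrative one-year cohort computation, by both estimation routes.

    100 normal-weight 18-year-olds; 10 move up to overweight by 19 while 3
    overweight participants move down: the normal-to-overweight net
    transition is 7 people, i.e. a net transition probability of 7%.
    Returns the value from direct longitudinal counting and from the
    marginal-prevalence (transport) route.
    """
    n_normal, n_over, n_obese = 100, 40, 20
    rows = []
    for i in range(n_normal):
        end = 2 if i < 10 else 1
        rows += [{"id": f"n{i}", "age": 18, "category": 1}, {"id": f"n{i}", "age": 19, "category": end}]
    for i in range(n_over):
        end = 1 if i < 3 else 2
        rows += [{"id": f"o{i}", "age": 18, "category": 2}, {"id": f"o{i}", "age": 19, "category": end}]
    for i in range(n_obese):
        rows += [{"id": f"b{i}", "age": 18, "category": 3}, {"id": f"b{i}", "age": 19, "category": 3}]
    traj = pd.DataFrame(rows)

    emp = empirical_net_from_longitudinal(traj, 18)
    emp_prob = float(
        emp.loc[(emp.boundary == "normal_overweight") & (emp.direction == "up"), "net_prob"].iloc[0]
    )

    n = n_normal + n_over + n_obese
    p = np.array([n_normal, n_over, n_obese]) / n
    q = np.array([n_normal - 7, n_over + 7, n_obese]) / n
    plan = solve_transport(p, q)
    table = net_probabilities(plan.net_flows(), p, age=18)
    lp_prob = float(
        table.loc[(table.boundary == "normal_overweight") & (table.direction == "up"), "net_prob"].iloc[0]
    )
    return {"empirical_net_prob": emp_prob, "transport_net_prob": lp_prob, "n_normal": n_normal}


def random_simplex_pairs(n_pairs: int, rng: np.random.Generator) -> np.ndarray:
    """(n_pairs, 2, 3) random probability-vector pairs, Dirichlet(1,1,1)."""
    return rng.dirichlet(np.ones(3), size=(n_pairs, 2))


def oracle_agreement(
    n_pairs: int = 10_000,
    seed: int = 0,
    triples=DEFAULT_COST_TRIPLES,
) -> dict:
    """LP nets vs closed form, and invariance across valid cost triples.

    For every random (p, q) pair the transport LP is solved under each cost
    triple; reported are the largest |LP net - closed form net| over all
    pairs and triples, and the largest spread of LP nets across triples.
    """
    rng = np.random.default_rng(seed)
    pairs = random_simplex_pairs(n_pairs, rng)
    max_diff = 0.0
    max_spread = 0.0
    for p, q in pairs:
        ref = closed_form_net(p, q)
        nets = []
        for triple in triples:
            plan = solve_transport(p, q, CostMatrix(constants=triple))
            nets.append(plan.net_flows())
        nets = np.array(nets)
        max_diff = max(max_diff, float(np.abs(nets - ref).max()))
        max_spread = max(max_spread, float((nets.max(axis=0) - nets.min(axis=0)).max()))
    return {"n_pairs": n_pairs, "max_abs_diff": max_diff, "max_cost_spread": max_spread}


def recovery_experiment(
    n: int = 50_000,
    scenario: str = "early_peak",
    seed: int = 0,
) -> dict:
    """Full-pipeline truth recovery on one synthetic stratum.

    Draws a survey cross-section of ``n`` records (with anthropometry),
    classifies them, fits the prevalence smooth, and compares the estimated
    net transition probabilities with the generating truth.  The headline
    number is the mean absolute error in percentage points over all ages
    (2-79), both boundaries and both directions.
    """
    truth = make_truth(scenario)
    records = sample_cross_section(
        truth, SurveyDesignSpec(n_per_cycle=n), cycle="recovery", seed=seed
    )
    classified, excl = classify_records(records, ref=toy_growth_reference())
    curve = fit_prevalence(classified, stratum=scenario)
    est = net_prob_array(curve.P)
    true = truth.true_net_probs()
    mae_pp = 100.0 * float(np.abs(est - true).mean())
    return {
        "n": n,
        "mae_pp": mae_pp,
        "max_err_pp": 100.0 * float(np.abs(est - true).max()),
        "excluded": excl.total_excluded,
        "curve": curve,
        "truth": truth,
        "estimated": est,
    }


def coverage_experiment(
    n_datasets: int = 200,
    n: int = 20_000,
    replicates: int = 400,
    scenario: str = "early_peak",
    seed: int = 0,
    ci_level: float = 0.95,
) -> dict:
    """Empirical coverage of the bootstrap CIs for the true net probabilities.

    Each replicate dataset skips anthropometry emission (the categories are
    exact, so only estimation noise is studied) and contributes one
    hit/miss per (age, boundary, direction) cell; coverage is averaged over
    the cells where the true net probability is positive.
    """
    truth = make_truth(scenario)
    true = truth.true_net_probs()
    mask = true > 1e-9
    alpha = 1.0 - ci_level
    ss = np.random.SeedSequence(seed)
    data_seeds, boot_seeds = ss.spawn(2)
    dseeds = data_seeds.generate_state(n_datasets)
    bseeds = boot_seeds.generate_state(n_datasets)
    hits = np.zeros_like(true)
    for r in range(n_datasets):
        df = sample_cross_section(
            truth, SurveyDesignSpec(n_per_cycle=n), cycle=f"rep{r}",
            seed=int(dseeds[r] % 2**31), emit_anthropometry=False,
        )
        curve = fit_prevalence(df, stratum=f"rep{r}")
        rng = np.random.default_rng(int(bseeds[r] % 2**31))
        surfaces = bootstrap_surfaces(curve, replicates, rng)
        reps = np.stack([net_prob_array(s) for s in surfaces])
        lo = np.quantile(reps, alpha / 2, axis=0)
        hi = np.quantile(reps, 1 - alpha / 2, axis=0)
        hits += (lo <= true) & (true <= hi)
    coverage = hits / n_datasets
    return {
        "n_datasets": n_datasets,
        "coverage_pct": 100.0 * float(coverage[mask].mean()),
        "coverage_all_cells_pct": 100.0 * float(coverage.mean()),
        "per_cell": coverage,
    }


def stability_experiment(
    n_sims: int = 200,
    n: int = 7_000,
    horizon: int = 2,
    drift: float = 1.5,
    scenario: str = "early_peak",
    seed: int = 0,
    n_boot: int = 200,
) -> dict:
    """Operating characteristics of the cycle-stability check.

    ``n_sims`` paired draws: a no-drift pair (both cycles from the same
    regime — the check should pass) and a drifted pair (the later cycle's
    upward transition rates scaled by ``drift`` — the check should flag).
    Reports the pass rate under the null and the detection rate under the
    alternative.
    """
    truth = make_truth(scenario)
    shifted = truth.with_drift(drift)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(5 * n_sims).reshape(n_sims, 5) % 2**31
    null_pass = 0
    drift_flag = 0
    design = SurveyDesignSpec(n_per_cycle=n)
    for r in range(n_sims):
        s = seeds[r]
        early = fit_prevalence(
            sample_cross_section(truth, design, "early", int(s[0]), emit_anthropometry=False),
            stratum="early",
        )
        late_null = fit_prevalence(
            sample_cross_section(truth, design, "late0", int(s[1]), emit_anthropometry=False),
            stratum="late0",
        )
        late_drift = fit_prevalence(
            sample_cross_section(shifted, design, "late1", int(s[2]), emit_anthropometry=False),
            stratum="late1",
        )
        rep0 = validate_stability(early, {"later": late_null}, horizon=horizon, n_boot=n_boot, seed=int(s[3]))
        rep1 = validate_stability(early, {"later": late_drift}, horizon=horizon, n_boot=n_boot, seed=int(s[4]))
        null_pass += rep0.stable
        drift_flag += not rep1.stable
    return {
        "n_sims": n_sims,
        "null_pass_rate_pct": 100.0 * null_pass / n_sims,
        "drift_detection_rate_pct": 100.0 * drift_flag / n_sims,
    }
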