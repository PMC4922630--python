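"""Synthetic cohorts with known transition truth.

Every stage of the pipeline is testable without external downloads against
data generated here: age-varying 3x3 one-year Markov transition matrices
with a dominant diagonal and rare two-step moves (the "economy of
movement" regime), longitudinal trajectories evolved under them, and
cross-sectional survey samples with stratified two-PSU-per-stratum designs
and unequal weights.  The generating matrices imply marginal prevalence
curves and true net transition probabilities, so estimator output can be
compared against known truth.

Presets
-------
``early_peak``
    The empirically motivated scenario: the overweight-to-obese net
    transition peaks at age two and declines with age, the
    normal-to-overweight net peaks in the mid-20s, and downward transitions
    become favored in late adulthood.
``adult_peak``
    Flat early-childhood obesity pressure with the normal-to-overweight
    peak in the 20s.
``identity``
    No movement at all; every net transition is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classification import GrowthReference, age_years_to_months
from .transport import net_prob_array, nets_from_prevalence

AGE_LO, AGE_HI = 2, 80
START_AGES = np.arange(AGE_LO, AGE_HI)  # transition matrices for ages 2..79

#: BMI ranges (kg/m^2) used to emit adult anthropometry per category;
#: kept clear of the cut-points so classification round-trips exactly
ADULT_BMI_RANGES = {1: (19.0, 24.9), 2: (25.05, 29.9), 3: (30.05, 44.0)}
#: child BMI-for-age percentile bands per category, likewise boundary-safe
CHILD_PCT_RANGES = {1: (5.0, 84.5), 2: (85.2, 94.8), 3: (95.2, 99.5)}


def toy_growth_reference() -> GrowthReference:
    """Small synthetic LMS table with the qualitative shape of a BMI-for-age
    reference (median dips in early childhood, rises through adolescence).
    Spans 24-246 months for both sexes; used by tests and the generator so
    no real growth-chart file needs to be bundled.
    """
    rows = []
    for sex, bump in (("female", 0.0), ("male", 0.2)):
        for t in np.arange(24, 252, 6):
            m = 15.2 + 1.3 * np.exp(-(t - 24) / 30.0) + 5.5 * (t / 240.0) ** 2 + bump
            rows.append({"sex": sex, "age_months": float(t), "L": -1.5, "M": round(m, 4), "S": 0.12})
    return GrowthReference(pd.DataFrame(rows))


@dataclass
class SyntheticTruth:
    """Generating regime: T[t] moves age (2+t) to (2+t+1); pi is p(age 2)."""

    name: str
    T: np.ndarray  # (78, 3, 3)
    pi: np.ndarray  # (3,)
    two_step_cap: float = 0.01

    def __post_init__(self):
        T = np.asarray(self.T, float)
        if T.shape != (len(START_AGES), 3, 3):
            raise ValueError(f"transition stack must be {(len(START_AGES), 3, 3)}")
        if (T < 0).any():
            raise ValueError("negative transition probabilities")
        if not np.allclose(T.sum(axis=2), 1.0, atol=1e-10):
            raise ValueError("transition rows must sum to 1")
        if T[:, 0, 2].max() > self.two_step_cap + 1e-12 or T[:, 2, 0].max() > self.two_step_cap + 1e-12:
            raise ValueError(f"two-step transition entries exceed the cap {self.two_step_cap}")

    @property
    def ages(self) -> np.ndarray:
        return np.arange(AGE_LO, AGE_HI + 1)

    def prevalence(self) -> np.ndarray:
        """Marginal prevalence p(a) on ages 2..80 via forward products."""
        P = np.empty((len(self.ages), 3))
        P[0] = self.pi
        for t, M in enumerate(self.T):
            P[t + 1] = P[t] @ M
        return P

    def true_net_flows(self) -> np.ndarray:
        return nets_from_prevalence(self.prevalence())

    def true_net_probs(self) -> np.ndarray:
        """(78, 2 boundaries, 2 directions) true net transition probabilities."""
        return net_prob_array(self.prevalence())

    def with_drift(self, upward_multiplier: float) -> "SyntheticTruth":
        """Secular-shift variant: all upward transition rates scaled.

        Off-diagonal entries above the diagonal are multiplied by the
        factor and diagonals recomputed, modelling a regime whose upward
        pressure differs from the stationary one.
        """
        T = self.T.copy()
        for i in range(3):
            for j in range(i + 1, 3):
                T[:, i, j] *= upward_multiplier
            T[:, i, i] = 1.0 - (T[:, i].sum(axis=1) - T[:, i, i])
        if (T < 0).any():
            raise ValueError("drift multiplier makes transition rows invalid")
        return replace(self, name=f"{self.name}+drift{upward_multiplier:g}", T=T)


def _rates_early_peak(a: np.ndarray):
    # annual category-change hazards, chosen to reproduce the qualitative
    # life-course pattern: strong early-childhood obesity pressure, an
    # adult peak in the move to overweight, net downward drift in old age
    u1 = 0.020 + 0.040 * np.exp(-(((a - 25.0) / 12.0) ** 2))
    u2 = 0.018 + 0.100 * np.exp(-(a - 2.0) / 10.0)
    d1 = 0.004 + 0.075 * (a / 80.0) ** 8
    d2 = 0.004 + 0.012 * (a / 80.0)
    return u1, u2, d1, d2


def _rates_adult_peak(a: np.ndarray):
    u1 = 0.015 + 0.045 * np.exp(-(((a - 24.0) / 10.0) ** 2))
    u2 = np.full_like(a, 0.02, dtype=float)
    d1 = 0.004 + 0.025 * (a / 80.0) ** 2
    d2 = np.full_like(a, 0.008, dtype=float)
    return u1, u2, d1, d2


_PRESETS = {
    "early_peak": (_rates_early_peak, np.array([0.70, 0.15, 0.15])),
    "adult_peak": (_rates_adult_peak, np.array([0.78, 0.14, 0.08])),
    "identity": (None, np.array([0.70, 0.15, 0.15])),
}


def make_truth(scenario: str = "early_peak", two_step: float = 0.002, two_step_cap: float = 0.01) -> SyntheticTruth:
    """Build a named generating regime.

    ``two_step`` is the constant one-year probability of a direct
    normal<->obese jump (capped at ``two_step_cap``, honoring the rarity of
    two-step moves that motivates the economy-of-movement costs).
    """
    if scenario not in _PRESETS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {sorted(_PRESETS)}")
    rates, pi = _PRESETS[scenario]
    a = START_AGES.astype(float)
    T = np.zeros((len(a), 3, 3))
    if rates is None:
        T[:] = np.eye(3)
    else:
        u1, u2, d1, d2 = rates(a)
        eps = two_step  # validated against the cap by SyntheticTruth
        T[:, 0, 1], T[:, 0, 2] = u1, eps
        T[:, 0, 0] = 1.0 - u1 - eps
        T[:, 1, 0], T[:, 1, 2] = d1, u2
        T[:, 1, 1] = 1.0 - d1 - u2
        T[:, 2, 1], T[:, 2, 0] = d2, eps
        T[:, 2, 2] = 1.0 - d2 - eps
    return SyntheticTruth(name=scenario, T=T, pi=pi.copy(), two_step_cap=two_step_cap)


def simulate_trajectories(
    truth: SyntheticTruth,
    n: int,
    seed: int,
    start_age: int = AGE_LO,
    end_age: int = AGE_HI,
) -> pd.DataFrame:
    """Longitudinal records: ``n`` individuals observed at every age in
    [start_age, end_age], evolving by the truth's one-year matrices.
    Returns tidy rows (id, age, category).
    """
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    ages = np.arange(start_age, end_age + 1)
    state = rng.choice(3, size=n, p=truth.pi / truth.pi.sum())
    out_age = np.empty((len(ages), n), dtype=np.int64)
    out_cat = np.empty((len(ages), n), dtype=np.int64)
    for t, a in enumerate(ages):
        out_age[t] = a
        out_cat[t] = state + 1
        if a < end_age:
            M = truth.T[a - AGE_LO]
            u = rng.random(n)
            cum = np.cumsum(M[state], axis=1)
            state = (u[:, None] > cum).sum(axis=1)
    ids = np.char.add("tr", np.arange(n).astype(str))
    return pd.DataFrame(
        {
            "id": np.tile(ids, len(ages)),
            "age": out_age.ravel(),
            "category": out_cat.ravel(),
        }
    ).sort_values(["id", "age"], kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class SurveyDesignSpec:
    """Stratified multistage design emulation.

    Weights are the product of a stratum-level sampling-fraction factor and
    individual lognormal noise, independent of weight category, so the
    weighted category distribution stays unbiased.  PSU effects are
    mean-zero shifts on the non-reference category logits, inducing
    within-PSU correlation.
    """

    n_strata: int = 14
    psus_per_stratum: int = 2
    psu_effect_scale: float = 0.05
    weight_sigma: float = 0.5
    stratum_weight_sigma: float = 0.3
    n_per_cycle: int = 7000
    pregnancy_rate: float = 0.01
    amputation_rate: float = 0.002
    missing_bmi_rate: float = 0.005

    def __post_init__(self):
        if self.psu_effect_scale > 0 and self.psus_per_stratum < 2:
            raise ValueError("clustered designs need >= 2 PSUs per stratum")


def sample_cross_section(
    truth: SyntheticTruth,
    design: SurveyDesignSpec | None = None,
    cycle: str = "cycle1",
    seed: int = 0,
    n: int | None = None,
    sex: str = "female",
    group: str = "GroupA",
    ref: GrowthReference | None = None,
    emit_anthropometry: bool = True,
) -> pd.DataFrame:
    """One survey cycle of individual records drawn from the truth's marginals.

    Ages are uniform on 2..80; the weight category at age ``a`` follows the
    truth's marginal prevalence p(a), perturbed by the PSU logit effect;
    BMI (adults) or an LMS-consistent BMI (children, via ``ref``) is then
    emitted inside the category's range so the classification stage can be
    exercised end to end.  A small fraction of records carries exclusion
    flags or missing anthropometry, independent of category.
    """
    design = design or SurveyDesignSpec()
    rng = np.random.default_rng(seed)
    ref = ref or toy_growth_reference()
    n = design.n_per_cycle if n is None else n

    P = truth.prevalence()
    ages = rng.integers(AGE_LO, AGE_HI + 1, size=n)

    strata = rng.integers(0, design.n_strata, size=n)
    psus = rng.integers(0, design.psus_per_stratum, size=n)
    psu_fx = rng.normal(0.0, design.psu_effect_scale, size=(design.n_strata, design.psus_per_stratum, 2))
    stratum_factor = np.exp(rng.normal(0.0, design.stratum_weight_sigma, size=design.n_strata))

    base_p = P[ages - AGE_LO]  # (n, 3)
    with np.errstate(divide="ignore"):
        logits = np.log(np.clip(base_p, 1e-12, None))
    logits[:, 1:] += psu_fx[strata, psus]
    logits -= logits.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(n)
    cats = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1) + 1

    weights = stratum_factor[strata] * np.exp(rng.normal(0.0, design.weight_sigma, size=n))
    weights *= 10000.0 / weights.mean()  # survey-weight-like scale; estimators are scale-free

    if not emit_anthropometry:
        # fast path for simulation studies that start from classified records
        return pd.DataFrame(
            {
                "id": [f"{cycle}-{i}" for i in range(n)],
                "age": ages,
                "sex": sex,
                "group": group,
                "survey_weight": weights,
                "stratum": [f"s{s}" for s in strata],
                "psu": [f"p{p}" for p in psus],
                "cycle": cycle,
                "category": cats,
                "true_category": cats,
            }
        )

    bmi = np.empty(n)
    pct = np.full(n, np.nan)
    is_child = ages < 20
    for c, (lo, hi) in ADULT_BMI_RANGES.items():
        m = (~is_child) & (cats == c)
        bmi[m] = rng.uniform(lo, hi, size=int(m.sum()))
    for c, (lo, hi) in CHILD_PCT_RANGES.items():
        m = is_child & (cats == c)
        pct[m] = rng.uniform(lo, hi, size=int(m.sum()))
    # invert the LMS reference per age so emitted child BMIs classify back
    # to the generating category exactly
    from scipy.stats import norm as _norm

    for a in np.unique(ages[is_child]):
        idx = np.flatnonzero(is_child & (ages == a))
        L, M, S = ref.lms_at(sex, age_years_to_months(int(a)))
        z = _norm.ppf(pct[idx] / 100.0)
        if abs(L) < 1e-12:
            bmi[idx] = M * np.exp(S * z)
        else:
            bmi[idx] = M * (1.0 + L * S * z) ** (1.0 / L)

    height = np.clip(rng.normal(1.66 if sex == "female" else 1.76, 0.09, size=n), 1.2, 2.1)
    height[is_child] = np.clip(
        0.85 + 0.055 * ages[is_child] + rng.normal(0, 0.04, size=int(is_child.sum())), 0.8, 2.0
    )
    weight_kg = bmi * height**2

    fertile = (~is_child | (ages >= 15)) & (ages <= 44) & (sex == "female")
    pregnant = fertile & (rng.random(n) < design.pregnancy_rate / max(fertile.mean(), 1e-9))
    amputation = rng.random(n) < design.amputation_rate
    missing = rng.random(n) < design.missing_bmi_rate
    bmi_out = bmi.copy()
    bmi_out[missing] = np.nan
    wkg = weight_kg.copy()
    wkg[missing] = np.nan

    return pd.DataFrame(
        {
            "id": [f"{cycle}-{i}" for i in range(n)],
            "age": ages,
            "sex": sex,
            "group": group,
            "weight_kg": wkg,
            "height_m": height,
            "bmi": bmi_out,
            "bmi_percentile": np.nan,  # the pipeline recomputes it from the reference
            "survey_weight": weights,
            "stratum": [f"s{s}" for s in strata],
            "psu": [f"p{p}" for p in psus],
            "cycle": cycle,
            "pregnant_or_recent": pregnant,
            "amputation": amputation,
            "true_category": cats,
        }
    )
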