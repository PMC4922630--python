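"""BMI-based weight classification and eligibility filtering.

Converts raw anthropometry into the three ordered weight categories used
throughout the pipeline — normal weight, overweight and obese — using the
adult BMI cut-points (<25, 25-29.99, >=30 kg/m^2) for ages >= 20 and
sex-specific growth-reference percentiles (<85th, 85th-95th, >95th) for
ages 2-19.  Underweight adults (BMI < 18.5) are folded into normal weight
and counted, since the three-state model does not carry a separate
underweight state and underweight is rare (<1%) in the target populations.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

#: Adult BMI cut-points (kg/m^2); intervals are half-open: [0,25), [25,30), [30,inf)
ADULT_CUTPOINTS = (25.0, 30.0)
#: Child BMI-percentile boundaries: <85 normal, [85,95] overweight, >95 obese
CHILD_PERCENTILES = (85.0, 95.0)
#: BMI above this is treated as a data error, not a measurement
ABSURD_BMI = 150.0
UNDERWEIGHT_BMI = 18.5
#: Age (years) at which classification switches from percentile to cut-point
ADULT_AGE = 20


class WeightCategory(enum.IntEnum):
    """Ordered weight categories; the order is load-bearing for the transport model."""

    NORMAL = 1
    OVERWEIGHT = 2
    OBESE = 3

    @property
    def label(self) -> str:
        return self.name.lower()


CATEGORY_LABELS = [c.label for c in WeightCategory]

# canonical column set for individual-level input files
RECORD_COLUMNS = [
    "id", "age", "sex", "group", "weight_kg", "height_m", "bmi",
    "bmi_percentile", "survey_weight", "stratum", "psu", "cycle",
    "pregnant_or_recent", "amputation",
]


class ClassificationError(ValueError):
    """Raised for out-of-contract anthropometry (nonpositive/absurd BMI, bad percentile)."""


def classify_adult(bmi: float) -> WeightCategory:
    """Classify an adult (age >= 20) BMI into a weight category.

    Uses half-open intervals [0,25) -> normal, [25,30) -> overweight,
    [30,inf) -> obese.  BMI < 18.5 (underweight) maps to normal weight.
    """
    if not np.isfinite(bmi) or bmi <= 0:
        raise ClassificationError(f"nonpositive or non-finite BMI: {bmi!r}")
    if bmi > ABSURD_BMI:
        raise ClassificationError(f"implausible BMI > {ABSURD_BMI}: {bmi!r}")
    if bmi < ADULT_CUTPOINTS[0]:
        return WeightCategory.NORMAL
    if bmi < ADULT_CUTPOINTS[1]:
        return WeightCategory.OVERWEIGHT
    return WeightCategory.OBESE


def classify_child(percentile: float) -> WeightCategory:
    """Classify a child (age 2-19) BMI-for-age percentile.

    <85th percentile -> normal; 85th through 95th inclusive -> overweight;
    >95th -> obese.
    """
    if not np.isfinite(percentile) or not (0.0 <= percentile <= 100.0):
        raise ClassificationError(f"percentile outside [0, 100]: {percentile!r}")
    if percentile < CHILD_PERCENTILES[0]:
        return WeightCategory.NORMAL
    if percentile <= CHILD_PERCENTILES[1]:
        return WeightCategory.OVERWEIGHT
    return WeightCategory.OBESE


@dataclass
class GrowthReference:
    """Sex-specific LMS growth reference for BMI-for-age.

    The LMS parameterization describes the age-varying BMI distribution with
    a Box-Cox power ``L``, median ``M`` (kg/m^2) and coefficient of variation
    ``S``.  Parameters are linearly interpolated to the requested age in
    months.  The table must cover at least ages 24-240 months for use with
    the child classifier; the real CDC growth-chart file shares this layout
    (columns sex, age_months, L, M, S).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sex", "age_months", "L", "M", "S"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"growth reference missing columns: {sorted(missing)}")
        if (self.table["M"] <= 0).any() or (self.table["S"] <= 0).any():
            raise ValueError("growth reference requires M > 0 and S > 0")
        for sex, sub in self.table.groupby("sex"):
            if not sub["age_months"].is_monotonic_increasing or sub["age_months"].duplicated().any():
                raise ValueError(f"age_months must be strictly increasing within sex {sex!r}")

    @classmethod
    def from_csv(cls, path) -> "GrowthReference":
        return cls(pd.read_csv(path))

    def span(self, sex: str) -> tuple[float, float]:
        sub = self.table[self.table["sex"] == sex]
        if sub.empty:
            raise ValueError(f"growth reference has no rows for sex {sex!r}")
        return float(sub["age_months"].min()), float(sub["age_months"].max())

    def lms_at(self, sex: str, age_months: float) -> tuple[float, float, float]:
        """Linearly interpolated (L, M, S) at ``age_months``."""
        sub = self.table[self.table["sex"] == sex]
        lo, hi = self.span(sex)
        if not (lo <= age_months <= hi):
            raise ValueError(
                f"age {age_months} months outside growth-reference span [{lo}, {hi}] for sex {sex!r}"
            )
        x = sub["age_months"].to_numpy(float)
        return tuple(
            float(np.interp(age_months, x, sub[c].to_numpy(float))) for c in ("L", "M", "S")
        )

    def bmi_at_percentile(self, sex: str, age_months: float, percentile: float) -> float:
        """Inverse of :func:`percentile_from_lms` (used by the synthetic generator)."""
        L, M, S = self.lms_at(sex, age_months)
        z = norm.ppf(percentile / 100.0)
        if abs(L) < 1e-12:
            return M * float(np.exp(S * z))
        return M * float((1.0 + L * S * z) ** (1.0 / L))


def percentile_from_lms(bmi: float, sex: str, age_months: float, ref: GrowthReference) -> float:
    """BMI-for-age percentile via the LMS method.

    z = ((bmi/M)^L - 1) / (L*S) for L != 0, z = ln(bmi/M)/S for L = 0;
    percentile = 100 * Phi(z).
    """
    if not np.isfinite(bmi) or bmi <= 0:
        raise ClassificationError(f"nonpositive or non-finite BMI: {bmi!r}")
    L, M, S = ref.lms_at(sex, age_months)
    if abs(L) < 1e-12:
        z = np.log(bmi / M) / S
    else:
        z = ((bmi / M) ** L - 1.0) / (L * S)
    return 100.0 * float(norm.cdf(z))


def age_years_to_months(age_years: float, midpoint: bool = True) -> float:
    """Integer-year ages are placed at the year's midpoint (12a + 6 months) by default."""
    months = 12.0 * age_years
    if midpoint and float(age_years) == int(age_years):
        months += 6.0
    return months


@dataclass
class ExclusionLog:
    """Counts of removed records by reason, plus bookkeeping notes."""

    counts: dict = field(default_factory=dict)
    underweight_folded: int = 0
    excluded_ids: dict = field(default_factory=dict)

    def add(self, reason: str, record_id: str) -> None:
        self.counts[reason] = self.counts.get(reason, 0) + 1
        self.excluded_ids.setdefault(reason, []).append(str(record_id))

    @property
    def total_excluded(self) -> int:
        return sum(self.counts.values())

    def to_json(self) -> str:
        return json.dumps(
            {
                "excluded_by_reason": self.counts,
                "total_excluded": self.total_excluded,
                "underweight_folded_into_normal": self.underweight_folded,
                "excluded_ids": self.excluded_ids,
            },
            indent=2,
        )


def apply_exclusions(records: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the eligibility filters, returning eligible records and a log.

    Exclusion reasons, checked in order so each record gets exactly one:
    ``age<2`` (ages 0-1), ``pregnancy``, ``amputation``, ``missing_bmi``,
    ``implausible_bmi`` (BMI <= 0 or > 150).  The returned frame gains a
    resolved ``bmi`` column (stored BMI, else weight/height^2).
    """
    log = ExclusionLog()
    df = records.reset_index(drop=True)
    ids = df["id"].astype(str) if "id" in df.columns else pd.Series(np.arange(len(df)).astype(str))

    bmi = pd.to_numeric(df["bmi"], errors="coerce") if "bmi" in df.columns else pd.Series(np.nan, index=df.index)
    if {"weight_kg", "height_m"}.issubset(df.columns):
        w = pd.to_numeric(df["weight_kg"], errors="coerce")
        h = pd.to_numeric(df["height_m"], errors="coerce")
        derived = w / h**2
        derived[(w <= 0) | (h <= 0)] = np.nan
        bmi = bmi.where(np.isfinite(bmi) & (bmi > 0), derived)

    def col(name):
        return df[name].fillna(False).astype(bool) if name in df.columns else pd.Series(False, index=df.index)

    reasons = pd.Series("", index=df.index, dtype=object)
    checks = [
        ("age<2", df["age"] < 2),
        ("pregnancy", col("pregnant_or_recent")),
        ("amputation", col("amputation")),
        ("missing_bmi", ~np.isfinite(bmi)),
        ("implausible_bmi", np.isfinite(bmi) & ((bmi <= 0) | (bmi > ABSURD_BMI))),
    ]
    for reason, mask in checks:
        hit = mask & (reasons == "")
        reasons[hit] = reason
    for reason, _ in checks:
        for rid in ids[reasons == reason]:
            log.add(reason, rid)

    eligible = df[reasons == ""].copy()
    eligible["bmi"] = bmi[reasons == ""]
    eligible = eligible.reset_index(drop=True)
    if eligible.empty:
        import warnings

        warnings.warn("no eligible records after exclusions", stacklevel=2)
    return eligible, log


def classify_records(
    records: pd.DataFrame,
    ref: GrowthReference | None = None,
    *,
    midpoint_months: bool = True,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Full classification stage: exclusions, then one category per record.

    Children (age < 20) are classified by BMI-for-age percentile; a stored
    ``bmi_percentile`` is used if present, otherwise it is computed from the
    growth reference (required in that case).  Adults use the BMI cut-points.
    Adds ``category`` (int 1..3) and ``category_label`` columns.
    """
    eligible, log = apply_exclusions(records)
    if eligible.empty:
        eligible = eligible.assign(category=pd.Series(dtype=int), category_label=pd.Series(dtype=str))
        return eligible, log

    bmi = eligible["bmi"].to_numpy(float)
    age = eligible["age"].to_numpy(float)
    cats = np.zeros(len(eligible), dtype=int)

    adult = age >= ADULT_AGE
    cats[adult] = 1 + np.digitize(bmi[adult], ADULT_CUTPOINTS)
    log.underweight_folded = int((adult & (bmi < UNDERWEIGHT_BMI)).sum())

    child = ~adult
    if child.any():
        pct = (
            pd.to_numeric(eligible["bmi_percentile"], errors="coerce").to_numpy(float)
            if "bmi_percentile" in eligible.columns
            else np.full(len(eligible), np.nan)
        )
        need = child & ~np.isfinite(pct)
        if need.any():
            if ref is None:
                bad = eligible.loc[need, "id"].iloc[0] if "id" in eligible.columns else "?"
                raise ClassificationError(
                    f"record {bad}: child ages require a growth reference or a stored bmi_percentile"
                )
            sexes = eligible["sex"].to_numpy()
            for (a, s), idx in pd.DataFrame({"a": age, "s": sexes}).groupby(["a", "s"]).groups.items():
                idx = np.asarray(idx)
                idx = idx[need[idx]]
                if idx.size == 0:
                    continue
                months = age_years_to_months(a, midpoint=midpoint_months)
                L, M, S = ref.lms_at(s, months)
                z = (
                    np.log(bmi[idx] / M) / S
                    if abs(L) < 1e-12
                    else ((bmi[idx] / M) ** L - 1.0) / (L * S)
                )
                pct[idx] = 100.0 * norm.cdf(z)
        bad = child & ~((pct >= 0) & (pct <= 100))
        if bad.any():
            raise ClassificationError(f"percentile outside [0, 100] for {int(bad.sum())} child records")
        cpct = pct[child]
        ccat = np.where(cpct < CHILD_PERCENTILES[0], 1, np.where(cpct <= CHILD_PERCENTILES[1], 2, 3))
        cats[child] = ccat
    eligible = eligible.assign(
        category=cats, category_label=[WeightCategory(c).label for c in cats]
    )
    return eligible, log
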