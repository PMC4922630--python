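import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from nettrans.classification import (
    ClassificationError,
    GrowthReference,
    WeightCategory,
    age_years_to_months,
    apply_exclusions,
    classify_adult,
    classify_child,
    classify_records,
    percentile_from_lms,
)


@pytest.mark.parametrize(
    "bmi, expected",
    [
        (24.999, WeightCategory.NORMAL),  # half-open upper boundary
        (25.0, WeightCategory.OVERWEIGHT),
        (29.99, WeightCategory.OVERWEIGHT),
        (30.0, WeightCategory.OBESE),
        (17.0, WeightCategory.NORMAL),  # underweight folds into normal
        (45.0, WeightCategory.OBESE),
    ],
)
def test_adult_cutpoints(bmi, expected):
    assert classify_adult(bmi) is expected


@pytest.mark.parametrize("bmi", [-1.0, 0.0, 151.0, float("nan")])
def test_adult_rejects_impossible_bmi(bmi):
    with pytest.raises(ClassificationError):
        classify_adult(bmi)


@pytest.mark.parametrize(
    "pct, expected",
    [
        (84.99, WeightCategory.NORMAL),
        (85.0, WeightCategory.OVERWEIGHT),  # 85th inclusive
        (95.0, WeightCategory.OVERWEIGHT),  # 95th inclusive
        (95.01, WeightCategory.OBESE),
        (50.0, WeightCategory.NORMAL),
    ],
)
def test_child_percentile_classes(pct, expected):
    assert classify_child(pct) is expected


def test_child_rejects_out_of_range_percentile():
    for pct in (-0.1, 100.1):
        with pytest.raises(ClassificationError):
            classify_child(pct)


@given(st.floats(min_value=10, max_value=60), st.floats(min_value=0, max_value=10))
def test_adult_classification_monotone(bmi, delta):
    assert classify_adult(bmi + delta) >= classify_adult(bmi)


@pytest.fixture(scope="module")
def flat_ref():
    """Constant-LMS reference so examples are hand-computable."""
    rows = []
    for sex in ("female", "male"):
        for t in (24, 120, 240):
            rows.append({"sex": sex, "age_months": t, "L": -2.0, "M": 16.0, "S": 0.1})
    return GrowthReference(pd.DataFrame(rows))


class TestLMS:
    def test_median_bmi_gives_50th_percentile(self, flat_ref):
        assert percentile_from_lms(16.0, "female", 100, flat_ref) == pytest.approx(50.0)

    def test_hand_computed_example(self, flat_ref):
        # z = ((20/16)^-2 - 1)/(-2*0.1) = 1.8 exactly
        expected = 100 * norm.cdf(1.8)
        assert percentile_from_lms(20.0, "male", 120, flat_ref) == pytest.approx(expected, abs=1e-9)

    def test_log_branch_when_l_zero(self):
        ref = GrowthReference(
            pd.DataFrame(
                {"sex": ["female"] * 2, "age_months": [24, 240], "L": [0.0, 0.0], "M": [16.0, 16.0], "S": [0.1, 0.1]}
            )
        )
        bmi = 16.0 * np.exp(0.1)  # M * e^S -> z = 1
        assert percentile_from_lms(bmi, "female", 100, ref) == pytest.approx(100 * norm.cdf(1.0))

    def test_age_outside_span_names_span(self, flat_ref):
        with pytest.raises(ValueError, match=r"\[24.*240"):
            flat_ref.lms_at("female", 260)

    @given(st.floats(min_value=12, max_value=30), st.floats(min_value=0.1, max_value=5))
    def test_strictly_increasing_in_bmi(self, flat_ref, bmi, delta):
        lo = percentile_from_lms(bmi, "female", 120, flat_ref)
        hi = percentile_from_lms(bmi + delta, "female", 120, flat_ref)
        assert hi > lo

    def test_percentile_bmi_roundtrip(self, flat_ref):
        bmi = flat_ref.bmi_at_percentile("female", 120, 92.0)
        assert percentile_from_lms(bmi, "female", 120, flat_ref) == pytest.approx(92.0, abs=1e-9)


def _record(**kw):
    base = dict(
        id="r1", age=40, sex="female", group="GroupA", weight_kg=70.0, height_m=1.7,
        bmi=70.0 / 1.7**2, bmi_percentile=np.nan, survey_weight=1.0, stratum="s", psu="p",
        cycle="c", pregnant_or_recent=False, amputation=False,
    )
    base.update(kw)
    return base


class TestExclusions:
    def test_reasons_and_retention(self):
        df = pd.DataFrame(
            [
                _record(id="keep"),
                _record(id="preg", pregnant_or_recent=True),
                _record(id="amp", amputation=True),
                _record(id="baby", age=1),
                _record(id="nobmi", bmi=np.nan, weight_kg=np.nan, height_m=np.nan),
                _record(id="huge", bmi=200.0),
            ]
        )
        eligible, log = apply_exclusions(df)
        assert list(eligible["id"]) == ["keep"]
        assert log.counts == {
            "pregnancy": 1, "amputation": 1, "age<2": 1, "missing_bmi": 1, "implausible_bmi": 1,
        }

    def test_single_reason_per_record(self):
        # pregnant AND amputation: only the first reason in the documented order is logged
        df = pd.DataFrame([_record(id="both", pregnant_or_recent=True, amputation=True)])
        _, log = apply_exclusions(df)
        assert log.counts == {"pregnancy": 1}

    def test_bmi_derived_from_weight_height(self):
        df = pd.DataFrame([_record(id="derive", bmi=np.nan)])
        eligible, _ = apply_exclusions(df)
        assert eligible["bmi"].iloc[0] == pytest.approx(70.0 / 1.7**2, abs=1e-9)

    def test_empty_output_warns(self):
        df = pd.DataFrame([_record(id="p", pregnant_or_recent=True)])
        with pytest.warns(UserWarning, match="no eligible"):
            apply_exclusions(df)


class TestClassifyRecords:
    def test_each_record_classified_or_logged(self, flat_ref):
        df = pd.DataFrame(
            [
                _record(id="adult", age=30, bmi=27.0),
                _record(id="child", age=10, bmi=20.0),
                _record(id="preg", pregnant_or_recent=True),
            ]
        )
        out, log = classify_records(df, ref=flat_ref)
        assert len(out) + log.total_excluded == len(df)
        assert set(out["category"]) <= {1, 2, 3}

    def test_child_without_reference_or_percentile_errors(self):
        df = pd.DataFrame([_record(id="child", age=5, bmi=17.0)])
        with pytest.raises(ClassificationError, match="growth reference"):
            classify_records(df, ref=None)

    def test_stored_percentile_takes_precedence(self):
        df = pd.DataFrame([_record(id="child", age=5, bmi=17.0, bmi_percentile=96.0)])
        out, _ = classify_records(df, ref=None)
        assert out["category"].iloc[0] == 3

    def test_underweight_fold_counted(self):
        df = pd.DataFrame([_record(id="uw", bmi=17.5)])
        out, log = classify_records(df)
        assert out["category"].iloc[0] == 1
        assert log.underweight_folded == 1

    def test_adult_child_switch_at_20(self, flat_ref):
        # BMI 26: overweight as adult; far above the flat reference's 95th pct as child
        df = pd.DataFrame([_record(id="a20", age=20, bmi=26.0), _record(id="c19", age=19, bmi=26.0)])
        out, _ = classify_records(df, ref=flat_ref)
        assert out.set_index("id").loc["a20", "category"] == 2
        assert out.set_index("id").loc["c19", "category"] == 3


def test_midpoint_month_convention():
    assert age_years_to_months(5) == 66.0
    assert age_years_to_months(5.25) == 63.0  # fractional ages are used as-is


def test_synthetic_roundtrip_agreement(truth_early, toy_ref):
    """Emitted BMIs classify back to the generating category (>=99.9%)."""
    from nettrans import sample_cross_section

    df = sample_cross_section(truth_early, n=8000, seed=99, ref=toy_ref)
    out, _ = classify_records(df, ref=toy_ref)
    agree = (out["category"] == out["true_category"]).mean()
    assert agree >= 0.999
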