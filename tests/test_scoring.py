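"""Single-indicator grading, composite totals and five-grade classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrpfnorms import (
    FitnessScorer,
    classify,
    cohort_distribution,
    composite_total,
    make_bmi_bands,
    make_centile_table,
    make_hrpf_bands,
    expert_final_weights,
    score_indicator,
)
from hrpfnorms.reference import BMI_SCHEME, HRPF_SCHEME
from hrpfnorms.scoring import CATEGORIES

INDICATOR_ORDER = ("bmi", "shuttle_vo2max", "hand_grip", "modified_pullup", "plank")


@pytest.fixture(scope="module")
def boys12_grip_bands():
    # published hand-grip centile row for 12-year-old boys
    tab = pd.DataFrame([{
        "indicator": "hand_grip", "sex": "boys", "age": 12,
        "p3": 8.14, "p10": 11.56, "p35": 18.63, "p65": 27.03, "p90": 40.21,
    }])
    return make_hrpf_bands(tab)


@pytest.fixture(scope="module")
def boys12_bmi_bands():
    tab = pd.DataFrame([{
        "indicator": "bmi", "sex": "boys", "age": 12,
        "p5": 13.08, "p15": 14.32, "p85": 19.14, "p95": 20.81,
    }])
    return make_bmi_bands(tab)


class TestScoreIndicator:
    def test_median_grip_scores_medium(self, boys12_grip_bands):
        assert score_indicator(22.53, boys12_grip_bands) == 3

    def test_obese_threshold_scores_one(self, boys12_bmi_bands):
        assert score_indicator(20.82, boys12_bmi_bands) == 1

    def test_below_minimum_line_gets_no_score(self, boys12_grip_bands):
        assert score_indicator(8.00, boys12_grip_bands) is None
        assert score_indicator(8.13, boys12_grip_bands) is None
        assert score_indicator(8.14, boys12_grip_bands) == 1

    def test_bmi_below_lean_edge_still_scores_lean(self, boys12_bmi_bands):
        assert score_indicator(11.00, boys12_bmi_bands) == 1

    def test_rounding_before_lookup(self, boys12_grip_bands):
        # 11.565 rounds half-up to 11.57, the poor band's lower edge
        assert score_indicator(11.565, boys12_grip_bands) == 2
        assert score_indicator(11.5649, boys12_grip_bands) == 1

    def test_empty_band_slice_errors(self, boys12_grip_bands):
        with pytest.raises(KeyError):
            score_indicator(20.0, boys12_grip_bands.iloc[0:0])


class TestCompositeTotal:
    def test_worked_example_total(self):
        """Published worked example: scores (1,3,2,3,4) with the final
        coefficients give 2.2668 (the source's own printed 2.247 is not
        consistent with its coefficients; the category, Poor, is)."""
        scores = dict(zip(INDICATOR_ORDER, (1, 3, 2, 3, 4)))
        total, renorm = composite_total(scores, expert_final_weights())
        assert total == pytest.approx(2.2668, abs=1e-9)
        assert not renorm
        assert classify(total) == "Poor"

    @pytest.mark.parametrize("score, expected", [(5, 4.979), (1, 0.9958)])
    def test_uniform_scores(self, score, expected):
        scores = {k: score for k in INDICATOR_ORDER}
        total, _ = composite_total(scores, expert_final_weights())
        assert total == pytest.approx(expected, abs=1e-9)

    def test_unscored_indicator_renormalises(self):
        scores = dict(zip(INDICATOR_ORDER, (1, 3, 2, None, 4)))
        total, renorm = composite_total(scores, expert_final_weights())
        assert renorm
        remaining = [1, 3, 2, 4]
        assert min(remaining) * 0.9958 <= total <= max(remaining) * 0.9958

    def test_all_unscored_errors(self):
        with pytest.raises(ValueError, match="no scored"):
            composite_total({k: None for k in INDICATOR_ORDER}, expert_final_weights())

    @given(
        scores=st.tuples(*[st.integers(1, 5)] * 5),
        bump=st.integers(0, 4),
    )
    @settings(max_examples=100, deadline=None)
    def test_raising_one_score_never_lowers_total(self, scores, bump):
        w = expert_final_weights()
        base = dict(zip(INDICATOR_ORDER, scores))
        raised = dict(base)
        raised[INDICATOR_ORDER[bump]] = min(5, scores[bump] + 1)
        t0, _ = composite_total(base, w)
        t1, _ = composite_total(raised, w)
        assert t1 >= t0
        assert CATEGORIES.index(classify(t1)) >= CATEGORIES.index(classify(t0))


class TestClassify:
    @pytest.mark.parametrize(
        "total, category",
        [
            (2.247, "Poor"),
            (1.4999, "Very poor"), (1.5, "Poor"),
            (2.4999, "Poor"), (2.5, "Medium"),
            (3.4999, "Medium"), (3.5, "Good"),
            (4.4999, "Good"), (4.5, "Excellent"),
            (5.0, "Excellent"),
        ],
    )
    def test_boundaries(self, total, category):
        assert classify(total) == category

    @pytest.mark.parametrize("bad", [0.0, -1.0, 5.001])
    def test_out_of_range_errors(self, bad):
        with pytest.raises(ValueError):
            classify(bad)

    @given(total=st.floats(0.001, 5.0))
    @settings(max_examples=200, deadline=None)
    def test_every_total_maps_to_exactly_one_category(self, total):
        assert classify(total) in CATEGORIES


class TestCohortDistribution:
    def test_identical_records_concentrate(self):
        res = pd.DataFrame({"category": ["Medium"] * 7})
        dist = cohort_distribution(res)
        assert dist["Medium"] == 100.0
        assert dist.drop("Medium").sum() == 0.0

    def test_percentages_match_counts(self):
        cats = ["Poor"] * 3 + ["Medium"] * 5 + ["Good"] * 2
        dist = cohort_distribution(pd.DataFrame({"category": cats}))
        assert dist["Poor"] == 30.0 and dist["Medium"] == 50.0 and dist["Good"] == 20.0
        assert dist.sum() == pytest.approx(100.0, abs=0.3)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            cohort_distribution(pd.DataFrame({"category": []}))


@pytest.fixture(scope="module")
def scorer():
    from hrpfnorms.cohort import generating_curves

    frames = []
    for (ind, sex), curve in generating_curves().items():
        if ind == "bmi":
            frames.append(make_bmi_bands(make_centile_table(curve, BMI_SCHEME)))
        else:
            frames.append(make_hrpf_bands(make_centile_table(curve, HRPF_SCHEME)))
    return FitnessScorer(bands=pd.concat(frames, ignore_index=True)).fit()


class TestFitnessScorer:

    def test_scores_default_cohort(self, scorer, default_cohort):
        results = scorer.transform(default_cohort.head(200))
        assert {"id", "total", "category", "flags"}.issubset(results.columns)
        assert results.total.between(0, 5, inclusive="right").all()

    def test_modal_class_is_medium_on_own_norms(self, scorer, default_cohort):
        """A cohort scored against its own generating norms centres on
        Medium, with all five grades populated."""
        dist = cohort_distribution(scorer.transform(default_cohort))
        assert dist.idxmax() == "Medium"
        assert (dist > 0).all()

    def test_missing_measurement_flagged_and_renormalised(self, scorer, default_cohort):
        rec = default_cohort.head(1).copy()
        rec.loc[rec.index[0], "plank"] = np.nan
        out = scorer.transform(rec)
        assert "missing:plank" in out.iloc[0]["flags"]
        assert "renormalized" in out.iloc[0]["flags"]

    def test_predict_returns_categories(self, scorer, default_cohort):
        pred = scorer.predict(default_cohort.head(50))
        assert set(pred) <= set(CATEGORIES)

    def test_unfitted_scorer_errors(self, default_cohort):
        with pytest.raises(AttributeError):
            FitnessScorer(bands=pd.DataFrame()).transform(default_cohort)

    def test_drop_mode_emits_no_composite(self, scorer, default_cohort):
        rec = default_cohort.head(3).copy()
        rec.loc[rec.index[0], "plank"] = np.nan
        dropper = FitnessScorer(bands=scorer.bands, on_unscored="drop").fit()
        out = dropper.transform(rec)
        assert np.isnan(out.iloc[0]["total"])
        assert "no_composite" in out.iloc[0]["flags"]
        # unaffected records still classify, and the summary excludes the rest
        assert out.iloc[1]["category"] in CATEGORIES
        dist = cohort_distribution(out)
        assert dist.sum() == pytest.approx(100.0, abs=0.3)

    def test_bad_unscored_mode_rejected(self, scorer):
        with pytest.raises(ValueError, match="on_unscored"):
            FitnessScorer(bands=scorer.bands, on_unscored="ignore").fit()
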