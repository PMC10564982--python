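"""Centile tables and grade-band construction."""

import numpy as np
import pandas as pd
import pytest

from hrpfnorms import (
    BMI_SCHEME,
    HRPF_SCHEME,
    LMSTriple,
    ReferenceCurve,
    make_bmi_bands,
    make_centile_table,
    make_hrpf_bands,
    random_sample,
)
from hrpfnorms.reference import bands_from_edges, chart_data
from hrpfnorms.norms import printed_band_edges


class TestCentileTable:
    def test_boys_bmi_row_12_matches_published(self, curves):
        tab = make_centile_table(curves[("bmi", "boys")], BMI_SCHEME)
        row = tab[tab.age == 12].iloc[0]
        assert (row.p5, row.p50, row.p90, row.p95) == (13.08, 16.59, 19.81, 20.81)

    def test_girls_grip_p90_row_12(self, curves):
        tab = make_centile_table(curves[("hand_grip", "girls")], HRPF_SCHEME)
        assert tab[tab.age == 12].iloc[0].p90 == 19.87

    def test_full_boys_grip_row_12(self, curves):
        # published cells carry their own rounding: agree to +/-0.015
        tab = make_centile_table(curves[("hand_grip", "boys")], HRPF_SCHEME)
        row = tab[tab.age == 12].iloc[0]
        got = [row.p3, row.p10, row.p35, row.p50, row.p65, row.p90]
        assert got == pytest.approx([8.14, 11.56, 18.63, 22.53, 27.03, 40.21],
                                    abs=0.015)

    def test_median_only_scheme_equals_mu(self, curves):
        curve = curves[("bmi", "girls")]
        tab = make_centile_table(curve, (50,))
        for r in tab.itertuples():
            assert r.p50 == pytest.approx(curve[int(r.age)].mu, abs=0.005)

    def test_rows_increase_along_percentiles(self, curves):
        tab = make_centile_table(curves[("hand_grip", "boys")], HRPF_SCHEME)
        pcols = [f"p{p}" for p in HRPF_SCHEME]
        assert (tab[pcols].diff(axis=1).iloc[:, 1:] > 0).all().all()

    def test_bad_scheme_rejected(self, curves):
        with pytest.raises(ValueError):
            make_centile_table(curves[("bmi", "boys")], (15, 5))


def printed_centile_row(indicator, sex, age, cells):
    """A one-row centile table holding published cells verbatim."""
    return pd.DataFrame([{"indicator": indicator, "sex": sex, "age": age, **cells}])


class TestBMIBands:
    def test_boys_12_row_matches_published_bands(self):
        # published centile row in, published band row out, edge for edge
        tab = printed_centile_row(
            "bmi", "boys", 12, {"p5": 13.08, "p15": 14.32, "p85": 19.14, "p95": 20.81}
        )
        bands = make_bmi_bands(tab)
        row = {r.label: (r.lo, r.hi, r.score) for r in bands[bands.age == 12].itertuples()}
        assert row["lean"] == (13.08, 14.32, 1)
        assert row["normal"] == (14.33, 19.14, 5)
        assert row["overweight"] == (19.15, 20.81, 3)
        assert row["obese"] == (20.82, float("inf"), 1)

    def test_girls_16_obese_threshold_is_p95_plus_step(self, curves):
        tab = make_centile_table(curves[("bmi", "girls")], BMI_SCHEME)
        bands = make_bmi_bands(tab)
        obese_lo = bands[(bands.age == 16) & (bands.label == "obese")].iloc[0].lo
        p95 = tab[tab.age == 16].iloc[0].p95
        assert obese_lo == pytest.approx(p95 + 0.01, abs=1e-9)

    def test_degenerate_curve_errors(self):
        tab = pd.DataFrame([
            {"indicator": "bmi", "sex": "boys", "age": 12,
             "p5": 15.0, "p15": 17.0, "p85": 17.0, "p95": 21.0}
        ])
        with pytest.raises(ValueError, match="zero-width"):
            make_bmi_bands(tab)

    def test_missing_columns_error(self, curves):
        tab = make_centile_table(curves[("bmi", "boys")], (5, 50, 95))
        with pytest.raises(ValueError, match="p15"):
            make_bmi_bands(tab)

    def test_strict_p5_lean_cut(self):
        # alternative reading: lean is everything at or below P5
        tab = printed_centile_row(
            "bmi", "boys", 12, {"p5": 13.08, "p15": 14.32, "p85": 19.14, "p95": 20.81}
        )
        bands = make_bmi_bands(tab, lean_upper="p5")
        row = {r.label: (r.lo, r.hi) for r in bands.itertuples()}
        assert row["lean"] == (0.01, 13.08)
        assert row["normal"] == (13.09, 19.14)
        with pytest.raises(ValueError, match="lean_upper"):
            make_bmi_bands(tab, lean_upper="p50")


class TestHRPFBands:
    def test_boys_12_grip_row_edge_for_edge(self):
        tab = printed_centile_row(
            "hand_grip", "boys", 12,
            {"p3": 8.14, "p10": 11.56, "p35": 18.63, "p65": 27.03, "p90": 40.21},
        )
        bands = make_hrpf_bands(tab)
        row = {r.label: (r.lo, r.hi, r.score) for r in bands[bands.age == 12].itertuples()}
        assert row["very_poor"] == (8.14, 11.56, 1)
        assert row["poor"] == (11.57, 18.63, 2)
        assert row["medium"] == (18.64, 27.03, 3)
        assert row["good"] == (27.04, 40.21, 4)
        assert row["excellent"] == (40.22, float("inf"), 5)

    def test_band_partition_covers_every_value(self, curves):
        """Any 2-dp value at or above the lowest edge lands in exactly one band."""
        bands = make_hrpf_bands(
            make_centile_table(curves[("hand_grip", "girls")], HRPF_SCHEME)
        )
        b12 = bands[bands.age == 12]
        lo = b12.lo.min()
        for v in np.round(np.arange(lo, 60.0, 0.01), 2):
            hits = b12[(b12.lo <= v) & (v <= b12.hi)]
            assert len(hits) == 1, f"value {v} hit {len(hits)} bands"

    def test_published_edges_build_contiguous_tables(self):
        bands = bands_from_edges(printed_band_edges())
        # every printed band row yields five bands; next lo = prev hi + 0.01
        assert len(bands) == 4 * 2 * 5 * 5
        for (_, _, _), grp in bands.groupby(["indicator", "sex", "age"]):
            g = grp.sort_values("lo")
            np.testing.assert_allclose(
                g.lo.to_numpy()[1:], g.hi.to_numpy()[:-1] + 0.01, atol=1e-9
            )

    def test_count_valued_indicator_keeps_2dp_edges(self):
        # modified pull-up bands are count-valued yet keep the 0.01 rule
        bands = bands_from_edges(printed_band_edges())
        mpu = bands[(bands.indicator == "modified_pullup")
                    & (bands.sex == "girls") & (bands.age == 12)]
        row = {r.label: (r.lo, r.hi) for r in mpu.itertuples()}
        assert row["very_poor"] == (1.0, 1.13)
        assert row["poor"] == (1.14, 2.35)


class TestGradeMassLaw:
    def test_sample_grade_fractions_match_band_probabilities(self):
        """Scoring draws against their own generating bands recovers the
        designed band masses 7/25/30/25/10% (+3% unscored) within 3 SE."""
        from hrpfnorms import score_indicator

        t = LMSTriple(0.227, 22.53, 0.483)
        curve = ReferenceCurve("hand_grip", "boys", {a: t for a in (12, 13, 14)})
        bands = make_hrpf_bands(make_centile_table(curve, HRPF_SCHEME))
        b12 = bands[bands.age == 12]
        n = 20_000
        draws = random_sample(t, n, seed=123)
        scores = pd.Series([score_indicator(v, b12) for v in draws])
        expected = {1: 0.07, 2: 0.25, 3: 0.30, 4: 0.25, 5: 0.10, None: 0.03}
        for grade, p in expected.items():
            got = (scores.isna().mean() if grade is None
                   else (scores == grade).mean())
            se = np.sqrt(p * (1 - p) / n)
            assert abs(got - p) < 3 * se, f"grade {grade}: {got} vs {p}"


def test_chart_data_long_format(curves):
    tab = make_centile_table(curves[("bmi", "boys")], BMI_SCHEME)
    long = chart_data(tab)
    assert set(long.columns) == {"indicator", "sex", "age", "percentile", "value"}
    assert len(long) == 5 * len(BMI_SCHEME)
    p50 = long[(long.percentile == 50) & (long.age == 12)].iloc[0].value
    assert p50 == 16.59
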