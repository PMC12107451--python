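import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gwgref.zscores import (
    ChartStandard,
    TableStandard,
    Z_Q25,
    Z_Q75,
    external_standard_zscore,
    gwg_zscore,
    iom_adequacy_ratio,
    iom_recommended,
    total_gwg,
    trimester_gwg,
    zscore_group,
)


def visits_frame(rows):
    return pd.DataFrame(rows, columns=["participant_id", "cohort", "ga_weeks", "weight_kg"])


def chart_row(cohort="C1", bmi="normal", week=38, mu=2.4, sd=0.3):
    row = {"cohort": cohort, "bmi_group": bmi, "ga_week": week, "mu_log": mu, "sd_log": sd}
    for p in (3, 5, 10, 25, 50, 75, 90, 95, 97):
        row[f"p{p}"] = np.exp(mu + stats.norm.ppf(p / 100) * sd) - 5
    return row


class TestTotalGwg:
    def test_latest_visit_before_delivery(self):
        v = visits_frame([("A", "C1", 20.0, 53.0), ("A", "C1", 38.0, 58.5)])
        assert total_gwg(v, 50.0, 39.0) == (8.5, 38.0)

    def test_single_visit_equal_to_baseline(self):
        v = visits_frame([("A", "C1", 22.0, 50.0)])
        assert total_gwg(v, 50.0, 39.0) == (0.0, 22.0)

    def test_visit_after_delivery_excluded(self):
        v = visits_frame([("A", "C1", 30.0, 55.0), ("A", "C1", 40.5, 60.0)])
        assert total_gwg(v, 50.0, 39.0) == (5.0, 30.0)

    def test_no_qualifying_visit_raises(self):
        v = visits_frame([("A", "C1", 40.0, 55.0)])
        with pytest.raises(ValueError):
            total_gwg(v, 50.0, 39.0)


class TestZScore:
    def test_hand_arithmetic(self):
        chart = pd.DataFrame([chart_row(mu=2.4, sd=0.3)])
        z = gwg_zscore(6.8, 38.0, chart, "C1", "normal")
        assert np.log(11.8) == pytest.approx(2.46810, abs=1e-5)
        assert z == pytest.approx(0.22700, abs=1e-5)

    def test_median_gives_zero(self):
        chart = pd.DataFrame([chart_row()])
        z = gwg_zscore(chart.iloc[0]["p50"], 38.0, chart, "C1", "normal")
        assert z == pytest.approx(0.0, abs=1e-12)

    def test_p25_gives_lower_quartile_quantile(self):
        chart = pd.DataFrame([chart_row()])
        z = gwg_zscore(chart.iloc[0]["p25"], 38.0, chart, "C1", "normal")
        assert z == pytest.approx(-0.6745, abs=1e-4)

    def test_outside_support_raises(self):
        chart = pd.DataFrame([chart_row(week=38)])
        with pytest.raises(ValueError, match="support"):
            gwg_zscore(5.0, 20.0, chart, "C1", "normal")

    def test_kg_scale_matches_log_scale_at_median(self):
        chart = pd.DataFrame([chart_row()])
        z_kg = gwg_zscore(chart.iloc[0]["p50"], 38.0, chart, "C1", "normal", scale="kg")
        assert z_kg == pytest.approx(0.0, abs=1e-12)


class TestGroups:
    @pytest.mark.parametrize(
        "z,grp", [(-1.0, "G1"), (-0.67449, "G1"), (-0.5, "G2"), (0.0, "G2"),
                  (0.3, "G3"), (0.674, "G3"), (0.68, "G4"), (2.0, "G4")]
    )
    def test_cutoffs(self, z, grp):
        assert zscore_group(z) == grp

    def test_cutoff_constants_round_to_printed_values(self):
        assert round(Z_Q25, 2) == -0.67
        assert round(Z_Q75, 2) == 0.67

    def test_partition(self, rng):
        z = rng.normal(size=1000)
        groups = zscore_group(z)
        assert set(np.unique(groups)) <= {"G1", "G2", "G3", "G4"}
        assert len(groups) == 1000

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            zscore_group(np.nan)

    def test_standard_normal_occupancy(self, rng):
        z = rng.normal(size=100_000)
        groups = zscore_group(z)
        for g in ("G1", "G2", "G3", "G4"):
            frac = np.mean(groups == g)
            assert abs(frac - 0.25) < 0.005


class TestIom:
    @pytest.mark.parametrize(
        "bmi,ga,expected",
        [
            ("normal", 40, 2 + 0.42 * 27),       # 13.34
            ("obese", 37, 0.5 + 0.22 * 24),      # 5.78
            ("underweight", 13, 2.0),
            ("overweight", 13, 0.5),
        ],
    )
    def test_recommended_gain(self, bmi, ga, expected):
        assert iom_recommended(bmi, ga) == pytest.approx(expected, abs=1e-12)

    def test_first_trimester_only_rejected(self):
        with pytest.raises(ValueError):
            iom_recommended("normal", 12.0)

    def test_adequacy_ratio_arithmetic(self):
        assert iom_adequacy_ratio(13.34, 13.34).ratio == pytest.approx(100.0)
        assert iom_adequacy_ratio(6.67, 13.34).ratio == pytest.approx(50.0, abs=1e-9)
        res = iom_adequacy_ratio(0.0, 13.34, bmi_group="normal")
        assert res.ratio == 0.0 and res.iom_category == "below"

    def test_adequacy_scale_equivariant(self):
        r1 = iom_adequacy_ratio(4.0, 13.0).ratio
        r2 = iom_adequacy_ratio(8.0, 13.0).ratio
        assert r2 == pytest.approx(2 * r1)

    def test_adequacy_categories(self):
        assert iom_adequacy_ratio(13.0, 13.34, "normal").iom_category == "adequate"
        assert iom_adequacy_ratio(17.0, 13.34, "normal").iom_category == "above"

    def test_nonpositive_recommended_rejected(self):
        with pytest.raises(ValueError):
            iom_adequacy_ratio(5.0, 0.0)


class TestExternalStandard:
    def test_own_chart_plugin_matches_gwg_zscore(self, study_pipeline):
        chart = study_pipeline["charts"]
        std = ChartStandard(chart, "C1", "normal")
        z1 = external_standard_zscore(7.0, 35.0, std)
        z2 = gwg_zscore(7.0, 35.0, chart, "C1", "normal")
        assert z1 == pytest.approx(z2, abs=1e-12)

    def test_median_of_standard_gives_zero(self):
        table = pd.DataFrame({"ga_week": [40], "mean": [13.2], "sd": [3.0]})
        std = TableStandard(table)
        assert external_standard_zscore(13.2, 40.0, std) == pytest.approx(0.0)

    def test_monotone_in_gwg(self):
        table = pd.DataFrame({"ga_week": [40], "mean": [13.2], "sd": [3.0]})
        std = TableStandard(table)
        zs = [external_standard_zscore(g, 40.0, std) for g in (5.0, 10.0, 15.0)]
        assert zs == sorted(zs)

    def test_outside_support_rejected(self):
        table = pd.DataFrame({"ga_week": [14, 40], "mean": [1.0, 13.2], "sd": [1.0, 3.0]})
        std = TableStandard(table)
        with pytest.raises(ValueError, match="support"):
            external_standard_zscore(5.0, 41.0, std)


class TestTrimesterGwg:
    def test_both_trimesters(self):
        v = visits_frame([("A", "C1", 20.0, 53.4), ("A", "C1", 38.0, 57.1)])
        assert trimester_gwg(v, 50.0) == (pytest.approx(3.4), pytest.approx(7.1))

    def test_missing_third_trimester(self):
        v = visits_frame([("A", "C1", 20.0, 53.4)])
        t2, t3 = trimester_gwg(v, 50.0)
        assert t2 == pytest.approx(3.4) and t3 is None

    def test_no_qualifying_visits(self):
        v = visits_frame([("A", "C1", 10.0, 50.5)])
        assert trimester_gwg(v, 50.0) == (None, None)
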