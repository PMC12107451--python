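import numpy as np
import pandas as pd
import pytest

import gwgref
from gwgref.outcomes import (
    baseline_assoc,
    gee_dose_response,
    modified_poisson_rr,
    run_primary_analysis,
)
from gwgref.simulate import OutcomeParams, default_config, generate_cohort


def two_group_frame(events_exposed, n_exposed, events_ref, n_ref, seed=0):
    rng = np.random.default_rng(seed)
    group = np.array(["G1"] * n_exposed + ["G3"] * n_ref)
    y = np.concatenate(
        [
            np.r_[np.ones(events_exposed), np.zeros(n_exposed - events_exposed)],
            np.r_[np.ones(events_ref), np.zeros(n_ref - events_ref)],
        ]
    )
    df = pd.DataFrame({"z_group": group, "outcome": y})
    return df.sample(frac=1.0, random_state=seed).reset_index(drop=True)


class TestModifiedPoisson:
    def test_saturated_2x2_equals_closed_form(self):
        """On a saturated design the log-link MLE is the ratio of proportions."""
        df = two_group_frame(30, 100, 20, 100)
        res = modified_poisson_rr(df, "outcome")
        tab = res.table.set_index("group")
        assert tab.loc["G1", "rr"] == pytest.approx(1.5, abs=1e-8)
        assert tab.loc["G3", "rr"] == 1.0

    def test_reference_rr_exactly_one(self):
        df = two_group_frame(25, 80, 30, 90, seed=1)
        tab = modified_poisson_rr(df, "outcome").table.set_index("group")
        assert tab.loc["G3", "rr"] == 1.0
        assert tab.loc["G3", "rr_lo"] == 1.0 and tab.loc["G3", "rr_hi"] == 1.0

    def test_missing_reference_group_rejected(self):
        df = pd.DataFrame({"z_group": ["G1"] * 10, "outcome": [1.0] * 5 + [0.0] * 5})
        with pytest.raises(ValueError, match="reference"):
            modified_poisson_rr(df, "outcome")

    def test_zero_event_group_flagged_not_fitted(self):
        df = two_group_frame(0, 50, 20, 100)
        res = modified_poisson_rr(df, "outcome")
        tab = res.table.set_index("group")
        assert np.isnan(tab.loc["G1", "rr"])
        assert any("zero events" in d for d in res.diagnostics)

    def test_sandwich_ci_coverage(self):
        """Robust Wald 95% CIs for the log RR cover at ~95%."""
        rng = np.random.default_rng(2)
        true_rr, base, n, reps = 1.5, 0.10, 5000, 200
        hits = 0
        for r in range(reps):
            exposed = rng.random(n) < 0.5
            p = np.where(exposed, base * true_rr, base)
            y = (rng.random(n) < p).astype(float)
            df = pd.DataFrame({"z_group": np.where(exposed, "G1", "G3"), "outcome": y})
            tab = modified_poisson_rr(df, "outcome").table.set_index("group")
            hits += tab.loc["G1", "rr_lo"] <= true_rr <= tab.loc["G1", "rr_hi"]
        assert 0.92 <= hits / reps <= 0.98

    def test_independent_covariates_leave_rr_unchanged(self):
        rng = np.random.default_rng(3)
        n = 20_000
        exposed = rng.random(n) < 0.5
        p = np.where(exposed, 0.15, 0.10)
        df = pd.DataFrame(
            {
                "z_group": np.where(exposed, "G1", "G3"),
                "outcome": (rng.random(n) < p).astype(float),
                "noise_cont": rng.normal(size=n),
                "noise_bin": (rng.random(n) < 0.4).astype(float),
            }
        )
        crude = modified_poisson_rr(df, "outcome").table.set_index("group")
        adj = modified_poisson_rr(
            df, "outcome", covariates=("noise_cont", "noise_bin")
        ).table.set_index("group")
        assert adj.loc["G1", "rr"] == pytest.approx(crude.loc["G1", "rr"], rel=0.05)

    def test_intercept_only_adjusted_risk_equals_crude(self):
        df = two_group_frame(30, 100, 20, 100)
        tab = modified_poisson_rr(df, "outcome").table.set_index("group")
        assert tab.loc["G1", "adj_risk_pct"] == pytest.approx(30.0, abs=1e-6)
        assert tab.loc["G3", "adj_risk_pct"] == pytest.approx(20.0, abs=1e-6)

    def test_risk_times_rr_internal_consistency(self):
        df = two_group_frame(35, 120, 22, 110, seed=4)
        tab = modified_poisson_rr(df, "outcome").table.set_index("group")
        lhs = tab.loc["G3", "adj_risk_pct"] * tab.loc["G1", "rr"]
        assert lhs == pytest.approx(tab.loc["G1", "adj_risk_pct"], rel=1e-6)


@pytest.fixture(scope="module")
def monotone_frame():
    rng = np.random.default_rng(5)
    n = 6000
    z = rng.normal(size=n)
    p = 1 / (1 + np.exp(-(-1.6 - 0.6 * z)))  # risk decreasing in z
    return pd.DataFrame(
        {
            "participant_id": np.arange(n),
            "bmi_group": "normal",
            "z": z,
            "outcome": (rng.random(n) < p).astype(float),
        }
    )


class TestDoseResponse:
    def test_monotone_risk_recovered(self, monotone_frame):
        curve = gee_dose_response(monotone_frame, "outcome")
        sub = curve[(curve.z >= -2) & (curve.z <= 2)].sort_values("z")
        probs = sub["prob"].to_numpy()
        # decreasing within smoother tolerance
        assert probs[0] > probs[-1]
        assert np.all(np.diff(probs) < 0.02)

    def test_null_effect_flat(self):
        rng = np.random.default_rng(6)
        n = 6000
        df = pd.DataFrame(
            {
                "participant_id": np.arange(n),
                "bmi_group": "normal",
                "z": rng.normal(size=n),
                "outcome": (rng.random(n) < 0.2).astype(float),
            }
        )
        curve = gee_dose_response(df, "outcome")
        sub = curve[(curve.z >= -2) & (curve.z <= 2)]
        # pointwise sampling noise of the spline fit bounds the wiggle
        assert sub["prob"].max() - sub["prob"].min() < 0.08

    def test_row_order_invariance(self, monotone_frame):
        c1 = gee_dose_response(monotone_frame, "outcome")
        c2 = gee_dose_response(
            monotone_frame.sample(frac=1.0, random_state=7), "outcome"
        )
        merged = c1.merge(c2, on=["bmi_group", "z"])
        assert merged["prob_x"].to_numpy() == pytest.approx(
            merged["prob_y"].to_numpy(), abs=1e-8
        )


class TestBaselineAssoc:
    def make_frame(self, shift=0.0, n=10_000, seed=8):
        rng = np.random.default_rng(seed)
        cat = rng.choice(["a", "b"], size=n)
        z = rng.normal(size=n) + np.where(cat == "b", shift, 0.0)
        cohort = rng.choice(["C1", "C2", "C3"], size=n)
        return pd.DataFrame({"z": z, "cat": cat, "cohort": cohort})

    def test_null_association(self):
        df = self.make_frame(shift=0.0)
        res = baseline_assoc(df, "z", "cat")
        assert abs(res["estimate"].iloc[0]) < 0.05

    def test_shift_recovered(self):
        df = self.make_frame(shift=-0.2)
        res = baseline_assoc(df, "z", "cat")
        assert res["estimate"].iloc[0] == pytest.approx(-0.2, abs=0.05)

    def test_duplicating_clusters_leaves_estimate_unchanged(self):
        df = self.make_frame(shift=-0.2, n=2000)
        dup = df.copy()
        dup["cohort"] = dup["cohort"] + "_dup"
        res1 = baseline_assoc(df, "z", "cat")
        res2 = baseline_assoc(pd.concat([df, dup], ignore_index=True), "z", "cat")
        assert res2["estimate"].iloc[0] == pytest.approx(res1["estimate"].iloc[0], abs=1e-9)

    def test_single_cohort_falls_back_with_warning(self):
        df = self.make_frame(n=500)
        df["cohort"] = "C1"
        with pytest.warns(UserWarning, match="single cohort"):
            res = baseline_assoc(df, "z", "cat")
        assert np.isfinite(res["se"].iloc[0])


class TestPrimaryPipeline:
    def test_complete_data_pipeline_runs_and_pools_degenerately(self, study_sim):
        res = run_primary_analysis(
            study_sim["visits"],
            study_sim["baselines"],
            study_sim["outcomes"],
            outcome_names=("preterm37",),
            bmi_strata=("normal",),
        )
        assert res.m == 1  # complete data: no imputation copies
        tab = res.risk_tables[("preterm37", "normal")].set_index("group")
        assert tab.loc["G3", "rr"] == 1.0
        assert (tab["N"] > 0).all()

    def test_effect_size_ordering(self):
        """Stronger simulated effects give larger estimated G1-vs-G3 RRs."""
        rrs = []
        for rr_true in (1.0, 1.5, 2.0):
            op = OutcomeParams(
                group_risks={
                    "lbw": {"G1": 0.25 * rr_true, "G2": 0.25, "G3": 0.25, "G4": 0.25}
                }
            )
            cfg = default_config(
                n_per_cohort=1500, cohorts=("C1", "C2"), seed=11,
                outcome_params=op,
            )
            v, b, o, _ = generate_cohort(cfg)
            res = run_primary_analysis(
                v, b, o, outcome_names=("lbw",), bmi_strata=("normal",)
            )
            tab = res.risk_tables[("lbw", "normal")].set_index("group")
            rrs.append(tab.loc["G1", "rr"])
        assert rrs[0] < rrs[1] < rrs[2]

    def test_sensitivity_rerun_reports_own_n(self, study_sim):
        res = run_primary_analysis(
            study_sim["visits"],
            study_sim["baselines"],
            study_sim["outcomes"],
            outcome_names=("preterm37",),
            bmi_strata=("normal",),
            exclude_prior_preterm=True,
        )
        sens = res.sensitivity["no_prior_preterm"]
        assert 0 < sens["n"] < len(study_sim["baselines"])
        assert ("preterm37", "normal") in sens["risk_tables"]

    def test_report_renders(self, study_sim):
        res = run_primary_analysis(
            study_sim["visits"],
            study_sim["baselines"],
            study_sim["outcomes"],
            outcome_names=("preterm37",),
            bmi_strata=("normal",),
        )
        text = res.table_report()
        assert "preterm37" in text and "G3" in text
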