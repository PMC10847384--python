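"""Moderator preparation, design construction, mixed-model fits, probing."""

import warnings

import numpy as np
import pandas as pd
import pytest

from hrvdyn.mlm import (
    PAIRS,
    build_design,
    fit_pair,
    prepare_moderators,
    probe_interaction,
    records_from_cohort,
    report_tables,
    simple_slopes,
    standardize,
)

warnings.filterwarnings("ignore", category=UserWarning)

IBI_POS = PAIRS[0]


@pytest.fixture(scope="module")
def latent_design(latent_cohort):
    return build_design(records_from_cohort(latent_cohort), IBI_POS)


@pytest.fixture(scope="module")
def base_fit(latent_design):
    return fit_pair(latent_design, IBI_POS)


class TestPrepareModerators:
    def test_composites_follow_stated_arithmetic(self):
        raw = pd.DataFrame(
            {
                "subject": ["a", "b"],
                "attribution_control": [40.0, 10.0],
                "attribution_hostile": [31.19, 20.0],
                "stress_difficult_child": [60.0, 40.0],
                "stress_dysfunction": [80.0, 20.0],
                "depression_t": [50.0, 62.0],
                "anxiety_t": [60.0, 42.0],
            }
        )
        out = prepare_moderators(raw)
        # attribution items are summed, stress percentiles and symptom
        # T-scores averaged
        assert out["harsh_attributions"].tolist() == [71.19, 30.0]
        assert out["parenting_stress"].tolist() == [70.0, 30.0]
        assert out["mental_health"].tolist() == [55.0, 52.0]

    def test_dichotomizations(self):
        raw = pd.DataFrame(
            {
                "subject": list("abcd"),
                "hit_rate_happy": [0.9, 0.8, 0.5, 0.3],
                "false_alarm_angry": [0.0, 0.1, 0.0, 0.2],
            }
        )
        out = prepare_moderators(raw)
        # above the sample median (0.65) -> 1
        assert out["hit_rate_positive"].tolist() == [1.0, 1.0, 0.0, 0.0]
        assert out["false_alarm_anger"].tolist() == [0.0, 1.0, 0.0, 1.0]

    def test_standardized_columns_have_unit_moments(self):
        rng = np.random.default_rng(0)
        raw = pd.DataFrame(
            {"subject": [f"s{i}" for i in range(50)],
             "inhibit_t": rng.normal(55, 10, 50)}
        )
        out = prepare_moderators(raw)
        z = out["inhibitory_control_z"]
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_all_missing_column_rejected(self):
        raw = pd.DataFrame({"subject": ["a", "b"], "x": [np.nan, np.nan]})
        with pytest.raises(ValueError):
            prepare_moderators(raw)

    def test_duplicate_subjects_rejected(self):
        raw = pd.DataFrame({"subject": ["a", "a"], "x": [1.0, 2.0]})
        with pytest.raises(ValueError, match="duplicate"):
            prepare_moderators(raw)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            standardize(pd.Series([1.0, 1.0, 1.0], name="c"))


class TestBuildDesign:
    def test_row_count_closed_form(self, latent_cohort, latent_design):
        n_sub = latent_cohort.n_subjects
        n_sec = int(latent_cohort.params.task_length)
        assert len(latent_design) == n_sub * n_sec

    def test_centering_column_near_zero_mean_per_subject(self, latent_design):
        # phys_c is centered on the generating set point in the latent route;
        # per-subject means deviate only by the subject's equilibrium shift
        # (a_i + c_i*mean beh)/|b| plus OU sample-mean error, ~0.05 s scale
        per_sub = latent_design.groupby("subject")["phys_c"].mean()
        assert np.abs(per_sub).max() < 0.15
        assert np.abs(per_sub).mean() < 0.06

    def test_missing_seconds_drop_rows(self, latent_cohort):
        recs = records_from_cohort(latent_cohort)
        recs[0].trajectories["ibi"].missing[:14] = True
        design = build_design(recs, IBI_POS)
        sub0 = recs[0].subject
        t0 = design.loc[design.subject == sub0, "t"]
        assert t0.min() == 14
        recs[0].trajectories["ibi"].missing[:14] = False

    def test_observed_person_mean_centering(self, observed_cohort):
        from hrvdyn.pipeline import PipelineConfig, process_subject

        config = PipelineConfig()
        rec, _ = process_subject(
            "s0", observed_cohort.subjects[0].beats,
            observed_cohort.subjects[0].events, config
        )
        design = build_design([rec, rec.__class__(**{**vars(rec), "subject": "s1"})], IBI_POS)
        per_sub = design.groupby("subject")["phys_c"].mean()
        # centered on the included smoothed samples -> near zero
        assert np.abs(per_sub).max() < 5e-3


class TestFitPair:
    def test_recovers_generating_couplings_within_ci(self, latent_cohort, base_fit):
        p = latent_cohort.params
        for which, truth in (("c", p.c0), ("f", p.f0)):
            row = base_fit.coupling(which)
            assert abs(row.estimate - truth) < 3 * row.se

    def test_single_subject_without_random_effects_equals_ols(self, latent_design):
        one = latent_design[latent_design.subject == latent_design.subject.iloc[0]]
        fit = fit_pair(one, IBI_POS, random_effects="none")
        X = np.column_stack([np.ones(len(one)), one.phys_c, one.beh])
        beta, *_ = np.linalg.lstsq(X, one.dphys, rcond=None)
        est = fit.phys_eq.params["estimate"]
        np.testing.assert_allclose(
            est[["a", "b", "c"]], beta, atol=1e-8
        )

    def test_zero_variance_constraint_matches_pooled_least_squares(self, latent_design):
        """With random-effect variances at 0, the mixed model collapses to
        pooled least squares; check against an independent normal-equation
        solve."""
        fit = fit_pair(latent_design, IBI_POS, random_effects="none")
        X = np.column_stack(
            [np.ones(len(latent_design)), latent_design.phys_c, latent_design.beh]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ latent_design.dphys)
        np.testing.assert_allclose(
            fit.phys_eq.params["estimate"][["a", "b", "c"]], beta, atol=1e-6
        )
        Xb = np.column_stack(
            [np.ones(len(latent_design)), latent_design.beh, latent_design.phys_c]
        )
        beta_b = np.linalg.solve(Xb.T @ Xb, Xb.T @ latent_design.dbeh)
        np.testing.assert_allclose(
            fit.beh_eq.params["estimate"][["d", "e", "f"]], beta_b, atol=1e-6
        )

    def test_moderator_terms_present_with_task_total_covariate(self, latent_cohort, latent_design):
        mods = latent_cohort.moderator_frame()
        mods["z_z"] = standardize(mods["z"])
        design = latent_design.merge(mods[["subject", "z_z"]], on="subject")
        design["total_pos_z"] = standardize(
            design.groupby("subject")["beh"].transform("mean")
        )
        fit = fit_pair(design, IBI_POS, moderator="z_z")
        idx = fit.phys_eq.params.index
        assert "gamma_a11:z_z" in idx and "gamma_c11:z_z" in idx
        assert "gamma_a12:total_pos_z" in idx and "gamma_c12:total_pos_z" in idx
        bidx = fit.beh_eq.params.index
        assert "gamma_d11:z_z" in bidx and "gamma_f11:z_z" in bidx

    def test_moderated_cohort_recovers_interaction(self):
        from hrvdyn.synthesize import TrueParams, simulate_cohort

        p = TrueParams(n_subjects=60, mod_effects={"c": -0.001})
        cohort = simulate_cohort(p, seed=33)
        design = build_design(records_from_cohort(cohort), IBI_POS)
        mods = cohort.moderator_frame()
        mods["z_z"] = standardize(mods["z"])
        design = design.merge(mods[["subject", "z_z"]], on="subject")
        fit = fit_pair(design, IBI_POS, moderator="z_z", include_task_total=False)
        row = fit.phys_eq.params.loc["gamma_c11:z_z"]
        assert abs(row.estimate - (-0.001)) < 3 * row.se

    def test_unknown_moderator_rejected(self, latent_design):
        with pytest.raises(ValueError, match="nope"):
            fit_pair(latent_design, IBI_POS, moderator="nope")


class TestProbing:
    def test_slope_at_zero_equals_base_coupling(self, latent_cohort, latent_design):
        mods = latent_cohort.moderator_frame()
        mods["z_z"] = standardize(mods["z"])
        design = latent_design.merge(mods[["subject", "z_z"]], on="subject")
        fit = fit_pair(design, IBI_POS, moderator="z_z", include_task_total=False)
        slopes = probe_interaction(fit, "c")
        at_zero = next(s for s in slopes if s.level == 0.0)
        assert at_zero.slope == fit.phys_eq.params.loc["c", "estimate"]
        assert at_zero.se == pytest.approx(
            fit.phys_eq.params.loc["c", "se"], rel=1e-12
        )

    def test_zero_interaction_identical_slopes(self):
        out = simple_slopes(0.5, 0.0, np.array([[0.01, 0.0], [0.0, 0.02]]))
        assert len({s.slope for s in out}) == 1

    def test_linear_in_level_with_delta_method_se(self):
        cov = np.array([[4.0, 1.0], [1.0, 9.0]])
        out = simple_slopes(1.0, 0.5, cov, levels=(-1.0, 1.0))
        assert out[0].slope == pytest.approx(0.5)
        assert out[1].slope == pytest.approx(1.5)
        assert out[0].se == pytest.approx(np.sqrt(4 + 9 - 2))
        assert out[1].se == pytest.approx(np.sqrt(4 + 9 + 2))

    def test_probe_without_moderator_rejected(self, base_fit):
        with pytest.raises(ValueError):
            probe_interaction(base_fit, "c")


class TestReportTables:
    def test_base_table_schema(self, base_fit):
        table = report_tables([base_fit])
        assert list(table["pair"]) == ["ibi-pos"]
        assert table.loc[0, "moderator"] == "(base model)"
        for col in ("c_estimate", "c_se", "c_p", "f_estimate", "f_se", "f_p"):
            assert np.isfinite(table.loc[0, col])

    def test_moderator_rows_labelled(self, latent_cohort, latent_design):
        mods = latent_cohort.moderator_frame()
        mods["z_z"] = standardize(mods["z"])
        design = latent_design.merge(mods[["subject", "z_z"]], on="subject")
        fit = fit_pair(design, IBI_POS, moderator="z_z", include_task_total=False)
        table = report_tables([fit])
        assert table.loc[0, "moderator"] == "z_z"
        assert table.loc[0, "pair"] == "ibi-pos"
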