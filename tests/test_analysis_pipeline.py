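import numpy as np
import pandas as pd
import pytest

import confusim as cf
from confusim import analysis_pipeline as ap
from confusim import glmm_core


class TestModelLadder:
    def test_lrt_degrees_of_freedom(self, default_ladder):
        # design-determined: 2x2x2 factor contrasts, 1 linear 3-way,
        # 2 density-interaction terms
        dfs = {k: c.df for k, c in default_ladder.comparisons.items()}
        assert dfs == {"M1_threeway": 8, "M2_threeway": 1, "M4_interaction": 2}

    def test_all_models_fit_same_rows(self, default_ladder):
        assert len({f.n_obs for f in default_ladder.models.values()}) == 1
        assert set(default_ladder.models) == {"M1", "M2", "M3", "M4", "M5", "M6"}

    def test_selected_is_argmin_bic(self, default_ladder):
        assert default_ladder.selected == min(default_ladder.bics, key=default_ladder.bics.get)

    def test_interaction_truth_selects_quadratic_density_model(self, default_ladder):
        # generating model: sigma slope quadratic in density -> M4
        assert default_ladder.selected == "M4"
        assert default_ladder.comparisons["M4_interaction"].p_value < 0.01

    def test_no_sigma_effect_prefers_simplest_models(self):
        design = cf.build_design(replicates=1)
        params = cf.PsychometricParams(beta0=0.5, beta_u=0.0, delta1=0.0, delta2=0.0)
        resp = cf.generate_responses(design, params, rng_seed=8)
        ladder = ap.model_ladder(resp)
        # no interaction in truth: the interaction-free / linear models win
        assert ladder.selected in {"M3", "M5", "M6"}
        assert ladder.comparisons["M4_interaction"].p_value > 0.01

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            ap.model_ladder(pd.DataFrame({"hit": [0, 1]}))

    def test_area_covariate_switch(self, default_responses):
        side = ap._with_area(default_responses, "side")
        sq = ap._with_area(default_responses, "squared")
        assert np.allclose(sq["area"], side["area"] ** 2)
        with pytest.raises(ValueError):
            ap._with_area(default_responses, "cubed")


class TestConditionSlopes:
    def test_profile_shape_and_densities(self, default_responses):
        prof = ap.condition_slopes(default_responses)
        assert len(prof.cell_slopes) == 9
        dens = np.sort(prof.cell_slopes["density"].round(6).unique())
        # 9 cells collapse onto 5 density clusters; diagonal agrees to 1%
        clusters = []
        for d in dens:
            if not clusters or d / clusters[-1][-1] > 1.01:
                clusters.append([d])
            else:
                clusters[-1].append(d)
        assert len(clusters) == 5

    def test_interaction_truth_gives_interior_slope_extremum(self, default_responses):
        prof = ap.condition_slopes(default_responses)
        a, b, c = prof.quad_coefs
        # slopes are negative and their magnitude peaks inside the design
        # range: the slope-vs-density parabola opens upwards
        assert (prof.cell_slopes["slope"] < 0).all()
        assert c > 0
        vertex = -b / (2 * c)
        assert 1.0 < vertex < 25.0

    def test_flat_data_gives_flat_profile(self):
        design = cf.build_design(replicates=2)
        params = cf.PsychometricParams(beta0=0.3, beta_u=0.0, delta1=0.0, delta2=0.0, tau=0.0)
        resp = cf.generate_responses(design, params, rng_seed=2)
        prof = ap.condition_slopes(resp)
        se = prof.cell_slopes["se"].to_numpy()
        z = prof.cell_slopes["slope"].to_numpy() / se
        assert np.nanmax(np.abs(z)) < 4.0

    def test_single_sigma_level_rejected(self, default_responses):
        sub = default_responses[np.isclose(default_responses["sigma"],
                                           default_responses["sigma"].min())]
        with pytest.raises(ValueError):
            ap.condition_slopes(sub)


class TestPerSubjectSlopes:
    def test_t_test_degrees_of_freedom(self):
        # 24 subjects all contributing a slope -> df = 23
        design = cf.build_design(replicates=4)
        resp = cf.generate_responses(design, cf.PsychometricParams(), rng_seed=11)
        prof = ap.condition_slopes(resp)
        t, df, p = ap.per_subject_slope_test(prof, 20, 380)
        assert df == 23
        # the shallowest cell still has a genuinely negative mean slope
        assert t < 0

    def test_unknown_cell(self, default_responses):
        prof = ap.condition_slopes(default_responses)
        with pytest.raises(ValueError):
            ap.per_subject_slope_test(prof, 999, 999)


class TestLowestSigmaTest:
    def test_df_and_balance(self, default_responses):
        comp = ap.lowest_sigma_test(default_responses)
        assert comp.df == 2
        sig_min = default_responses["sigma"].min()
        frac = np.isclose(default_responses["sigma"], sig_min).mean()
        assert frac == pytest.approx(1 / 7)

    def test_density_flat_truth_rarely_significant(self):
        # truth has no density effect at the lowest sigma; the test should
        # be non-significant in the clear majority of runs
        hits = 0
        for seed in range(12):
            design = cf.build_design(replicates=2)
            resp = cf.generate_responses(design, cf.PsychometricParams(), rng_seed=100 + seed)
            comp = ap.lowest_sigma_test(resp)
            hits += comp.p_value < 0.05
        assert hits <= 3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ap.lowest_sigma_test(pd.DataFrame(columns=ap.REQUIRED_COLUMNS))


class TestWithinSubjectCI:
    def test_subject_shift_invariance_gives_zero_width(self):
        # identical per-cell profiles shifted per subject: CIs collapse
        design = cf.build_design(n_subjects=6, replicates=1,
                                 sigma_levels=[0.05, 0.1])
        rows = []
        for _, r in design.iterrows():
            base = 1.0 if r.sigma < 0.08 else 0.0
            rows.append(base)
        df = design.copy()
        df["hit"] = rows
        # add a subject-constant shift via duplicated rows (binary data
        # cannot shift continuously, so use the degenerate all-equal case)
        ci = ap.within_subject_ci(df)
        assert np.allclose(ci["ci_high"] - ci["ci_low"], 0.0, atol=1e-12)

    def test_morey_factor_value(self):
        assert np.sqrt(63 / 62) == pytest.approx(1.008, abs=5e-4)

    def test_grand_mean_preserved(self, default_responses):
        ci = ap.within_subject_ci(default_responses)
        per_subject_cell = default_responses.groupby(
            ["subject_id", "n_items", "area_side_px", "sigma"])["hit"].mean()
        grand = per_subject_cell.groupby(["n_items", "area_side_px", "sigma"]).mean().mean()
        assert ci["mean"].mean() == pytest.approx(grand, abs=1e-12)

    def test_incomplete_subject_excluded_with_warning(self, default_responses):
        df = default_responses.copy()
        drop_mask = (df["subject_id"] == 0) & np.isclose(df["sigma"], df["sigma"].min())
        df = df[~drop_mask]
        with pytest.warns(UserWarning):
            ci = ap.within_subject_ci(df)
        assert (ci["n_subjects"] == 23).all()


class TestRunReport:
    def test_report_files_and_determinism(self, tmp_path, default_responses):
        out1 = ap.run_report(default_responses, tmp_path / "r1")
        for p in out1["paths"].values():
            assert p.exists()
        ladder_csv = (tmp_path / "r1" / "ladder.csv").read_text()
        assert ladder_csv.count("\n") == 7  # header + six models
        ap.run_report(default_responses, tmp_path / "r2")
        assert (tmp_path / "r2" / "ladder.csv").read_text() == ladder_csv

    def test_missing_columns(self, tmp_path):
        with pytest.raises(ValueError):
            ap.run_report(pd.DataFrame({"hit": [1]}), tmp_path)
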