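import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

import confusim as cf
from confusim import glmm_core
from confusim.formula import build_matrices, parse_formula
from confusim.glmm_core import (
    ConvergenceError,
    GLMMFit,
    NotNestedError,
    SeparationError,
)


def brute_force_loglik(spec, data, beta, tau, n_grid=20001, half_width=8.0):
    """Independent oracle: dense trapezoid integration of the random effect."""
    X, names, y, codes, levels, _ = build_matrices(parse_formula(spec) if isinstance(spec, str) else spec, data)
    eta = X @ beta
    total = 0.0
    width = max(half_width * tau, 1e-3)
    u = np.linspace(-width, width, n_grid)
    for g in range(len(levels)):
        m = codes == g
        ll_u = (y[m, None] * (eta[m, None] + u) - np.logaddexp(0.0, eta[m, None] + u)).sum(axis=0)
        dens = np.exp(-(u**2) / (2 * tau**2)) / np.sqrt(2 * np.pi * tau**2)
        total += np.log(np.trapezoid(np.exp(ll_u) * dens, u))
    return total


def toy_data(n_subj=3, n_per=5, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "subject_id": np.repeat(np.arange(n_subj), n_per),
            "x": rng.normal(size=n_subj * n_per),
        }
    )
    df["hit"] = (rng.uniform(size=len(df)) < 0.5).astype(int)
    return df


def simulate_glmm(design, formula, beta, tau, seed):
    """Draw Bernoulli responses from a known GLMM truth on a design table."""
    df = design.copy()
    df["hit"] = 0  # placeholder so the formula parses
    X, names, y, codes, levels, order = build_matrices(parse_formula(formula), df)
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, tau, size=len(levels))
    p = expit(X @ np.asarray(beta) + u[codes])
    hits_sorted = (rng.uniform(size=len(df)) < p).astype(int)
    out = df.iloc[order].reset_index(drop=True)
    out["hit"] = hits_sorted
    return out


class TestFormula:
    @pytest.mark.parametrize(
        "formula, n_fixed",
        [
            ("hit ~ poly(sigma,2) * factor(n_items) * factor(area_side_px) + (1|subject_id)", 27),
            ("hit ~ log(n_items) * area_side_px * sigma + (1|subject_id)", 8),
            ("hit ~ poly(density,2) * sigma + (1|subject_id)", 6),
            ("hit ~ density * sigma + (1|subject_id)", 4),
            ("hit ~ poly(density,2) + sigma + (1|subject_id)", 4),
            ("hit ~ 1 + (1|subject_id)", 1),
        ],
    )
    def test_fixed_effect_counts(self, default_responses, formula, n_fixed):
        X, names, *_ = build_matrices(parse_formula(formula), default_responses)
        assert X.shape[1] == n_fixed
        assert names[0] == "(Intercept)"

    def test_orthogonal_poly_is_orthonormal(self, default_responses):
        X, names, *_ = build_matrices(
            parse_formula("hit ~ poly(density,2) + (1|subject_id)"), default_responses
        )
        gram = X[:, 1:].T @ X[:, 1:]
        assert np.allclose(gram, np.eye(2), atol=1e-10)
        assert np.allclose(X[:, 1:].sum(axis=0), 0.0, atol=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError):
            parse_formula("hit ~ x")  # no random term
        with pytest.raises(ValueError):
            parse_formula("hit ~ x + (1|a) + (1|b)")
        with pytest.raises(ValueError):
            parse_formula("hit ~ poly(x, 3) + (1|s)")
        with pytest.raises(ValueError):
            parse_formula("no tilde here")


class TestMarginalLoglik:
    def test_tau_zero_is_plain_logistic(self):
        df = toy_data()
        beta = np.array([0.3, -0.7])
        ours = glmm_core.marginal_loglik("hit ~ x + (1|subject_id)", df, beta, 0.0)
        X = sm.add_constant(df["x"])
        theirs = sm.Logit(df["hit"], X).loglike(beta)
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_single_trial_limit(self):
        df = pd.DataFrame({"subject_id": [0, 1], "hit": [1, 0]})
        ll = glmm_core.marginal_loglik("hit ~ 1 + (1|subject_id)", df, [0.0], 0.0)
        assert ll == pytest.approx(2 * np.log(0.5))

    @pytest.mark.parametrize("tau", [0.3, 0.9, 2.0])
    def test_agq_matches_brute_force(self, tau):
        df = toy_data(n_subj=2, n_per=3, seed=4)
        beta = np.array([0.5, -1.1])
        oracle = brute_force_loglik("hit ~ x + (1|subject_id)", df, beta, tau)
        agq = glmm_core.marginal_loglik("hit ~ x + (1|subject_id)", df, beta, tau, quad_order=25)
        assert agq == pytest.approx(oracle, abs=1e-6)

    def test_laplace_close_but_not_exact(self):
        df = toy_data(n_subj=2, n_per=3, seed=4)
        beta = np.array([0.5, -1.1])
        lap = glmm_core.marginal_loglik("hit ~ x + (1|subject_id)", df, beta, 0.9, quad_order=1)
        oracle = brute_force_loglik("hit ~ x + (1|subject_id)", df, beta, 0.9)
        assert abs(lap - oracle) < 0.05

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            glmm_core.marginal_loglik("hit ~ x + (1|subject_id)", toy_data(), [0, 0], -0.1)


class TestFit:
    def test_parameter_recovery(self, default_design):
        formula = "hit ~ density + sigma + (1|subject_id)"
        truth = np.array([1.5, -0.05, -6.0])
        data = simulate_glmm(default_design, formula, truth, tau=0.8, seed=21)
        f = glmm_core.fit(formula, data)
        assert f.converged
        se = f.std_errors()
        for name, b in zip(f.coef.index, truth):
            assert abs(f.coef[name] - b) < 3 * se[name]
        assert abs(f.tau - 0.8) < 0.45  # 24 subjects: tau is noisy but sane

    def test_tau_zero_truth_hits_boundary(self, default_design):
        formula = "hit ~ sigma + (1|subject_id)"
        data = simulate_glmm(default_design, formula, [1.0, -5.0], tau=0.0, seed=3)
        f = glmm_core.fit(formula, data)
        assert f.converged
        assert f.tau < 0.05

    def test_tau_pinned_to_zero_reduces_to_logistic(self, default_design):
        formula = "hit ~ sigma + (1|subject_id)"
        data = simulate_glmm(default_design, formula, [1.0, -5.0], tau=0.0, seed=3)
        f = glmm_core.fit(formula, data, fix_tau=0.0)
        X = sm.add_constant(data["sigma"])
        ref = sm.Logit(data["hit"], X).fit(disp=0)
        assert np.allclose(f.beta, ref.params.to_numpy(), atol=1e-4)
        assert f.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_laplace_vs_agq_on_design(self, default_responses):
        f1 = glmm_core.fit("hit ~ density + sigma + (1|subject_id)", default_responses)
        f15 = glmm_core.fit(
            "hit ~ density + sigma + (1|subject_id)", default_responses, quad_order=15
        )
        # >= 63 trials per subject: quadrature order barely matters
        assert abs(f1.loglik - f15.loglik) < 0.1

    def test_deviance_monotone_in_terms(self, default_responses):
        small = glmm_core.fit("hit ~ sigma + (1|subject_id)", default_responses)
        big = glmm_core.fit("hit ~ density * sigma + (1|subject_id)", default_responses)
        assert big.loglik >= small.loglik - 1e-4

    def test_covariate_rescaling_invariance(self, default_responses):
        df = default_responses.copy()
        f = glmm_core.fit("hit ~ sigma + (1|subject_id)", df)
        df["sigma"] = df["sigma"] * 100.0
        g = glmm_core.fit("hit ~ sigma + (1|subject_id)", df)
        assert g.loglik == pytest.approx(f.loglik, abs=1e-5)
        assert glmm_core.bic(g) == pytest.approx(glmm_core.bic(f), abs=1e-4)
        assert g.coef["sigma"] == pytest.approx(f.coef["sigma"] / 100.0, rel=1e-3)

    def test_collinear_design_rejected(self, default_responses):
        df = default_responses.copy()
        df["sigma2"] = df["sigma"]
        with pytest.raises(ValueError):
            glmm_core.fit("hit ~ sigma + sigma2 + (1|subject_id)", df)

    def test_single_group_rejected(self):
        df = toy_data(n_subj=1, n_per=10)
        with pytest.raises(ValueError):
            glmm_core.fit("hit ~ x + (1|subject_id)", df)


class TestLrtAndBic:
    def test_identical_models(self, default_responses):
        f = glmm_core.fit("hit ~ sigma + (1|subject_id)", default_responses)
        c = glmm_core.lrt(f, f)
        assert c.chi_sq == 0.0
        assert c.p_value == 1.0

    def test_nested_comparison(self, default_responses):
        full = glmm_core.fit("hit ~ poly(density,2) * sigma + (1|subject_id)", default_responses)
        red = glmm_core.fit("hit ~ poly(density,2) + sigma + (1|subject_id)", default_responses)
        c = glmm_core.lrt(full, red)
        assert c.df == 2
        assert c.chi_sq >= 0
        assert 0 <= c.p_value <= 1

    def test_non_nested_rejected(self, default_responses):
        a = glmm_core.fit("hit ~ density + (1|subject_id)", default_responses)
        b = glmm_core.fit("hit ~ sigma + (1|subject_id)", default_responses)
        with pytest.raises(NotNestedError):
            glmm_core.lrt(a, b)

    def test_bic_formula(self):
        f = GLMMFit(
            spec=parse_formula("hit ~ x + (1|s)"), coef=pd.Series(dtype=float),
            tau=0.5, loglik=-700.0, n_obs=1512, n_params=8, converged=True,
            quad_order=1, n_groups=24,
        )
        assert glmm_core.bic(f) == pytest.approx(-2 * -700.0 + 8 * np.log(1512))
        assert glmm_core.bic(f) == pytest.approx(1458.57, abs=0.01)

    def test_bic_guards(self):
        bad = GLMMFit(
            spec=parse_formula("hit ~ x + (1|s)"), coef=pd.Series(dtype=float),
            tau=0.5, loglik=-1.0, n_obs=10, n_params=2, converged=False,
            quad_order=1, n_groups=2,
        )
        with pytest.raises(ConvergenceError):
            glmm_core.bic(bad)
        bad.converged = True
        bad.n_params = 0
        with pytest.raises(ValueError):
            glmm_core.bic(bad)


@pytest.fixture(scope="module")
def small_fit():
    design = cf.build_design(n_subjects=12, replicates=1,
                             sigma_levels=cf.unpredictability_levels(n_levels=4))
    data = simulate_glmm(design, "hit ~ sigma + (1|subject_id)", [2.0, -7.0], 0.8, seed=6)
    return glmm_core.fit("hit ~ sigma + (1|subject_id)", data)


class TestParametricBootstrap:
    def test_reproducible_and_sane(self, small_fit):
        a = glmm_core.parametric_bootstrap(small_fit, statistic="sigma", n_boot=60, seed=2)
        b = glmm_core.parametric_bootstrap(small_fit, statistic="sigma", n_boot=60, seed=2)
        assert np.array_equal(a.samples, b.samples)
        assert a.ci_low < small_fit.coef["sigma"] < a.ci_high
        assert a.n_failed < 10

    def test_all_statistics(self, small_fit):
        out = glmm_core.parametric_bootstrap(small_fit, statistic="all", n_boot=30, seed=3)
        assert set(out) == {"(Intercept)", "sigma", "tau"}

    def test_zero_boot_rejected(self, small_fit):
        with pytest.raises(ValueError):
            glmm_core.parametric_bootstrap(small_fit, statistic="sigma", n_boot=0)

    def test_degenerate_all_hits_flagged(self, default_design):
        data = default_design.head(300).copy()
        data["hit"] = 1
        with pytest.warns(RuntimeWarning):
            f = glmm_core.fit("hit ~ sigma + (1|subject_id)", data)
        with pytest.raises(SeparationError):
            glmm_core.parametric_bootstrap(f, statistic="sigma", n_boot=10, seed=0)
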