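"""End-to-end analysis of hit/miss tracking data.

The inferential engine is the six-model BIC ladder of binomial
random-intercept GLMMs:

    M1  hit ~ poly(sigma,2) * factor(n_items) * factor(area) + (1|subject)
    M2  hit ~ log(n_items) * area * sigma                    + (1|subject)
    M3  M2 without its three-way interaction
    M4  hit ~ poly(density,2) * sigma                        + (1|subject)
    M5  hit ~ density * sigma                                + (1|subject)
    M6  hit ~ poly(density,2) + sigma                        + (1|subject)

M1 treats item number and display area as three-level factors and
unpredictability as a quadratic; M2/M3 ask whether linear terms suffice;
M4-M6 ask whether a single density covariate replaces number and area,
and whether its interaction with unpredictability (the density-dependent
confusion effect) is needed.  Models are compared by BIC; three targeted
likelihood-ratio tests probe the three-way interaction in M1 (df = 8:
2 sigma x 2 items x 2 area contrasts), the three-way interaction in M2
(df = 1) and the density x sigma interaction in M4 (df = 2).  These
degrees of freedom are determined by the factorial design alone.

Descriptive summaries mirror the figures: per-condition logistic slopes
of hit on sigma (fixed-effect fits, pooled over subjects, with a
per-subject variant for t-tests), a quadratic fit of slope against
density, and within-subject (Cousineau-Morey) condition means and 95%
confidence intervals appropriate for a repeated-measures design.

"Area" as a linear covariate means the display side length in pixels by
default; side-squared is available via ``area_covariate="squared"``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import glmm_core
from .glmm_core import GLMMFit, ModelComparison

REQUIRED_COLUMNS = ["subject_id", "n_items", "area_side_px", "sigma", "density", "hit"]

LADDER_FORMULAS = {
    "M1": "hit ~ poly(sigma,2) * factor(n_items) * factor(area_side_px) + (1|subject_id)",
    "M2": "hit ~ log(n_items) * area * sigma + (1|subject_id)",
    "M3": "hit ~ log(n_items) * area + sigma * log(n_items) + sigma * area + (1|subject_id)",
    "M4": "hit ~ poly(density,2) * sigma + (1|subject_id)",
    "M5": "hit ~ density * sigma + (1|subject_id)",
    "M6": "hit ~ poly(density,2) + sigma + (1|subject_id)",
}
# auxiliary reduced model for the M1 three-way LRT (all two-way interactions)
_M1_NO3WAY = (
    "hit ~ poly(sigma,2) * factor(n_items) + poly(sigma,2) * factor(area_side_px)"
    " + factor(n_items) * factor(area_side_px) + (1|subject_id)"
)


@dataclass
class LadderResult:
    """Fits, BICs and targeted LRTs of the six-model ladder."""

    models: dict                      # id -> GLMMFit
    bics: dict                        # id -> float
    comparisons: dict                 # name -> ModelComparison
    selected: str
    failed: dict = field(default_factory=dict)  # id -> message

    def table(self) -> pd.DataFrame:
        rows = []
        for mid, f in self.models.items():
            rows.append(
                {
                    "model": mid,
                    "formula": f.spec.formula,
                    "k": f.n_params,
                    "loglik": f.loglik,
                    "bic": self.bics[mid],
                    "converged": f.converged,
                    "selected": mid == self.selected,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class SlopeProfile:
    """Per-condition sigma slopes and their quadratic trend in density."""

    cell_slopes: pd.DataFrame      # n_items, area_side_px, density, slope, se, ci, flags
    quad_coefs: np.ndarray         # intercept, density, density^2
    quad_result: object            # statsmodels OLS results
    per_subject_slopes: pd.DataFrame


def _check_columns(data: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"data lacks required columns: {missing}")


def _with_area(data: pd.DataFrame, area_covariate: str) -> pd.DataFrame:
    df = data.copy()
    if area_covariate == "side":
        df["area"] = df["area_side_px"].astype(float)
    elif area_covariate == "squared":
        df["area"] = df["area_side_px"].astype(float) ** 2
    else:
        raise ValueError("area_covariate must be 'side' or 'squared'")
    return df


def model_ladder(
    data: pd.DataFrame, area_covariate: str = "side", quad_order: int = 1
) -> LadderResult:
    """Fit the six-model BIC ladder plus the three targeted LRTs.

    All models are fitted on the identical row set.  Individual model
    non-convergence is recorded in ``failed`` and the ladder is returned
    for the converged subset.
    """
    _check_columns(data)
    df = _with_area(data, area_covariate)

    models: dict[str, GLMMFit] = {}
    failed: dict[str, str] = {}
    for mid, formula in LADDER_FORMULAS.items():
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                f = glmm_core.fit(formula, df, quad_order=quad_order)
            if f.converged:
                models[mid] = f
            else:
                failed[mid] = f.message
        except Exception as exc:  # noqa: BLE001 - per-model failures are reported
            failed[mid] = str(exc)
    if not models:
        raise RuntimeError("no ladder model converged")
    ns = {f.n_obs for f in models.values()}
    assert len(ns) == 1, "ladder models fitted on different row sets"

    bics = {mid: glmm_core.bic(f) for mid, f in models.items()}
    comparisons: dict[str, ModelComparison] = {}
    if "M1" in models:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m1_red = glmm_core.fit(_M1_NO3WAY, df, quad_order=quad_order)
        if m1_red.converged:
            comparisons["M1_threeway"] = glmm_core.lrt(models["M1"], m1_red)
    if "M2" in models and "M3" in models:
        comparisons["M2_threeway"] = glmm_core.lrt(models["M2"], models["M3"])
    if "M4" in models and "M6" in models:
        comparisons["M4_interaction"] = glmm_core.lrt(models["M4"], models["M6"])

    selected = min(bics, key=bics.get)
    return LadderResult(models=models, bics=bics, comparisons=comparisons,
                        selected=selected, failed=failed)


def _ridge_logistic(X: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Newton fit of a logistic regression with a small ridge on non-intercept
    terms; always finite, used when the ML fit separates."""
    from scipy.special import expit

    pen = alpha * np.eye(X.shape[1])
    pen[0, 0] = 0.0
    beta = np.zeros(X.shape[1])
    for _ in range(100):
        mu = expit(X @ beta)
        g = X.T @ (y - mu) - pen @ beta
        H = X.T @ (X * (mu * (1 - mu) + 1e-10)[:, None]) + pen
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def _cell_logistic_slope(sub: pd.DataFrame):
    """Fixed-effect logistic slope of hit on sigma for one cell.

    Separation (e.g. a subject at ceiling for every sigma) is flagged and
    the slope replaced by a ridge-stabilised fit so every cell/subject
    still contributes a finite slope; the SE is NaN in that case.
    """
    X = sm.add_constant(sub["sigma"].to_numpy())
    y = sub["hit"].to_numpy(dtype=float)
    separated = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        slope, se = float(res.params[1]), float(res.bse[1])
        if not np.isfinite(slope) or not np.isfinite(se) or abs(slope) > 100:
            separated = True
    except Exception:  # noqa: BLE001
        separated = True
    if separated:
        slope, se = float(_ridge_logistic(X, y)[1]), np.nan
    return slope, se, separated


def condition_slopes(data: pd.DataFrame, weighted_quadratic: bool = False) -> SlopeProfile:
    """Logistic slopes of hit on sigma per (n_items, area) condition.

    The per-cell fits are descriptive fixed-effect logistic regressions
    pooled over subjects (the GLMM remains the inferential engine).  A
    quadratic is then fitted to slope vs density by ordinary least
    squares (optionally weighted by inverse squared slope SE).  A
    per-subject-slope table is also returned for t-tests.
    """
    _check_columns(data)
    rows, subj_rows = [], []
    for (n_items, area), sub in data.groupby(["n_items", "area_side_px"]):
        if sub["sigma"].nunique() < 2:
            raise ValueError(f"cell ({n_items}, {area}) has fewer than two sigma levels")
        slope, se, separated = _cell_logistic_slope(sub)
        ci_half = 1.959963984540054 * se
        rows.append(
            {
                "n_items": n_items,
                "area_side_px": area,
                "density": float(sub["density"].iloc[0]),
                "slope": slope,
                "se": se,
                "ci_low": slope - ci_half,
                "ci_high": slope + ci_half,
                "separated": separated,
            }
        )
        for subject, ssub in sub.groupby("subject_id"):
            s_slope, s_se, s_sep = _cell_logistic_slope(ssub)
            subj_rows.append(
                {
                    "subject_id": subject,
                    "n_items": n_items,
                    "area_side_px": area,
                    "density": float(sub["density"].iloc[0]),
                    "slope": s_slope,
                    "separated": s_sep,
                }
            )
    cell = pd.DataFrame(rows).sort_values(["density", "n_items"]).reset_index(drop=True)
    subj = pd.DataFrame(subj_rows)

    ok = cell[np.isfinite(cell["slope"]) & (~cell["separated"] if weighted_quadratic else True)]
    Xq = np.column_stack([np.ones(len(ok)), ok["density"], ok["density"] ** 2])
    if weighted_quadratic:
        w = 1.0 / np.clip(ok["se"].to_numpy() ** 2, 1e-12, None)
        quad = sm.WLS(ok["slope"].to_numpy(), Xq, weights=w).fit()
    else:
        quad = sm.OLS(ok["slope"].to_numpy(), Xq).fit()
    return SlopeProfile(
        cell_slopes=cell,
        quad_coefs=np.asarray(quad.params),
        quad_result=quad,
        per_subject_slopes=subj,
    )


def per_subject_slope_test(profile: SlopeProfile, n_items: int, area_side_px: int):
    """One-sample t-test that the mean per-subject slope in a cell is zero.

    Returns (t, df, p); df is the number of contributing subjects minus 1.
    """
    sub = profile.per_subject_slopes
    sel = sub[
        (sub["n_items"] == n_items)
        & (sub["area_side_px"] == area_side_px)
        & np.isfinite(sub["slope"])
    ]["slope"]
    if len(sel) < 2:
        raise ValueError("fewer than two usable per-subject slopes in this cell")
    t, p = stats.ttest_1samp(sel, 0.0)
    return float(t), int(len(sel) - 1), float(p)


def lowest_sigma_test(data: pd.DataFrame, quad_order: int = 1) -> ModelComparison:
    """Density effect at the lowest unpredictability level only.

    Filters to the minimum sigma in the data and compares a
    quadratic-density GLMM against an intercept-only GLMM (df = 2).
    """
    _check_columns(data)
    if len(data) == 0:
        raise ValueError("no data")
    sig_min = data["sigma"].min()
    sub = data[np.isclose(data["sigma"], sig_min)]
    if len(sub) == 0:
        raise ValueError("no rows at the lowest sigma level")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        full = glmm_core.fit("hit ~ poly(density,2) + (1|subject_id)", sub, quad_order)
        reduced = glmm_core.fit("hit ~ 1 + (1|subject_id)", sub, quad_order)
    return glmm_core.lrt(full, reduced)


def within_subject_ci(data: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Cousineau-Morey within-subject condition means and CIs.

    Each subject's cell means are normalised by subtracting the subject
    mean and adding the grand mean (removing between-subject variation),
    then the per-cell SD across subjects is inflated by the Morey factor
    sqrt(C/(C-1)) over the C conditions; intervals are t-based.  Subjects
    missing any cell are excluded with a warning.
    """
    _check_columns(data)
    cell_cols = ["n_items", "area_side_px", "sigma"]
    tab = data.groupby(["subject_id", *cell_cols])["hit"].mean().unstack(cell_cols)
    complete = tab.dropna()
    if len(complete) < len(tab):
        dropped = sorted(set(tab.index) - set(complete.index))
        warnings.warn(f"excluding subjects missing cells: {dropped}")
    if len(complete) < 2:
        raise ValueError("need at least two subjects with complete cells")
    n_subj, n_cells = complete.shape
    grand = complete.to_numpy().mean()
    normalised = complete.sub(complete.mean(axis=1), axis=0) + grand
    morey = np.sqrt(n_cells / (n_cells - 1))
    means = normalised.mean(axis=0)
    sds = normalised.std(axis=0, ddof=1) * morey
    half = stats.t.ppf(0.5 + level / 2.0, n_subj - 1) * sds / np.sqrt(n_subj)
    out = means.rename("mean").reset_index()
    out["ci_low"] = (means - half).to_numpy()
    out["ci_high"] = (means + half).to_numpy()
    out["n_subjects"] = n_subj
    return out


def run_report(data: pd.DataFrame, out_dir, area_covariate: str = "side") -> dict:
    """Run the full analysis and write tables, figures and a text summary.

    Emits ``ladder.csv``/``ladder.json``, ``conditions.png`` (hit rate vs
    sigma per condition with within-subject CIs), ``slopes.png`` (slope
    vs density with the quadratic trend) and ``summary.txt``.  Returns
    the paths and key results.
    """
    _check_columns(data)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ladder = model_ladder(data, area_covariate=area_covariate)
    profile = condition_slopes(data)
    ci = within_subject_ci(data)
    low = lowest_sigma_test(data)

    ladder_table = ladder.table()
    ladder_table.to_csv(out / "ladder.csv", index=False)
    (out / "ladder.json").write_text(
        json.dumps(
            {
                "models": {m: f.to_dict() for m, f in ladder.models.items()},
                "bics": ladder.bics,
                "selected": ladder.selected,
                "failed": ladder.failed,
                "comparisons": {
                    k: {"chi_sq": c.chi_sq, "df": c.df, "p_value": c.p_value,
                        "bic_full": c.bic_full, "bic_reduced": c.bic_reduced}
                    for k, c in ladder.comparisons.items()
                },
                "lowest_sigma_test": {"chi_sq": low.chi_sq, "df": low.df,
                                      "p_value": low.p_value},
            },
            indent=2,
        )
    )

    _plot_conditions(data, ci, out / "conditions.png")
    _plot_slopes(profile, out / "slopes.png")

    lines = [
        "Model ladder (binomial GLMM, subject random intercept):",
        ladder_table.to_string(index=False),
        "",
        f"Selected by BIC: {ladder.selected}",
    ]
    for name, c in ladder.comparisons.items():
        lines.append(f"LRT {name}: chi2 = {c.chi_sq:.3f}, df = {c.df}, p = {c.p_value:.4g}")
    lines.append(
        f"Lowest-sigma density test: chi2 = {low.chi_sq:.3f}, df = {low.df}, "
        f"p = {low.p_value:.4g}"
    )
    lines.append("")
    lines.append("Slope vs density quadratic coefficients "
                 f"(intercept, d, d^2): {np.round(profile.quad_coefs, 4).tolist()}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")

    return {
        "ladder": ladder,
        "slopes": profile,
        "within_subject_ci": ci,
        "lowest_sigma_test": low,
        "paths": {
            "ladder_csv": out / "ladder.csv",
            "ladder_json": out / "ladder.json",
            "conditions_png": out / "conditions.png",
            "slopes_png": out / "slopes.png",
            "summary_txt": out / "summary.txt",
        },
    }


def _plot_conditions(data: pd.DataFrame, ci: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    items_levels = sorted(data["n_items"].unique())
    area_levels = sorted(data["area_side_px"].unique())
    cmap = plt.get_cmap("viridis")
    densities = sorted({round(float(d), 6) for d in data["density"].unique()})

    fig, axes = plt.subplots(
        len(items_levels), len(area_levels), figsize=(9, 8), sharex=True, sharey=True
    )
    axes = np.atleast_2d(axes)
    for i, n_items in enumerate(items_levels):
        for j, area in enumerate(area_levels):
            ax = axes[i, j]
            sub = ci[(ci["n_items"] == n_items) & (ci["area_side_px"] == area)]
            d = float(data[(data["n_items"] == n_items)
                           & (data["area_side_px"] == area)]["density"].iloc[0])
            colour = cmap(densities.index(round(d, 6)) / max(1, len(densities) - 1))
            ax.errorbar(
                sub["sigma"], sub["mean"],
                yerr=[sub["mean"] - sub["ci_low"], sub["ci_high"] - sub["mean"]],
                fmt="o", ms=4, color=colour, capsize=2,
            )
            ax.set_xscale("log")
            ax.set_ylim(0, 1.05)
            ax.set_title(f"{n_items} items, {area} px", fontsize=9)
    fig.supxlabel("unpredictability sigma (rad, log scale)")
    fig.supylabel("proportion of targets tracked")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_slopes(profile: SlopeProfile, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cell = profile.cell_slopes
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.errorbar(
        cell["density"], cell["slope"],
        yerr=[cell["slope"] - cell["ci_low"], cell["ci_high"] - cell["slope"]],
        fmt="o", capsize=3,
    )
    grid = np.linspace(cell["density"].min(), cell["density"].max(), 200)
    a, b, c = profile.quad_coefs
    ax.plot(grid, a + b * grid + c * grid**2, "-")
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("density (items per 10^4 px^2)")
    ax.set_ylabel("logistic slope of hit on sigma")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
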