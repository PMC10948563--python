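"""Mixed-model ANOVA machinery for the three responses.

Model structure mirrors the field study's analysis:

* absorptive fine-root density — linear mixed model on log(x + 1)
  density with species x soil depth x water treatment fixed effects
  (all 2- and 3-way interactions), random intercepts for block and plot;
* dead fine-root density — density x 10 rounded to the nearest integer
  (half-up) and fit as Poisson counts, same fixed-effect structure;
* weighted mean rooting depth — Box-Cox transformed, species x treatment
  fixed effects, block random intercept (depth is one value per plot, so
  no plot term is needed).

Type-III tables use sum-to-zero contrasts and joint Wald tests on the
fixed effects.  Denominator degrees of freedom follow the classic
split-plot partition: terms that vary only between plots (species,
treatment and their interaction) are tested against plot-level df,
terms involving soil depth against the residual df.  Per-species
high-vs-low contrasts are extracted per stratum and Holm-adjusted within
each stratum's family of six species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from scipy.special import inv_boxcox

from .errors import ValidationError

TABLE1_TERMS_DENSITY = [
    "Species", "Soil depth", "H2O",
    "Species x Soil depth", "Species x H2O", "Soil depth x H2O",
    "Species x Soil depth x H2O",
]
TABLE1_TERMS_DEPTH = ["Species", "H2O", "Species x H2O"]

_FORMULA_DENSITY = (
    "y ~ C(species_code, Sum) * C(stratum_index, Sum) * C(treatment, Sum)"
)
_TERM_LABELS_DENSITY = {
    "C(species_code, Sum)": "Species",
    "C(stratum_index, Sum)": "Soil depth",
    "C(treatment, Sum)": "H2O",
    "C(species_code, Sum):C(stratum_index, Sum)": "Species x Soil depth",
    "C(species_code, Sum):C(treatment, Sum)": "Species x H2O",
    "C(stratum_index, Sum):C(treatment, Sum)": "Soil depth x H2O",
    "C(species_code, Sum):C(stratum_index, Sum):C(treatment, Sum)":
        "Species x Soil depth x H2O",
}
_FORMULA_DEPTH = "y ~ C(species_code, Sum) * C(treatment, Sum)"
_TERM_LABELS_DEPTH = {
    "C(species_code, Sum)": "Species",
    "C(treatment, Sum)": "H2O",
    "C(species_code, Sum):C(treatment, Sum)": "Species x H2O",
}


# ---------------------------------------------------------------- transforms

def transform_log1p(density):
    """Natural log of (density + 1); densities must be non-negative."""
    arr = np.asarray(density, dtype=float)
    if (arr < 0).any():
        raise ValidationError("log1p transform requires non-negative densities")
    return np.log1p(arr)


def inverse_log1p(transformed):
    return np.expm1(np.asarray(transformed, dtype=float))


def transform_dead_counts(density):
    """Density x 10, rounded half-up to a non-negative integer count."""
    arr = np.asarray(density, dtype=float)
    if (arr < 0).any():
        raise ValidationError("count transform requires non-negative densities")
    return np.floor(arr * 10.0 + 0.5).astype(int)


def transform_boxcox(depths):
    """Box-Cox transform with maximum-likelihood lambda.

    Returns (transformed values, lambda); inputs must be strictly
    positive.  lambda = 0 corresponds to the log transform.
    """
    arr = np.asarray(depths, dtype=float)
    if (arr <= 0).any():
        raise ValidationError("Box-Cox requires strictly positive values")
    transformed, lam = scipy.stats.boxcox(arr)
    return transformed, float(lam)


def inverse_boxcox(transformed, lam: float):
    return inv_boxcox(np.asarray(transformed, dtype=float), lam)


# ------------------------------------------------------------------ results

@dataclass
class FittedAnova:
    """Type-III table, post-hoc contrasts and fit metadata for one response."""

    response: str
    anova: pd.DataFrame
    contrasts: pd.DataFrame = field(repr=False)
    metadata: dict = field(default_factory=dict)


def _term_slices(design_info, labels: dict) -> dict[str, slice]:
    return {
        labels[name]: design_info.term_name_slices[name]
        for name in design_info.term_names
        if name in labels
    }


def _wald_term_table(
    fe_params: np.ndarray,
    fe_cov: np.ndarray,
    design_info,
    labels: dict,
    den_df: dict[str, float] | None,
    stat_name: str,
) -> pd.DataFrame:
    """Joint Wald test per model term.

    With ``den_df`` given, the Wald chi-square is converted to an F
    statistic (chi2 / q) against that term's denominator df; otherwise a
    chi-square test is reported (``stat_name`` = "X2").
    """
    rows = []
    for label, sl in _term_slices(design_info, labels).items():
        idx = np.arange(sl.start, sl.stop)
        c = fe_params[idx]
        v = fe_cov[np.ix_(idx, idx)]
        q = len(idx)
        chi2 = float(c @ np.linalg.solve(v, c))
        if den_df is not None:
            f_stat = chi2 / q
            ddf = den_df[label]
            p = float(scipy.stats.f.sf(f_stat, q, ddf))
            rows.append({"term": label, "num_df": q, "den_df": ddf,
                         stat_name: f_stat, "p_value": p})
        else:
            p = float(scipy.stats.chi2.sf(chi2, q))
            rows.append({"term": label, "df": q, stat_name: chi2, "p_value": p})
    return pd.DataFrame(rows)


def _density_denominator_df(df: pd.DataFrame, k_fe: int) -> dict[str, float]:
    """Split-plot df partition for the density models."""
    n_plots = df["plot_id"].nunique()
    n_species = df["species_code"].nunique()
    between_params = n_species * 2  # species x treatment cell means
    between_df = max(n_plots - between_params, 1)
    within_df = max(len(df) - k_fe, 1)
    return {
        "Species": between_df, "H2O": between_df, "Species x H2O": between_df,
        "Soil depth": within_df, "Species x Soil depth": within_df,
        "Soil depth x H2O": within_df, "Species x Soil depth x H2O": within_df,
    }


def _fit_lmm_with_fallback(formula: str, df: pd.DataFrame, use_plot_vc: bool):
    """Fit a block-grouped LMM, simplifying the random structure on failure.

    Ladder: block intercept + plot intercepts (variance component) ->
    block intercept only -> OLS.  Returns (results, fe_params, fe_cov,
    design_info, metadata).
    """
    attempts = []
    if use_plot_vc:
        attempts.append(("block+plot", {"vc_formula": {"plot": "0 + C(plot_id)"}}))
    attempts.append(("block", {}))
    last_error = None
    for name, extra in attempts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, data=df, groups="block",
                                    re_formula="1", **extra)
                res = model.fit(method="lbfgs", reml=True, maxiter=500)
            fe = np.asarray(res.fe_params)
            cov = np.asarray(res.cov_params())[: len(fe), : len(fe)]
            if not np.all(np.isfinite(cov)):
                raise np.linalg.LinAlgError("non-finite fixed-effect covariance")
            meta = {"random_structure": name, "converged": bool(res.converged)}
            return res, fe, cov, res.model.data.design_info, meta
        except (np.linalg.LinAlgError, ValueError) as err:  # pragma: no cover
            last_error = err
            continue
    with warnings.catch_warnings():  # pragma: no cover
        warnings.simplefilter("ignore")
        res = smf.ols(formula, data=df).fit()
    meta = {"random_structure": "none (OLS fallback)", "converged": True,
            "fallback_reason": repr(last_error)}
    return (res, np.asarray(res.params), np.asarray(res.cov_params()),
            res.model.data.design_info, meta)


# ----------------------------------------------------------------- contrasts

def _treatment_contrasts(
    fe_params, fe_cov, design_info, df, den_df: float,
    strata: list | None = None, constants: dict | None = None,
) -> pd.DataFrame:
    """High-vs-low contrast per species (x stratum), Holm-adjusted.

    The family for adjustment is the set of six species contrasts within
    one stratum (or the single family of six for the depth model).
    ``constants`` pins additive covariates (e.g. block) to a reference
    level; their columns cancel in the high-minus-low difference.
    """
    species = sorted(df["species_code"].unique())
    if strata is None:
        strata = [None]
    rows = []
    for s in strata:
        for code in species:
            new = {"species_code": [code, code], "treatment": ["high", "low"]}
            if s is not None:
                new["stratum_index"] = [s, s]
            for col, value in (constants or {}).items():
                new[col] = [value, value]
            (x,) = build_design_matrices([design_info], pd.DataFrame(new))
            diff = np.asarray(x)[0] - np.asarray(x)[1]
            est = float(diff @ fe_params)
            se = float(np.sqrt(diff @ fe_cov @ diff))
            t = est / se if se > 0 else np.inf
            p = 2.0 * float(scipy.stats.t.sf(abs(t), den_df))
            rows.append({"species_code": code, "stratum_index": s,
                         "estimate": est, "se": se, "t": t, "p_value": p})
    out = pd.DataFrame(rows)
    adj = np.full(len(out), np.nan)
    for s in strata:
        mask = (
            out["stratum_index"].isna() if s is None
            else out["stratum_index"] == s
        ).to_numpy()
        adj[mask] = _holm(out.loc[mask, "p_value"].to_numpy())
    out["p_adjusted"] = adj
    return out


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment of a family of p-values."""
    order = np.argsort(p)
    m = len(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adjusted[i] = min(running, 1.0)
    return adjusted


# --------------------------------------------------------------- model fits

def fit_absorptive_lmm(densities: pd.DataFrame,
                       use_plot_vc: bool = True) -> FittedAnova:
    """Table-style Type-III ANOVA for log(x+1) absorptive density."""
    df = densities.copy()
    df["y"] = transform_log1p(df["absorptive_density"])
    res, fe, cov, design_info, meta = _fit_lmm_with_fallback(
        _FORMULA_DENSITY, df, use_plot_vc
    )
    den_df = _density_denominator_df(df, len(fe))
    anova = _wald_term_table(fe, cov, design_info, _TERM_LABELS_DENSITY,
                             den_df, "F")
    contrasts = _treatment_contrasts(
        fe, cov, design_info, df, den_df["Species"],
        strata=sorted(df["stratum_index"].unique()),
    )
    meta.update({"transform": "log1p", "family": "gaussian",
                 "formula": _FORMULA_DENSITY})
    return FittedAnova("absorptive_density", anova, contrasts, meta)


def fit_dead_glm(densities: pd.DataFrame) -> FittedAnova:
    """Poisson model of x10-rounded dead-root density counts.

    Fit as a Poisson GLM with block entering as a fixed covariate to
    absorb block-level heterogeneity; Type-III Wald chi-square per term.
    """
    df = densities.copy()
    df["y"] = transform_dead_counts(df["dead_density"])
    formula = _FORMULA_DENSITY + " + C(block, Sum)"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = smf.glm(formula, data=df, family=sm.families.Poisson()).fit()
    fe = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    design_info = res.model.data.design_info
    anova = _wald_term_table(fe, cov, design_info, _TERM_LABELS_DENSITY,
                             None, "X2")
    contrasts = _treatment_contrasts(
        fe, cov, design_info, df, np.inf,
        strata=sorted(df["stratum_index"].unique()),
        constants={"block": df["block"].iloc[0]},
    )
    meta = {"transform": "times10_round", "family": "poisson",
            "formula": formula, "random_structure": "block as fixed effect",
            "converged": bool(res.converged)}
    return FittedAnova("dead_density", anova, contrasts, meta)


def fit_depth_lmm(profiles: pd.DataFrame) -> FittedAnova:
    """Box-Cox LMM for weighted mean rooting depth (species x H2O)."""
    df = profiles.copy()
    y, lam = transform_boxcox(df["weighted_mean_depth_cm"])
    df["y"] = y
    res, fe, cov, design_info, meta = _fit_lmm_with_fallback(
        _FORMULA_DEPTH, df, use_plot_vc=False
    )
    n_plots = len(df)
    den = max(n_plots - len(fe), 1)
    den_df = {label: den for label in TABLE1_TERMS_DEPTH}
    anova = _wald_term_table(fe, cov, design_info, _TERM_LABELS_DEPTH,
                             den_df, "F")
    contrasts = _treatment_contrasts(fe, cov, design_info, df, den)
    meta.update({"transform": "boxcox", "boxcox_lambda": lam,
                 "family": "gaussian", "formula": _FORMULA_DEPTH})
    return FittedAnova("weighted_mean_depth", anova, contrasts, meta)


def fit_table1_models(densities: pd.DataFrame,
                      profiles: pd.DataFrame,
                      use_plot_vc: bool = True) -> dict[str, FittedAnova]:
    """All three response models, keyed by response name."""
    return {
        "absorptive_density": fit_absorptive_lmm(densities, use_plot_vc),
        "dead_density": fit_dead_glm(densities),
        "weighted_mean_depth": fit_depth_lmm(profiles),
    }


def correlation_report(plot_table: pd.DataFrame,
                       columns: list[str]) -> pd.DataFrame:
    """Pairwise Pearson correlations among candidate predictors.

    Collinearity screen: pairs with |r| >= 0.5 are flagged and should not
    enter the same model.
    """
    rows = []
    for i, a in enumerate(columns):
        for b in columns[i + 1:]:
            r = float(np.corrcoef(plot_table[a], plot_table[b])[0, 1])
            rows.append({"var_a": a, "var_b": b, "pearson_r": r,
                         "collinear": abs(r) >= 0.5})
    return pd.DataFrame(rows)
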