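"""Week-24 statistical battery.

Pearson correlations, multivariable OLS with standardized coefficients,
ANCOVA (Type-II factor F with Bonferroni post-hoc comparisons), the
exposure x sex interaction model, sex-stratified models, and regression
diagnostics — assembled into a serializable AnalysisReport.

OLS fitting itself is delegated to statsmodels; everything layered on top
(standardized betas, the nested-model ANCOVA F, adjusted means, contrasts)
is computed here so that each quantity has a single explicit definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._errors import (
    CollinearityError,
    GroupingError,
    StateError,
    UndefinedStatisticError,
)
from .distributions import LikertSpec
from .outcomes import EXPOSURE_CATEGORIES
from .psychometrics import (
    ReliabilityReport,
    convergent_validity,
    cronbach_alpha,
    icc_test_retest,
)

__all__ = [
    "RegressionTable",
    "AncovaTable",
    "DiagnosticsReport",
    "pearson_r",
    "fit_linear_model",
    "ancova",
    "interaction_model",
    "diagnostics",
    "build_report",
    "REPORT_SCHEMA_VERSION",
    "REPORT_SECTIONS",
]

REPORT_SCHEMA_VERSION = 1
REPORT_SECTIONS = (
    "correlations", "regression_sahl", "regression_density", "ancova",
    "interaction", "stratified", "psychometrics", "diagnostics",
)


@dataclass(frozen=True)
class RegressionTable:
    """OLS results: per-predictor B, standardized beta, 95% CI on B, p."""

    predictors: list[str]
    B: np.ndarray
    beta_std: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    r2: float
    adj_r2: float
    n: int
    df_resid: int
    resid: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "rows": [
                {
                    "predictor": name,
                    "B": float(self.B[i]),
                    "beta_std": None if self.beta_std[i] is None or np.isnan(self.beta_std[i]) else float(self.beta_std[i]),
                    "ci_low": float(self.ci_low[i]),
                    "ci_high": float(self.ci_high[i]),
                    "p": float(self.p[i]),
                }
                for i, name in enumerate(self.predictors)
            ],
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "n": self.n,
            "df_resid": self.df_resid,
        }


@dataclass(frozen=True)
class AncovaTable:
    factor_F: float
    df1: int
    df2: int
    p: float
    covariates: list[dict]
    adjusted_means: dict
    posthoc: list[dict]
    group_counts: dict

    def to_dict(self) -> dict:
        return {
            "factor_F": self.factor_F, "df1": self.df1, "df2": self.df2,
            "p": self.p, "covariates": self.covariates,
            "adjusted_means": self.adjusted_means, "posthoc": self.posthoc,
            "group_counts": self.group_counts,
        }


@dataclass(frozen=True)
class DiagnosticsReport:
    resid_skewness: float
    resid_excess_kurtosis: float
    levene_W: float
    levene_p: float
    qq: list
    alpha_recomputed: float | None = None

    def to_dict(self) -> dict:
        return {
            "resid_skewness": self.resid_skewness,
            "resid_excess_kurtosis": self.resid_excess_kurtosis,
            "levene_W": self.levene_W,
            "levene_p": self.levene_p,
            "qq": self.qq,
            "alpha_recomputed": self.alpha_recomputed,
        }


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with a two-sided p from the t transform on n-2 df."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise StateError("inputs must be equal-length 1-D vectors, length >= 3")
    if np.var(a) == 0 or np.var(b) == 0:
        raise UndefinedStatisticError("zero variance input")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def _design(predictors: dict[str, np.ndarray], n: int) -> pd.DataFrame:
    X = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in predictors.items()})
    if len(X) != n:
        raise StateError("predictor lengths do not match outcome length")
    return X


def _check_rank(X: pd.DataFrame) -> None:
    M = sm.add_constant(X, has_constant="add").to_numpy()
    if np.linalg.matrix_rank(M) < M.shape[1]:
        bad = []
        for col in X.columns:
            sub = sm.add_constant(X.drop(columns=[col]), has_constant="add")
            if np.linalg.matrix_rank(sub.to_numpy()) == np.linalg.matrix_rank(M):
                bad.append(col)
        raise CollinearityError(
            f"design matrix is rank deficient; offending columns: {bad or list(X.columns)}"
        )


def fit_linear_model(
    outcome: np.ndarray, predictors: dict[str, np.ndarray]
) -> RegressionTable:
    """OLS of ``outcome`` on the named predictors (intercept added).

    Standardized beta_j = B_j * SD(x_j) / SD(y); 95% CIs via the t
    distribution on the residual df; adjusted R² = 1-(1-R²)(n-1)/(n-p-1).
    """
    y = np.asarray(outcome, dtype=float)
    n = y.size
    X = _design(predictors, n)
    if n <= X.shape[1] + 1:
        raise StateError("need n > number of predictors + 1")
    _check_rank(X)
    model = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    names = ["const"] + list(X.columns)
    ci = model.conf_int(alpha=0.05)
    sy = np.std(y, ddof=1)
    beta_std = np.full(len(names), np.nan)
    for i, name in enumerate(names):
        if name != "const":
            beta_std[i] = model.params[name] * np.std(X[name], ddof=1) / sy
    return RegressionTable(
        predictors=names,
        B=model.params.to_numpy(),
        beta_std=beta_std,
        ci_low=ci[0].to_numpy(),
        ci_high=ci[1].to_numpy(),
        p=model.pvalues.to_numpy(),
        r2=float(model.rsquared),
        adj_r2=float(model.rsquared_adj),
        n=n,
        df_resid=int(model.df_resid),
        resid=model.resid,
    )


def _factor_levels(factor: np.ndarray) -> list[str]:
    levels = list(pd.unique(np.asarray(factor).astype(str)))
    # use the canonical dose ordering whenever the labels match it
    if set(levels) <= set(EXPOSURE_CATEGORIES):
        return [c for c in EXPOSURE_CATEGORIES if c in levels]
    return sorted(levels)


def ancova(
    outcome: np.ndarray,
    factor: np.ndarray,
    covariates: dict[str, np.ndarray],
) -> AncovaTable:
    """ANCOVA with a Type-II factor F (full vs drop-factor nested comparison).

    Adjusted group means are model predictions at the covariate means;
    post-hoc pairwise comparisons are t contrasts on the factor dummies with
    Bonferroni-adjusted p-values.
    """
    y = np.asarray(outcome, dtype=float)
    f = np.asarray(factor).astype(str)
    levels = _factor_levels(f)
    counts = {lv: int(np.sum(f == lv)) for lv in levels}
    if len(levels) < 2 or min(counts.values()) == 0:
        raise GroupingError(f"need >= 2 non-empty groups; counts: {counts}")
    X_cov = _design(covariates, y.size) if covariates else pd.DataFrame(index=range(y.size))
    dummies = pd.DataFrame(
        {f"grp_{lv}": (f == lv).astype(float) for lv in levels[1:]}
    )
    X_full = pd.concat([X_cov.reset_index(drop=True), dummies], axis=1)
    if covariates:
        _check_rank(X_full)
    full = sm.OLS(y, sm.add_constant(X_full, has_constant="add")).fit()
    if covariates:
        reduced = sm.OLS(y, sm.add_constant(X_cov, has_constant="add")).fit()
    else:
        reduced = sm.OLS(y, np.ones((y.size, 1))).fit()
    df1 = len(levels) - 1
    df2 = int(full.df_resid)
    rss_f, rss_r = full.ssr, reduced.ssr
    F = ((rss_r - rss_f) / df1) / (rss_f / df2)
    p = float(stats.f.sf(F, df1, df2))

    cov_rows = [
        {"covariate": c, "B": float(full.params[c]), "p": float(full.pvalues[c])}
        for c in X_cov.columns
    ]
    cov_means = {c: float(np.mean(X_cov[c])) for c in X_cov.columns}
    base = float(full.params["const"]) + sum(
        full.params[c] * cov_means[c] for c in X_cov.columns
    )
    adjusted = {levels[0]: base}
    for lv in levels[1:]:
        adjusted[lv] = base + float(full.params[f"grp_{lv}"])

    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
    m = len(pairs)
    V = full.cov_params()
    posthoc = []
    for a, b in pairs:
        contrast = pd.Series(0.0, index=full.params.index)
        if a != levels[0]:
            contrast[f"grp_{a}"] = 1.0
        if b != levels[0]:
            contrast[f"grp_{b}"] = -1.0
        diff = float(contrast @ full.params)
        se = float(np.sqrt(contrast @ V @ contrast))
        t = diff / se
        praw = 2.0 * float(stats.t.sf(abs(t), df2))
        posthoc.append({
            "pair": f"{a} vs {b}", "diff": diff, "se": se, "t": t,
            "p_raw": praw, "p_bonferroni": min(1.0, m * praw),
        })
    return AncovaTable(
        factor_F=float(F), df1=df1, df2=df2, p=p, covariates=cov_rows,
        adjusted_means={k: float(v) for k, v in adjusted.items()},
        posthoc=posthoc, group_counts=counts,
    )


def interaction_model(
    outcome: np.ndarray,
    X: np.ndarray,
    sex: np.ndarray,
    covariates: dict[str, np.ndarray],
) -> RegressionTable:
    """OLS with a centered-exposure x sex product term appended."""
    x = np.asarray(X, dtype=float)
    s = np.asarray(sex, dtype=float)
    preds = {"exposure": x, "sex": s}
    preds.update({k: np.asarray(v, dtype=float) for k, v in covariates.items()
                  if k not in preds})
    preds["exposure_x_sex"] = (x - x.mean()) * s
    return fit_linear_model(outcome, preds)


def diagnostics(
    residuals: np.ndarray,
    factor: np.ndarray,
    alpha_recomputed: float | None = None,
    n_qq: int = 100,
) -> DiagnosticsReport:
    """Residual shape, variance homogeneity across strata, QQ pairs.

    Levene's test uses the median center (Brown-Forsythe variant). QQ output
    is ``n_qq`` (theoretical, empirical) normal quantile pairs of the
    standardized residuals, sorted by theoretical quantile.
    """
    r = np.asarray(residuals, dtype=float)
    if r.size < 3:
        raise StateError("need at least 3 residuals")
    f = np.asarray(factor).astype(str)
    groups = [r[f == lv] for lv in _factor_levels(f)]
    groups = [g for g in groups if g.size >= 2]
    if len(groups) >= 2:
        W, p = stats.levene(*groups, center="median")
    else:
        W, p = np.nan, np.nan
    z = (r - r.mean()) / np.std(r, ddof=1)
    probs = (np.arange(1, n_qq + 1) - 0.5) / n_qq
    qq = [
        [float(t), float(e)]
        for t, e in zip(stats.norm.ppf(probs), np.quantile(np.sort(z), probs))
    ]
    return DiagnosticsReport(
        resid_skewness=float(stats.skew(r)),
        resid_excess_kurtosis=float(stats.kurtosis(r)),
        levene_W=float(W),
        levene_p=float(p),
        qq=qq,
        alpha_recomputed=alpha_recomputed,
    )


# ---------------------------------------------------------------------------
# report assembly

def _item_matrix(df: pd.DataFrame, prefix: str, n_items: int) -> np.ndarray:
    cols = [f"{prefix}_{j + 1}" for j in range(n_items)]
    return df[cols].to_numpy(dtype=float)


def _safe(fn, *args, **kwargs):
    """Run an estimator; degrade to an error marker instead of aborting."""
    try:
        return fn(*args, **kwargs), None
    except UndefinedStatisticError as e:
        return None, {"error": str(e)}
    except (CollinearityError, GroupingError, StateError) as e:
        return None, {"error": str(e)}


def build_report(
    df: pd.DataFrame,
    likert: LikertSpec | None = None,
    provenance: dict | None = None,
) -> dict:
    """Full AnalysisReport as a nested JSON-serializable dict.

    Week-24 sections are marked ``skipped`` when the Week-24 columns are
    absent; degenerate inputs (zero-variance columns, empty strata) yield
    per-statistic error markers rather than a failed report.
    """
    likert = likert or LikertSpec()
    n_items = likert.n_items
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION}
    if provenance:
        report["provenance"] = provenance

    has_wk24 = "sahl_total_week24" in df.columns and "density_week24" in df.columns
    covs = {
        "age": df["age"].to_numpy(float),
        "sex": df["sex"].to_numpy(float),
        "diet": df["diet"].to_numpy(float),
    }
    x = df["exposure"].to_numpy(float)

    # correlations
    corr: dict = {}
    pairs = [("exposure", "sahl_total_baseline")]
    if has_wk24:
        pairs += [
            ("exposure", "sahl_total_week24"),
            ("exposure", "density_week24"),
            ("sahl_total_week24", "density_week24"),
        ]
    for a, b in pairs:
        val, err = _safe(pearson_r, df[a].to_numpy(float), df[b].to_numpy(float))
        corr[f"{a}__{b}"] = {"r": val[0], "p": val[1]} if val else err
    report["correlations"] = corr

    if not has_wk24:
        for sec in ("regression_sahl", "regression_density", "ancova",
                    "interaction", "stratified", "psychometrics", "diagnostics"):
            report[sec] = {"skipped": "Week-24 columns absent"}
        return report

    s24 = df["sahl_total_week24"].to_numpy(float)
    d24 = df["density_week24"].to_numpy(float)
    preds = {"exposure": x, **covs}

    reg_s, err = _safe(fit_linear_model, s24, preds)
    report["regression_sahl"] = reg_s.to_dict() if reg_s else err
    reg_d, err = _safe(fit_linear_model, d24, preds)
    report["regression_density"] = reg_d.to_dict() if reg_d else err

    anc, err = _safe(ancova, d24, df["exposure_category"].to_numpy(), covs)
    report["ancova"] = anc.to_dict() if anc else err

    inter, err = _safe(
        interaction_model, d24, x, covs["sex"],
        {"age": covs["age"], "diet": covs["diet"]},
    )
    report["interaction"] = inter.to_dict() if inter else err

    strat: dict = {}
    for label, code in (("male", 0), ("female", 1)):
        mask = df["sex"].to_numpy() == code
        entry: dict = {"n": int(mask.sum())}
        if mask.sum() >= 5:
            sub, err = _safe(
                fit_linear_model, d24[mask],
                {"exposure": x[mask], "age": covs["age"][mask],
                 "diet": covs["diet"][mask]},
            )
            entry["regression_density"] = sub.to_dict() if sub else err
            entry["sahl_week24_mean"] = float(np.mean(s24[mask]))
        else:
            entry["regression_density"] = {"error": "stratum too small"}
        strat[label] = entry
    report["stratified"] = strat

    base_items = _item_matrix(df, "sahl_base_item", n_items)
    wk24_items = _item_matrix(df, "sahl_wk24_item", n_items)
    s0 = df["sahl_total_baseline"].to_numpy(float)
    a0, e0 = _safe(cronbach_alpha, base_items)
    a24, e24 = _safe(cronbach_alpha, wk24_items)
    icc, eicc = _safe(icc_test_retest, s0, s24)
    conv, econv = _safe(convergent_validity, s24, d24)
    report["psychometrics"] = ReliabilityReport(
        alpha_baseline=a0 if a0 is not None else float("nan"),
        alpha_week24=a24 if a24 is not None else float("nan"),
        icc_test_retest=icc if icc is not None else float("nan"),
        convergent_r=conv if conv is not None else float("nan"),
    ).to_dict()

    if reg_d is not None:
        diag, err = _safe(
            diagnostics, reg_d.resid, df["exposure_category"].to_numpy(),
            alpha_recomputed=a24,
        )
        report["diagnostics"] = diag.to_dict() if diag else err
    else:
        report["diagnostics"] = {"skipped": "density regression unavailable"}
    return report
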