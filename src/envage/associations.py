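"""Covariate-adjusted association testing with BH-FDR families.

Linear models of each aging metric on exposures (IQR-scaled, one at a time)
or on subpopulation membership, adjusted for the standard covariate set
(age, sex, ethnicity, SES, smoking, BMI category, alcohol, exercise, diet,
CVD and cancer history).  P-values within an analysis family are adjusted by
the Benjamini-Hochberg step-up procedure at FDR 0.05 (the procedure controls
the false discovery rate, not the family-wise error rate).  Sensitivity
variants: stratified fits, a >= 5-year residence filter, and an individual
SES variable built by a three-class latent class analysis (EM on categorical
income/education/employment indicators).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exposure_prep import iqr_scale
from .wqs import build_design, _collinear_columns

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_COVARIATES",
    "RegressionSpec",
    "RegressionResult",
    "LCAResult",
    "fit_linear",
    "bh_adjust",
    "single_exposure_scan",
    "stratified_scan",
    "residence_filter",
    "lca_ses",
    "spearman_matrix",
    "describe_cohort",
]

DEFAULT_COVARIATES = [
    "age", "sex", "ethnicity", "nses", "smoking", "bmi_cat",
    "alcohol", "exercise", "diet", "cvd", "cancer",
]

_Z95 = 1.959963984540054


@dataclass
class RegressionSpec:
    outcome: str
    predictor: str
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    stratum: tuple[str, object] | None = None   # (column, value) filter
    family: str = "main"

    def validate(self) -> None:
        if self.predictor in self.covariates:
            raise ValueError(f"predictor {self.predictor!r} must not appear among the covariates")


@dataclass
class RegressionResult:
    spec: RegressionSpec
    beta: float
    se: float
    ci: tuple[float, float]      # beta +- 1.96 SE
    p_value: float
    n: int                       # complete-case rows used
    iqr: float | None = None     # set when the predictor was IQR-scaled
    p_adjusted: float | None = None
    significant_fdr: bool | None = None


def fit_linear(spec: RegressionSpec, cohort: pd.DataFrame) -> RegressionResult:
    """OLS of the outcome on the predictor plus dummy-coded covariates.

    Complete-case per model; categorical covariates are dummy-coded with the
    alphabetically first level as reference. Raises on rank deficiency,
    naming the collinear columns.
    """
    import statsmodels.api as sm

    spec.validate()
    df = cohort
    if spec.stratum is not None:
        col, val = spec.stratum
        df = df[df[col] == val]
    use = [spec.outcome, spec.predictor] + spec.covariates
    before = len(df)
    df = df.dropna(subset=use)
    if before - len(df):
        logger.info("fit_linear %s~%s: dropped %d incomplete rows", spec.outcome, spec.predictor, before - len(df))
    C, cov_names = build_design(df, spec.covariates)
    if len(df) < (0 if C is None else C.shape[1]) + 10:
        raise ValueError(f"too few complete cases ({len(df)}) for {spec.outcome}~{spec.predictor}")
    y = df[spec.outcome].to_numpy(dtype=float)
    x = df[spec.predictor].to_numpy(dtype=float)
    names = ["const", spec.predictor] + cov_names
    X = np.column_stack([np.ones(len(df)), x] + ([C] if C is not None else []))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient design; collinear columns: {_collinear_columns(X, names)}")
    fit = sm.OLS(y, X).fit()
    b, se = float(fit.params[1]), float(fit.bse[1])
    return RegressionResult(spec=spec, beta=b, se=se, ci=(b - _Z95 * se, b + _Z95 * se),
                            p_value=float(fit.pvalues[1]), n=len(df))


def bh_adjust(p_values, fdr: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted p-values and decisions at ``fdr``.

    adjusted p_(i) = min over j >= i of m * p_(j) / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adj_sorted, 1.0)
    return adjusted, adjusted <= fdr


def _apply_family_fdr(results: list[RegressionResult], fdr: float = 0.05) -> None:
    by_family: dict[str, list[RegressionResult]] = {}
    for r in results:
        by_family.setdefault(r.spec.family, []).append(r)
    for members in by_family.values():
        adjusted, decisions = bh_adjust([r.p_value for r in members], fdr)
        for r, a, d in zip(members, adjusted, decisions):
            r.p_adjusted, r.significant_fdr = float(a), bool(d)


def _results_frame(results: list[RegressionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "outcome": [r.spec.outcome for r in results],
            "predictor": [r.spec.predictor for r in results],
            "stratum": [None if r.spec.stratum is None else f"{r.spec.stratum[0]}={r.spec.stratum[1]}" for r in results],
            "family": [r.spec.family for r in results],
            "beta": [r.beta for r in results],
            "se": [r.se for r in results],
            "ci_low": [r.ci[0] for r in results],
            "ci_high": [r.ci[1] for r in results],
            "p_value": [r.p_value for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "significant_fdr": [r.significant_fdr for r in results],
            "n": [r.n for r in results],
            "iqr": [r.iqr for r in results],
        }
    )


def single_exposure_scan(
    cohort: pd.DataFrame,
    exposures: list[str],
    outcomes: list[str],
    covariates: list[str] | None = None,
    fdr: float = 0.05,
    family: str = "single-exposure",
) -> pd.DataFrame:
    """One IQR-scaled model per exposure x outcome, all in one BH family.

    Slopes read "per IQR increase in exposure"; per-IQR slope = raw slope x IQR.
    """
    covariates = DEFAULT_COVARIATES if covariates is None else covariates
    results = []
    for exp in exposures:
        scaled, iqr = iqr_scale(cohort[exp].to_numpy(dtype=float))
        df = cohort.copy()
        df[f"{exp}_per_iqr"] = scaled
        for out in outcomes:
            spec = RegressionSpec(outcome=out, predictor=f"{exp}_per_iqr",
                                  covariates=list(covariates), family=family)
            res = fit_linear(spec, df)
            res.iqr = iqr
            res.spec.predictor = exp  # report under the exposure's own name
            results.append(res)
    _apply_family_fdr(results, fdr)
    return _results_frame(results)


_STRATA = {
    "sex": lambda df: [(lev, df["sex"] == lev) for lev in sorted(df["sex"].dropna().unique())],
    "age": lambda df: [("age<60", df["age"] < 60), ("age>=60", df["age"] >= 60)],
    "smoking": lambda df: [(lev, df["smoking"] == lev) for lev in sorted(df["smoking"].dropna().unique())],
    "alcohol": lambda df: [(lev, df["alcohol"] == lev) for lev in sorted(df["alcohol"].dropna().unique())],
}


def stratified_scan(
    cohort: pd.DataFrame,
    exposures: list[str],
    outcomes: list[str],
    strata: list[str] | None = None,
    covariates: list[str] | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-stratum single-exposure scans (sex, age>=60, smoking, alcohol).

    The stratifying covariate is dropped from each stratum's model; empty
    strata are skipped with a log entry. Each stratum forms its own BH family.
    """
    strata = ["sex", "age", "smoking", "alcohol"] if strata is None else strata
    covariates = DEFAULT_COVARIATES if covariates is None else covariates
    frames = []
    for var in strata:
        for label, mask in _STRATA[var](cohort):
            sub = cohort[mask]
            if len(sub) == 0:
                logger.info("stratum %s=%s empty; skipped", var, label)
                continue
            covs = [c for c in covariates if c != var]
            frame = single_exposure_scan(sub, exposures, outcomes, covs, fdr,
                                         family=f"stratified:{var}={label}")
            frame["stratum"] = f"{var}={label}"
            frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def residence_filter(cohort: pd.DataFrame, min_years: float = 5.0) -> pd.DataFrame:
    """Keep participants resident at their current address >= ``min_years`` years."""
    if "residence_years" not in cohort.columns:
        raise KeyError("cohort has no 'residence_years' column")
    return cohort[cohort["residence_years"] >= min_years].copy()


# ---------------------------------------------------------------------------
# latent class analysis for individual SES
# ---------------------------------------------------------------------------

@dataclass
class LCAResult:
    assignments: np.ndarray                  # hard class per row (labelled)
    posterior: np.ndarray                    # n x k
    class_probs: np.ndarray                  # mixing proportions
    item_probs: dict[str, pd.DataFrame]      # item -> (class x level) response probabilities
    log_likelihood: float
    ll_trace: list[float]
    class_labels: list[str]                  # ordered high/medium/low by income


def _lca_em(Xcodes, levels, k, rng, max_iter, tol):
    n, items = Xcodes.shape
    pi = rng.dirichlet(np.ones(k))
    theta = [rng.dirichlet(np.ones(L), size=k) for L in levels]  # k x L per item
    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        logp = np.log(pi)[None, :] + sum(
            np.log(theta[j][:, Xcodes[:, j]].T + 1e-300) for j in range(items)
        )
        mx = logp.max(axis=1, keepdims=True)
        post = np.exp(logp - mx)
        norm = post.sum(axis=1, keepdims=True)
        post /= norm
        ll = float((mx.ravel() + np.log(norm.ravel())).sum())
        trace.append(ll)
        if ll + 1e-8 < prev:
            raise RuntimeError("EM log-likelihood decreased — implementation bug")
        if ll - prev < tol:
            prev = ll
            break
        prev = ll
        pi = post.mean(axis=0)
        for j in range(items):
            counts = np.zeros((levels[j], k))
            np.add.at(counts, Xcodes[:, j], post)   # counts[level, class]
            counts = counts.T                        # class x level
            theta[j] = (counts + 1e-10) / (counts.sum(axis=1, keepdims=True) + 1e-10 * levels[j])
    return pi, theta, post, prev, trace


def lca_ses(
    indicators: pd.DataFrame,
    k: int = 3,
    seed: int = 0,
    n_starts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-8,
    income_order: list[str] | None = None,
) -> LCAResult:
    """Latent class analysis of categorical SES indicators via EM.

    ``indicators`` holds the income/education/employment columns. Classes are
    multinomial mixtures over the items; the best of ``n_starts`` random EM
    starts is kept, classes are ordered by mean income level and labelled
    high/medium/low (for k=3, else class-1..k).
    """
    if len(indicators) < 100:
        raise ValueError("latent class analysis needs at least 100 rows")
    items = list(indicators.columns)
    level_names, codes = [], []
    for c in items:
        cat = pd.Categorical(indicators[c])
        level_names.append(list(cat.categories))
        codes.append(cat.codes.astype(int))
    Xcodes = np.column_stack(codes)
    if np.any(Xcodes < 0):
        raise ValueError("indicators must not contain missing values")
    levels = [len(ln) for ln in level_names]

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_starts):
        fit = _lca_em(Xcodes, levels, k, rng, max_iter, tol)
        if best is None or fit[3] > best[3]:
            best = fit
    pi, theta, post, ll, trace = best

    # order classes by expected income rank
    if "income" in items and k > 1:
        j = items.index("income")
        order = income_order or ["low", "medium", "high"]
        rank = np.array([order.index(lv) if lv in order else i for i, lv in enumerate(level_names[j])], float)
        score = theta[j] @ rank
        class_order = np.argsort(-score)        # descending income
    else:
        class_order = np.arange(k)
    labels = ["high", "medium", "low"] if k == 3 else [f"class-{i + 1}" for i in range(k)]

    remap = {int(old): labels[pos] for pos, old in enumerate(class_order)}
    hard = post.argmax(axis=1)
    item_probs = {
        items[j]: pd.DataFrame(theta[j][class_order], index=labels, columns=level_names[j])
        for j in range(len(items))
    }
    return LCAResult(
        assignments=np.asarray([remap[int(h)] for h in hard]),
        posterior=post[:, class_order],
        class_probs=pi[class_order],
        item_probs=item_probs,
        log_likelihood=ll,
        ll_trace=trace,
        class_labels=labels,
    )


# ---------------------------------------------------------------------------
# descriptive statistics
# ---------------------------------------------------------------------------

def spearman_matrix(X: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank-correlation matrix (average ranks over ties)."""
    rho = stats.spearmanr(X.to_numpy(dtype=float)).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    return pd.DataFrame(rho, index=X.columns, columns=X.columns)


def describe_cohort(cohort: pd.DataFrame, grouping: str) -> pd.DataFrame:
    """Two-group descriptive table: mean (SD) with Mann-Whitney U p for
    continuous variables, counts (%) with chi-squared p for categoricals."""
    groups = sorted(cohort[grouping].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"describe_cohort compares exactly two groups, found {len(groups)}")
    a = cohort[cohort[grouping] == groups[0]]
    b = cohort[cohort[grouping] == groups[1]]
    rows = []
    for col in cohort.columns:
        if col == grouping or col.startswith("truth_"):
            continue
        if pd.api.types.is_numeric_dtype(cohort[col]) and cohort[col].nunique() > 5:
            xa, xb = a[col].dropna(), b[col].dropna()
            p = float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
            rows.append({"variable": col, "type": "continuous",
                         f"{groups[0]}": f"{xa.mean():.2f} ({xa.std():.2f})",
                         f"{groups[1]}": f"{xb.mean():.2f} ({xb.std():.2f})",
                         "test": "Mann-Whitney U", "p_value": p})
        else:
            tab = pd.crosstab(cohort[grouping], cohort[col])
            if tab.shape[1] < 2:
                continue
            p = float(stats.chi2_contingency(tab.to_numpy()).pvalue)
            fmt = lambda s: ", ".join(f"{lev}: {int(c)} ({100 * c / s.sum():.1f}%)" for lev, c in s.items())
            rows.append({"variable": col, "type": "categorical",
                         f"{groups[0]}": fmt(tab.loc[groups[0]]),
                         f"{groups[1]}": fmt(tab.loc[groups[1]]),
                         "test": "chi-squared", "p_value": p})
    return pd.DataFrame(rows)
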