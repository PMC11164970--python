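"""Multidimensional aging metrics.

PhenoAge (phenotypic age, years) is computed from nine clinical biomarkers
plus chronological age through a Gompertz proportional-hazards model of
10-year all-cause mortality: a linear predictor ``xb`` feeds a Gompertz
survival function, and the resulting mortality risk is mapped back onto an
age scale.  The constants are the published ones and are frozen in
:class:`PhenoAgeConstants`.

The frailty phenotype score is the Fried count (0-5) of present criteria:
unintentional weight loss, exhaustion, weakness, slow gait speed and low
physical activity.  The score is complete-case: any missing component makes
the score missing.

Continuous outcomes (brain volumes, cognitive scores) are z-scored; cognitive
scores are rank-inverse-normal transformed first when a normality screen
fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "PhenoAgeConstants",
    "PHENOAGE_CONSTANTS",
    "BIOMARKER_UNITS",
    "BIOMARKER_RANGES",
    "FRAILTY_COMPONENTS",
    "compute_xb",
    "mortality_risk_10yr",
    "phenoage_from_risk",
    "compute_phenoage",
    "frailty_score",
    "zscore",
    "normalize_then_zscore",
    "rank_inverse_normal",
]


@dataclass(frozen=True)
class PhenoAgeConstants:
    """Published Gompertz / linear-predictor constants for PhenoAge.

    ``phenoage = intercept + ln(hazard_scale * ln(1 - risk)) / log_divisor``
    with ``risk = 1 - exp(-e^xb * (exp(horizon_months * gamma) - 1) / gamma)``.
    """

    intercept: float = 141.50225            # years
    log_divisor: float = 0.090165
    hazard_scale: float = -0.00553
    gamma: float = 0.0076927
    horizon_months: float = 120.0
    xb_intercept: float = -19.907
    coefficients: Mapping[str, float] = field(
        default_factory=lambda: {
            "albumin": -0.0336,        # g/L
            "creatinine": 0.0095,      # umol/L
            "glucose": 0.1953,         # mmol/L
            "log_crp": 0.0954,         # ln(mg/L)
            "lymphocyte_pct": -0.012,  # %
            "mcv": 0.0268,             # fL
            "rdw": 0.3306,             # %
            "alp": 0.00188,            # U/L
            "wbc": 0.0554,             # 10^9 cells/L
            "age": 0.0804,             # years
        }
    )


PHENOAGE_CONSTANTS = PhenoAgeConstants()

#: Units assumed for each biomarker column (the published convention).
BIOMARKER_UNITS = {
    "albumin": "g/L",
    "creatinine": "umol/L",
    "glucose": "mmol/L",
    "crp": "mg/L",
    "lymphocyte_pct": "%",
    "mcv": "fL",
    "rdw": "%",
    "alp": "U/L",
    "wbc": "10^9/L",
    "age": "years",
}

#: Broad physiological plausibility ranges used for warnings, not errors.
BIOMARKER_RANGES = {
    "albumin": (25.0, 60.0),
    "creatinine": (20.0, 250.0),
    "glucose": (2.0, 25.0),
    "crp": (0.01, 200.0),
    "lymphocyte_pct": (0.0, 100.0),
    "mcv": (60.0, 120.0),
    "rdw": (10.0, 25.0),
    "alp": (10.0, 500.0),
    "wbc": (1.0, 30.0),
    "age": (18.0, 110.0),
}

FRAILTY_COMPONENTS = (
    "weight_loss",
    "exhaustion",
    "weakness",
    "slow_gait",
    "low_activity",
)

_XB_INPUTS = (
    "albumin",
    "creatinine",
    "glucose",
    "crp",
    "lymphocyte_pct",
    "mcv",
    "rdw",
    "alp",
    "wbc",
    "age",
)


def _as_columns(panel) -> dict[str, np.ndarray]:
    """Accept a mapping, Series-of-scalars, or DataFrame of biomarker columns."""
    if isinstance(panel, pd.DataFrame):
        cols = {k: panel[k].to_numpy(dtype=float) for k in _XB_INPUTS if k in panel}
    else:
        cols = {k: np.asarray(panel[k], dtype=float) for k in _XB_INPUTS if k in panel}
    missing = [k for k in _XB_INPUTS if k not in cols]
    if missing:
        raise KeyError(f"biomarker panel missing fields: {missing}")
    return cols


def compute_xb(panel, constants: PhenoAgeConstants = PHENOAGE_CONSTANTS):
    """Linear predictor of the Gompertz mortality model (dimensionless).

    CRP enters as its natural logarithm; all other markers enter linearly.
    Accepts scalars or equal-length arrays per field. Raises ``ValueError``
    naming the field if any value is non-finite (or CRP is non-positive).
    """
    cols = _as_columns(panel)
    for name, values in cols.items():
        if not np.all(np.isfinite(values)):
            raise ValueError(f"non-finite value in biomarker field {name!r}")
    if np.any(cols["crp"] <= 0):
        raise ValueError("non-finite value in biomarker field 'crp' (log of non-positive CRP)")
    coef = constants.coefficients
    xb = constants.xb_intercept + coef["log_crp"] * np.log(cols["crp"])
    for name in _XB_INPUTS:
        if name == "crp":
            continue
        xb = xb + coef[name] * cols[name]
    return xb


def mortality_risk_10yr(xb, constants: PhenoAgeConstants = PHENOAGE_CONSTANTS):
    """10-year mortality risk in (0, 1) from the Gompertz cumulative hazard.

    ``risk = 1 - exp(-e^xb * (exp(120*gamma) - 1) / gamma)``; strictly
    increasing in ``xb`` and saturating smoothly at both ends.
    """
    xb = np.asarray(xb, dtype=float)
    if not np.all(np.isfinite(xb)):
        raise ValueError("xb must be finite")
    g = constants.gamma
    scale = (np.exp(constants.horizon_months * g) - 1.0) / g
    # -expm1 keeps precision when the cumulative hazard is tiny
    risk = -np.expm1(-np.exp(xb) * scale)
    return risk if risk.ndim else float(risk)


def phenoage_from_risk(risk=None, constants: PhenoAgeConstants = PHENOAGE_CONSTANTS, *, survival=None):
    """Map 10-year mortality risk onto the phenotypic-age scale (years).

    ``phenoage = 141.50225 + ln(-0.00553 * ln(1 - risk)) / 0.090165``.

    Risks extremely close to 1 are not representable in float64 (``1 - risk``
    underflows); the survival probability ``1 - risk`` may be passed instead
    via the ``survival`` keyword to evaluate the same formula exactly.
    """
    if (risk is None) == (survival is None):
        raise ValueError("pass exactly one of risk or survival")
    if survival is not None:
        survival = np.asarray(survival, dtype=float)
        if np.any(survival <= 0) or np.any(survival >= 1):
            raise ValueError("survival must lie strictly inside (0, 1)")
        log_survival = np.log(survival)
    else:
        risk = np.asarray(risk, dtype=float)
        if np.any(risk <= 0) or np.any(risk >= 1):
            raise ValueError("mortality risk must lie strictly inside (0, 1)")
        log_survival = np.log1p(-risk)
    inner = constants.hazard_scale * log_survival   # = -0.00553 * ln(1-risk) > 0
    age = constants.intercept + np.log(inner) / constants.log_divisor
    return age if age.ndim else float(age)


def compute_phenoage(panel, constants: PhenoAgeConstants = PHENOAGE_CONSTANTS):
    """PhenoAge in years: composition of xb -> mortality risk -> age scale.

    Composed through the log-survival ``-e^xb (exp(120*gamma)-1)/gamma`` so
    that panels with near-certain 10-year mortality do not saturate.
    """
    xb = np.asarray(compute_xb(panel, constants), dtype=float)
    g = constants.gamma
    scale = (np.exp(constants.horizon_months * g) - 1.0) / g
    log_survival = -np.exp(xb) * scale
    inner = constants.hazard_scale * log_survival
    age = constants.intercept + np.log(inner) / constants.log_divisor
    return age if age.ndim else float(age)


def frailty_score(components) -> "pd.Series | float":
    """Fried frailty phenotype score: count of present criteria, 0-5.

    ``components`` is a DataFrame (or mapping) with the five boolean columns in
    :data:`FRAILTY_COMPONENTS`; values may be True/False/NaN. Any missing
    component makes the row's score missing (complete-case rule).
    """
    if not isinstance(components, pd.DataFrame):
        components = pd.DataFrame({k: np.atleast_1d(components[k]) for k in FRAILTY_COMPONENTS})
    missing_cols = [c for c in FRAILTY_COMPONENTS if c not in components]
    if missing_cols:
        raise KeyError(f"frailty components missing: {missing_cols}")
    sub = components[list(FRAILTY_COMPONENTS)].astype(float)
    score = sub.sum(axis=1)
    score[sub.isna().any(axis=1)] = np.nan
    return score


def zscore(values) -> np.ndarray:
    """Standardize to mean 0, SD 1 (sample SD, n-1 divisor).

    Raises ``ValueError`` on a constant vector or fewer than 2 distinct
    finite values.
    """
    x = np.asarray(values, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size < 2 or np.unique(finite).size < 2:
        raise ValueError("zscore requires at least 2 distinct finite values")
    mu = finite.mean()
    sd = finite.std(ddof=1)
    return (x - mu) / sd


def rank_inverse_normal(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform (Blom offset by default)."""
    x = np.asarray(values, dtype=float)
    ranks = stats.rankdata(x, method="average")
    return special.ndtri((ranks - offset) / (x.size - 2 * offset + 1))


def normalize_then_zscore(values, skew_threshold: float = 1.0) -> np.ndarray:
    """Z-score after normalizing when a skewness screen fails.

    If ``|sample skewness| > skew_threshold`` the values are passed through a
    rank-based inverse normal transform first; otherwise they are z-scored
    directly. Rank order is preserved either way.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 10:
        raise ValueError("normalize_then_zscore requires at least 10 observations")
    if abs(stats.skew(x)) > skew_threshold:
        x = rank_inverse_normal(x)
    return zscore(x)
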