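"""Seeded synthetic cohorts emulating the study's data structure.

The real cohort (UK Biobank) is access-restricted, so every downstream stage
is exercised on synthetic participants that reproduce the *stated* structure
of the data:

* eleven residential exposures — five air pollutants (PM10, PM2.5, coarse
  PM2.5-10, NO2, NOx, ug/m3), green and blue space percentages at 300 m and
  1000 m buffers, and 24-h / night-time road-traffic noise (dB) — drawn from
  a Gaussian copula hitting target Spearman correlations (green buffers
  0.813, blue buffers 0.629, green-blue at 1000 m 0.18, a strongly
  correlated pollutant block);
* an imaging-subcohort age profile (mean 55.46, SD 7.37 years);
* five exposure archetypes (air pollution, green space, rural-urban fringe,
  noise, blue space) planted as a Gaussian mixture in standardized exposure
  space;
* planted mixture effects: outcomes built as
  ``y = beta * sum_i w_i q_i + gamma' c + eps`` on quantized, direction-
  aligned exposure scores, so weight and effect recovery can be tested
  against known truth.

Ground-truth columns are prefixed ``truth_`` and are stripped on read unless
explicitly requested, so pipeline stages cannot accidentally use them.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exposure_prep import quantize_table, reverse_protective

logger = logging.getLogger(__name__)

__all__ = [
    "EXPOSURES",
    "POLLUTANTS",
    "GREEN",
    "BLUE",
    "NOISE",
    "PROTECTIVE",
    "ARCHETYPES",
    "GeneratorConfig",
    "default_spearman_targets",
    "default_archetype_means",
    "generate_exposures",
    "generate_archetype_exposures",
    "generate_biomarkers",
    "generate_covariates",
    "generate_outcomes",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "SchemaError",
]

POLLUTANTS = ("pm10", "pm2_5", "pm_coarse", "no2", "nox")
GREEN = ("green_300m", "green_1000m")
BLUE = ("blue_300m", "blue_1000m")
NOISE = ("noise_24h", "noise_night")
EXPOSURES = POLLUTANTS + GREEN + BLUE + NOISE
PROTECTIVE = GREEN + BLUE

ARCHETYPES = ("air pollution", "green space", "rural-urban fringe", "noise", "blue space")

# Marginal distributions per exposure: pollutants log-normal, green/blue
# logit-normal on [0, 100] %, noise normal truncated to [30, 90] dB.
# Location/scale are plausible UK residential values; the source study prints
# no marginal distributions, so these are package choices.
_LOGNORMAL = {
    "pm10": (np.log(16.0), 0.12),
    "pm2_5": (np.log(10.0), 0.10),
    "pm_coarse": (np.log(6.2), 0.18),
    "no2": (np.log(26.0), 0.35),
    "nox": (np.log(42.0), 0.40),
}
_LOGITNORMAL = {
    "green_300m": (-0.20, 1.00),
    "green_1000m": (0.00, 0.90),
    "blue_300m": (-4.60, 1.20),
    "blue_1000m": (-4.20, 1.10),
}
_TRUNCNORM = {
    "noise_24h": (55.0, 4.5, 30.0, 90.0),
    "noise_night": (47.0, 4.5, 30.0, 90.0),
}


def default_spearman_targets() -> pd.DataFrame:
    """Default 11x11 Spearman rank-correlation targets.

    Stated entries: green buffers 0.813, blue buffers 0.629, green-blue at
    1000 m 0.18, and a strongly correlated pollutant block (0.70, with the
    coarse fraction weaker at 0.35). Unstated cross-family entries are
    interpolated at a mild 0.20; the noise pair is set to 0.75.
    """
    k = len(EXPOSURES)
    m = np.full((k, k), 0.20)
    np.fill_diagonal(m, 1.0)
    df = pd.DataFrame(m, index=EXPOSURES, columns=EXPOSURES)
    strong = [p for p in POLLUTANTS if p != "pm_coarse"]
    for a in strong:
        for b in strong:
            if a != b:
                df.loc[a, b] = 0.70
    for a in strong:
        df.loc[a, "pm_coarse"] = df.loc["pm_coarse", a] = 0.35
    df.loc["green_300m", "green_1000m"] = df.loc["green_1000m", "green_300m"] = 0.813
    df.loc["blue_300m", "blue_1000m"] = df.loc["blue_1000m", "blue_300m"] = 0.629
    df.loc["green_1000m", "blue_1000m"] = df.loc["blue_1000m", "green_1000m"] = 0.18
    df.loc["noise_24h", "noise_night"] = df.loc["noise_night", "noise_24h"] = 0.75
    return df


def default_archetype_means() -> pd.DataFrame:
    """Standardized exposure means of the five planted archetypes.

    Rows encode the described patterns: the air-pollution group has the
    highest pollutants and least green space; the green-space group the
    lowest pollution and most green; the rural-urban fringe is moderate in
    everything; the noise group has the loudest roads; the blue-space group
    the most blue space.
    """
    rows = {
        "air pollution":      [1.6, 1.6, 0.8, 1.6, 1.6, -1.2, -1.2, -0.3, -0.3, 0.8, 0.8],
        "green space":        [-1.4, -1.4, -0.7, -1.4, -1.4, 1.8, 1.8, 0.0, 0.0, -1.0, -1.0],
        "rural-urban fringe": [0.0] * 11,
        "noise":              [0.4, 0.4, 0.2, 0.4, 0.4, -0.3, -0.3, -0.2, -0.2, 2.0, 2.0],
        "blue space":         [-0.4, -0.4, -0.2, -0.4, -0.4, 0.2, 0.2, 2.2, 2.2, 0.0, 0.0],
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(EXPOSURES))


def _default_planted_weights() -> dict[str, np.ndarray]:
    # Air pollution carries most weight; green space and noise contribute,
    # blue space little — mirroring the qualitative contribution pattern.
    w = np.array([0.25, 0.20, 0.05, 0.15, 0.10, 0.05, 0.05, 0.0, 0.0, 0.10, 0.05])
    return {"brain_age_gap": w.copy(), "gm_volume_z": w.copy()}


@dataclass
class GeneratorConfig:
    """Everything that determines a synthetic cohort.

    ``spearman_targets`` drives the copula mode; ``archetype_means`` /
    ``archetype_proportions`` / ``archetype_scatter_sd`` drive the mixture
    mode. ``planted_weights`` (per-outcome simplex vectors over the eleven
    exposures), ``planted_beta`` and ``noise_sd`` define the planted
    structural model for each generated outcome column.
    """

    n: int = 10_000
    seed: int = 0
    exposure_mode: str = "archetypes"  # "archetypes" | "copula"
    spearman_targets: pd.DataFrame = field(default_factory=default_spearman_targets)
    archetype_means: pd.DataFrame = field(default_factory=default_archetype_means)
    archetype_proportions: np.ndarray = field(
        default_factory=lambda: np.array([0.18, 0.22, 0.34, 0.12, 0.14])
    )
    archetype_scatter_sd: float = 0.5
    planted_weights: dict = field(default_factory=_default_planted_weights)
    planted_beta: dict = field(default_factory=lambda: {"brain_age_gap": 0.5, "gm_volume_z": -0.4})
    noise_sd: dict = field(default_factory=lambda: {"brain_age_gap": 1.0, "gm_volume_z": 1.0})
    q: int = 4
    age_mean: float = 55.46
    age_sd: float = 7.37
    phenoage_exposure_beta: float = 0.8  # planted exposure acceleration of PhenoAge, years/index unit

    def validate(self) -> None:
        p = np.asarray(self.archetype_proportions, dtype=float)
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("archetype_proportions must be nonnegative and sum to 1")
        for name, w in self.planted_weights.items():
            w = np.asarray(w, dtype=float)
            if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
                raise ValueError(f"planted_weights[{name!r}] must lie on the simplex")
        s = self.spearman_targets.to_numpy()
        if not np.allclose(s, s.T) or not np.allclose(np.diag(s), 1.0):
            raise ValueError("spearman_targets must be symmetric with unit diagonal")
        for name, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"noise_sd[{name!r}] must be nonnegative")

    def fingerprint(self) -> str:
        payload = {
            "n": self.n,
            "seed": self.seed,
            "exposure_mode": self.exposure_mode,
            "spearman_targets": np.round(self.spearman_targets.to_numpy(), 10).tolist(),
            "archetype_means": np.round(self.archetype_means.to_numpy(), 10).tolist(),
            "archetype_proportions": np.asarray(self.archetype_proportions, float).tolist(),
            "archetype_scatter_sd": self.archetype_scatter_sd,
            "planted_weights": {k: np.asarray(v, float).tolist() for k, v in self.planted_weights.items()},
            "planted_beta": dict(self.planted_beta),
            "noise_sd": dict(self.noise_sd),
            "q": self.q,
            "age_mean": self.age_mean,
            "age_sd": self.age_sd,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


class SchemaError(ValueError):
    """A cohort file does not match the expected column schema."""


# ---------------------------------------------------------------------------
# copula exposures
# ---------------------------------------------------------------------------

def _spearman_to_pearson(rho_s: np.ndarray) -> np.ndarray:
    """Map rank-correlation targets to Gaussian-copula correlations."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def _nearest_psd(corr: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() >= eps:
        return corr
    warnings.warn("implied copula correlation not positive semidefinite; applying nearest-PSD repair")
    vals = np.clip(vals, eps, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


def _marginal_from_normal(z: np.ndarray) -> pd.DataFrame:
    """Transform standard-normal columns (order EXPOSURES) into exposure units."""
    out = {}
    for j, name in enumerate(EXPOSURES):
        col = z[:, j]
        if name in _LOGNORMAL:
            mu, sigma = _LOGNORMAL[name]
            out[name] = np.exp(mu + sigma * col)
        elif name in _LOGITNORMAL:
            mu, sigma = _LOGITNORMAL[name]
            out[name] = 100.0 / (1.0 + np.exp(-(mu + sigma * col)))
        else:
            mean, sd, lo, hi = _TRUNCNORM[name]
            a, b = (lo - mean) / sd, (hi - mean) / sd
            u = stats.norm.cdf(col)
            out[name] = stats.truncnorm.ppf(np.clip(u, 1e-12, 1 - 1e-12), a, b, loc=mean, scale=sd)
    return pd.DataFrame(out)


def generate_exposures(config: GeneratorConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw exposures from a Gaussian copula hitting the Spearman targets.

    Rank correlations are mapped to copula correlations via
    ``r = 2 sin(pi * rho_s / 6)``; each marginal is then a strictly monotone
    transform of its normal score, so empirical Spearman correlations
    converge to the targets as n grows.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    targets = config.spearman_targets.loc[list(EXPOSURES), list(EXPOSURES)].to_numpy()
    corr = _nearest_psd(_spearman_to_pearson(targets))
    try:
        factor = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        # singular (e.g. comonotone pairs): eigenfactorization of the PSD matrix
        vals, vecs = np.linalg.eigh(corr)
        if vals.min() < -1e-8:
            raise ValueError("implied copula correlation matrix is not positive semidefinite")
        factor = vecs * np.sqrt(np.clip(vals, 0.0, None))
    z = rng.standard_normal((config.n, len(EXPOSURES))) @ factor.T
    # a unit rank-correlation target means comonotone columns: enforce exact
    # equality of the normal scores so empirical Spearman is exactly 1
    for i in range(len(EXPOSURES)):
        for j in range(i + 1, len(EXPOSURES)):
            if targets[i, j] == 1.0:
                z[:, j] = z[:, i]
    return _marginal_from_normal(z)


def generate_archetype_exposures(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw exposures from the planted five-archetype Gaussian mixture.

    Archetype means live in standardized exposure space; within-archetype
    scatter is isotropic Gaussian with SD ``archetype_scatter_sd``. The
    standardized draws pass through the same monotone marginal transforms as
    the copula mode, so the cluster structure survives into exposure units.
    Returns ``(exposures, labels)`` with labels as archetype names.
    """
    config.validate()
    means = config.archetype_means.loc[:, list(EXPOSURES)].to_numpy()
    if len(np.unique(means, axis=0)) < means.shape[0]:
        raise ValueError("archetype_means rows must be pairwise distinct")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    labels_idx = rng.choice(means.shape[0], size=config.n, p=np.asarray(config.archetype_proportions, float))
    z = means[labels_idx] + config.archetype_scatter_sd * rng.standard_normal((config.n, means.shape[1]))
    labels = np.asarray(config.archetype_means.index)[labels_idx]
    return _marginal_from_normal(z), labels


# ---------------------------------------------------------------------------
# biomarkers, covariates, outcomes
# ---------------------------------------------------------------------------

def generate_biomarkers(age, rng: np.random.Generator | int = 0) -> pd.DataFrame:
    """Nine-biomarker panel with mild age trends and physiological ranges.

    Marginal means/SDs (albumin 46+-2.5 g/L, creatinine 70+-12 umol/L,
    glucose 5.0+-0.7 mmol/L, CRP log-normal median 1.3 mg/L, lymphocytes
    30+-6 %, MCV 91+-4 fL, RDW 13.5+-0.9 %, ALP 80+-20 U/L, WBC 6.8+-1.5
    10^9/L) are plausible adult reference values; age slopes make the derived
    PhenoAge increase with age.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    age = np.asarray(age, dtype=float)
    if np.any(age < 40) or np.any(age > 70):
        raise ValueError("ages must lie in [40, 70] (the cohort's age window)")
    n = age.size
    da = age - 55.0
    panel = pd.DataFrame(
        {
            "albumin": np.clip(46.0 - 0.05 * da + 2.5 * rng.standard_normal(n), 25, 60),
            "creatinine": np.clip(70.0 + 0.20 * da + 12.0 * rng.standard_normal(n), 25, 250),
            "glucose": np.clip(5.0 + 0.02 * da + 0.7 * rng.standard_normal(n), 2.5, 25),
            "crp": np.exp(np.log(1.3) + 0.015 * da + 0.8 * rng.standard_normal(n)),
            "lymphocyte_pct": np.clip(30.0 - 0.10 * da + 6.0 * rng.standard_normal(n), 2, 80),
            "mcv": np.clip(91.0 + 0.05 * da + 4.0 * rng.standard_normal(n), 62, 118),
            "rdw": np.clip(13.5 + 0.03 * da + 0.9 * rng.standard_normal(n), 10.5, 24),
            "alp": np.clip(80.0 + 0.30 * da + 20.0 * rng.standard_normal(n), 12, 480),
            "wbc": np.clip(6.8 + 0.02 * da + 1.5 * rng.standard_normal(n), 1.5, 28),
        }
    )
    panel["age"] = age
    return panel


_CATEGORIES = {
    "sex": (["female", "male"], [0.54, 0.46]),
    "ethnicity": (["white", "asian", "black", "mixed", "other"], [0.94, 0.02, 0.015, 0.01, 0.015]),
    "smoking": (["never", "previous", "current"], [0.55, 0.35, 0.10]),
    "bmi_cat": (["normal", "overweight", "obese", "underweight"], [0.35, 0.42, 0.22, 0.01]),
    "alcohol": (["never", "occasional", "regular"], [0.08, 0.40, 0.52]),
    "exercise": (["no", "yes"], [0.35, 0.65]),
    "diet": (["healthy", "unhealthy"], [0.45, 0.55]),
}

# 3-class latent SES: item-response probabilities for income/education/
# employment, well separated so latent-class analysis can recover them.
_SES_CLASSES = ("high", "medium", "low")
_SES_PROPS = (0.30, 0.40, 0.30)
_SES_ITEMS = {
    "income": (
        ["low", "medium", "high"],
        {"high": [0.05, 0.20, 0.75], "medium": [0.20, 0.65, 0.15], "low": [0.75, 0.20, 0.05]},
    ),
    "education": (
        ["none", "secondary", "degree"],
        {"high": [0.05, 0.20, 0.75], "medium": [0.20, 0.60, 0.20], "low": [0.55, 0.40, 0.05]},
    ),
    "employment": (
        ["unemployed", "retired", "employed"],
        {"high": [0.03, 0.17, 0.80], "medium": [0.10, 0.35, 0.55], "low": [0.30, 0.40, 0.30]},
    ),
}


def _age_parent_params(mean: float, sd: float, lo: float = 40.0, hi: float = 70.0):
    """Parent (mu, sigma) of a normal truncated to [lo, hi] whose truncated
    distribution has the requested mean and SD (truncation shrinks both)."""
    from scipy import optimize

    def gap(p):
        mu, s = p
        d = stats.truncnorm((lo - mu) / s, (hi - mu) / s, loc=mu, scale=s)
        return [d.mean() - mean, d.std() - sd]

    sol, info, ok, _ = optimize.fsolve(gap, [mean, sd], full_output=True)
    if not ok:
        raise ValueError(f"no truncated-normal parent for age mean={mean}, sd={sd} on [{lo}, {hi}]")
    return float(sol[0]), float(sol[1])


def generate_covariates(n: int, rng: np.random.Generator, age_mean: float, age_sd: float) -> pd.DataFrame:
    """Demographics, lifestyle and SES covariates, plus residence duration.

    Age is truncated-normal on the cohort window [40, 70] years, calibrated
    so the realized mean and SD match ``age_mean`` / ``age_sd``.
    """
    mu, s = _age_parent_params(age_mean, age_sd)
    a, b = (40.0 - mu) / s, (70.0 - mu) / s
    age = stats.truncnorm.ppf(rng.random(n), a, b, loc=mu, scale=s)
    cov = {"age": age}
    for name, (levels, probs) in _CATEGORIES.items():
        cov[name] = rng.choice(levels, size=n, p=probs)
    cov["nses"] = rng.normal(0.0, 3.0, size=n)  # Townsend-style deprivation index
    ses_class = rng.choice(len(_SES_CLASSES), size=n, p=_SES_PROPS)
    for item, (levels, by_class) in _SES_ITEMS.items():
        probs = np.array([by_class[_SES_CLASSES[c]] for c in ses_class])
        u = rng.random(n)
        cum = np.cumsum(probs, axis=1)
        idx = (u[:, None] > cum).sum(axis=1)
        cov[item] = np.asarray(levels)[idx]
    cov["cvd"] = (rng.random(n) < 0.08).astype(int)
    cov["cancer"] = (rng.random(n) < 0.07).astype(int)
    cov["residence_years"] = np.round(rng.gamma(shape=3.0, scale=5.0, size=n), 1)
    df = pd.DataFrame(cov)
    df["truth_ises_class"] = np.asarray(_SES_CLASSES)[ses_class]
    return df


def generate_outcomes(
    quantized: pd.DataFrame,
    planted_weights,
    planted_beta: float,
    covariates: pd.DataFrame | None,
    noise_sd: float,
    rng: np.random.Generator,
    covariate_effects: dict[str, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Planted structural outcome ``y = beta * index + gamma' c + eps``.

    ``index = sum_i w_i q_i`` on the (direction-aligned) quantile scores.
    Returns ``(y, true_index)``; the true index is retained for recovery
    tests. Raises on negative ``noise_sd`` or off-simplex weights.
    """
    w = np.asarray(planted_weights, dtype=float)
    if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise ValueError("planted weights must lie on the simplex")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    index = quantized.to_numpy(dtype=float) @ w
    y = planted_beta * index
    if covariates is not None and covariate_effects:
        for name, gamma in covariate_effects.items():
            y = y + gamma * covariates[name].to_numpy(dtype=float)
    if noise_sd > 0:
        y = y + noise_sd * rng.standard_normal(index.size)
    return y, index


def _frailty_components(age: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Binary Fried components with prevalence rising in age."""
    base = {"weight_loss": 0.05, "exhaustion": 0.12, "weakness": 0.10, "slow_gait": 0.07, "low_activity": 0.15}
    out = {}
    z = (age - 55.0) / 7.37
    for name, p0 in base.items():
        logit = np.log(p0 / (1 - p0)) + 0.45 * z
        out[name] = (rng.random(age.size) < 1.0 / (1.0 + np.exp(-logit))).astype(int)
    return pd.DataFrame(out)


def generate_cohort(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Assemble a full synthetic cohort table.

    Exposures (archetype-mixture or copula mode), covariates, biomarker
    panel, frailty components, and outcome columns with planted mixture
    effects. Ground truth (archetype label, per-outcome true index, latent
    SES class) is kept under ``truth_``-prefixed columns.
    """
    from .aging_metrics import compute_phenoage  # deferred: avoid cycle at import time

    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    if config.exposure_mode == "archetypes":
        exposures, labels = generate_archetype_exposures(config, rng)
    elif config.exposure_mode == "copula":
        exposures = generate_exposures(config, rng)
        labels = None
    else:
        raise ValueError(f"unknown exposure_mode {config.exposure_mode!r}")

    covariates = generate_covariates(config.n, rng, config.age_mean, config.age_sd)
    panel = generate_biomarkers(covariates["age"].to_numpy(), rng)
    frailty = _frailty_components(covariates["age"].to_numpy(), rng)

    scores, _ = quantize_table(exposures, EXPOSURES, q=config.q)
    scores = reverse_protective(scores, config.q, PROTECTIVE)

    table = pd.concat([exposures, covariates, panel.drop(columns="age"), frailty], axis=1)

    # PhenoAge: biomarker-derived, plus a planted exposure acceleration using
    # the same planted weight profile as the first outcome.
    phenoage = compute_phenoage(panel)
    w0 = next(iter(config.planted_weights.values()))
    accel_index = scores.to_numpy(dtype=float) @ np.asarray(w0, float)
    table["phenoage"] = phenoage + config.phenoage_exposure_beta * (accel_index - accel_index.mean())
    table["truth_index_phenoage"] = accel_index

    cov_fx = {"age": 0.02}
    for outcome, w in config.planted_weights.items():
        y, index = generate_outcomes(
            scores, w, config.planted_beta[outcome], covariates, config.noise_sd[outcome], rng, cov_fx
        )
        table[outcome] = y
        table[f"truth_index_{outcome}"] = index

    if labels is not None:
        table["truth_archetype"] = labels
    return table


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = list(EXPOSURES) + ["age", "sex"]


def write_cohort(table: pd.DataFrame, path, config: GeneratorConfig | None = None) -> None:
    """Write the cohort as CSV plus a JSON sidecar with seed/config metadata."""
    path = Path(path)
    table.to_csv(path, index=False)
    meta = {"columns": list(table.columns), "n": int(len(table))}
    if config is not None:
        meta.update({"seed": config.seed, "config_hash": config.fingerprint()})
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_cohort(path, include_truth: bool = False) -> pd.DataFrame:
    """Read a cohort CSV, validating the schema.

    Missing required columns raise :class:`SchemaError` listing them; unknown
    extra columns are kept with a logged warning. ``truth_``-prefixed ground
    truth is stripped unless ``include_truth`` is set.
    """
    path = Path(path)
    table = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"cohort file {path} is missing required columns: {missing}")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        known = set(json.loads(meta_path.read_text())["columns"])
        extra = [c for c in table.columns if c not in known]
        if extra:
            logger.warning("cohort file %s has unknown extra columns: %s", path, extra)
    if not include_truth:
        table = table.drop(columns=[c for c in table.columns if c.startswith("truth_")])
    return table
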