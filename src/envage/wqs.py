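"""Weighted quantile sum (WQS) regression, implemented from definition.

WQS summarizes a correlated exposure mixture as one index
``WQS_i = sum_j w_j q_ij`` over quantile-scored exposures, with nonnegative
weights summing to 1 and a direction-constrained index coefficient.  The
sample splits 40/60 into a training and a validation set; weights are
estimated on bootstrap resamples of the training set by solving

    minimize  || y - b0 - beta1 * Q w - C gamma ||^2
    s.t.      w on the simplex,  sign(beta1) fixed by the model direction,

and the final weight vector averages the converged bootstrap solutions.  The
validation set then tests the significance of the resulting index by OLS.

The solver profiles out the linear part: covariates are residualized from
``y`` and ``Q`` once per bootstrap sample (Frisch-Waugh), leaving a smooth
objective over the simplex handled by a softmax reparameterization with
quasi-Newton local optimization from multiple starts (uniform, near-vertex
and random).  The sign constraint binds at the boundary ``beta1 = 0``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .exposure_prep import QuantileBoundaries, quantize_table, reverse_protective

logger = logging.getLogger(__name__)

__all__ = ["WQSConfig", "WQSResult", "split_sample", "fit_weights_once",
           "average_weights", "wqs_index", "validate_index", "run_wqs",
           "build_design"]


@dataclass
class WQSConfig:
    """Tuning knobs of the WQS fit.

    ``train_fraction`` 0.4 and ``n_boot`` 500 are the study's settings;
    tests and demos scale ``n_boot`` down. ``direction`` is "positive",
    "negative" or "both".
    """

    q: int = 4
    n_boot: int = 500
    train_fraction: float = 0.4
    direction: str = "positive"
    seed: int = 0
    n_restarts: int = 5
    maxiter: int = 200
    gtol: float = 1e-7

    def validate(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.direction not in ("positive", "negative", "both"):
            raise ValueError("direction must be 'positive', 'negative' or 'both'")


@dataclass
class WQSResult:
    """One fitted WQS model (one direction)."""

    direction: str
    exposures: list[str]
    weights: np.ndarray                 # final averaged simplex vector
    boot_weights: np.ndarray            # n_converged x n_exposures
    beta: float                         # validation index effect
    se: float
    ci: tuple[float, float]
    p_value: float
    covariate_coefficients: pd.Series
    n_boot: int
    n_converged: int
    n_direction_consistent: int         # bootstraps whose beta1 is strictly in-direction
    n_train: int
    n_validation: int
    seed: int
    boundaries: dict[str, QuantileBoundaries] = field(default_factory=dict)

    @property
    def weight_table(self) -> pd.Series:
        return pd.Series(self.weights, index=self.exposures, name="weight")


def split_sample(n: int, train_fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint train/validation row indices: floor(frac*n) training rows."""
    if n < 10:
        raise ValueError("need at least 10 rows to split")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(np.floor(train_fraction * n))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _residualize(y: np.ndarray, Q: np.ndarray, C: np.ndarray | None):
    """Project out intercept + covariates from y and each column of Q."""
    n = y.size
    X = np.ones((n, 1)) if C is None else np.column_stack([np.ones(n), C])
    coef_y, *_ = np.linalg.lstsq(X, y, rcond=None)
    coef_Q, *_ = np.linalg.lstsq(X, Q, rcond=None)
    return y - X @ coef_y, Q - X @ coef_Q


def _softmax(theta: np.ndarray) -> np.ndarray:
    e = np.exp(theta - theta.max())
    return e / e.sum()


def _profiled_rss(w, Qr, yr, sign):
    """RSS at the best direction-consistent beta1 for fixed weights."""
    z = Qr @ w
    zz = float(z @ z)
    if zz <= 0.0:
        return float(yr @ yr), 0.0
    beta = float(z @ yr) / zz
    if sign * beta < 0:
        return float(yr @ yr), 0.0  # constraint binds at beta1 = 0
    return float(yr @ yr) - beta * beta * zz, beta


def fit_weights_once(
    Q: np.ndarray,
    y: np.ndarray,
    C: np.ndarray | None,
    direction: str,
    rng: np.random.Generator,
    n_restarts: int = 5,
    maxiter: int = 200,
    gtol: float = 1e-7,
) -> tuple[np.ndarray, float, bool]:
    """Estimate simplex weights on one (bootstrap) sample.

    Returns ``(weights, beta1, converged)``. Multi-start BFGS over softmax
    logits; candidate solutions also include the simplex vertices and the
    uniform vector, and the lowest profiled RSS wins.
    """
    k = Q.shape[1]
    sign = 1.0 if direction == "positive" else -1.0
    yr, Qr = _residualize(np.asarray(y, float), np.asarray(Q, float), C)

    if k == 1:
        w = np.ones(1)
        _, beta = _profiled_rss(w, Qr, yr, sign)
        return w, beta, True

    def objective(theta):
        return _profiled_rss(_softmax(theta), Qr, yr, sign)[0]

    starts = [np.zeros(k)]
    starts += [8.0 * np.eye(k)[j] for j in range(k)]          # near-vertex starts
    starts += [rng.standard_normal(k) for _ in range(n_restarts)]

    best_w, best_rss, opt_rss, converged = None, np.inf, np.inf, False
    for theta0 in starts:
        res = optimize.minimize(objective, theta0, method="L-BFGS-B",
                                options={"maxiter": maxiter, "gtol": gtol})
        w = _softmax(res.x)
        rss, _ = _profiled_rss(w, Qr, yr, sign)
        if rss < best_rss:
            best_w, best_rss = w, rss
        if res.success:
            opt_rss = min(opt_rss, rss)
    # exact vertices and the uniform vector are feasible limits of the softmax
    for w in [np.full(k, 1.0 / k)] + [np.eye(k)[j] for j in range(k)]:
        rss, _ = _profiled_rss(w, Qr, yr, sign)
        if rss < best_rss:
            best_w, best_rss = w, rss
    # converged: some successful restart reached the returned optimum (small
    # slack absorbs softmax-plateau termination noise)
    converged = np.isfinite(opt_rss) and opt_rss <= best_rss * (1 + 1e-6) + 1e-9

    _, beta = _profiled_rss(best_w, Qr, yr, sign)
    return best_w, beta, converged


def average_weights(boot_weights: np.ndarray) -> np.ndarray:
    """Arithmetic mean of converged bootstrap weight vectors, renormalized."""
    boot_weights = np.atleast_2d(np.asarray(boot_weights, float))
    if boot_weights.shape[0] == 0:
        raise ValueError("no converged bootstraps to average")
    w = boot_weights.mean(axis=0)
    return w / w.sum()


def wqs_index(quantized, weights) -> np.ndarray:
    """Per-participant index: weighted average of quantile scores, in [0, q-1]."""
    Q = quantized.to_numpy(dtype=float) if isinstance(quantized, pd.DataFrame) else np.asarray(quantized, float)
    w = np.asarray(weights, dtype=float)
    if Q.shape[1] != w.size:
        raise ValueError(f"dimension mismatch: {Q.shape[1]} exposure columns vs {w.size} weights")
    if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must lie on the simplex")
    return Q @ w


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    bad, rank = [], 0
    kept = np.empty((X.shape[0], 0))
    for j, name in enumerate(names):
        trial = np.column_stack([kept, X[:, j]])
        r = np.linalg.matrix_rank(trial)
        if r > rank:
            kept, rank = trial, r
        else:
            bad.append(name)
    return bad


def validate_index(
    index: np.ndarray, y: np.ndarray, C: np.ndarray | None, covariate_names: list[str] | None = None
):
    """OLS of the outcome on the WQS index plus covariates on the validation set.

    Returns ``(beta, se, (lo, hi), p, covariate_coefficients)`` with a
    normal-theory 95% CI (beta +- 1.96 SE) and a two-sided t-test p-value.
    Raises on a rank-deficient design, listing the collinear columns.
    """
    n = y.size
    names = ["const", "wqs_index"] + list(covariate_names or [])
    X = np.column_stack([np.ones(n), index] + ([C] if C is not None else []))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient validation design; collinear columns: {_collinear_columns(X, names)}")
    import statsmodels.api as sm

    fit = sm.OLS(y, X).fit()
    beta, se = float(fit.params[1]), float(fit.bse[1])
    ci = (beta - 1.959963984540054 * se, beta + 1.959963984540054 * se)
    return beta, se, ci, float(fit.pvalues[1]), pd.Series(fit.params, index=names)


def build_design(cohort: pd.DataFrame, covariates: list[str]) -> tuple[np.ndarray, list[str]]:
    """Numeric covariate design: categoricals dummy-coded, first level (alphabetical) as reference."""
    if not covariates:
        return None, []
    pieces, names = [], []
    for c in covariates:
        col = cohort[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.dropna().unique())
            for lev in levels[1:]:
                pieces.append((col == lev).astype(float).to_numpy())
                names.append(f"{c}[{lev}]")
        else:
            pieces.append(col.to_numpy(dtype=float))
            names.append(c)
    return np.column_stack(pieces), names


def _run_one_direction(cohort, outcome, exposures, covariates, reverse, config, direction) -> WQSResult:
    train_idx, valid_idx = split_sample(len(cohort), config.train_fraction, config.seed)
    train = cohort.iloc[train_idx]

    # quantile boundaries come from the training split only (no leakage)
    _, boundaries = quantize_table(train, exposures, q=config.q)
    scores_all, _ = quantize_table(cohort, exposures, q=config.q, boundaries=boundaries)
    reverse = [c for c in (reverse or []) if c in exposures]
    if reverse:
        scores_all = reverse_protective(scores_all, config.q, reverse)

    C_all, cov_names = build_design(cohort, covariates)
    y_all = cohort[outcome].to_numpy(dtype=float)
    Q_tr = scores_all.iloc[train_idx].to_numpy(dtype=float)
    y_tr, C_tr = y_all[train_idx], (None if C_all is None else C_all[train_idx])

    rng = np.random.default_rng([config.seed, 0 if direction == "positive" else 1])
    boot_w, n_conv, n_dir = [], 0, 0
    for _ in range(config.n_boot):
        rows = rng.integers(0, len(train_idx), size=len(train_idx))
        w, beta1, ok = fit_weights_once(
            Q_tr[rows], y_tr[rows], None if C_tr is None else C_tr[rows],
            direction, rng, config.n_restarts, config.maxiter, config.gtol,
        )
        if ok:
            boot_w.append(w)
            n_conv += 1
            if (beta1 > 0) == (direction == "positive") and beta1 != 0:
                n_dir += 1
        else:
            logger.warning("bootstrap did not converge; excluded from averaging")
    w_bar = average_weights(np.array(boot_w))

    idx_val = wqs_index(scores_all.iloc[valid_idx], w_bar)
    beta, se, ci, p, cov_coefs = validate_index(
        idx_val, y_all[valid_idx], None if C_all is None else C_all[valid_idx], cov_names
    )
    return WQSResult(
        direction=direction, exposures=list(exposures), weights=w_bar,
        boot_weights=np.array(boot_w), beta=beta, se=se, ci=ci, p_value=p,
        covariate_coefficients=cov_coefs, n_boot=config.n_boot, n_converged=n_conv,
        n_direction_consistent=n_dir, n_train=len(train_idx), n_validation=len(valid_idx),
        seed=config.seed, boundaries=boundaries,
    )


def run_wqs(
    cohort: pd.DataFrame,
    outcome: str,
    exposures: list[str],
    covariates: list[str] | None = None,
    config: WQSConfig | None = None,
    reverse: list[str] | None = None,
):
    """Full WQS pipeline: quantize -> reverse -> split -> bootstrap -> average -> validate.

    ``reverse`` names protective exposures whose scores are flipped before
    fitting. With ``direction='both'`` a dict with a result per direction is
    returned, else a single :class:`WQSResult`.
    """
    config = config or WQSConfig()
    config.validate()
    covariates = covariates or []
    use = [outcome] + list(exposures) + covariates
    cohort = cohort.dropna(subset=use).reset_index(drop=True)
    if config.direction == "both":
        return {d: _run_one_direction(cohort, outcome, exposures, covariates, reverse, config, d)
                for d in ("positive", "negative")}
    return _run_one_direction(cohort, outcome, exposures, covariates, reverse, config, config.direction)
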