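"""WQS: split, simplex weight estimation vs grid oracle, averaging, inference."""

import itertools

import numpy as np
import pandas as pd
import pytest

from envage.exposure_prep import quantize_table
from envage.synthetic_cohort import EXPOSURES, GeneratorConfig, generate_exposures, generate_outcomes
from envage.wqs import (
    WQSConfig,
    average_weights,
    fit_weights_once,
    run_wqs,
    split_sample,
    validate_index,
    wqs_index,
)


def grid_sse(Q, y, direction="positive", step=0.05):
    """Independent oracle: constrained SSE at every simplex grid point.

    For each candidate weight vector the index is formed explicitly and the
    best direction-consistent slope found by closed-form OLS.
    """
    k = Q.shape[1]
    n = len(y)
    steps = int(round(1 / step))
    sign = 1.0 if direction == "positive" else -1.0
    best = np.inf
    ones = np.ones(n)
    for combo in itertools.product(range(steps + 1), repeat=k - 1):
        if sum(combo) > steps:
            continue
        w = np.array(list(combo) + [steps - sum(combo)], dtype=float) / steps
        z = Q @ w
        X = np.column_stack([ones, z])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        if sign * coef[1] < 0:
            resid = y - ones * y.mean()
        else:
            resid = y - X @ coef
        best = min(best, float(resid @ resid))
    return best


class TestSplitSample:
    def test_sizes_and_coverage(self):
        tr, va = split_sample(10, 0.4, seed=0)
        assert len(tr) == 4 and len(va) == 6
        assert sorted(np.concatenate([tr, va])) == list(range(10))

    def test_deterministic_per_seed(self):
        a = split_sample(100, 0.4, seed=5)
        b = split_sample(100, 0.4, seed=5)
        np.testing.assert_array_equal(a[0], b[0])

    def test_different_seeds_differ(self):
        a, _ = split_sample(200, 0.4, seed=1)
        b, _ = split_sample(200, 0.4, seed=2)
        assert not np.array_equal(a, b)


class TestFitWeightsOnce:
    def test_single_exposure_reduces_to_ols(self, rng):
        q = rng.integers(0, 4, size=100).astype(float)
        y = 0.7 * q + rng.normal(size=100)
        w, beta, ok = fit_weights_once(q[:, None], y, None, "positive", rng)
        np.testing.assert_array_equal(w, [1.0])
        slope = np.polyfit(q, y, 1)[0]
        assert beta == pytest.approx(slope, rel=1e-9)

    def test_recovers_dominant_exposure(self, rng):
        Q = rng.integers(0, 4, size=(200, 3)).astype(float)
        y = 1.5 * Q[:, 0] + 0.3 * rng.normal(size=200)
        w, beta, ok = fit_weights_once(Q, y, None, "positive", rng)
        assert w[0] > 0.9 and ok

    def test_matches_grid_oracle(self, rng):
        # oracle equivalence on small 3-exposure problems
        for trial in range(3):
            Q = rng.integers(0, 4, size=(150, 3)).astype(float)
            w_true = np.array([0.5, 0.35, 0.15])
            y = 0.8 * (Q @ w_true) + rng.normal(size=150)
            w, _, _ = fit_weights_once(Q, y, None, "positive", rng)
            z = Q @ w
            X = np.column_stack([np.ones(150), z])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ coef
            assert float(resid @ resid) <= grid_sse(Q, y) + 1e-6

    def test_null_outcome_shrinks_beta(self, rng):
        Q = rng.integers(0, 4, size=(300, 3)).astype(float)
        y = rng.normal(size=300)
        _, beta, _ = fit_weights_once(Q, y, None, "positive", rng)
        assert 0 <= beta < 0.5


class TestAverageWeights:
    def test_identical_vectors(self):
        w = np.array([[0.2, 0.3, 0.5]] * 4)
        np.testing.assert_allclose(average_weights(w), [0.2, 0.3, 0.5], atol=1e-15)

    def test_opposite_vertices(self):
        np.testing.assert_allclose(average_weights(np.array([[1.0, 0], [0, 1.0]])), [0.5, 0.5])

    def test_simplex_conservation(self, rng):
        raw = rng.dirichlet(np.ones(5), size=50)
        avg = average_weights(raw)
        assert avg.sum() == pytest.approx(1.0, abs=1e-12) and (avg >= 0).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_weights(np.empty((0, 3)))


class TestIndex:
    def test_constant_scores_give_constant_index(self, rng):
        Q = np.full((20, 4), 2.0)
        w = rng.dirichlet(np.ones(4))
        np.testing.assert_allclose(wqs_index(Q, w), 2.0, atol=1e-12)

    def test_unit_weight_selects_column(self):
        Q = np.arange(12, dtype=float).reshape(4, 3)
        np.testing.assert_array_equal(wqs_index(Q, [0, 1, 0]), Q[:, 1])

    def test_hand_computed_fixture(self):
        Q = np.array([[0, 3.0], [2, 1]])
        np.testing.assert_allclose(wqs_index(Q, [0.25, 0.75]), [2.25, 1.25])

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            wqs_index(np.zeros((5, 3)), [0.5, 0.5])


class TestValidateIndex:
    def test_duplicated_index_collinear(self, rng):
        idx = rng.normal(size=100)
        y = idx + rng.normal(size=100)
        with pytest.raises(ValueError, match="collinear"):
            validate_index(idx, y, idx[:, None], ["dup"])

    def test_recovers_planted_effect(self, rng):
        n = 5000
        idx = rng.integers(0, 4, size=n).astype(float)
        y = 0.05 * idx + rng.normal(size=n)
        beta, se, ci, p, _ = validate_index(idx, y, None)
        assert abs(beta - 0.05) < 3 * se
        assert ci[0] < beta < ci[1]


class TestRunWqs:
    def _planted_cohort(self, n, seed, w_true, beta=1.0, noise=1.0):
        ex = generate_exposures(GeneratorConfig(n=n, seed=seed, exposure_mode="copula"))
        cols = list(EXPOSURES[: len(w_true)])
        scores, _ = quantize_table(ex, cols, q=4)
        rng = np.random.default_rng(seed + 1)
        y, _ = generate_outcomes(scores, w_true, beta, None, noise, rng)
        df = ex[cols].copy()
        df["y"] = y
        return df, cols

    def test_recovers_planted_weights_end_to_end(self):
        w_true = np.array([0.4, 0.4, 0.2, 0, 0, 0])
        df, cols = self._planted_cohort(5000, 101, w_true)
        res = run_wqs(df, "y", cols, [], WQSConfig(n_boot=30, seed=5))
        assert np.abs(res.weights - w_true).max() < 0.12
        assert res.weights.sum() == pytest.approx(1.0, abs=1e-10)
        assert (res.boot_weights.sum(axis=1) == pytest.approx(1.0, abs=1e-8))

    def test_deterministic_replay(self):
        w_true = np.array([0.6, 0.4, 0.0])
        df, cols = self._planted_cohort(600, 55, w_true)
        cfg = WQSConfig(n_boot=5, seed=9)
        a = run_wqs(df, "y", cols, [], cfg)
        b = run_wqs(df, "y", cols, [], cfg)
        np.testing.assert_array_equal(a.weights, b.weights)
        assert a.beta == b.beta and a.p_value == b.p_value

    def test_weight_bias_shrinks_with_n(self):
        w_true = np.array([0.5, 0.3, 0.2, 0.0])
        errs = {}
        for n in (500, 5000):
            df, cols = self._planted_cohort(n, 77, w_true, beta=1.0, noise=0.5)
            res = run_wqs(df, "y", cols, [], WQSConfig(n_boot=15, seed=3))
            errs[n] = np.abs(res.weights - w_true).max()
        assert errs[5000] < errs[500]

    def test_reversed_protective_column_gets_positive_weight(self):
        # a protective exposure (negative raw effect) enters the positive
        # model with positive weight once its scores are reversed
        ex = generate_exposures(GeneratorConfig(n=3000, seed=88, exposure_mode="copula"))
        cols = ["pm10", "green_1000m"]
        scores, _ = quantize_table(ex, cols, q=4)
        rng = np.random.default_rng(1)
        y = 0.8 * scores["pm10"].to_numpy() - 0.8 * scores["green_1000m"].to_numpy()
        y = y + 0.5 * rng.normal(size=3000)
        df = ex[cols].copy()
        df["y"] = y
        res = run_wqs(df, "y", cols, [], WQSConfig(n_boot=10, seed=2),
                      reverse=["green_1000m"])
        assert res.weights[1] > 0.25 and res.beta > 0

    def test_both_directions_requested(self):
        df, cols = self._planted_cohort(600, 91, np.array([0.7, 0.3]))
        out = run_wqs(df, "y", cols, [], WQSConfig(n_boot=3, seed=4, direction="both"))
        assert set(out) == {"positive", "negative"}
        # both directions return simplex weight vectors; the positive model
        # detects the planted positive signal
        for res in out.values():
            assert res.weights.sum() == pytest.approx(1.0, abs=1e-10)
            assert (res.weights >= 0).all()
        assert out["positive"].beta > 0 and out["positive"].p_value < 0.01
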