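"""OLS engine, BH-FDR, scans, residence filter, latent-class SES, descriptives."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from envage.associations import (
    RegressionSpec,
    bh_adjust,
    describe_cohort,
    fit_linear,
    lca_ses,
    residence_filter,
    single_exposure_scan,
    spearman_matrix,
    stratified_scan,
)


def bh_oracle(p):
    """Textbook step-up: adjusted p_(i) = min_{j>=i} m p_(j)/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_i, i in enumerate(order, start=1):
        candidates = [m * p[j] / (rank_j + 1)
                      for rank_j, j in enumerate(order) if rank_j + 1 >= rank_i]
        adj[i] = min(1.0, min(candidates))
    return adj


class TestFitLinear:
    def test_recovers_known_slope(self, rng):
        n = 1000
        x = rng.normal(size=n)
        df = pd.DataFrame({"x": x, "y": 2.0 * x + rng.normal(size=n)})
        res = fit_linear(RegressionSpec("y", "x", covariates=[]), df)
        assert abs(res.beta - 2.0) < 3 * res.se
        assert res.ci == pytest.approx((res.beta - 1.959963984540054 * res.se,
                                        res.beta + 1.959963984540054 * res.se))

    def test_predictor_in_covariates_rejected(self):
        with pytest.raises(ValueError, match="covariates"):
            RegressionSpec("y", "x", covariates=["x"]).validate()

    def test_matches_normal_equations(self, rng):
        n = 300
        df = pd.DataFrame({
            "x": rng.normal(size=n), "a": rng.normal(size=n), "y": rng.normal(size=n),
        })
        df["y"] += 0.5 * df["x"] - 0.3 * df["a"]
        res = fit_linear(RegressionSpec("y", "x", covariates=["a"]), df)
        X = np.column_stack([np.ones(n), df["x"], df["a"]])
        beta_ne = np.linalg.solve(X.T @ X, X.T @ df["y"].to_numpy())
        assert res.beta == pytest.approx(beta_ne[1], abs=1e-8)

    def test_categorical_covariates_dummy_coded(self, small_cohort):
        res = fit_linear(RegressionSpec("phenoage", "pm10",
                                        covariates=["age", "sex", "smoking"]), small_cohort)
        assert res.n == len(small_cohort)
        assert np.isfinite(res.p_value)

    def test_collinear_design_named(self, rng):
        n = 200
        df = pd.DataFrame({"x": rng.normal(size=n), "y": rng.normal(size=n)})
        df["x2"] = 2 * df["x"]
        with pytest.raises(ValueError, match="x2"):
            fit_linear(RegressionSpec("y", "x", covariates=["x2"]), df)


class TestBH:
    def test_textbook_example(self):
        adj, dec = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])
        assert dec.all()

    def test_all_ones_none_significant(self):
        adj, dec = bh_adjust(np.ones(10))
        assert not dec.any() and (adj == 1).all()

    def test_single_p_unchanged(self):
        adj, _ = bh_adjust([0.031])
        assert adj[0] == pytest.approx(0.031)

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.random(rng.integers(1, 12))
            adj, _ = bh_adjust(p)
            np.testing.assert_allclose(adj, bh_oracle(p), atol=1e-12)

    def test_matches_statsmodels(self, rng):
        for _ in range(50):
            p = rng.random(20)
            adj, dec = bh_adjust(p)
            sm_dec, sm_adj, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
            np.testing.assert_allclose(adj, sm_adj, atol=1e-12)
            np.testing.assert_array_equal(dec, sm_dec)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=60)
    def test_adjusted_at_least_raw_and_monotone(self, p):
        adj, _ = bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-15).all() and (adj <= 1).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestScans:
    def test_per_iqr_slope_equals_raw_times_iqr(self, rng):
        n = 800
        x = rng.lognormal(size=n)
        df = pd.DataFrame({"x": x, "y": 0.3 * x + rng.normal(size=n)})
        table = single_exposure_scan(df, ["x"], ["y"], covariates=[])
        from envage.exposure_prep import iqr_scale
        _, iqr = iqr_scale(x)
        raw = fit_linear(RegressionSpec("y", "x", covariates=[]), df)
        assert table["beta"].iloc[0] == pytest.approx(raw.beta * iqr, rel=1e-9)

    def test_planted_pair_flagged(self, rng):
        n = 2000
        df = pd.DataFrame(rng.normal(size=(n, 4)), columns=["e1", "e2", "o1", "o2"])
        df["o1"] += 0.5 * df["e1"]
        table = single_exposure_scan(df, ["e1", "e2"], ["o1", "o2"], covariates=[])
        hit = table[(table.predictor == "e1") & (table.outcome == "o1")]
        assert bool(hit["significant_fdr"].iloc[0])
        others = table[~((table.predictor == "e1") & (table.outcome == "o1"))]
        assert others["significant_fdr"].sum() <= 1

    def test_null_false_discovery_control(self, rng):
        # 40 null replicates of an 8-test family; average FDP stays near 0.05
        flagged = []
        for _ in range(40):
            n = 150
            df = pd.DataFrame(rng.normal(size=(n, 6)),
                              columns=["e1", "e2", "e3", "e4", "o1", "o2"])
            table = single_exposure_scan(df, ["e1", "e2", "e3", "e4"], ["o1", "o2"],
                                         covariates=[])
            flagged.append(table["significant_fdr"].mean())
        assert np.mean(flagged) <= 0.05 + 0.03

    def test_stratified_recovers_per_stratum_effects(self, rng):
        n = 3000
        sex = rng.choice(["female", "male"], size=n)
        x = rng.normal(size=n)
        beta = np.where(sex == "female", 1.0, 0.2)
        df = pd.DataFrame({"sex": sex, "x": x, "y": beta * x + rng.normal(size=n),
                           "age": rng.uniform(40, 70, n),
                           "smoking": rng.choice(["never", "current"], size=n),
                           "alcohol": rng.choice(["never", "regular"], size=n)})
        table = stratified_scan(df, ["x"], ["y"], strata=["sex"], covariates=["age"])
        f = table[table.stratum == "sex=female"].iloc[0]
        m = table[table.stratum == "sex=male"].iloc[0]
        from envage.exposure_prep import iqr_scale
        _, iqr_f = iqr_scale(df.loc[sex == "female", "x"].to_numpy())
        assert abs(f.beta - 1.0 * iqr_f) < 3 * f.se
        assert f.beta > m.beta
        # strata partition the cohort
        assert f.n + m.n == n

    def test_residence_filter(self):
        df = pd.DataFrame({"residence_years": [1.0, 5.0, 10.0, 4.9]})
        kept = residence_filter(df)
        assert len(kept) == 2
        all_ok = pd.DataFrame({"residence_years": [6.0, 7.0]})
        pd.testing.assert_frame_equal(residence_filter(all_ok), all_ok)
        with pytest.raises(KeyError):
            residence_filter(pd.DataFrame({"x": [1]}))


class TestLCA:
    def test_separable_two_class_recovery(self):
        # two perfectly separated response patterns
        n = 200
        df = pd.DataFrame({
            "income": ["high"] * (n // 2) + ["low"] * (n // 2),
            "education": ["degree"] * (n // 2) + ["none"] * (n // 2),
            "employment": ["employed"] * (n // 2) + ["unemployed"] * (n // 2),
        })
        res = lca_ses(df, k=2, seed=0, n_starts=3)
        post_max = res.posterior.max(axis=1)
        assert (post_max > 0.999).all()
        assert len(set(res.assignments[: n // 2])) == 1
        assert res.assignments[0] != res.assignments[-1]

    def test_loglik_nondecreasing(self, small_cohort):
        res = lca_ses(small_cohort[["income", "education", "employment"]].iloc[:500],
                      k=3, seed=1, n_starts=2)
        trace = np.array(res.ll_trace)
        assert (np.diff(trace) >= -1e-6).all()

    def test_k1_recovers_marginals(self, small_cohort):
        sub = small_cohort[["income", "education", "employment"]].iloc[:400]
        res = lca_ses(sub, k=1, seed=2, n_starts=1)
        marg = sub["income"].value_counts(normalize=True)
        for level in marg.index:
            assert res.item_probs["income"].loc[:, level].iloc[0] == pytest.approx(marg[level], abs=1e-6)

    def test_three_class_labels_ordered_by_income(self, small_cohort):
        res = lca_ses(small_cohort[["income", "education", "employment"]], k=3, seed=3)
        probs = res.item_probs["income"]
        assert probs.loc["high", "high"] > probs.loc["low", "high"]


class TestDescriptives:
    def test_spearman_matrix_monotone_pairs(self):
        x = np.arange(50.0)
        df = pd.DataFrame({"up": x, "up2": np.exp(x / 10), "down": -x})
        m = spearman_matrix(df)
        assert m.loc["up", "up2"] == pytest.approx(1.0)
        assert m.loc["up", "down"] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(m), 1.0)

    def test_spearman_ties_average_rank_oracle(self, rng):
        x = rng.integers(0, 5, size=60).astype(float)
        y = x + rng.integers(0, 3, size=60)
        m = spearman_matrix(pd.DataFrame({"x": x, "y": y}))
        from scipy.stats import rankdata
        rx, ry = rankdata(x), rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert m.loc["x", "y"] == pytest.approx(oracle, abs=1e-12)

    def test_identical_groups_rarely_reject(self, rng):
        rejections = 0
        for _ in range(30):
            df = pd.DataFrame({"g": rng.choice(["a", "b"], size=300),
                               "v": rng.normal(size=300)})
            tab = describe_cohort(df, "g")
            rejections += int((tab["p_value"] < 0.05).any())
        assert rejections <= 3  # >=90% of null reps show no rejection

    def test_shifted_group_detected_and_counts_sum(self, rng):
        g = rng.choice(["a", "b"], size=400)
        v = rng.normal(size=400) + (g == "b") * 2.0
        cat = rng.choice(["x", "y"], size=400)
        df = pd.DataFrame({"g": g, "v": v, "cat": cat})
        tab = describe_cohort(df, "g")
        assert tab.loc[tab.variable == "v", "p_value"].iloc[0] < 1e-6
        row = tab.loc[tab.variable == "cat"].iloc[0]
        total = sum(int(s.split(": ")[1].split(" ")[0]) for col in ("a", "b")
                    for s in row[col].split(", "))
        assert total == 400
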