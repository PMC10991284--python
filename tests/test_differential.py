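"""Normalization, BH adjustment, differential testing, cluster selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcbreg.differential import (
    PeakCountMatrix,
    bh_adjust,
    diff_test,
    hclust_top_variable,
    kmeans_gap,
    size_factors,
    vst_like,
)


def median_ratio_oracle(X):
    """Independent brute-force median-of-ratios reimplementation.

    Geometric means via exact integer products (math.prod on Python
    ints) so the oracle carries no float accumulation error.
    """
    import math

    X = np.asarray(X)
    ratios = []
    for f in range(X.shape[0]):
        row = X[f]
        if (row > 0).all():
            gm = math.prod(int(v) for v in row) ** (1.0 / len(row))
            ratios.append(np.asarray(row, float) / gm)
    return np.median(np.array(ratios), axis=0)


class TestSizeFactors:
    def test_proportional_columns(self):
        counts = pd.DataFrame([[1, 2], [2, 4], [3, 6]], columns=["a", "b"])
        f = size_factors(counts)
        np.testing.assert_allclose(f.values, [1 / np.sqrt(2), np.sqrt(2)], atol=1e-12)

    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [3, 5, 9], "b": [3, 5, 9], "c": [3, 5, 9]})
        np.testing.assert_allclose(size_factors(counts).values, 1.0, atol=1e-12)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_oracle_random_nb(self, trial):
        rng = np.random.default_rng(trial)
        X = rng.negative_binomial(20, 0.3, size=(50, 4)) + (1 if trial % 2 else 0)
        if not (X > 0).all(axis=1).any():
            X[0] = 1
        counts = pd.DataFrame(X, columns=list("abcd"))
        np.testing.assert_allclose(
            size_factors(counts).values, median_ratio_oracle(X), atol=1e-12
        )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.lists(st.integers(1, 9), min_size=3, max_size=6),
            min_size=2,
            max_size=10,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1)
    )
    def test_property_matches_oracle(self, rows):
        X = np.array(rows)
        counts = pd.DataFrame(X, columns=[f"s{j}" for j in range(X.shape[1])])
        np.testing.assert_allclose(
            size_factors(counts).values, median_ratio_oracle(X), atol=1e-12
        )

    def test_promoter_reads_geometric_mean_one(self, rng):
        X = rng.poisson(50, size=(40, 5))
        mask = rng.random(40) < 0.3
        mask[0] = True
        f = size_factors(pd.DataFrame(X), mode="promoter_reads", promoter_mask=mask)
        assert np.isclose(np.exp(np.mean(np.log(f))), 1.0, atol=1e-12)

    def test_no_all_positive_feature_errors(self):
        counts = pd.DataFrame([[0, 1], [1, 0]], columns=["a", "b"])
        with pytest.raises(ValueError, match="median-of-ratios"):
            size_factors(counts)


def bh_oracle(p):
    """Smallest q at which each p-value is rejected (step-up enumeration)."""
    p = np.asarray(p, float)
    n = len(p)
    out = np.empty(n)
    for i, pi in enumerate(p):
        qs = []
        for q in sorted(set(np.minimum(p * n / (np.argsort(np.argsort(p)) + 1), 1))):
            rej = _bh_reject(p, q)
            if rej[i]:
                qs.append(q)
        out[i] = min(qs) if qs else 1.0
    return out


def _bh_reject(p, q):
    n = len(p)
    order = np.argsort(p)
    k = 0
    for rank, idx in enumerate(order, start=1):
        # epsilon guards the q = padj boundary against float roundoff
        if p[idx] <= q * rank / n + 1e-12:
            k = rank
    rej = np.zeros(n, bool)
    rej[order[:k]] = True
    return rej


class TestBHAdjust:
    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_degenerate(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_padj_at_least_p_and_monotone(self, rng):
        p = rng.random(100)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    @pytest.mark.parametrize("trial", range(20))
    def test_is_smallest_rejecting_q(self, trial):
        rng = np.random.default_rng(trial)
        p = np.round(rng.random(int(rng.integers(1, 9))), 3)
        adj = bh_adjust(p)
        for i in range(len(p)):
            # rejected at its own padj, not rejected just below it
            assert _bh_reject(p, adj[i])[i]
            if adj[i] > 1e-9:
                assert not _bh_reject(p, adj[i] - 1e-9)[i]


class TestVst:
    def test_basic_values(self):
        counts = pd.DataFrame({"a": [0, 3], "b": [0, 3]})
        out = vst_like(counts, factors=pd.Series([1.0, 1.0], index=["a", "b"]))
        assert out.iloc[0, 0] == 0.0
        assert out.iloc[1, 0] == pytest.approx(2.0)

    def test_column_scaling_invariance(self, rng):
        X = np.tile(rng.poisson(40, size=(30, 1)).astype(float) + 1, (1, 3))
        scaled = X * np.array([1.0, 2.0, 4.0])
        counts = pd.DataFrame(scaled, columns=list("abc"))
        out = vst_like(counts)
        np.testing.assert_allclose(out["a"], out["b"], rtol=1e-10)
        np.testing.assert_allclose(out["a"], out["c"], rtol=1e-10)


def _nb_counts(rng, mu, n_samples, dispersion=0.05):
    size = 1.0 / dispersion
    p = size / (size + np.asarray(mu, float))[:, None]
    return rng.negative_binomial(size, p, size=(len(mu), n_samples))


class TestDiffTest:
    def _pcm(self, X):
        cols = [f"a{i}" for i in range(X.shape[1] // 2)] + [
            f"b{i}" for i in range(X.shape[1] - X.shape[1] // 2)
        ]
        counts = pd.DataFrame(X, columns=cols)
        groups = {c: ("A" if c.startswith("a") else "B") for c in cols}
        return PeakCountMatrix(counts, groups)

    def test_identical_groups_ns(self, rng):
        X = np.tile(rng.poisson(100, size=(20, 1)), (1, 8))
        t = diff_test(self._pcm(X), "A", "B")
        np.testing.assert_allclose(t["log2FC"], 0.0, atol=1e-12)
        assert (t["call"] == "ns").all()

    def test_padj_at_least_p(self, rng):
        mu = rng.lognormal(np.log(80), 0.4, 50)[:, None]
        X = _nb_counts(rng, np.broadcast_to(mu, (50, 1)).ravel(), 10)
        t = diff_test(self._pcm(X), "A", "B")
        assert (t["padj"] >= t["p"] - 1e-15).all()

    def test_planted_effects_power(self):
        # planted log2FC=2 in a tenth of features at n=5 vs 5, low
        # dispersion: >=90% of planted features called up
        called = total = 0
        for s in range(1, 21):
            rng = np.random.default_rng(s)
            mu = np.full(100, 100.0)
            mu_b = mu.copy()
            mu_b[:10] *= 4
            a = _nb_counts(rng, mu, 5)
            b = _nb_counts(rng, mu_b, 5)
            t = diff_test(self._pcm(np.hstack([a, b])), "A", "B")
            called += (t["call"].iloc[:10] == "up").sum()
            total += 10
        assert called / total >= 0.9

    def test_small_group_rejected(self, rng):
        X = rng.poisson(50, size=(10, 3))
        cols = ["a0", "a1", "b0"]
        counts = pd.DataFrame(X, columns=cols)
        pcm = PeakCountMatrix(counts, {"a0": "A", "a1": "A", "b0": "B"})
        with pytest.raises(ValueError, match=">= 2 samples"):
            diff_test(pcm, "A", "B")


class TestKmeansGap:
    def test_three_blobs(self):
        hits = 0
        for s in range(8):
            rng = np.random.default_rng(s)
            centers = np.array([[0, 0], [5, 5], [0, 5]])
            X = np.vstack([rng.normal(c, 0.1, size=(50, 2)) for c in centers])
            k, labels = kmeans_gap(X, k_max=5, B=30, seed=s)
            hits += k == 3
            if k == 3:
                assert len(np.unique(labels)) == 3
                assert len(labels) == X.shape[0]
        assert hits >= 7

    def test_uniform_data_prefers_one_cluster(self):
        ones = 0
        for s in range(8):
            rng = np.random.default_rng(50 + s)
            X = rng.uniform(0, 1, size=(120, 2))
            k, _ = kmeans_gap(X, k_max=4, B=30, seed=s)
            ones += k == 1
        assert ones >= 5  # majority

    def test_degenerate_input_warns(self):
        X = np.ones((10, 3))
        with pytest.warns(UserWarning, match="identical"):
            k, labels = kmeans_gap(X, k_max=3, B=10, seed=0)
        assert k == 1 and (labels == 0).all()


class TestHclustTopVariable:
    def test_duplicated_column_groups_separate(self, rng):
        base = rng.normal(0, 1, size=(100, 1))
        X = pd.DataFrame(
            np.hstack([base, base + 0.01, base + 5, base + 5.01]),
            columns=["a1", "a2", "b1", "b2"],
        )
        labels = hclust_top_variable(X, top_frac=0.5, n_clusters=2)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_constant_rows_excluded(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 4)))
        X.iloc[:10] = 1.0  # constant rows must not survive a 50% variance filter
        labels = hclust_top_variable(X, top_frac=0.5, n_clusters=2)
        assert len(labels) == 4

    def test_row_permutation_invariance(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 5)))
        l1 = hclust_top_variable(X, top_frac=0.2, n_clusters=2)
        perm = rng.permutation(60)
        l2 = hclust_top_variable(X.iloc[perm], top_frac=0.2, n_clusters=2)
        np.testing.assert_array_equal(l1, l2)

    def test_manhattan_distance_option(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 4)))
        Z = hclust_top_variable(X, top_frac=1.0, distance="manhattan")
        assert Z.shape == (3, 4)

    def test_bad_top_frac(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 3)))
        with pytest.raises(ValueError):
            hclust_top_variable(X, top_frac=0.0)
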