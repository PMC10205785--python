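"""GMM clustering and external metrics against brute-force pair-counting
and contingency oracles."""

import itertools

import numpy as np
import pytest

from adept import ScoreTable, ari, fms, gmm_cluster, purity, rank_methods

# ---------------------------------------------------------------------------
# oracles


def pair_counts(a, b):
    n11 = n10 = n01 = n00 = 0
    for i, j in itertools.combinations(range(len(a)), 2):
        sa, sb = a[i] == a[j], b[i] == b[j]
        n11 += sa and sb
        n10 += sa and not sb
        n01 += sb and not sa
        n00 += not sa and not sb
    return n11, n10, n01, n00


def ari_oracle(a, b):
    n11, n10, n01, n00 = pair_counts(a, b)
    total = n11 + n10 + n01 + n00
    pa, pb = n11 + n10, n11 + n01
    expected = pa * pb / total if total else 0.0
    maximum = (pa + pb) / 2.0
    if maximum == expected:  # both partitions trivial and identical
        return 1.0
    return (n11 - expected) / (maximum - expected)


def fms_oracle(a, b):
    n11, n10, n01, _ = pair_counts(a, b)
    denom = (n11 + n10) * (n11 + n01)
    return n11 / np.sqrt(denom) if denom else 0.0


def purity_oracle(truth, pred):
    total = 0
    for c in set(pred):
        members = [truth[i] for i in range(len(pred)) if pred[i] == c]
        total += max(members.count(t) for t in set(members))
    return total / len(pred)


def set_partitions(n):
    """All partitions of range(n) as label vectors (restricted growth strings)."""
    if n == 0:
        return
    labels = [0] * n

    def rec(i, k):
        if i == n:
            yield tuple(labels)
            return
        for c in range(k + 1):
            labels[i] = c
            yield from rec(i + 1, max(k, c + 1))

    yield from rec(1, 1)


# ---------------------------------------------------------------------------
# metric tests


class TestMetricOracles:
    def test_exhaustive_agreement_small_n(self):
        """ari/fms/purity equal brute-force enumeration on every pair of
        partitions of up to 5 items (and a spot check at n=6 below)."""
        for n in (2, 3, 4, 5):
            parts = list(set_partitions(n))
            for a in parts:
                for b in parts:
                    assert ari(a, b) == pytest.approx(ari_oracle(a, b), abs=1e-12)
                    assert fms(a, b) == pytest.approx(fms_oracle(a, b), abs=1e-12)
                    assert purity(a, b) == pytest.approx(purity_oracle(a, b), abs=1e-12)

    def test_exhaustive_agreement_n6_sample(self):
        parts = list(set_partitions(6))
        rng = np.random.default_rng(0)
        idx = rng.choice(len(parts), size=60, replace=False)
        for i in idx:
            for j in idx[:20]:
                a, b = parts[i], parts[j]
                assert ari(a, b) == pytest.approx(ari_oracle(a, b), abs=1e-12)
                assert fms(a, b) == pytest.approx(fms_oracle(a, b), abs=1e-12)
                assert purity(a, b) == pytest.approx(purity_oracle(a, b), abs=1e-12)

    @pytest.mark.parametrize("metric", [ari, fms])
    def test_identical_partitions_score_one(self, metric):
        assert metric([0, 0, 1, 2], [5, 5, 7, 9]) == pytest.approx(1.0)

    def test_ari_chance_level_degenerate(self):
        assert ari([0, 0, 0, 0], [0, 1, 2, 3]) == pytest.approx(0.0)

    def test_ari_hand_example(self):
        # contingency of [0,0,1,1] vs [0,1,1,1]: 1 agreeing pair of 6,
        # expectation exactly matches -> 0
        assert ari([0, 0, 1, 1], [0, 1, 1, 1]) == pytest.approx(0.0)

    def test_fms_hand_enumeration(self):
        # pairs same in both: {0,1}; same a only: {2,3}; same b only: {0,2},{1,2}
        assert fms([0, 0, 1, 1], [0, 0, 0, 1]) == pytest.approx(1 / np.sqrt(6))

    def test_purity_single_cluster_balanced(self):
        assert purity([0, 1, 2, 0, 1, 2], [0] * 6) == pytest.approx(1 / 3)

    def test_ari_symmetric(self):
        rng = np.random.default_rng(1)
        a, b = rng.integers(0, 3, 30), rng.integers(0, 4, 30)
        assert ari(a, b) == pytest.approx(ari(b, a))

    def test_purity_monotone_under_refinement(self):
        rng = np.random.default_rng(2)
        truth = rng.integers(0, 3, 40)
        pred = rng.integers(0, 3, 40)
        refined = pred * 2 + rng.integers(0, 2, 40)  # split every cluster
        assert purity(truth, refined) >= purity(truth, pred)

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError):
            ari([0, 1], [0, 1, 2])


# ---------------------------------------------------------------------------
# GMM clustering


class TestGMMCluster:
    def test_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(0)
        h = np.vstack([rng.normal(0, 0.1, (20, 3)), rng.normal(5, 0.1, (20, 3))])
        truth = [0] * 20 + [1] * 20
        out = gmm_cluster(h, n_clusters=2, seed=0)
        assert ari(truth, out.labels) == pytest.approx(1.0)

    def test_each_spot_own_cluster_at_saturation(self):
        rng = np.random.default_rng(1)
        h = rng.normal(size=(8, 2)) * 10
        out = gmm_cluster(h, n_clusters=8, seed=0, n_init=3)
        assert len(set(out.labels.tolist())) == 8

    def test_three_blob_mean_ari(self):
        """Three moderately separated Gaussian blobs: ARI vs the generating
        labels averages >= 0.95 over 20 seeds."""
        aris = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            centers = np.array([[0, 0], [4, 0], [0, 4]], dtype=float)
            h = np.vstack([rng.normal(c, 0.7, (30, 2)) for c in centers])
            truth = np.repeat([0, 1, 2], 30)
            out = gmm_cluster(h, n_clusters=3, seed=seed, n_init=5)
            aris.append(ari(truth, out.labels))
        assert np.mean(aris) >= 0.95

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        h = rng.normal(size=(50, 4))
        a = gmm_cluster(h, 3, seed=7)
        b = gmm_cluster(h, 3, seed=7)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_invalid_cluster_count(self):
        with pytest.raises(ValueError):
            gmm_cluster(np.zeros((5, 2)), n_clusters=1)


# ---------------------------------------------------------------------------
# ranking


class TestRankMethods:
    def test_minimum_rank_ties(self):
        t = ScoreTable(["m1", "m2"], ["d1", "d2"], [[3.0, 1.0], [2.0, 2.0]])
        out = rank_methods(t)
        assert list(out["avg_rank"]) == [1.5, 1.5]

    def test_all_equal_scores_all_rank_one(self):
        t = ScoreTable(["a", "b", "c"], ["d1", "d2"], np.ones((3, 2)))
        out = rank_methods(t)
        assert (out[["d1", "d2"]].to_numpy() == 1).all()

    def test_distinct_scores_give_permutation(self):
        rng = np.random.default_rng(4)
        scores = rng.permutation(20).reshape(4, 5).astype(float)
        t = ScoreTable(list("abcd"), [f"d{i}" for i in range(5)], scores)
        ranks = rank_methods(t)[[f"d{i}" for i in range(5)]].to_numpy()
        for col in ranks.T:
            assert sorted(col) == [1, 2, 3, 4]

    def test_single_method_rejected(self):
        with pytest.raises(ValueError):
            rank_methods(ScoreTable(["only"], ["d"], [[1.0]]))

    def test_nan_scores_rejected(self):
        with pytest.raises(ValueError):
            ScoreTable(["a", "b"], ["d"], [[1.0], [np.nan]])
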