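import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from waspclock.clustering import (ClusterModel, cluster_rhythm_enrichment,
                                  fuzzy_cmeans, harden, select_c, standardize)
from waspclock.core_io import ValidationError


def antiphase_families(n_per=100, noise=0.15, seed=0, times=None):
    rng = np.random.default_rng(seed)
    t = times if times is not None else 1.0 + 4.0 * np.arange(12)
    a = np.cos(2 * np.pi * (t[None, :] - 2.0) / 24.0)
    b = np.cos(2 * np.pi * (t[None, :] - 14.0) / 24.0)
    X = np.vstack([np.repeat(a, n_per, 0), np.repeat(b, n_per, 0)])
    X = X + rng.normal(0, noise, X.shape)
    labels = np.repeat([0, 1], n_per)
    return standardize(X)[0], labels


class TestStandardize:
    def test_hand_example(self):
        z, kept = standardize(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(z, [[-1.0, 0.0, 1.0]])
        assert kept.all()

    def test_constant_rows_excluded(self):
        z, kept = standardize(np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]]))
        assert list(kept) == [False, True]
        assert z.shape == (1, 3)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 10, (20, 12))
        z1, _ = standardize(X)
        z2, _ = standardize(z1)
        np.testing.assert_allclose(z1, z2, atol=1e-12)

    def test_moments(self):
        rng = np.random.default_rng(2)
        z, _ = standardize(rng.uniform(0, 5, (30, 12)))
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1, atol=1e-12)


class TestFuzzyCMeans:
    def test_single_cluster_closed_form(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 5))
        model = fuzzy_cmeans(X, c=1, seed=0)
        np.testing.assert_allclose(model.centroids[0], X.mean(axis=0), atol=1e-9)
        np.testing.assert_allclose(model.membership, 1.0)

    def test_coincident_point_gets_full_membership(self):
        X = np.array([[0.0, 0.0], [10.0, 10.0], [0.0, 0.0]])
        model = fuzzy_cmeans(X, c=2, seed=1)
        i = np.argmin(np.abs(model.centroids).sum(axis=1))
        assert model.membership[0, i] == pytest.approx(1.0)

    def test_memberships_sum_to_one(self):
        X, _ = antiphase_families(seed=4)
        model = fuzzy_cmeans(X, c=5, seed=2)
        np.testing.assert_allclose(model.membership.sum(axis=1), 1.0, atol=1e-9)
        assert ((model.membership >= 0) & (model.membership <= 1)).all()

    def test_objective_non_increasing(self):
        X, _ = antiphase_families(seed=5)
        model = fuzzy_cmeans(X, c=4, seed=3)
        path = np.array(model.objective_path)
        assert (np.diff(path) <= 1e-8 * np.abs(path[:-1]) + 1e-12).all()

    def test_antiphase_families_recovered(self):
        X, labels = antiphase_families(seed=6)
        model = fuzzy_cmeans(X, c=2, m=1.25, seed=4)
        assert adjusted_rand_score(labels, harden(model)) >= 0.95

    def test_labels_stable_across_seeds_up_to_permutation(self):
        X, _ = antiphase_families(seed=7)
        a = harden(fuzzy_cmeans(X, c=2, m=1.25, seed=10))
        b = harden(fuzzy_cmeans(X, c=2, m=1.25, seed=20))
        assert adjusted_rand_score(a, b) >= 0.95

    def test_too_many_clusters_rejected(self):
        with pytest.raises(ValidationError):
            fuzzy_cmeans(np.zeros((3, 2)), c=4)


class TestSelectC:
    def test_three_families_recovered(self):
        rng = np.random.default_rng(8)
        t = 1.0 + 4.0 * np.arange(12)
        fams = [np.cos(2 * np.pi * (t - ph) / 24.0) for ph in (1.0, 9.0, 17.0)]
        X = np.vstack([np.repeat(f[None, :], 60, 0) for f in fams])
        X, _ = standardize(X + rng.normal(0, 0.1, X.shape))
        chosen, curve = select_c(X, c_range=range(2, 9), seed=0)
        assert chosen in (3, 4)
        assert len(curve) == 7

    def test_noise_curve_decreases(self):
        # centroid redundancy on structureless data emerges once n is large
        # relative to c: duplicated centroids drive the minimum distance down
        rng = np.random.default_rng(9)
        X, _ = standardize(rng.normal(size=(1000, 12)))
        _, curve = select_c(X, c_range=range(2, 9), seed=0)
        d = curve["min_centroid_dist"].to_numpy()
        from scipy.stats import spearmanr
        assert spearmanr(np.arange(len(d)), d).statistic < 0

    def test_singleton_range(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(30, 12))
        chosen, curve = select_c(X, c_range=[4], seed=0)
        assert chosen == 4 and len(curve) == 1


def one_hot_model(labels, c):
    n = len(labels)
    u = np.zeros((n, c))
    u[np.arange(n), labels] = 1.0
    return ClusterModel(centroids=np.zeros((c, 12)), membership=u, m=1.25,
                        objective=0.0, objective_path=(0.0,), n_iter=0)


class TestClusterRhythmEnrichment:
    def test_direct_enumeration_example(self):
        # N=10, K=5, n=4, k=4 -> C(5,4)C(5,0)/C(10,4) = 5/210
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1, 1, 1])
        ids = np.array([f"t{i}" for i in range(10)])
        model = one_hot_model(labels, 2)
        out = cluster_rhythm_enrichment(model, ids, rhythmic_ids=ids[:5])
        assert out.loc[0, "p"] == pytest.approx(5 / 210, rel=1e-10)

    def test_rhythmic_equals_universe_gives_p_one(self):
        labels = np.array([0, 0, 1, 1, 1])
        ids = np.array([f"t{i}" for i in range(5)])
        out = cluster_rhythm_enrichment(one_hot_model(labels, 2), ids, ids)
        assert (out["p"] == 1.0).all()

    def test_pure_rhythmic_cluster_extreme_p(self):
        from math import comb
        ids = np.array([f"t{i}" for i in range(30)])
        labels = np.zeros(30, dtype=int)
        labels[10:] = 1
        out = cluster_rhythm_enrichment(one_hot_model(labels, 2), ids, ids[:10])
        want = comb(10, 10) * comb(20, 0) / comb(30, 10)
        assert out.loc[0, "p"] == pytest.approx(want, rel=1e-10)

    def test_rhythmic_outside_universe_rejected(self):
        ids = np.array(["a", "b"])
        with pytest.raises(ValidationError):
            cluster_rhythm_enrichment(one_hot_model(np.array([0, 1]), 2), ids,
                                      ["z"])

    def test_empty_cluster_gets_p_one(self):
        labels = np.array([0, 0, 0])
        ids = np.array(["a", "b", "c"])
        out = cluster_rhythm_enrichment(one_hot_model(labels, 2), ids, ["a"])
        assert out.loc[1, "p"] == 1.0
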