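"""Under-sampling techniques against brute-force oracles.

The oracles re-derive nearest neighbors and Tomek's links with plain
Python loops over all pairs, independently of the vectorized
implementation path.
"""

import numpy as np
import pytest

from tfsum.imbalance import (
    UnderSampler,
    instance_hardness_threshold,
    one_sided_selection,
    oss_consistent_subset,
    random_undersample,
    tomek_link_removal,
    tomek_links,
)


def brute_force_nn(X):
    """Nearest other point per point, scanning all pairs (ties: lowest index)."""
    n = len(X)
    out = []
    for i in range(n):
        best, best_d = None, None
        for j in range(n):
            if j == i:
                continue
            d = float(np.sqrt(((X[i] - X[j]) ** 2).sum()))
            if best_d is None or d < best_d:
                best, best_d = j, d
        out.append(best)
    return out


def brute_force_tomek_removal(X, y):
    nn = brute_force_nn(X)
    removed = set()
    for i in range(len(y)):
        j = nn[i]
        if nn[j] == i and y[i] != y[j]:
            for idx in (i, j):
                if y[idx] == 0:
                    removed.add(idx)
    return [i for i in range(len(y)) if i not in removed]


def random_dataset(rng, n_max=200):
    n = int(rng.integers(10, n_max + 1))
    n_pos = int(rng.integers(2, max(3, n // 4)))
    X = rng.normal(size=(n, int(rng.integers(1, 4))))
    y = np.zeros(n, dtype=int)
    y[rng.choice(n, size=n_pos, replace=False)] = 1
    # shift positives so both overlapping and separated layouts occur
    X[y == 1] += rng.normal() * rng.integers(0, 4)
    return X, y


class TestRandomUndersample:
    def test_exact_one_to_one_ratio(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(13, 2))
        y = np.array([1] * 3 + [0] * 10)
        kept = random_undersample(X, y, seed=5)
        assert (y[kept] == 1).sum() == 3 and (y[kept] == 0).sum() == 3

    def test_determinism(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 2))
        y = (np.arange(30) < 6).astype(int)
        assert np.array_equal(random_undersample(X, y, 9), random_undersample(X, y, 9))

    def test_balanced_input_unchanged(self):
        X = np.zeros((10, 1))
        y = np.array([1] * 5 + [0] * 5)
        assert len(random_undersample(X, y, 0)) == 10

    def test_fewer_negatives_is_noop_with_warning(self):
        X = np.zeros((5, 1))
        y = np.array([1, 1, 1, 0, 0])
        with pytest.warns(UserWarning):
            kept = random_undersample(X, y, 0)
        assert len(kept) == 5


class TestTomek:
    def test_one_dimensional_example(self):
        X = np.array([[0.0], [0.1], [5.0]])
        y = np.array([1, 0, 0])
        assert tomek_links(X, y) == [(0, 1)]
        assert list(tomek_link_removal(X, y)) == [0, 2]

    def test_separated_dense_clusters_have_no_links(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 0.1, size=(10, 2)), rng.normal(10, 0.1, size=(30, 2))])
        y = np.array([1] * 10 + [0] * 30)
        assert tomek_links(X, y) == []
        assert len(tomek_link_removal(X, y)) == 40

    def test_single_pair_is_a_link(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([1, 0])
        assert list(tomek_link_removal(X, y)) == [0]

    def test_matches_brute_force_on_random_datasets(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            X, y = random_dataset(rng)
            got = list(tomek_link_removal(X, y))
            expected = brute_force_tomek_removal(X, y)
            assert got == expected


class TestOneSidedSelection:
    def brute_force_stage1(self, X, y, seed):
        """Exhaustive 1NN simulation with pure-Python distance scans."""
        pos = [i for i in range(len(y)) if y[i] == 1]
        neg = [i for i in range(len(y)) if y[i] == 0]
        order = np.random.default_rng(seed).permutation(len(neg))
        store = pos + [neg[order[0]]]
        for k in order[1:]:
            idx = neg[k]
            best, best_d = None, None
            for ref in store:
                d = float(np.sqrt(((X[idx] - X[ref]) ** 2).sum()))
                if best_d is None or d < best_d:
                    best, best_d = ref, d
            if y[best] != y[idx]:
                store.append(idx)
        return sorted(store)

    def test_stage1_matches_exhaustive_simulation(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            X, y = random_dataset(rng, n_max=120)
            seed = int(rng.integers(0, 1000))
            got = list(oss_consistent_subset(X, y, seed))
            assert got == self.brute_force_stage1(X, y, seed)

    def test_tight_clusters_shrink_negatives(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 0.05, size=(5, 2)), rng.normal(8, 0.05, size=(100, 2))])
        y = np.array([1] * 5 + [0] * 100)
        kept = one_sided_selection(X, y, seed=0)
        assert (y[kept] == 0).sum() < 20

    def test_identical_negatives_keep_exactly_one(self):
        X = np.vstack([[[0.0, 0.0]], np.tile([[5.0, 5.0]], (20, 1))])
        y = np.array([1] + [0] * 20)
        kept = oss_consistent_subset(X, y, seed=4)
        assert (y[kept] == 0).sum() == 1


class TestInstanceHardness:
    def test_negatives_inside_positive_cluster_removed_first(self):
        rng = np.random.default_rng(5)
        pos = rng.normal(0, 0.3, size=(20, 2))
        hard_neg = rng.normal(0, 0.1, size=(5, 2))  # deep inside the positives
        easy_neg = rng.normal(6, 0.3, size=(40, 2))
        X = np.vstack([pos, hard_neg, easy_neg])
        y = np.array([1] * 20 + [0] * 45)
        kept = set(instance_hardness_threshold(X, y, seed=0))
        hard_kept = sum(1 for i in range(20, 25) if i in kept)
        easy_kept = sum(1 for i in range(25, 65) if i in kept)
        assert hard_kept <= 1
        assert easy_kept == 40

    def test_separable_data_removes_nothing(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(0, 0.2, size=(10, 2)), rng.normal(10, 0.2, size=(30, 2))])
        y = np.array([1] * 10 + [0] * 30)
        assert len(instance_hardness_threshold(X, y, seed=1)) == 40

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 3))
        y = (np.arange(40) < 8).astype(int)
        a = instance_hardness_threshold(X, y, seed=3)
        b = instance_hardness_threshold(X, y, seed=3)
        assert np.array_equal(a, b)


class TestSamplerContract:
    @pytest.mark.parametrize("method", ["NONE", "RANDOM_US", "TOMEK", "OSS", "IHT"])
    def test_never_removes_positives_and_subsets_input(self, method):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(60, 2))
        y = (np.arange(60) < 9).astype(int)
        X[y == 1] += 1.0
        sampler = UnderSampler(method=method, seed=2)
        Xr, yr = sampler.fit_resample(X, y)
        kept = sampler.sample_indices_
        assert set(kept) <= set(range(60))
        assert (y[kept] == 1).sum() == 9  # all positives kept
        assert len(Xr) == len(kept) == len(yr)
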