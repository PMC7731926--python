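"""Under-sampling of the negative (majority) class.

Four techniques: random under-sampling to a 1:1 ratio, Tomek's-link
removal, one-sided selection (1NN-consistent subset + Tomek cleaning) and
the instance hardness threshold (drop negatives that a cross-fitted
classifier finds hard to recognize as negative). All samplers operate on
the positive=1 / negative=0 convention, never remove a positive example,
and return the subset of row indices to keep.

Distances are Euclidean; nearest-neighbor ties are broken by lowest index
so every technique is deterministic given its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, clone
from sklearn.metrics import pairwise_distances
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

SAMPLER_NONE = "NONE"
SAMPLER_RANDOM = "RANDOM_US"
SAMPLER_TOMEK = "TOMEK"
SAMPLER_OSS = "OSS"
SAMPLER_IHT = "IHT"
SAMPLERS = (SAMPLER_NONE, SAMPLER_RANDOM, SAMPLER_TOMEK, SAMPLER_OSS, SAMPLER_IHT)


def _as_array(y) -> np.ndarray:
    y = np.asarray(y).astype(int)
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary with positives = 1, negatives = 0")
    return y


def random_undersample(X, y, seed: int) -> np.ndarray:
    """Keep all positives and exactly |positives| random negatives."""
    y = _as_array(y)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0:
        raise ValueError("random under-sampling needs at least one positive example")
    if len(neg) < len(pos):
        warnings.warn(
            "negatives < positives: random under-sampling is a no-op", stacklevel=2
        )
        return np.arange(len(y))
    rng = np.random.default_rng(seed)
    kept_neg = rng.choice(neg, size=len(pos), replace=False)
    return np.sort(np.concatenate([pos, kept_neg]))


def _nearest_neighbors(X) -> np.ndarray:
    """Index of each point's nearest other point (ties -> lowest index)."""
    d = pairwise_distances(X, metric="euclidean")
    np.fill_diagonal(d, np.inf)
    return d.argmin(axis=1)


def tomek_links(X, y) -> list[tuple[int, int]]:
    """All Tomek's links: mutual-nearest-neighbor pairs of opposite class."""
    y = _as_array(y)
    nn = _nearest_neighbors(X)
    links = []
    for i in range(len(y)):
        j = nn[i]
        if j > i and nn[j] == i and y[i] != y[j]:
            links.append((i, int(j)))
    return links


def tomek_link_removal(X, y) -> np.ndarray:
    """Drop the majority-class member of every Tomek's link."""
    y = _as_array(y)
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("Tomek's-link removal needs at least one example per class")
    removed = set()
    for i, j in tomek_links(X, y):
        for idx in (i, j):
            if y[idx] == 0:
                removed.add(idx)
    return np.array([i for i in range(len(y)) if i not in removed], dtype=int)


def _one_nn_predict(X_ref, y_ref: np.ndarray, X_query) -> np.ndarray:
    d = pairwise_distances(X_query, X_ref, metric="euclidean")
    return y_ref[d.argmin(axis=1)]


def oss_consistent_subset(X, y, seed: int) -> np.ndarray:
    """Stage 1 of one-sided selection: a 1NN-consistent subset.

    All positives plus one random negative seed the reference set;
    remaining negatives are visited once in seeded random order, and each
    negative the current reference set misclassifies with the
    one-nearest-neighbor rule is added.
    """
    y = _as_array(y)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("one-sided selection needs at least one example per class")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(neg))
    store = list(pos) + [int(neg[order[0]])]
    for k in order[1:]:
        idx = int(neg[k])
        pred = _one_nn_predict(X[store], y[store], X[[idx]])[0]
        if pred != y[idx]:
            store.append(idx)
    return np.sort(np.array(store, dtype=int))


def one_sided_selection(X, y, seed: int) -> np.ndarray:
    """One-sided selection: 1NN-consistent subset, then Tomek cleaning.

    Stage 1 (:func:`oss_consistent_subset`) keeps the majority examples
    needed for 1NN consistency; stage 2 removes majority members of
    Tomek's links within that subset.
    """
    store_idx = oss_consistent_subset(X, y, seed)
    y = _as_array(y)
    sub_keep = tomek_link_removal(X[store_idx], y[store_idx])
    return store_idx[sub_keep]


def instance_hardness_threshold(
    X, y, base_learner=None, seed: int = 0, n_folds: int = 5
) -> np.ndarray:
    """Drop the negatives hardest to recognize as negative.

    Class-membership probabilities are cross-fitted with ``n_folds``
    stratified folds of ``base_learner`` (default: an RBF-kernel SVC with
    Platt-scaled probabilities). A negative is removed when its predicted
    probability of the negative class falls below 0.5, except that the
    |positives| easiest negatives are always retained so the majority class
    never shrinks past balance. The kept count is an output of the data,
    not a parameter.
    """
    y = _as_array(y)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("instance hardness threshold needs both classes")
    if base_learner is None:
        base_learner = SVC(kernel="rbf", gamma="scale", probability=True, random_state=seed)
    if not hasattr(base_learner, "predict_proba") and not hasattr(base_learner, "fit"):
        raise ValueError("base learner must implement fit/predict_proba")

    n_folds = min(n_folds, len(pos), len(neg))
    prob_own = np.ones(len(y))  # P(own class); positives stay at 1 (never removed)
    if n_folds >= 2:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
            est = clone(base_learner)
            est.fit(X[train_idx], y[train_idx])
            if not hasattr(est, "predict_proba"):
                raise ValueError("base learner does not produce class probabilities")
            proba = est.predict_proba(X[test_idx])
            neg_col = int(np.flatnonzero(est.classes_ == 0)[0])
            for local, idx in enumerate(test_idx):
                if y[idx] == 0:
                    prob_own[idx] = proba[local, neg_col]
    easy = neg[prob_own[neg] >= 0.5]
    if len(easy) < len(pos):
        # retain the |positives| negatives with the highest P(negative)
        order = np.argsort(-prob_own[neg], kind="stable")
        easy = neg[np.sort(order[: min(len(pos), len(neg))])]
    return np.sort(np.concatenate([pos, easy]))


@dataclass(frozen=True)
class SamplerConfig:
    method: str = SAMPLER_NONE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in SAMPLERS:
            raise ValueError(f"unknown sampler {self.method!r}")


def sample_indices(X, y, config: SamplerConfig, base_learner=None) -> np.ndarray:
    """Dispatch to the configured technique; returns kept row indices."""
    if config.method == SAMPLER_NONE:
        return np.arange(len(np.asarray(y)))
    if config.method == SAMPLER_RANDOM:
        return random_undersample(X, y, config.seed)
    if config.method == SAMPLER_TOMEK:
        return tomek_link_removal(X, y)
    if config.method == SAMPLER_OSS:
        return one_sided_selection(X, y, config.seed)
    return instance_hardness_threshold(X, y, base_learner=base_learner, seed=config.seed)


class UnderSampler(BaseEstimator):
    """Resampler with the imbalanced-learn-style ``fit_resample`` surface.

    ``fit_resample(X, y)`` returns the resampled ``(X, y)`` and records the
    kept row indices in ``sample_indices_``.
    """

    def __init__(self, method: str = SAMPLER_NONE, seed: int = 0, base_learner=None):
        self.method = method
        self.seed = seed
        self.base_learner = base_learner

    def fit_resample(self, X, y):
        config = SamplerConfig(self.method, self.seed)
        idx = sample_indices(X, y, config, base_learner=self.base_learner)
        self.sample_indices_ = idx
        y = np.asarray(y)
        return X[idx], y[idx]
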