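"""Sentence representation: feature combinations, n-grams, vector spaces.

Three feature combinations are supported, mirroring how lemmas, POS tags
and dictionary NER tags can be mixed in one sentence representation:

``LEMMA_POS_NER``
    lemma sequence followed by the POS sequence in which each NER-tagged
    position's POS tag is replaced by its NER tag;
``LEMMA_NER``
    lemma sequence followed by the sequence of NER tags only;
``NER_FOR_LEMMA``
    lemma sequence with NER-tagged lemmas replaced in place by their tags.

Feature streams are grouped into blocks (lemma block, appended tag block);
n-grams never cross a block boundary. Three weightings: BINARY (presence),
TFIDF (count x idf with smoothed idf), and BINARY_TFIDF in which every
strictly positive TF-IDF weight is turned into 1.

Punctuation-only tokens carry no features.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import TruncatedSVD
from sklearn.feature_selection import chi2 as sk_chi2

from .preprocess import AnnotatedSentence, is_punctuation

LEMMA_POS_NER = "LEMMA_POS_NER"
LEMMA_NER = "LEMMA_NER"
NER_FOR_LEMMA = "NER_FOR_LEMMA"
COMBOS = (LEMMA_POS_NER, LEMMA_NER, NER_FOR_LEMMA)

BINARY = "BINARY"
TFIDF = "TFIDF"
BINARY_TFIDF = "BINARY_TFIDF"
WEIGHTINGS = (BINARY, TFIDF, BINARY_TFIDF)


@dataclass(frozen=True)
class RepresentationConfig:
    combo: str = LEMMA_NER
    ngram_max: int = 1
    weighting: str = BINARY

    def __post_init__(self) -> None:
        if self.combo not in COMBOS:
            raise ValueError(f"unknown combo {self.combo!r}")
        if self.ngram_max < 1:
            raise ValueError("ngram_max must be >= 1")
        if self.weighting not in WEIGHTINGS:
            raise ValueError(f"unknown weighting {self.weighting!r}")


def compose_feature_blocks(
    sentence: AnnotatedSentence, combo: str
) -> list[list[str]]:
    """Feature stream of a sentence as blocks (lemma block, tag block)."""
    toks = [t for t in sentence.tokens if not is_punctuation(t.surface)]
    lemmas = [t.lemma for t in toks]
    if combo == LEMMA_POS_NER:
        tagged = [t.ner if t.ner is not None else t.pos for t in toks]
        return [lemmas, tagged]
    if combo == LEMMA_NER:
        ners = [t.ner for t in toks if t.ner is not None]
        return [lemmas, ners] if ners else [lemmas]
    if combo == NER_FOR_LEMMA:
        substituted = [t.ner if t.ner is not None else t.lemma for t in toks]
        return [substituted]
    raise ValueError(f"unknown combo {combo!r}")


def compose_features(sentence: AnnotatedSentence, combo: str) -> list[str]:
    """Flat ordered feature stream (blocks concatenated)."""
    return [f for block in compose_feature_blocks(sentence, combo) for f in block]


def extract_ngrams(
    stream: Sequence[str] | Sequence[Sequence[str]], ngram_max: int
) -> Counter:
    """All contiguous 1..ngram_max-grams, joined with ``_``.

    ``stream`` may be a flat feature list (one block) or a list of blocks;
    n-grams never span a block boundary.
    """
    if ngram_max < 1 or ngram_max > 3:
        raise ValueError("ngram_max must be in {1, 2, 3}")
    if stream and not isinstance(stream[0], str):
        blocks: list[Sequence[str]] = list(stream)  # type: ignore[arg-type]
    else:
        blocks = [stream]  # type: ignore[list-item]
    features: Counter = Counter()
    for block in blocks:
        for n in range(1, ngram_max + 1):
            for i in range(len(block) - n + 1):
                features["_".join(block[i : i + n])] += 1
    return features


@dataclass
class VectorSpace:
    """Learned vocabulary + weighting, mapping feature multisets to vectors.

    Vocabulary indices are dense 0..V-1 in lexicographic feature order
    (determinism anchor for downstream tie-breaks). ``idf`` is present only
    for the TF-IDF weightings and uses smoothed idf:
    ``idf(f) = ln((1 + N) / (1 + df(f))) + 1``.
    """

    vocabulary: dict[str, int]
    idf: np.ndarray | None
    config: RepresentationConfig
    n_documents_fitted: int


def fit_vector_space(
    corpus: Sequence[Counter], config: RepresentationConfig
) -> VectorSpace:
    if len(corpus) == 0:
        raise ValueError("cannot fit a vector space on an empty corpus")
    df: Counter = Counter()
    for doc in corpus:
        df.update(set(doc))
    vocabulary = {f: i for i, f in enumerate(sorted(df))}
    idf = None
    if config.weighting in (TFIDF, BINARY_TFIDF):
        n = len(corpus)
        idf = np.empty(len(vocabulary))
        for f, i in vocabulary.items():
            idf[i] = math.log((1 + n) / (1 + df[f])) + 1.0
    return VectorSpace(
        vocabulary=vocabulary, idf=idf, config=config, n_documents_fitted=len(corpus)
    )


def vectorize(features: Counter, space: VectorSpace) -> sp.csr_matrix:
    """One sparse row vector for a feature multiset; unseen features ignored."""
    cols, vals = [], []
    for f, count in features.items():
        idx = space.vocabulary.get(f)
        if idx is None:
            continue
        if space.config.weighting == BINARY:
            w = 1.0
        else:
            w = count * float(space.idf[idx])
            if space.config.weighting == BINARY_TFIDF and w > 0:
                w = 1.0
        if w != 0.0:
            cols.append(idx)
            vals.append(w)
    return sp.csr_matrix(
        (vals, (np.zeros(len(cols), dtype=int), cols)),
        shape=(1, len(space.vocabulary)),
    )


def vectorize_corpus(corpus: Sequence[Counter], space: VectorSpace) -> sp.csr_matrix:
    if not corpus:
        return sp.csr_matrix((0, len(space.vocabulary)))
    return sp.vstack([vectorize(doc, space) for doc in corpus]).tocsr()


class SentenceVectorizer(BaseEstimator, TransformerMixin):
    """Transformer from annotated sentences to sparse feature vectors.

    Parameters
    ----------
    combo : one of LEMMA_POS_NER, LEMMA_NER, NER_FOR_LEMMA
    ngram_max : int in {1, 2, 3}; cumulative 1..ngram_max n-grams
    weighting : one of BINARY, TFIDF, BINARY_TFIDF
    """

    def __init__(self, combo: str = LEMMA_NER, ngram_max: int = 1, weighting: str = BINARY):
        self.combo = combo
        self.ngram_max = ngram_max
        self.weighting = weighting

    def _features(self, sentences: Sequence[AnnotatedSentence]) -> list[Counter]:
        return [
            extract_ngrams(compose_feature_blocks(s, self.combo), self.ngram_max)
            for s in sentences
        ]

    def fit(self, X: Sequence[AnnotatedSentence], y=None):
        config = RepresentationConfig(self.combo, self.ngram_max, self.weighting)
        self.space_ = fit_vector_space(self._features(X), config)
        self.vocabulary_ = self.space_.vocabulary
        self.n_features_out_ = len(self.vocabulary_)
        return self

    def transform(self, X: Sequence[AnnotatedSentence]) -> sp.csr_matrix:
        if not hasattr(self, "space_"):
            raise ValueError("SentenceVectorizer is not fitted")
        return vectorize_corpus(self._features(X), self.space_)


REDUCE_NONE = "NONE"
REDUCE_SVD = "SVD"
REDUCE_CHI2 = "CHI2"


@dataclass(frozen=True)
class ReducerConfig:
    method: str = REDUCE_NONE
    k: int = 0

    def __post_init__(self) -> None:
        if self.method not in (REDUCE_NONE, REDUCE_SVD, REDUCE_CHI2):
            raise ValueError(f"unknown reducer method {self.method!r}")
        if self.method != REDUCE_NONE and self.k < 1:
            raise ValueError("k must be >= 1")


class FeatureReducer(BaseEstimator, TransformerMixin):
    """Dimensionality reduction (truncated SVD) or chi-squared feature selection.

    SVD projects onto the top-k singular directions (typical k: 200, 300);
    CHI2 keeps the k features with the largest chi-squared statistic of the
    feature/class contingency table (typical k: 1000, 800, 500), leaving
    their weights untouched. CHI2 requires labels at fit time. Ties in the
    chi-squared ranking are broken by column order, which is lexicographic
    feature order when the matrix comes from a SentenceVectorizer.
    """

    def __init__(self, method: str = REDUCE_NONE, k: int = 0, random_state: int | None = 0):
        self.method = method
        self.k = k
        self.random_state = random_state

    def fit(self, X, y=None):
        ReducerConfig(self.method, self.k)  # validate
        n_rows, n_cols = X.shape
        if self.method == REDUCE_NONE:
            self.support_ = None
        elif self.method == REDUCE_SVD:
            if self.k > min(n_rows, n_cols):
                raise ValueError(
                    f"SVD k={self.k} exceeds min(rows, features) = {min(n_rows, n_cols)}"
                )
            self.svd_ = TruncatedSVD(n_components=self.k, random_state=self.random_state)
            self.svd_.fit(X)
        else:
            if y is None:
                raise ValueError("CHI2 feature selection requires labels")
            if self.k > n_cols:
                raise ValueError(f"CHI2 k={self.k} exceeds feature count {n_cols}")
            scores, _ = sk_chi2(X, y)
            scores = np.nan_to_num(scores, nan=0.0)
            # stable sort on -score keeps column (lexicographic) order on ties
            order = np.argsort(-scores, kind="stable")
            self.support_ = np.sort(order[: self.k])
            self.scores_ = scores
        return self

    def transform(self, X):
        if self.method == REDUCE_NONE:
            return X
        if self.method == REDUCE_SVD:
            return self.svd_.transform(X)
        return X[:, self.support_]
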