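"""Synthetic corpora with the statistical structure the pipeline assumes.

The generator emulates the shape of the real training data: a pool of
~2244 manual-summary sentences in which each of the six TF properties has
a small positive subset (6-15% of the pool), article sentences that mirror
the summary sentences with light paraphrase noise and planted duplicates,
and lexicons/stop-word lists in the same formats the readers consume.
Positive sentences carry property-specific planted keywords, so gold
labels are exact by construction; paraphrase noise swaps synonyms within
the filler vocabulary only and never touches planted keywords.

This is template-based generation: it reproduces class imbalance, keyword
signal, redundancy and provenance structure — not biomedical prose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .corpus_io import (
    PROPERTIES,
    LabeledSentence,
    Lexicon,
    SourceSentence,
    write_article_collection,
    write_labeled_summaries,
)

#: Default per-property positive rates, mirroring the observed class
#: balance of the real training pool (6-15% positives per property).
DEFAULT_POSITIVE_RATES: dict[str, float] = {
    "ACT": 0.12,
    "DOM": 0.15,
    "EVO": 0.07,
    "RP": 0.12,
    "SITE": 0.06,
    "TU": 0.07,
}

#: Disjoint planted keyword vocabularies, one per property. Their lemmas
#: are pairwise distinct so feature streams keep the signal separable.
PROPERTY_KEYWORDS: dict[str, tuple[str, ...]] = {
    "ACT": ("effector", "inducer", "allosteric", "conformational", "autoregulation"),
    "DOM": ("helix-turn-helix", "domain", "amino-terminal", "fold", "linker"),
    "EVO": ("family", "ortholog", "paralog", "phylogenetic", "ancestral"),
    "RP": ("metabolism", "virulence", "biofilm", "chemotaxis", "osmotic"),
    "SITE": ("palindromic", "dyad", "consensus", "box", "spacer"),
    "TU": ("operon", "monocistronic", "polycistronic", "cotranscribed", "autogenous"),
}

REGULATION_VERBS = ("regulates", "activates", "represses", "controls", "modulates")

#: Synonym groups for paraphrase noise; swapping stays within a group.
SYNONYM_GROUPS: tuple[tuple[str, ...], ...] = (
    ("shows", "exhibits"),
    ("cells", "bacteria"),
    ("analysis", "study"),
    ("observed", "detected"),
    ("expression", "transcription"),
    ("important", "essential"),
)

FILLER_WORDS = (
    "protein",
    "gene",
    "level",
    "activity",
    "growth",
    "condition",
    "response",
    "region",
    "system",
    "role",
    "function",
    "target",
    "presence",
    "mechanism",
    "product",
)

DEFAULT_STOPWORDS = frozenset(
    {
        "the", "of", "a", "an", "in", "to", "is", "are", "was", "were",
        "for", "and", "or", "by", "with", "that", "this", "its", "it",
        "on", "at", "as", "be",
    }
)


@dataclass(frozen=True)
class CorpusSpec:
    """Knobs of the synthetic corpus.

    ``positive_rates`` gives the fraction of the sentence pool that is
    positive for each property (counts use the floor convention);
    ``keyword_injection_rate`` is the probability that a positive sentence
    contains its property's planted keywords; ``noise_rate`` the
    probability that a negative sentence contains a decoy keyword from a
    random property; ``duplicate_rate`` the fraction of article sentences
    that get a planted duplicate or near-duplicate.
    """

    n_tfs: int = 12
    total_sentences: int = 2244
    positive_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_POSITIVE_RATES)
    )
    keyword_injection_rate: float = 1.0
    noise_rate: float = 0.05
    duplicate_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name, rate in [
            ("keyword_injection_rate", self.keyword_injection_rate),
            ("noise_rate", self.noise_rate),
            ("duplicate_rate", self.duplicate_rate),
        ]:
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        unknown = set(self.positive_rates) - set(PROPERTIES)
        if unknown:
            raise ValueError(f"unknown properties in positive_rates: {sorted(unknown)}")
        if self.n_tfs < 1 or self.total_sentences < 1:
            raise ValueError("n_tfs and total_sentences must be >= 1")
        total_rate = sum(self.positive_rates.values())
        if total_rate > 1:
            raise ValueError("positive rates sum to more than 1")
        for prop, rate in self.positive_rates.items():
            if rate > 0 and math.floor(rate * self.total_sentences) == 0:
                raise ValueError(
                    f"inconsistent spec: rate {rate} for {prop} yields zero "
                    f"positives at total_sentences={self.total_sentences}"
                )

    def positive_counts(self) -> dict[str, int]:
        """Exact per-property positive counts: floor(rate * total)."""
        return {
            p: math.floor(self.positive_rates.get(p, 0.0) * self.total_sentences)
            for p in PROPERTIES
        }


@dataclass
class SyntheticCorpus:
    spec: CorpusSpec
    tf_names: list[str]
    summaries: list[LabeledSentence]
    articles: list[SourceSentence]
    gold_labels: list[frozenset[str]]  # parallel to ``articles``
    lexicon: Lexicon
    stopwords: set[str]
    metadata: dict


def _make_lexicon(tf_names: list[str]) -> Lexicon:
    lex = Lexicon()
    for tf in tf_names:
        lex.add(tf, "ACTTF", case_sensitive=True)
    for verb in REGULATION_VERBS:
        lex.add(verb, "ACTREG", case_sensitive=False)
    for prop, keywords in PROPERTY_KEYWORDS.items():
        for kw in keywords:
            lex.add(kw, f"{prop}TERM", case_sensitive=False)
    return lex


def _filler(rng: np.random.Generator, k: int) -> list[str]:
    pool = list(FILLER_WORDS) + [g[0] for g in SYNONYM_GROUPS]
    return [pool[i] for i in rng.integers(0, len(pool), size=k)]


def _sentence_tokens(
    rng: np.random.Generator,
    tf: str,
    prop: str | None,
    spec: CorpusSpec,
) -> list[str]:
    verb = REGULATION_VERBS[rng.integers(0, len(REGULATION_VERBS))]
    tokens = [tf, verb] + _filler(rng, 2)
    if prop is not None:
        if rng.random() < spec.keyword_injection_rate:
            kws = PROPERTY_KEYWORDS[prop]
            picks = rng.choice(len(kws), size=2, replace=False)
            tokens += [kws[picks[0]]] + _filler(rng, 1) + [kws[picks[1]]]
        tokens += _filler(rng, 2)
    else:
        tokens += _filler(rng, 3)
        if rng.random() < spec.noise_rate:
            decoy_prop = PROPERTIES[rng.integers(0, len(PROPERTIES))]
            kws = PROPERTY_KEYWORDS[decoy_prop]
            tokens.append(kws[rng.integers(0, len(kws))])
        tokens += _filler(rng, 1)
    return tokens


def _paraphrase(rng: np.random.Generator, tokens: list[str]) -> list[str]:
    """Swap filler synonyms with probability 1/2; keywords never change."""
    groups = {w: g for g in SYNONYM_GROUPS for w in g}
    out = []
    for tok in tokens:
        group = groups.get(tok)
        if group is not None and rng.random() < 0.5:
            choices = [w for w in group if w != tok]
            tok = choices[rng.integers(0, len(choices))]
        out.append(tok)
    return out


def make_corpus(spec: CorpusSpec) -> SyntheticCorpus:
    """Generate lexicons, labeled summaries, articles and gold labels.

    Deterministic: the same spec (including seed) yields an identical
    corpus. Per-property positive counts equal floor(rate * total) exactly;
    each positive sentence is labeled with exactly one property.
    """
    rng = np.random.default_rng(spec.seed)
    tf_names = [f"Reg{chr(65 + i % 26)}{'' if i < 26 else i // 26}" for i in range(spec.n_tfs)]
    lexicon = _make_lexicon(tf_names)
    n_pos = spec.positive_counts()

    # slot assignment: property label (or None) per sentence, then shuffled
    slots: list[str | None] = []
    for prop in PROPERTIES:
        slots += [prop] * n_pos[prop]
    slots += [None] * (spec.total_sentences - len(slots))
    order = rng.permutation(len(slots))
    slots = [slots[i] for i in order]

    tf_of = [tf_names[int(i)] for i in rng.integers(0, spec.n_tfs, size=len(slots))]

    summaries: list[LabeledSentence] = []
    doc_counters: dict[str, int] = {}
    summary_pmids = {tf: str(100 + i) for i, tf in enumerate(tf_names)}
    token_lists: list[list[str]] = []
    for prop, tf in zip(slots, tf_of):
        tokens = _sentence_tokens(rng, tf, prop, spec)
        token_lists.append(tokens)
        text = " ".join(tokens) + "."
        idx = doc_counters.get(tf, 0)
        doc_counters[tf] = idx + 1
        summaries.append(
            LabeledSentence(
                sentence=SourceSentence(text=text, pmid=summary_pmids[tf], doc_index=idx),
                labels=frozenset({prop}) if prop else frozenset(),
                tf_name=tf,
            )
        )

    # article collection mirrors the summary sentences with paraphrase noise
    # and planted duplicates; 3 article PMIDs per TF
    article_pmids = {
        tf: [str(1000 + 10 * i + j) for j in range(3)] for i, tf in enumerate(tf_names)
    }
    articles: list[SourceSentence] = []
    gold: list[frozenset[str]] = []
    art_counters: dict[str, int] = {}

    def add_article_sentence(tokens: list[str], tf: str, labels: frozenset[str]) -> None:
        pmids = article_pmids[tf]
        pmid = pmids[int(rng.integers(0, len(pmids)))]
        idx = art_counters.get(pmid, 0)
        art_counters[pmid] = idx + 1
        articles.append(
            SourceSentence(text=" ".join(tokens) + ".", pmid=pmid, doc_index=idx)
        )
        gold.append(labels)

    for ls, tokens in zip(summaries, token_lists):
        para = _paraphrase(rng, tokens)
        add_article_sentence(para, ls.tf_name, ls.labels)
        if rng.random() < spec.duplicate_rate:
            dup = _paraphrase(rng, para) if rng.random() < 0.5 else list(para)
            add_article_sentence(dup, ls.tf_name, ls.labels)

    metadata = {
        "positive_counts": n_pos,
        "count_convention": "floor(rate * total_sentences)",
        "n_article_sentences": len(articles),
        "seed": spec.seed,
    }
    return SyntheticCorpus(
        spec=spec,
        tf_names=tf_names,
        summaries=summaries,
        articles=articles,
        gold_labels=gold,
        lexicon=lexicon,
        stopwords=set(DEFAULT_STOPWORDS),
        metadata=metadata,
    )


def write_corpus(corpus: SyntheticCorpus, directory: str | Path) -> dict[str, Path]:
    """Write the corpus in the formats the readers consume.

    Returns the paths written: articles.jsonl, summaries.txt, stopwords.txt
    and one lexicon file per NER tag under lexicons/.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["articles"] = directory / "articles.jsonl"
    write_article_collection(corpus.articles, paths["articles"], format="jsonl")

    paths["summaries"] = directory / "summaries.txt"
    write_labeled_summaries(corpus.summaries, paths["summaries"])

    paths["stopwords"] = directory / "stopwords.txt"
    paths["stopwords"].write_text("\n".join(sorted(corpus.stopwords)) + "\n")

    lexdir = directory / "lexicons"
    lexdir.mkdir(exist_ok=True)
    by_tag: dict[str, list[str]] = {}
    for term, tag in corpus.lexicon.terms():
        by_tag.setdefault(tag, []).append(term)
    for tag, terms in by_tag.items():
        p = lexdir / f"{tag}.txt"
        p.write_text("\n".join(sorted(terms)) + "\n")
        paths[f"lexicon:{tag}"] = p
    return paths


# --- evaluation-pair construction -----------------------------------------

_EVAL_VOCAB_SIZE = 200


def _eval_vocab() -> list[str]:
    # distinct content words, none of which are stop words
    return [f"term{i:03d}" for i in range(_EVAL_VOCAB_SIZE)]


def make_eval_pair(
    overlap_fraction: float, n_manual_words: int = 40, seed: int = 0
) -> tuple[str, str, float]:
    """Construct (manual, automatic) texts with a designed ROUGE-1 recall.

    The manual text holds ``n_manual_words`` distinct content words (plus
    stop words, which the evaluation discards); the automatic text shares
    exactly ``round(overlap_fraction * n_manual_words)`` of them and pads
    with disjoint words. Returns the expected stop-word-free clipped
    recall for assertion.
    """
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    vocab = _eval_vocab()
    if 2 * n_manual_words > len(vocab):
        raise ValueError("n_manual_words too large for the construction vocabulary")
    picked = rng.permutation(len(vocab))
    manual_words = [vocab[i] for i in picked[:n_manual_words]]
    k = round(overlap_fraction * n_manual_words)
    shared = manual_words[:k]
    disjoint = [vocab[i] for i in picked[n_manual_words : 2 * n_manual_words - k]]
    auto_words = shared + disjoint

    stops = sorted(DEFAULT_STOPWORDS)

    def weave(words: list[str]) -> str:
        out = []
        for i, w in enumerate(words):
            out.append(w)
            if i % 3 == 2:
                out.append(stops[i % len(stops)])
        return " ".join(out) + "."

    expected = k / n_manual_words
    return weave(manual_words), weave(auto_words), expected
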