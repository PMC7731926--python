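"""Evaluation of extracted knowledge.

ROUGE-1 recall/precision without stop words compares an automatic summary
against the manual reference: recall is the overlapped word count divided
by the manual summary's word count, precision divides by the automatic
summary's. Overlap uses clipped multiset counts by default (sum over word
types of min(count in manual, count in auto)); a unique-word-type mode is
available behind ``mode="types"``.

Property coverage compares the set of properties present in a manual
summary with the sections of the automatic one; the coverage distribution
reports how many TFs gained at least one property absent from their manual
summary. Curator evaluations (per-sentence relevance judgements) aggregate
to per-property correct-classification rates averaged over evaluators.

All printed percentages round half away from zero to integers.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .corpus_io import PROPERTIES, LabeledSentence
from .summarize import Summary

_WORD_RE = re.compile(r"[a-z0-9]+(?:[-'][a-z0-9]+)*")


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (65 from 64.5)."""
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RougeReport:
    overlap_count: int
    manual_word_count: int
    auto_word_count: int
    recall: float
    precision: float


def _rouge_tokens(text: str, stopwords: set[str]) -> Counter:
    words = _WORD_RE.findall(text.lower())
    return Counter(w for w in words if w not in stopwords)


def rouge1(
    manual_text: str,
    auto_text: str,
    stopwords: set[str] | None = None,
    mode: str = "clipped",
) -> RougeReport:
    """Stop-word-free unigram overlap between manual and automatic summaries."""
    if mode not in ("clipped", "types"):
        raise ValueError(f"unknown mode {mode!r}")
    stopwords = stopwords or set()
    manual = _rouge_tokens(manual_text, stopwords)
    auto = _rouge_tokens(auto_text, stopwords)
    if mode == "types":
        manual = Counter(set(manual))
        auto = Counter(set(auto))
    m_count = sum(manual.values())
    a_count = sum(auto.values())
    if m_count == 0:
        raise ValueError("manual summary is empty after stop-word removal")
    if a_count == 0:
        raise ValueError("automatic summary is empty after stop-word removal")
    overlap = sum(min(c, auto[w]) for w, c in manual.items())
    return RougeReport(
        overlap_count=overlap,
        manual_word_count=m_count,
        auto_word_count=a_count,
        recall=overlap / m_count,
        precision=overlap / a_count,
    )


@dataclass(frozen=True)
class CoverageEntry:
    tf_name: str
    manual_properties: frozenset[str]
    auto_properties: frozenset[str]

    @property
    def additional(self) -> int:
        return len(self.auto_properties - self.manual_properties)

    @property
    def missing(self) -> int:
        return len(self.manual_properties - self.auto_properties)


def property_coverage(manual: Sequence[LabeledSentence], auto: Summary) -> CoverageEntry:
    """Compare properties covered manually vs automatically for one TF."""
    tf_names = {ls.tf_name for ls in manual}
    if tf_names and tf_names != {auto.tf_name}:
        raise ValueError(
            f"TF mismatch: manual summary is for {sorted(tf_names)}, automatic for {auto.tf_name}"
        )
    manual_props = frozenset().union(*(ls.labels for ls in manual)) if manual else frozenset()
    auto_props = auto.section_properties(visible_only=True)
    return CoverageEntry(auto.tf_name, manual_props, auto_props)


@dataclass(frozen=True)
class CoverageDistribution:
    histogram: dict[int, int]  # additional-property count -> number of TFs
    n_tfs: int
    pct_with_additional: int  # % of TFs with >= 1 additional property


def coverage_distribution(
    entries: Sequence[CoverageEntry] | Sequence[int],
) -> CoverageDistribution:
    """Histogram of additional-property counts over TFs.

    Accepts CoverageEntry objects or bare additional-property counts.
    """
    if len(entries) == 0:
        raise ValueError("no coverage entries")
    counts = [
        e.additional if isinstance(e, CoverageEntry) else int(e) for e in entries
    ]
    hist = {k: 0 for k in range(7)}
    for c in counts:
        hist[c] = hist.get(c, 0) + 1
    n = len(counts)
    pct = round_half_away(100 * sum(1 for c in counts if c >= 1) / n)
    return CoverageDistribution(histogram=hist, n_tfs=n, pct_with_additional=pct)


@dataclass(frozen=True)
class CuratorEvaluation:
    """One curator's judgement of one automatic-summary sentence."""

    sentence_id: str
    property: str
    relevant_for_property: bool
    relevant_for_tf: bool
    evaluator: str

    def __post_init__(self) -> None:
        if self.property not in PROPERTIES:
            raise ValueError(f"unknown property {self.property!r}")


@dataclass(frozen=True)
class CuratorReport:
    per_property_pct: dict[str, float]  # % correctly classified, evaluator-averaged
    pct_relevant_overall: float  # % relevant for the TF regardless of property
    macro_average_pct: int  # unweighted mean over properties, integer-rounded


def curator_report(evaluations: Sequence[CuratorEvaluation]) -> CuratorReport:
    """Aggregate per-sentence curator judgements.

    Per property: the percentage of sentences judged relevant for that
    property, computed per evaluator and averaged over evaluators.
    Properties with no evaluated sentence are omitted with a warning. The
    macro average is the unweighted mean of the per-property percentages,
    rounded half away from zero.
    """
    if not evaluations:
        raise ValueError("no curator evaluations")
    evaluators = sorted({e.evaluator for e in evaluations})
    per_property: dict[str, float] = {}
    for prop in PROPERTIES:
        rates = []
        for ev in evaluators:
            subset = [
                e for e in evaluations if e.property == prop and e.evaluator == ev
            ]
            if subset:
                rates.append(
                    100 * sum(e.relevant_for_property for e in subset) / len(subset)
                )
        if rates:
            per_property[prop] = sum(rates) / len(rates)
        else:
            warnings.warn(f"no evaluated sentences for property {prop}", stacklevel=2)
    overall_rates = []
    for ev in evaluators:
        subset = [e for e in evaluations if e.evaluator == ev]
        overall_rates.append(100 * sum(e.relevant_for_tf for e in subset) / len(subset))
    macro = sum(per_property.values()) / len(per_property)
    return CuratorReport(
        per_property_pct=per_property,
        pct_relevant_overall=sum(overall_rates) / len(overall_rates),
        macro_average_pct=round_half_away(macro),
    )


def macro_average_pct(rates: Iterable[float]) -> int:
    """Unweighted mean of per-property percentages, rounded half away from zero."""
    rates = list(rates)
    if not rates:
        raise ValueError("no rates")
    return round_half_away(sum(rates) / len(rates))
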