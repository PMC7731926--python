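"""Reading and writing of on-disk artifacts.

Article collections (JSONL or TSV, one sentence per record with its PubMed
ID), property-tagged manual summaries, term lexicons for dictionary NER and
stop-word lists. All files are UTF-8.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

#: The six transcription-factor property labels, in canonical section order:
#: transcriptional activity, structural domains, evolutionary properties,
#: regulated processes, binding sites, transcription-unit organization.
PROPERTIES: tuple[str, ...] = ("ACT", "DOM", "EVO", "RP", "SITE", "TU")

_PMID_RE = re.compile(r"^\d{1,9}$")


@dataclass(frozen=True)
class SourceSentence:
    """One sentence of an article, with provenance.

    ``doc_index`` is the ordinal position of the sentence within its article
    (0-based), so ``(pmid, doc_index)`` identifies a sentence uniquely within
    a collection.
    """

    text: str
    pmid: str
    doc_index: int

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError("sentence text is empty")
        if not _PMID_RE.match(self.pmid):
            raise ValueError(f"invalid PubMed ID {self.pmid!r} (expected 1-9 digits)")
        if self.doc_index < 0:
            raise ValueError("doc_index must be >= 0")


@dataclass(frozen=True)
class LabeledSentence:
    """A manual-summary sentence with its set of property labels.

    An empty label set marks a negative example for all six properties.
    Sentences are multi-label: each property classifier treats the sentence
    independently.
    """

    sentence: SourceSentence
    labels: frozenset[str]
    tf_name: str

    def __post_init__(self) -> None:
        unknown = set(self.labels) - set(PROPERTIES)
        if unknown:
            raise ValueError(f"unknown property labels: {sorted(unknown)}")


class Lexicon:
    """Term -> NER tag mapping for dictionary-based entity tagging.

    Entries are added with a per-entry case policy: entity-name entries
    (TF, gene, TU names) are matched exact-case to protect short gene
    symbols; descriptive-term entries are matched case-insensitively.
    Multiword terms are stored as token tuples and matched leftmost-longest
    by the tagger.
    """

    def __init__(self) -> None:
        # token-tuple -> tag, keyed separately by case policy
        self._exact: dict[tuple[str, ...], str] = {}
        self._folded: dict[tuple[str, ...], str] = {}

    def add(self, term: str, tag: str, case_sensitive: bool = True) -> None:
        tokens = tuple(term.split())
        if not tokens:
            raise ValueError("empty lexicon term")
        table = self._exact if case_sensitive else self._folded
        key = tokens if case_sensitive else tuple(t.lower() for t in tokens)
        existing = table.get(key)
        if existing is not None and existing != tag:
            raise ValueError(
                f"term {term!r} already mapped to tag {existing}, cannot remap to {tag}"
            )
        # a term must not map to two tags across case policies either
        other = self._folded if case_sensitive else self._exact
        for k, v in other.items():
            if tuple(t.lower() for t in tokens) == tuple(t.lower() for t in k) and v != tag:
                raise ValueError(
                    f"term {term!r} conflicts with existing entry {' '.join(k)!r} -> {v}"
                )
        table[key] = tag

    def lookup(self, tokens: Sequence[str]) -> str | None:
        """Tag for an exact token-sequence match, or None."""
        tag = self._exact.get(tuple(tokens))
        if tag is not None:
            return tag
        return self._folded.get(tuple(t.lower() for t in tokens))

    @property
    def max_term_length(self) -> int:
        lengths = [len(k) for k in self._exact] + [len(k) for k in self._folded]
        return max(lengths, default=0)

    def __len__(self) -> int:
        return len(self._exact) + len(self._folded)

    def terms(self) -> list[tuple[str, str]]:
        """All (term, tag) pairs, exact-case entries first."""
        out = [(" ".join(k), v) for k, v in self._exact.items()]
        out += [(" ".join(k), v) for k, v in self._folded.items()]
        return out


def read_article_collection(path: str | Path, format: str = "jsonl") -> list[SourceSentence]:
    """Read a sentence-segmented article collection.

    JSONL records carry ``{"pmid": ..., "text": ...}``; the TSV dialect is
    ``pmid<TAB>text``. ``doc_index`` is assigned per PMID in file order,
    starting at 0.
    """
    path = Path(path)
    if format not in ("jsonl", "tsv"):
        raise ValueError(f"unknown format {format!r} (expected 'jsonl' or 'tsv')")
    counters: dict[str, int] = {}
    out: list[SourceSentence] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if format == "jsonl":
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed JSON record: {exc}") from exc
                if not isinstance(rec, dict) or "pmid" not in rec:
                    raise ValueError(f"{path}:{lineno}: record missing 'pmid' field")
                if "text" not in rec:
                    raise ValueError(f"{path}:{lineno}: record missing 'text' field")
                pmid, text = str(rec["pmid"]), str(rec["text"])
            else:
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: expected pmid<TAB>text")
                pmid, text = parts
            idx = counters.get(pmid, 0)
            try:
                sent = SourceSentence(text=text.strip(), pmid=pmid, doc_index=idx)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            counters[pmid] = idx + 1
            out.append(sent)
    return out


def write_article_collection(
    sentences: Iterable[SourceSentence], path: str | Path, format: str = "jsonl"
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for s in sentences:
            if format == "jsonl":
                fh.write(json.dumps({"pmid": s.pmid, "text": s.text}) + "\n")
            elif format == "tsv":
                fh.write(f"{s.pmid}\t{s.text}\n")
            else:
                raise ValueError(f"unknown format {format!r}")


# --- property-tagged manual summaries ------------------------------------

_TAG_RE = re.compile(r"<(/?)([A-Za-z]+)>")
_SUMMARY_HEADER_RE = re.compile(r"^#TF:\s*(\S.*?)\s*(?:\|\s*pmid=(\d{1,9}))?\s*$")


def _parse_tagged_text(text: str, where: str) -> list[tuple[str, frozenset[str]]]:
    """Split tagged running text into (fragment, active-label-set) pieces.

    Tags may nest or overlap; a fragment carries the union of all labels
    open at that point.
    """
    pieces: list[tuple[str, frozenset[str]]] = []
    open_tags: list[str] = []
    pos = 0
    for m in _TAG_RE.finditer(text):
        frag = text[pos : m.start()]
        if frag:
            pieces.append((frag, frozenset(open_tags)))
        closing, name = m.group(1), m.group(2)
        if name not in PROPERTIES:
            raise ValueError(f"{where}: unknown property tag <{name}>")
        if closing:
            if name not in open_tags:
                raise ValueError(f"{where}: unbalanced closing tag </{name}>")
            open_tags.remove(name)
        else:
            open_tags.append(name)
        pos = m.end()
    if open_tags:
        raise ValueError(f"{where}: unclosed tags {open_tags}")
    tail = text[pos:]
    if tail:
        pieces.append((tail, frozenset()))
    return pieces


def read_labeled_summaries(path: str | Path) -> list[LabeledSentence]:
    """Parse a file of property-tagged manual TF summaries.

    The file holds one summary per TF, introduced by a ``#TF: Name`` header
    (optionally ``#TF: Name | pmid=123``). Sentences wrapped in property
    tags like ``<ACT>...</ACT>`` receive that label; a sentence overlapped
    by several tags receives their union; untagged sentences get an empty
    label set.
    """
    from .preprocess import segment  # deferred: avoid import cycle at module load

    path = Path(path)
    out: list[LabeledSentence] = []
    current_tf: str | None = None
    current_pmid = "1"
    body_lines: list[str] = []

    def flush() -> None:
        nonlocal body_lines
        if current_tf is None:
            return
        text = " ".join(body_lines).strip()
        body_lines = []
        if not text:
            return
        pieces = _parse_tagged_text(text, f"{path} (summary of {current_tf})")
        # flatten to plain text with per-character label sets
        plain: list[str] = []
        char_labels: list[frozenset[str]] = []
        for frag, labels in pieces:
            plain.append(frag)
            char_labels.extend([labels] * len(frag))
        full = "".join(plain)
        offset = 0
        doc_idx = 0
        for sent in segment(full):
            start = full.index(sent, offset)
            end = start + len(sent)
            offset = end
            labels = frozenset().union(*char_labels[start:end]) if end > start else frozenset()
            out.append(
                LabeledSentence(
                    sentence=SourceSentence(text=sent, pmid=current_pmid, doc_index=doc_idx),
                    labels=labels,
                    tf_name=current_tf,
                )
            )
            doc_idx += 1

    with path.open(encoding="utf-8") as fh:
        for line in fh:
            m = _SUMMARY_HEADER_RE.match(line)
            if m:
                flush()
                current_tf = m.group(1)
                current_pmid = m.group(2) or "1"
            else:
                body_lines.append(line.rstrip("\n"))
    flush()
    if current_tf is None and out == []:
        # file had no headers at all -> treat whole file as one unnamed summary?
        # Explicit is better: require headers.
        raise ValueError(f"{path}: no '#TF:' summary headers found")
    return out


def write_labeled_summaries(sentences: Sequence[LabeledSentence], path: str | Path) -> None:
    """Write labeled sentences back to the tagged-summary format.

    Groups by TF in first-seen order; each sentence is wrapped in its sorted
    labels so that re-reading reproduces the labels exactly.
    """
    path = Path(path)
    by_tf: dict[str, list[LabeledSentence]] = {}
    for ls in sentences:
        by_tf.setdefault(ls.tf_name, []).append(ls)
    with path.open("w", encoding="utf-8") as fh:
        for tf, group in by_tf.items():
            pmid = group[0].sentence.pmid
            fh.write(f"#TF: {tf} | pmid={pmid}\n")
            for ls in group:
                text = ls.sentence.text
                for label in sorted(ls.labels, reverse=True):
                    text = f"<{label}>{text}</{label}>"
                fh.write(text + "\n")
            fh.write("\n")


def read_lexicons(
    spec: Mapping[str, Sequence[str | Path]],
    case_insensitive_tags: Iterable[str] = (),
) -> Lexicon:
    """Merge one-term-per-line lexicon files into a single Lexicon.

    ``spec`` maps an NER tag to the files holding its terms. Tags listed in
    ``case_insensitive_tags`` (descriptive-term classes such as verbs of
    regulation) match case-insensitively; all others exact-case. A term
    appearing under two different tags is an error; duplicates under the
    same tag are merged silently.
    """
    folded = set(case_insensitive_tags)
    lex = Lexicon()
    for tag, paths in spec.items():
        for p in paths:
            p = Path(p)
            with p.open(encoding="utf-8") as fh:
                for line in fh:
                    term = line.strip()
                    if not term:
                        continue
                    lex.add(term, tag, case_sensitive=tag not in folded)
    return lex


def read_stopwords(path: str | Path) -> set[str]:
    """Read a one-term-per-line stop-word list; lookup is case-insensitive."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stop-word file not found: {path}")
    with path.open(encoding="utf-8") as fh:
        words = {line.strip().lower() for line in fh if line.strip()}
    if not words:
        warnings.warn(f"stop-word file {path} is empty", stacklevel=2)
    return words
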