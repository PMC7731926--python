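"""Sentence segmentation, tokenization and annotation.

Each token receives a lemma, a POS tag and optionally one NER tag from a
dictionary lookup (leftmost-longest match) or the DNA-motif pattern. The
lemma/POS engine is pluggable: any deterministic callable mapping a token
list to a same-length list of ``(lemma, pos)`` pairs can replace the naive
built-in fallback.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Sequence

from .corpus_io import Lexicon, SourceSentence

TaggerFn = Callable[[Sequence[str]], list[tuple[str, str]]]

#: NER tag for tokens matching the DNA-motif pattern.
DNA_MOTIF_TAG = "DNAMOTIF"

#: Default motif rule: a maximal run of >= 6 uppercase nucleotide-alphabet
#: characters, including the IUPAC degeneracy letters W,S,R,Y, N and gaps.
DNA_MOTIF_RE = re.compile(r"^[ACGTNWSRY\-]{6,}$")

_PUNCT = ".,;:!?()[]{}\"'"


@dataclass(frozen=True)
class TokenAnnotation:
    """One token with its normalized form, grammatical category and NER tag."""

    surface: str
    lemma: str
    pos: str
    ner: str | None = None


@dataclass(frozen=True)
class AnnotatedSentence:
    """A source sentence with its ordered token annotations."""

    source: SourceSentence
    tokens: tuple[TokenAnnotation, ...]


# --- segmentation ----------------------------------------------------------

# Abbreviations after which a period does not end the sentence. Single
# capital letters ("E." in "E. coli") are guarded by a separate rule.
_ABBREVIATIONS = frozenset(
    {
        "fig",
        "figs",
        "eq",
        "eqs",
        "ref",
        "refs",
        "al",
        "et",
        "e.g",
        "i.e",
        "vs",
        "cf",
        "sp",
        "spp",
        "subsp",
        "str",
        "approx",
        "no",
    }
)

_BOUNDARY_RE = re.compile(r"([.!?])(\s+)")


def segment(text: str) -> list[str]:
    """Split running text into sentences, keeping terminal punctuation.

    Rule-based: a sentence ends at ``.``, ``!`` or ``?`` followed by
    whitespace, unless the period belongs to a known abbreviation or a
    single capital letter (genus initials such as "E. coli").
    """
    if not text.strip():
        return []
    sentences: list[str] = []
    start = 0
    for m in _BOUNDARY_RE.finditer(text):
        if m.group(1) == ".":
            prev = text[start : m.start()].rstrip()
            last_word = prev.split()[-1] if prev.split() else ""
            bare = last_word.rstrip(".").lower()
            if len(last_word) == 1 and last_word.isupper():
                continue  # genus initial: "E. coli"
            if bare in _ABBREVIATIONS or last_word.lower() in _ABBREVIATIONS:
                continue
        candidate = text[start : m.end(1)].strip()
        if candidate:
            sentences.append(candidate)
        start = m.end()
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


def tokenize(sentence: str) -> list[str]:
    """Whitespace tokenization with punctuation detached at token edges.

    Hyphenated biomedical compounds ("toxin-antitoxin") stay single tokens;
    a sentence-terminal period becomes its own token.
    """
    tokens: list[str] = []
    for chunk in sentence.split():
        left: list[str] = []
        right: list[str] = []
        while chunk and chunk[0] in _PUNCT:
            left.append(chunk[0])
            chunk = chunk[1:]
        while chunk and chunk[-1] in _PUNCT:
            right.append(chunk[-1])
            chunk = chunk[:-1]
        tokens.extend(left)
        if chunk:
            tokens.append(chunk)
        tokens.extend(reversed(right))
    return tokens


def is_punctuation(token: str) -> bool:
    return all(c in _PUNCT for c in token)


# --- fallback lemma/POS tagger ---------------------------------------------

_CLOSED_CLASS = {
    "the": "DT",
    "a": "DT",
    "an": "DT",
    "this": "DT",
    "that": "DT",
    "these": "DT",
    "those": "DT",
    "of": "IN",
    "in": "IN",
    "at": "IN",
    "on": "IN",
    "by": "IN",
    "for": "IN",
    "with": "IN",
    "from": "IN",
    "under": "IN",
    "during": "IN",
    "between": "IN",
    "within": "IN",
    "to": "TO",
    "and": "CC",
    "or": "CC",
    "but": "CC",
    "is": "VBZ",
    "are": "VBP",
    "was": "VBD",
    "were": "VBD",
    "be": "VB",
    "been": "VBN",
    "it": "PRP",
    "its": "PRP$",
    "not": "RB",
    "also": "RB",
    "when": "WRB",
    "which": "WDT",
}

# Stems with these endings are treated as verbs when carrying -s/-ed/-ing.
_VERB_STEM_SUFFIXES = ("ate", "ize", "ify", "ess", "uce", "ind", "olve", "ribe", "ear")


def _strip_lemma(word: str) -> str:
    w = word.lower()
    if len(w) > 4 and w.endswith("ies"):
        return w[:-3] + "y"
    if len(w) > 4 and w.endswith("ing"):
        stem = w[:-3]
        if stem.endswith(("at", "iz", "if", "uc", "olv", "rib")):
            return stem + "e"
        return stem
    if len(w) > 3 and w.endswith("ed"):
        if w.endswith(("ated", "ized", "ified", "uced", "olved", "ribed")):
            return w[:-1]
        return w[:-2]
    if len(w) > 3 and w.endswith("s") and not w.endswith(("ss", "us", "is")):
        return w[:-1]
    return w


def fallback_tagger(tokens: Sequence[str]) -> list[tuple[str, str]]:
    """Naive deterministic lemma/POS provider.

    Lemma: lowercased surface with plural/verbal suffix stripping. POS: a
    small closed-class table, then suffix heuristics (e.g. "-ates" -> VBZ),
    defaulting to NN. A full lemmatizer/POS engine can be plugged in via
    the tagger contract instead.
    """
    out: list[tuple[str, str]] = []
    for tok in tokens:
        low = tok.lower()
        lemma = _strip_lemma(tok)
        if is_punctuation(tok):
            out.append((tok, "."))
            continue
        if low in _CLOSED_CLASS:
            out.append((lemma, _CLOSED_CLASS[low]))
            continue
        if re.fullmatch(r"[\d.,%]+", tok):
            out.append((lemma, "CD"))
            continue
        if low.endswith("ing") and len(low) > 4:
            pos = "VBG"
        elif low.endswith("ed") and len(low) > 3:
            pos = "VBN"
        elif low.endswith("ly") and len(low) > 3:
            pos = "RB"
        elif (
            low.endswith("s")
            and not low.endswith(("ss", "us", "is"))
            and lemma.endswith(_VERB_STEM_SUFFIXES)
        ):
            pos = "VBZ"
        elif low.endswith("s") and not low.endswith(("ss", "us", "is")):
            pos = "NNS"
        else:
            pos = "NN"
        out.append((lemma, pos))
    return out


def make_dictionary_tagger(table: dict[str, tuple[str, str]]) -> TaggerFn:
    """Build a tagger from an explicit surface -> (lemma, pos) table.

    Tokens absent from the table fall back to the naive tagger. Useful to
    plug in gold annotations or the output of an external engine.
    """

    def tagger(tokens: Sequence[str]) -> list[tuple[str, str]]:
        out = []
        for tok, fallback in zip(tokens, fallback_tagger(tokens)):
            out.append(table.get(tok, fallback))
        return out

    return tagger


def annotate_linguistic(
    tokens: Sequence[str], tagger: TaggerFn = fallback_tagger
) -> list[tuple[str, str]]:
    """Apply the lemma/POS tagger, enforcing the one-pair-per-token contract."""
    result = tagger(tokens)
    if len(result) != len(tokens):
        raise ValueError(
            f"tagger returned {len(result)} annotations for {len(tokens)} tokens"
        )
    for lemma, _pos in result:
        if not lemma:
            raise ValueError("tagger produced an empty lemma")
    return list(result)


def annotate_ner(tokens: Sequence[str], lexicon: Lexicon) -> list[str | None]:
    """Dictionary NER with leftmost-longest matching.

    Scanning left to right, at each position the longest lexicon entry
    starting there wins; all tokens of a multiword match carry its tag and
    matched spans never overlap.
    """
    n = len(tokens)
    tags: list[str | None] = [None] * n
    max_len = lexicon.max_term_length
    i = 0
    while i < n:
        matched = 0
        matched_tag = None
        for length in range(min(max_len, n - i), 0, -1):
            tag = lexicon.lookup(tokens[i : i + length])
            if tag is not None:
                matched, matched_tag = length, tag
                break
        if matched:
            for j in range(i, i + matched):
                tags[j] = matched_tag
            i += matched
        else:
            i += 1
    return tags


def tag_dna_motifs(tokens: Sequence[str]) -> list[bool]:
    """Flag tokens that are uppercase nucleotide runs of length >= 6."""
    return [bool(DNA_MOTIF_RE.fullmatch(tok)) for tok in tokens]


def annotate(
    sentence: SourceSentence,
    lexicon: Lexicon | None = None,
    tagger: TaggerFn = fallback_tagger,
) -> AnnotatedSentence:
    """Full annotation chain: tokenize, lemma/POS, dictionary NER, motifs.

    Lexicon matches take precedence over the DNA-motif pattern so that a
    token never carries two tags.
    """
    tokens = tokenize(sentence.text)
    ling = annotate_linguistic(tokens, tagger)
    ner: list[str | None]
    if lexicon is not None:
        ner = annotate_ner(tokens, lexicon)
    else:
        ner = [None] * len(tokens)
    for i, flagged in enumerate(tag_dna_motifs(tokens)):
        if flagged and ner[i] is None:
            ner[i] = DNA_MOTIF_TAG
    annotations = tuple(
        TokenAnnotation(surface=t, lemma=lm, pos=p, ner=nr)
        for t, (lm, p), nr in zip(tokens, ling, ner)
    )
    return AnnotatedSentence(source=sentence, tokens=annotations)
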