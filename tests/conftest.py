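"""Shared fixtures: the worked HipAB sentence and small synthetic corpora."""

from __future__ import annotations

import numpy as np
import pytest

from tfsum.corpus_io import Lexicon, SourceSentence
from tfsum.preprocess import annotate, make_dictionary_tagger
from tfsum.synthetic_data import CorpusSpec, make_corpus

#: Worked example: a sentence about the HipAB toxin-antitoxin system with
#: gold lemma/POS annotations and dictionary NER tags (TF names tagged
#: ACTTF, verbs of regulation ACTREG).
HIPAB_TEXT = "HipAB toxin-antitoxin system appears to be regulated at level of HipB stability."

HIPAB_TAGS = {
    "HipAB": ("HipAB", "NNP"),
    "toxin-antitoxin": ("toxin-antitoxin", "NN"),
    "system": ("system", "NN"),
    "appears": ("appear", "VBZ"),
    "to": ("to", "TO"),
    "be": ("be", "VB"),
    "regulated": ("regulate", "VBN"),
    "at": ("at", "IN"),
    "level": ("level", "NN"),
    "of": ("of", "IN"),
    "HipB": ("HipB", "NNP"),
    "stability": ("stability", "NN"),
}

# expected representation rows for the three feature combinations
HIPAB_ROW_LEMMA_POS_NER = (
    "HipAB toxin-antitoxin system appear to be regulate at level of HipB stability. "
    "ACTTF NN NN VBZ TO VB ACTREG IN NN IN ACTTF NN"
)
HIPAB_ROW_LEMMA_NER = (
    "HipAB toxin-antitoxin system appear to be regulate at level of HipB stability. "
    "ACTTF ACTREG ACTTF"
)
HIPAB_ROW_NER_FOR_LEMMA = (
    "ACTTF toxin-antitoxin system appear to be ACTREG at level of ACTTF stability."
)


def row_tokens(row: str) -> list[str]:
    """Tokens of a printed representation row, terminal period dropped."""
    out = []
    for tok in row.split():
        if tok.endswith("."):
            tok = tok[:-1]
        if tok:
            out.append(tok)
    return out


@pytest.fixture(scope="session")
def hipab_lexicon() -> Lexicon:
    lex = Lexicon()
    lex.add("HipAB", "ACTTF", case_sensitive=True)
    lex.add("HipB", "ACTTF", case_sensitive=True)
    lex.add("regulated", "ACTREG", case_sensitive=False)
    return lex


@pytest.fixture(scope="session")
def hipab_sentence(hipab_lexicon):
    source = SourceSentence(text=HIPAB_TEXT, pmid="15576772", doc_index=0)
    tagger = make_dictionary_tagger(HIPAB_TAGS)
    return annotate(source, hipab_lexicon, tagger)


@pytest.fixture(scope="session")
def small_corpus():
    """A 400-sentence synthetic corpus with planted duplicates."""
    return make_corpus(CorpusSpec(total_sentences=400, n_tfs=6, duplicate_rate=0.3, seed=7))


@pytest.fixture(scope="session")
def recovery_corpus():
    """Corpus at realistic per-property imbalance for recovery tests."""
    return make_corpus(
        CorpusSpec(total_sentences=600, n_tfs=12, keyword_injection_rate=1.0,
                   noise_rate=0.05, seed=11)
    )


@pytest.fixture(scope="session")
def annotated_summaries(recovery_corpus):
    return [
        annotate(ls.sentence, recovery_corpus.lexicon)
        for ls in recovery_corpus.summaries
    ]


def labels_for(corpus, prop: str) -> np.ndarray:
    return np.array([1 if prop in ls.labels else 0 for ls in corpus.summaries])
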