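"""Corpus classification, TF filtering, redundancy reduction, HTML output."""

import numpy as np
import pytest

from conftest import labels_for
from tfsum.corpus_io import PROPERTIES, SourceSentence
from tfsum.learn import PropertySentenceClassifier
from tfsum.preprocess import annotate
from tfsum.summarize import (
    build_summary,
    classify_corpus,
    deduplicate,
    filter_by_tf,
    parse_html,
    render_html,
)


def src(text, pmid="1", idx=0):
    return SourceSentence(text=text, pmid=pmid, doc_index=idx)


def ann(text, pmid="1", idx=0):
    return annotate(src(text, pmid, idx))


@pytest.fixture(scope="module")
def six_models(recovery_corpus, annotated_summaries):
    models = {}
    for prop in PROPERTIES:
        y = labels_for(recovery_corpus, prop)
        models[prop] = PropertySentenceClassifier(
            combo="NER_FOR_LEMMA", random_state=0
        ).fit(annotated_summaries, y)
    return models


class TestClassifyCorpus:
    def test_missing_model_rejected(self, six_models):
        partial = {p: m for p, m in six_models.items() if p != "TU"}
        with pytest.raises(ValueError, match="TU"):
            classify_corpus([], partial)

    def test_drops_unlabeled_and_keeps_all_predicted_properties(
        self, recovery_corpus, six_models
    ):
        arts = [
            annotate(s, recovery_corpus.lexicon) for s in recovery_corpus.articles[:200]
        ]
        out = classify_corpus(arts, six_models)
        assert all(props for _, props in out)
        assert len(out) <= 200

    def test_recovers_gold_positives(self, recovery_corpus, six_models):
        """Sentences with planted keywords come back with their property."""
        arts = [annotate(s, recovery_corpus.lexicon) for s in recovery_corpus.articles]
        out = {id(a): props for a, props in classify_corpus(arts, six_models)}
        hits = total = 0
        for a, gold in zip(arts, recovery_corpus.gold_labels):
            if gold:
                total += 1
                if gold <= out.get(id(a), frozenset()):
                    hits += 1
        assert hits / total >= 0.95


class TestFilterByTf:
    def wrap(self, texts):
        return [(ann(t, idx=i), frozenset({"ACT"})) for i, t in enumerate(texts)]

    def test_keeps_mentions_drops_others(self):
        items = self.wrap(["MatA represses flhDC.", "The regulator represses flhDC."])
        kept = filter_by_tf(items, "MatA")
        assert len(kept) == 1
        assert "MatA" in kept[0][0].source.text

    def test_word_boundary_rule(self):
        items = self.wrap(["This format is odd.", "The mat protein binds."])
        kept = filter_by_tf(items, "mat")
        assert len(kept) == 1
        assert kept[0][0].source.text.startswith("The mat")

    def test_naive_substring_oracle_disagrees_on_boundaries(self):
        texts = ["formation of the complex.", "mat binds.", "a mat-like protein."]
        items = self.wrap(texts)
        kept = {k[0].source.text for k in filter_by_tf(items, "mat")}
        substr = {t for t in texts if "mat" in t}
        assert kept == {"mat binds."}
        assert kept < substr  # substring matching would over-collect

    def test_aliases(self):
        items = self.wrap(["The histone-like factor binds."])
        assert filter_by_tf(items, "MatA", aliases=["histone-like"]) != []


class TestDeduplicate:
    STOPS = {"the", "of", "a", "is", "and", "to"}

    def section(self, texts):
        return [(src(t, idx=i), frozenset({"ACT"})) for i, t in enumerate(texts)]

    def test_identical_sentences_collapse_to_one_visible(self):
        out = deduplicate(self.section(["MatA binds DNA tightly."] * 3), 0.8, self.STOPS)
        assert sum(s.visible for s in out) == 1
        assert sum(not s.visible for s in out) == 2
        assert all(s.similarity_to_kept >= 0.8 for s in out if not s.visible)

    def test_disjoint_sentences_stay_visible(self):
        out = deduplicate(
            self.section(["MatA binds DNA.", "Growth requires iron."]), 0.8, self.STOPS
        )
        assert all(s.visible for s in out)

    def test_planted_near_duplicate_triples(self):
        """Two triples of near-duplicates collapse to two visible sentences."""
        triple1 = [
            "MatA represses flhDC transcription strongly.",
            "MatA represses flhDC transcription strongly today.",
            "MatA represses flhDC transcription.",
        ]
        triple2 = [
            "The operon contains four genes downstream.",
            "The operon contains four genes downstream here.",
            "The operon contains four genes.",
        ]
        out = deduplicate(self.section(triple1 + triple2), 0.8, self.STOPS)
        assert len(out) == 6
        assert sum(s.visible for s in out) == 2

    def test_conservation_and_idempotence(self, small_corpus):
        texts = [ls.sentence.text for ls in small_corpus.summaries[:40]]
        out = deduplicate(self.section(texts), 0.8, small_corpus.stopwords)
        assert len(out) == 40
        visible = [(s.sentence, s.properties) for s in out if s.visible]
        again = deduplicate(visible, 0.8, small_corpus.stopwords)
        assert all(s.visible for s in again)
        assert len(again) == len(visible)

    def test_empty_section(self):
        assert deduplicate([], 0.8, self.STOPS) == []

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            deduplicate(self.section(["x y."]), 0.0, self.STOPS)


class TestHtml:
    def make_summary(self):
        classified = [
            (ann("MatA represses flhDC <strongly>.", pmid="123", idx=0), frozenset({"ACT"})),
            (ann("MatA binds a palindromic site.", pmid="456", idx=0), frozenset({"SITE"})),
            (ann("MatA binds a palindromic site.", pmid="789", idx=0), frozenset({"SITE"})),
        ]
        return build_summary("MatA", classified, stopwords={"a", "the"})

    def test_links_escaping_and_partition_round_trip(self):
        summary = self.make_summary()
        doc = render_html(summary)
        assert "/123" in doc
        assert "&lt;strongly&gt;" in doc  # raw '<' escaped
        parsed = parse_html(doc)
        for prop, sents in summary.sections.items():
            if not sents:
                assert prop not in parsed
                continue
            assert [s.sentence.pmid for s in sents if s.visible] == [
                p for _, p in parsed[prop]["visible"]
            ]
            assert [s.sentence.pmid for s in sents if not s.visible] == [
                p for _, p in parsed[prop]["hidden"]
            ]

    def test_empty_sections_omitted(self):
        doc = render_html(self.make_summary())
        assert "Structural domains" not in doc
        assert "Transcriptional activity" in doc

    def test_sentence_in_two_sections(self):
        both = [(ann("MatA controls motility genes.", pmid="5", idx=0), frozenset({"ACT", "RP"}))]
        summary = build_summary("MatA", both, stopwords=set())
        assert summary.sections["ACT"] and summary.sections["RP"]

    def test_every_rendered_sentence_mentions_tf(self, recovery_corpus, six_models):
        tf = recovery_corpus.tf_names[0]
        arts = [annotate(s, recovery_corpus.lexicon) for s in recovery_corpus.articles[:300]]
        filtered = filter_by_tf(classify_corpus(arts, six_models), tf)
        summary = build_summary(tf, filtered, stopwords=recovery_corpus.stopwords)
        parsed = parse_html(render_html(summary))
        for entry in parsed.values():
            for text, _pmid in entry["visible"] + entry["hidden"]:
                assert tf in text
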