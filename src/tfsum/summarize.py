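"""Assembly of per-TF extractive summaries.

The six fitted property classifiers are applied to an annotated article
collection; sentences with no predicted property are dropped and the rest
are kept only when they mention the TF by name (whole-token match). Within
each property section, near-duplicate sentences are grouped by
average-linkage hierarchical clustering of cosine similarities over binary
TF-IDF vectors (stop words removed); walking the dendrogram leaf order,
a sentence is hidden when its similarity to the most recently kept sentence
reaches the redundancy threshold (default 0.8). Hidden sentences stay in
the HTML output, collapsed, so a curator can expand them; every sentence
links to its PubMed record.
"""

from __future__ import annotations

import html
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

from .corpus_io import PROPERTIES, SourceSentence
from .learn import predict_labels
from .preprocess import AnnotatedSentence, is_punctuation, tokenize
from .represent import BINARY_TFIDF, RepresentationConfig, fit_vector_space, vectorize_corpus

#: Human-readable section headings, in canonical order.
SECTION_TITLES: dict[str, str] = {
    "ACT": "Transcriptional activity",
    "DOM": "Structural domains",
    "EVO": "Evolutionary properties",
    "RP": "Processes regulated",
    "SITE": "Binding sites",
    "TU": "Transcription unit organization",
}

DEFAULT_PUBMED_URL = "https://pubmed.ncbi.nlm.nih.gov/{pmid}/"
DEFAULT_REDUNDANCY_THRESHOLD = 0.8


@dataclass
class SummarySentence:
    sentence: SourceSentence
    properties: frozenset[str]
    visible: bool
    cluster_id: int
    similarity_to_kept: float | None = None  # hidden sentences only


@dataclass
class Summary:
    tf_name: str
    sections: dict[str, list[SummarySentence]]
    n_source_articles: int

    def section_properties(self, visible_only: bool = True) -> frozenset[str]:
        """Properties with at least one (visible) sentence."""
        return frozenset(
            p
            for p, sents in self.sections.items()
            if any(s.visible or not visible_only for s in sents)
        )


def classify_corpus(
    sentences: Sequence[AnnotatedSentence], models: Mapping[str, object]
) -> list[tuple[AnnotatedSentence, frozenset[str]]]:
    """Apply all six property models; drop sentences with no property."""
    missing = set(PROPERTIES) - set(models)
    if missing:
        raise ValueError(f"missing models for properties: {sorted(missing)}")
    label_sets = predict_labels(dict(models), sentences)
    return [
        (s, frozenset(labels))
        for s, labels in zip(sentences, label_sets)
        if labels
    ]


def _token_pattern(name: str, case_sensitive: bool) -> re.Pattern:
    flags = 0 if case_sensitive else re.IGNORECASE
    return re.compile(rf"(?<![\w-]){re.escape(name)}(?![\w-])", flags)


def filter_by_tf(
    classified: Sequence[tuple[AnnotatedSentence, frozenset[str]]],
    tf_name: str,
    aliases: Iterable[str] = (),
    aliases_case_sensitive: bool = True,
) -> list[tuple[AnnotatedSentence, frozenset[str]]]:
    """Keep only sentences mentioning the TF as a whole token.

    The canonical name matches exact-case; aliases follow
    ``aliases_case_sensitive``. Word-boundary matching prevents "mat"
    matching inside "format".
    """
    if not tf_name:
        raise ValueError("tf_name must be non-empty")
    patterns = [_token_pattern(tf_name, True)]
    patterns += [_token_pattern(a, aliases_case_sensitive) for a in aliases]
    return [
        (s, props)
        for s, props in classified
        if any(p.search(s.source.text) for p in patterns)
    ]


def _content_words(text: str, stopwords: set[str]) -> Counter:
    return Counter(
        t.lower()
        for t in tokenize(text)
        if not is_punctuation(t) and t.lower() not in stopwords
    )


def deduplicate(
    section: Sequence[tuple[SourceSentence, frozenset[str]]],
    threshold: float = DEFAULT_REDUNDANCY_THRESHOLD,
    stopwords: set[str] | None = None,
) -> list[SummarySentence]:
    """Mark redundant sentences within one property section.

    Sentences become binary TF-IDF vectors over their stop-word-free words
    (the vector space is fitted per section). Cosine similarities feed
    average-linkage hierarchical clustering; sentences are reordered by
    dendrogram leaf order and walked once: a sentence is hidden iff its
    cosine similarity to the most recently kept sentence is >= threshold.
    Every input sentence appears exactly once, visible or hidden.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    stopwords = stopwords or set()
    n = len(section)
    if n == 0:
        return []
    docs = [_content_words(s.text, stopwords) for s, _ in section]
    if n == 1 or not any(docs):
        # single sentence, or no sentence has any content word left: all
        # cosine similarities are 0, nothing is redundant
        return [
            SummarySentence(s, props, visible=True, cluster_id=i)
            for i, (s, props) in enumerate(section)
        ]
    space = fit_vector_space(docs, RepresentationConfig(weighting=BINARY_TFIDF))
    M = vectorize_corpus(docs, space).toarray()
    norms = np.linalg.norm(M, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    sim = (M @ M.T) / np.outer(safe, safe)
    sim[norms == 0, :] = 0.0
    sim[:, norms == 0] = 0.0
    np.fill_diagonal(sim, 1.0)
    sim = np.clip(sim, 0.0, 1.0)

    if n == 2:
        order = [0, 1]
        clusters = [1, 1] if sim[0, 1] >= threshold else [1, 2]
    else:
        dist = 1.0 - sim
        np.fill_diagonal(dist, 0.0)
        link = linkage(squareform(dist, checks=False), method="average")
        order = list(leaves_list(link))
        clusters = list(fcluster(link, t=1.0 - threshold, criterion="distance"))

    out_by_pos: dict[int, SummarySentence] = {}
    last_kept: int | None = None
    for pos in order:
        s, props = section[pos]
        if last_kept is None or sim[pos, last_kept] < threshold:
            out_by_pos[pos] = SummarySentence(
                s, props, visible=True, cluster_id=int(clusters[pos])
            )
            last_kept = pos
        else:
            out_by_pos[pos] = SummarySentence(
                s,
                props,
                visible=False,
                cluster_id=int(clusters[pos]),
                similarity_to_kept=float(sim[pos, last_kept]),
            )
    return [out_by_pos[pos] for pos in order]


def build_summary(
    tf_name: str,
    classified: Sequence[tuple[AnnotatedSentence, frozenset[str]]],
    threshold: float = DEFAULT_REDUNDANCY_THRESHOLD,
    stopwords: set[str] | None = None,
) -> Summary:
    """Assemble the per-property sections of one TF's summary.

    ``classified`` should already be filtered to TF-mentioning sentences.
    A sentence predicted for several properties appears in each of those
    sections; de-duplication runs independently per section.
    """
    sections: dict[str, list[SummarySentence]] = {}
    for prop in PROPERTIES:
        members = [
            (s.source, props) for s, props in classified if prop in props
        ]
        sections[prop] = deduplicate(members, threshold=threshold, stopwords=stopwords)
    pmids = {s.source.pmid for s, _ in classified}
    return Summary(tf_name=tf_name, sections=sections, n_source_articles=len(pmids))


def render_html(
    summary: Summary, pubmed_url_template: str = DEFAULT_PUBMED_URL
) -> str:
    """Render a Summary as a standalone HTML document.

    One section per property with at least one sentence; visible sentences
    listed in order; redundant sentences collapsed inside a <details>
    element; each sentence followed by its PubMed ID as a hyperlink.
    """
    parts = [
        "<!DOCTYPE html>",
        "<html><head><meta charset='utf-8'>",
        f"<title>Automatic summary of {html.escape(summary.tf_name)}</title>",
        "<style>.hidden-sentences { color: #666; }</style>",
        "</head><body>",
        f"<h1>Automatic summary of {html.escape(summary.tf_name)}</h1>",
        f"<p class='provenance'>Extracted from {summary.n_source_articles} article(s).</p>",
    ]
    for prop in PROPERTIES:
        sentences = summary.sections.get(prop, [])
        if not sentences:
            continue
        parts.append(f"<section data-property='{prop}'>")
        parts.append(f"<h2>{html.escape(SECTION_TITLES[prop])}</h2>")
        parts.append("<ul class='visible-sentences'>")
        hidden = []
        for ss in sentences:
            url = pubmed_url_template.format(pmid=ss.sentence.pmid)
            item = (
                f"<li>{html.escape(ss.sentence.text)} "
                f"<a class='pmid' href='{html.escape(url, quote=True)}'>"
                f"{ss.sentence.pmid}</a></li>"
            )
            if ss.visible:
                parts.append(item)
            else:
                hidden.append(item)
        parts.append("</ul>")
        if hidden:
            parts.append("<details><summary>Redundant sentences "
                         f"({len(hidden)})</summary>")
            parts.append("<ul class='hidden-sentences'>")
            parts.extend(hidden)
            parts.append("</ul></details>")
        parts.append("</section>")
    parts.append("</body></html>")
    return "\n".join(parts)


def parse_html(document: str) -> dict[str, dict[str, list[tuple[str, str]]]]:
    """Recover the visible/hidden partition and PMIDs from rendered HTML.

    Returns ``{property: {"visible": [(text, pmid), ...], "hidden": [...]}}``.
    """
    from lxml import html as lxml_html

    tree = lxml_html.fromstring(document)
    out: dict[str, dict[str, list[tuple[str, str]]]] = {}
    for section in tree.xpath("//section[@data-property]"):
        prop = section.get("data-property")
        entry: dict[str, list[tuple[str, str]]] = {"visible": [], "hidden": []}
        for kind, cls in (("visible", "visible-sentences"), ("hidden", "hidden-sentences")):
            for li in section.xpath(f".//ul[@class='{cls}']/li"):
                link = li.xpath(".//a[@class='pmid']")[0]
                pmid = link.text_content().strip()
                text = li.text_content()
                text = text[: text.rfind(pmid)].strip()
                entry[kind].append((text, pmid))
        out[prop] = entry
    return out
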