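# tfsum

Assisted curation of bacterial transcription-factor (TF) summaries by
extractive, user-oriented multi-document summarization.

Curated databases of bacterial transcriptional regulation (RegulonDB,
EcoCyc) describe each TF in a short textual summary covering six
properties: transcriptional activity (**ACT**), structural domains
(**DOM**), evolutionary properties (**EVO**), regulated processes
(**RP**), binding sites (**SITE**) and the organization of the
transcription unit encoding the TF (**TU**). Writing these summaries by
hand means reading thousands of articles. `tfsum` assists that work: it
trains one binary sentence classifier per property from property-tagged
manual summaries, applies all six to an article collection, keeps only
sentences that mention the TF by name, collapses near-duplicate sentences,
and renders an HTML draft summary whose every sentence links back to its
PubMed record — candidate knowledge for a curator, not publishable text.

## Method

**Representation.** Sentences are tokenized, lemmatized and POS-tagged
(pluggable engine; a naive deterministic fallback is built in), and
dictionary NER replaces or augments tokens with biological tags (e.g.
`ACTTF` for a TF name, `ACTREG` for a verb of regulation, `DNAMOTIF` for a
nucleotide run). Three feature combinations — *lemma POS NER*, *lemma
NER*, *NER for lemma* — with cumulative 1..n-grams are vectorized as
binary presence, TF–IDF, or binary TF–IDF (every positive TF–IDF weight
set to 1). Optional truncated SVD (k ∈ {200, 300}) or χ² feature selection
(k ∈ {1000, 800, 500}) reduces dimensionality.

**Imbalance.** Positives are 6–15% of the training pool, so the negative
class can be under-sampled by four from-scratch techniques: random
under-sampling to 1:1, Tomek's-link removal, one-sided selection (a
1NN-consistent subset followed by Tomek cleaning) and the instance
hardness threshold (drop negatives a cross-fitted classifier finds hard to
recognize as negative). Samplers never remove a positive.

**Model selection.** Support vector classifiers (linear / RBF / polynomial
kernels, optional class weighting) are scored by 10-fold stratified
cross-validation with the geometric mean of sensitivity and specificity,

    G-mean = √(Sens × Spec),  Sens = TP/(TP+FN),  Spec = TN/(TN+FP),

under-sampling applied to the nine training folds only — the validation
fold keeps the original imbalance. Grid search ranks configurations by
highest median fold G-mean, then lower IQR, then lower |skewness|.

**Summarization.** Each classified, TF-mentioning sentence joins the
sections of its predicted properties (a sentence can carry several).
Within a section, sentences become binary TF–IDF vectors without stop
words; average-linkage hierarchical clustering of cosine similarities
orders them, and a sentence is hidden (not dropped) when its similarity to
the most recently kept sentence reaches 0.8.

**Evaluation.** ROUGE-1 recall/precision without stop words (clipped
unigram counts) measures knowledge overlap with a manual summary;
coverage reports count properties present automatically but absent from
the manual summary; curator relevance judgements aggregate to
per-property correct-classification rates.

Because the curated corpora are not redistributable, the package ships a
`synthetic_data` generator that reproduces the *structure* of the training
data — class imbalance, planted keyword signal, paraphrase noise,
duplicate sentences, provenance — so every stage is testable offline.

## Worked example

```python
import numpy as np
from tfsum import (CorpusSpec, make_corpus, annotate, PropertySentenceClassifier,
                   grid_search, classify_corpus, filter_by_tf, build_summary)
from tfsum.corpus_io import PROPERTIES

spec = CorpusSpec(total_sentences=600, n_tfs=12, noise_rate=0.05, seed=1)
corpus = make_corpus(spec)
train = [annotate(ls.sentence, corpus.lexicon) for ls in corpus.summaries]

grid = [PropertySentenceClassifier(combo="LEMMA_NER", random_state=1),
        PropertySentenceClassifier(combo="NER_FOR_LEMMA", random_state=1)]
models = {}
for prop in PROPERTIES:
    y = np.array([1 if prop in ls.labels else 0 for ls in corpus.summaries])
    best = grid_search(train, y, grid, k=10, seed=1)[0]
    models[prop] = best.estimator.fit(train, y)
    print(f"{prop}: {int(y.sum()):3d}/{len(y)} positives, "
          f"median CV G-mean {best.median_gmean:.3f}")

articles = [annotate(s, corpus.lexicon) for s in corpus.articles]
classified = filter_by_tf(classify_corpus(articles, models), "RegA")
summary = build_summary("RegA", classified, threshold=0.8,
                        stopwords=corpus.stopwords)
for prop, sents in summary.sections.items():
    if sents:
        print(f"{prop}: {sum(s.visible for s in sents)} visible, "
              f"{sum(not s.visible for s in sents)} hidden")
```

prints

```
ACT:  72/600 positives, median CV G-mean 1.000
DOM:  90/600 positives, median CV G-mean 1.000
EVO:  42/600 positives, median CV G-mean 1.000
RP:  72/600 positives, median CV G-mean 1.000
SITE:  36/600 positives, median CV G-mean 1.000
TU:  42/600 positives, median CV G-mean 1.000
ACT: 2 visible, 1 hidden
...
```

Each line of the first block is one property's class balance and the
cross-validated G-mean of the best grid configuration — 1.000 because the
synthetic positives carry planted keywords, the idealized upper bound of
the real task. The second block is RegA's assembled summary: per section,
how many sentences a curator sees immediately and how many near-duplicates
are collapsed but expandable. `render_html(summary)` turns this into the
final HTML document.

The same workflow is available from the shell:

```
tfsum make-fixtures --out fixtures/ --total-sentences 600 --seed 1
tfsum train --fixtures fixtures/ --models models/ --seed 1
tfsum summarize --models models/ --articles fixtures/articles.jsonl \
      --fixtures fixtures/ --tf RegA --out RegA.html
tfsum rouge --manual manual.txt --auto auto.txt --stopwords fixtures/stopwords.txt
```

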