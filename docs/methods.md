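# Methods

## Problem setting and model

`tfsum` treats knowledge extraction of transcription-factor (TF)
properties as user-oriented, multi-document *extractive* summarization
driven by sentence classification. Six binary support-vector classifiers
— one per property (ACT, DOM, EVO, RP, SITE, TU) — decide independently
whether a sentence describes their property, so a sentence can carry
several labels. Negative examples for each property are all sentences of
the training pool not tagged with it, which makes every per-property
dataset heavily imbalanced (positives are roughly 6–15% of the pool).
The assumptions this rests on:

- the sentence is the unit of meaning: a property is either stated within
  one sentence or not extracted;
- dictionary NER tags plus lemmas carry enough signal to separate
  property-bearing sentences; no syntactic or discourse structure is used;
- a sentence is about the TF only if it mentions the TF by name
  (whole-token match). This is a deliberate, known-weak filter: anaphoric
  references ("this regulator …") are lost.

## Representation

Tokenization splits on whitespace and detaches edge punctuation, keeping
hyphenated compounds ("toxin-antitoxin") whole. Punctuation-only tokens
carry no features, so a sentence-terminal period never enters a vector.

The lemma/POS engine is a contract (a deterministic token-list →
(lemma, pos)-list function). The built-in fallback lowercases and strips
plural/verbal suffixes for lemmas and combines a small closed-class table
with suffix heuristics for POS; it is intentionally naive and documented
as such — any external engine can be plugged in without code change, and
the dictionary-backed tagger (`make_dictionary_tagger`) lets gold
annotations drive the chain in tests.

Dictionary NER is leftmost-longest over token sequences. Case policy is
per entry class: entity names (TF/gene/TU symbols) match exact-case to
protect short gene symbols (`mat` must not fire inside "format"), while
descriptive terms and verbs match case-insensitively. A token matching a
maximal run of ≥ 6 characters over `{A,C,G,T,N,W,S,R,Y,-}` is tagged
`DNAMOTIF` unless a lexicon entry already claimed it (one tag per token).
The motif rule is a configurable default; the alphabet includes the IUPAC
degeneracy letters a binding-site description typically uses.

The three feature combinations and the n-gram rule: n-grams (cumulative
1..`ngram_max`, `ngram_max` ≤ 3) are taken per block and never join the
lemma block to an appended tag block — cross-block n-grams would be
meaningless concatenations. IDF uses the smoothed form
`ln((1+N)/(1+df)) + 1`; no vector-length normalization, which keeps the
binary TF–IDF weighting exactly equal to binary presence (any positive
weight becomes 1) rather than approximately so. The vocabulary is stored
in lexicographic order, which doubles as the deterministic tie-break for
χ² feature selection.

## Under-sampling

All four techniques are implemented in this package directly (the sampler
contract returns kept row indices; positives are never removed):

- **random** — keep all positives and exactly |positives| negatives drawn
  without replacement under the seed; a no-op with a warning when
  negatives are already the minority;
- **Tomek's links** — mutual nearest neighbors of opposite class
  (Euclidean distance, ties to the lowest index); the negative member of
  every link is dropped;
- **one-sided selection** — stage 1 seeds the reference set with all
  positives plus one random negative and adds, in one seeded random pass,
  every negative the current set misclassifies by 1NN; stage 2 applies
  Tomek cleaning to that subset;
- **instance hardness threshold** — 5-fold cross-fitted class
  probabilities from a base learner (default: RBF-kernel SVC with Platt
  scaling); negatives with P(negative) < 0.5 are dropped, except that the
  |positives| easiest negatives are always retained. The kept count is an
  output of the data, not a parameter. The 0.5 threshold is a design
  choice where several are defensible; it makes perfectly separable data
  lose nothing and removes the hardest negatives first.

The Tomek and 1NN stages are verified against brute-force pure-Python
oracles (all-pairs distance scans) on randomized datasets; those oracles
share no code with the vectorized implementation.

## Cross-validation and model selection

10-fold stratified CV; every stage — vector space, reducer, sampler,
classifier — is fitted on the nine training folds only, so the validation
fold keeps the original imbalance and no validation index can enter a
sampled training set (asserted fold-by-fold in the tests). The score is
the G-mean of sensitivity and specificity; a configuration is ranked by
median fold G-mean, with ties broken by lower IQR, then lower absolute
adjusted Fisher–Pearson skewness of the fold scores, then grid order.
Skewness of a constant score vector is defined as 0. The decision
threshold is fixed at 0 (no probability calibration). The full grid axes
(`build_grid`) cover three combinations × three weightings × reducers
{none, SVD-200/300, χ²-1000/800/500} × five samplers × three kernels ×
C ∈ {0.1, 1, 10, 100} × γ ∈ {scale, 0.01, 0.001} × degree ∈ {2, 3} ×
class weighting {off, balanced}; routine runs restrict the axes
(`default_grid`) because the cross-product is far larger than a planted-
signal corpus warrants.

## Redundancy reduction

Per property section (per TF): sentences become binary TF–IDF vectors of
their stop-word-free lowercased words, the vector space fitted on that
section alone. Cosine similarity (zero-norm vectors defined as similarity
0) feeds average-linkage hierarchical clustering; sentences are reordered
by dendrogram leaf order and walked once, keeping the first and hiding
any sentence whose similarity to the most recently kept one is ≥ 0.8.
The boundary is resolved as *redundant iff similarity ≥ 0.8*, the strict
complement of "dissimilar iff < 0.8". Hidden sentences are retained in
the HTML, collapsed inside a `<details>` element, with their similarity
recorded; nothing is deleted. De-duplication runs within a section only —
a sentence appearing in two sections is judged independently in each.
With fewer than three sentences the linkage degenerates gracefully (two
sentences: one cluster iff similarity ≥ threshold).

## Evaluation

ROUGE-1 without stop words uses clipped multiset counts (Σ over word
types of min(count in manual, count in auto)); a unique-word-type variant
sits behind `mode="types"`. Tokens are lowercased alphanumeric runs
(internal hyphens/apostrophes kept); no stemming — lemmatization belongs
to training, not evaluation. Recall divides by the manual summary's word
count, precision by the automatic one's; an empty manual text after
stop-word removal is an error, not a zero.

Coverage compares the property set of a manual summary (union of sentence
labels) with the sections holding at least one *visible* sentence.
Curator aggregation averages per-property correct-classification rates
over evaluators and reports the unweighted macro average across
properties. All printed percentages round half away from zero — the
convention under which six rates of 80/41/76/74/78/38 average to 65.

## Synthetic data

`make_corpus` emulates the training-data structure: a pool of
`total_sentences` (default 2244) template sentences, each naming a TF and
a regulation verb; per property, `floor(rate × total)` sentences
(defaults: ACT 12%, DOM 15%, EVO 7%, RP 12%, SITE 6%, TU 7%) additionally
carry two planted keywords from that property's disjoint vocabulary, and
are labeled with exactly that property. Negative sentences carry a decoy
keyword with probability `noise_rate` (default 0.05) — label noise that
caps attainable specificity the way off-topic keyword mentions do in real
text. The article collection mirrors every summary sentence with synonym
swaps inside the filler vocabulary (never the keywords) and plants
duplicates at `duplicate_rate` (default 0.1); gold labels follow each
sentence. Lexicons (TF names exact-case; verbs and keywords folded) and a
small stop-word list are emitted in the same formats the readers consume.

What the generator does *not* emulate: real biomedical prose, multi-label
sentences, property signal expressed without keywords, co-reference, and
realistic vocabulary overlap between properties. A perfect G-mean on this
corpus therefore demonstrates the pipeline's mechanics (leakage-free CV,
representation, selection), not real-corpus performance, where reported
G-means for comparable setups fall in the 0.80–0.97 range.

Test and acceptance runs use a 600-sentence corpus (rates unchanged) —
large enough for 10-fold CV on the rarest property (36 positives) while
keeping grid search fast; the generator default remains 2244.

`make_eval_pair` builds manual/automatic text pairs whose stop-word-free
clipped ROUGE-1 recall equals a designed overlap fraction by word-count
construction (40 distinct content words in the manual text, an exact
subset shared).

## Numerical and degenerate-input choices

- Nearest-neighbor and dendrogram ties break toward the lowest original
  index; χ² ties toward lexicographic feature order.
- `fold_metrics` refuses single-class truth rather than defining 0/0.
- SVD k is bounded by min(rows, features); χ² k by the feature count.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng` / scikit-learn `random_state`); repeated
  runs are bit-identical, and fitted models pickle round-trip with
  identical decision values.

## Known limitations

- The TF-mention filter misses anaphora and alias spellings unless
  aliases are supplied.
- The fallback lemmatizer/POS tagger is heuristic; quality work on real
  text should plug in a proper engine via the tagger contract.
- The TU property is known to be hard in practice (models tend to learn
  regulation *of* transcription units rather than the TF's own TU); the
  synthetic corpus does not reproduce that confusion.
- De-duplication is within-section only; the same fact phrased for two
  properties is shown twice.
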