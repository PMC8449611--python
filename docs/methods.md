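# Methods

This note documents the models, rules and numerical choices behind
`ohcmine`, and what the synthetic-corpus experiments do and do not
show about real forum data.

## Problem setting

A post is evidence of off-label use when (i) it relays firsthand
patient experience with the target drug, (ii) it links the drug to an
indication, and (iii) that indication is not on the drug's
FDA-approved label. The pipeline decomposes accordingly: a statistical
relevance filter, deterministic linguistic normalization and entity
recognition, a rule-based relation extractor over dependency trees,
and a table lookup against an approved-indication map. Errors compose
multiplicatively, which is why every stage is independently testable
and seeded.

## Relevance classifier

* Tokenization: lowercase, split on non-alphanumeric runs (apostrophes
  kept inside tokens). The same tokenizer is shared by every stage so
  token indices line up across modules.
* Vectorization: term caps select the highest-corpus-frequency terms
  (scikit-learn `max_features` semantics). The `count_plus_tfidf`
  ensemble concatenates a 450-feature count half and a 450-feature
  TF-IDF half; `doc_embedding` averages corpus-trained word vectors
  (dimension = the cap, 300 by convention). Stopword removal uses
  scikit-learn's fixed English list.
* Default classifier: XGBoost (200 trees, depth 4, lr 0.3, single
  thread for determinism). Model selection criterion across the grid
  is held-out F1; the class threshold is 0.5.
* Validation: stratified 80/20 split; stratified, shuffled, seeded
  10-fold CV. The vectorizer is refitted inside every fold — no
  information leaks from validation folds into fitting.

## Spelling normalization

Candidate corrections are retrieved from a length-bucketed index over
the union of lexicon surface tokens and a bundled ~400-word general
vocabulary, scored by bounded Levenshtein distance (edlib), max 2.
A correction is applied only for a unique minimum; ties prefer medical
surfaces, then lexicographic order. Tokens shorter than 4 characters
or containing digits are never corrected (protects "it", "rx",
dosages). Corrected output is always in-vocabulary, which makes
`correct_text` idempotent by construction. Real-word errors (a wrong
word spelled correctly) and token splitting/merging are out of scope.

## Entity recognition and the nonmedical filter

Dictionary NER: greedy longest match of lowercase token n-grams
against the lexicon, scanning left to right, so retained spans never
overlap and "nerve pain" beats bare "pain". The module boundary
accepts any mention producer with the same contract, so a
UMLS-backed tagger can be swapped in.

The nonmedical filter trains **skip-gram with negative sampling**
(SGNS) word vectors and drops a mention iff its vector exists and its
cosine with the target drug is negative; out-of-vocabulary mentions
are always retained. The trainer fits the SGNS objective by full-batch
gradient descent on the within-window co-occurrence matrix (negative
term = 5 expected samples from the 0.75-power unigram distribution),
with seeded Gaussian initialization — fully deterministic, O(V²)
memory, intended for desk-scale vocabularies. Defaults: d=100,
window 5, min-count 2, 200 full-batch steps, learning rate 0.05 (the
pipeline uses d=50 for its corpus-level filter). The negative-sampling
term is essential here: it is what pushes words sharing no context
with the drug to negative cosine, the sign structure the filter's
decision rule relies on. A count-based PPMI+SVD factorization was
evaluated first and rejected — its truncation noise gives rare but
genuine drug–indication pairs small negative cosines, which the sign
test then misreads.

## Pairing rules

* A **jump** is one undirected dependency edge; jump distance is the
  shortest-path edge count (NetworkX BFS). Retention is inclusive:
  distance ≤ 9 kept, 10 dropped.
* Multi-token mentions are anchored at their syntactic head — the
  span token whose head lies outside the span — giving each mention
  one well-defined graph node; edits to non-head span tokens cannot
  change distances.
* Cross-sentence rule: only adjacent sentences (window 1, preceding
  checked first) are examined; the first substitution word in reading
  order ("it", "drug", "medication", case-insensitive) is rewritten as
  the drug, and distance is measured *within the rewritten sentence*
  — not across a merged multi-sentence graph.
* Negation: cue set {not, never, no, without, n't}, plus any token
  ending in "n't". A pair is negated iff a cue is on the drug–
  indication dependency path or is a direct dependent of a path
  token. Both the cue list and the scoping are configurable; clause-
  level negation semantics and hedging are out of scope.
* Only mentions of the post's scrape-keyword drug participate in
  pairing; co-mentioned other drugs are ignored.

The bundled parser is a deterministic rule-based one (first non-
auxiliary verb is the root; prepositions attach to the most recent
verb and open a noun-phrase chain; negation cues attach to the nearest
following verb). It always emits a valid tree and handles the simple
subject–verb–object–prepositional shapes of forum sentences; it is a
fixture-grade backend, and any parser producing valid `ParsedSentence`
objects (e.g. a statistical dependency parser) can replace it.

## Off-label adjudication

Matching is concept-level: indication surfaces normalize through a
synonym table ("insomnia" and "sleep disorder" share one concept)
before the approved-set lookup; unknown surfaces become novel concepts
and are therefore off-label for every drug. Negation dominates: a
negated pair is never off-label. A symptom of an approved indication
(e.g. fatigue with an antidepressant) still flags off-label if the
concept itself is not approved — a deliberate, known limitation of
concept-set matching. The label map for the 12 study drugs is bundled
and versioned so everything runs offline; `fetch_label` can refresh it
from openFDA when network access is available. Confidence buckets
(high: same sentence ≤ 4 jumps; medium: 5–9; low: cross-sentence
substitution) are a package convention — the bucket boundaries carry
no external definition and are configurable.

## Synthetic corpus

The generator emulates keyword-scraped OHC posts with one planted
drug–indication statement per relevant post. Defaults and rationale:

| parameter | default | rationale |
|---|---|---|
| frac_relevant | 0.7 | matches the ~70/30 relevant/irrelevant split observed in manually annotated forum samples |
| frac_off_label | 0.2 | matches the ~20% off-label-positive rate in annotated validation sets |
| misspell_rate | 0.1 | one recoverable corruption in 10% of posts; drug tokens preferred, since misspelled drug names are what correction exists to recover |
| negation_rate | 0.1 | negated statements are a minority phenomenon |
| cross_sentence_rate | 0.2 | anaphoric "It works for my X" constructions |
| ambiguous_rate | 0.0 | hedged posts; off by default, exposed as a knob |

Misspellings are single-character substitutions or deletions, never in
the first character, never sentence-initial, and are verified at
generation time to be uniquely recoverable by the corrector — the
recovery guarantee is by construction. One root seed drives all
sampling; identical configs give byte-identical corpora.

What the generator does **not** emulate: free narrative syntax beyond
its template inventory, real misspelling distributions, multi-drug
posts, sarcasm/speculation, symptom-vs-indication ambiguity, and
annotator disagreement. Passing the end-to-end test therefore shows
the machinery is correct and internally consistent under the stated
conditions — not that real-forum accuracy would match; on real data
the parser and classifier are the binding constraints.

## Evaluation

Confusion cells follow the usual convention (tp: predicted and actual
off-label, etc.); accuracy=(tp+tn)/n, precision=tp/(tp+fp),
recall=tp/(tp+fn), F1 the harmonic mean. Zero denominators yield an
undefined marker rendered "NA", never 0. Per-post prediction is "any
extracted pair flags off-label"; posts with neither an extracted nor a
planted pair are excluded from scoring, and hedged posts can be
excluded to mirror ambiguity-free validation. Reported percentages
round to the nearest integer; on the published full validation matrix
this recomputes precision as 39% and F1 as 53%, one point away from
the printed 40%/52% — a rounding-path discrepancy in the source
tables, documented here and excluded from machine checks.

## Problem sizes

The test suite and acceptance script run at desk scale by design:
1000-post corpora for end-to-end recovery, 600 posts for classifier
sanity, 200 for spelling checks, 1000 random trees (≤ 50 nodes) for
the BFS cross-check. The full suite completes in seconds on one CPU.
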