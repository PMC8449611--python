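# ohcmine

Detection of **off-label drug usage** in online health community (OHC)
posts. Patients describe on forums what they actually take their
medication for; when that indication is not on the drug's FDA-approved
label, the post is evidence of off-label use — a signal
pharmacovigilance teams otherwise only see through sparse spontaneous
reports. `ohcmine` implements the full text-mining pipeline that turns
raw forum posts into per-post off-label flags with confidence buckets.

## Method

The pipeline runs five stages over each corpus:

1. **Relevance classification.** Only posts relaying firsthand patient
   (or family/friend) experience with the target drug are informative.
   Texts are vectorized (count / TF-IDF / their 450+450-feature
   concatenation / 300-dim averaged word embeddings, all capped at 900
   features) and classified with a classic model grid (SVM, naive
   Bayes, linear SGD, random forest, gradient-boosted trees). The
   default model is a gradient-boosted tree ensemble over concatenated
   count+TF-IDF vectors, validated with a stratified 80/20 split and
   10-fold cross-validation.
2. **Spelling normalization.** Consumer spelling is noisy; misspelled
   drug and condition names are recovered with a conservative
   edit-distance corrector (unique candidate within Levenshtein
   distance ≤ 2, medical surfaces preferred, tokens < 4 characters
   never touched). Idempotent by construction.
3. **Entity recognition.** Drug and indication mentions are found by
   greedy longest token-n-gram match against a bundled medical lexicon
   (surface → concept, category ∈ {drug, indication}). Spurious
   matches are removed by a distributional filter: skip-gram word
   vectors are trained on the corpus, and a mention whose cosine
   similarity with the target drug is *negative* is discarded as
   nonmedical.
4. **Drug–indication pairing.** Each sentence is parsed into a
   dependency tree; the *jump distance* between a drug and an
   indication mention is the shortest-path edge count between their
   anchor tokens in the undirected tree. Pairs within **9 jumps**
   (inclusive) are retained. When drug and indication sit in adjacent
   sentences, the indication's sentence is scanned for a substitution
   word ("it", "drug", "medication"); the anaphor is rewritten as the
   drug and distance is measured in the rewritten sentence. A pair is
   *negated* when a negation cue lies on, or hangs directly off, the
   dependency path between the two mentions.
5. **Off-label flagging.** The indication concept (after synonym
   normalization) is compared with the drug's approved set from the
   bundled openFDA-derived label map covering the 12 study drugs:
   `off_label = (not negated) AND (indication ∉ approved(drug))`.
   Confidence is bucketed: *high* (same sentence, distance ≤ 4),
   *medium* (same sentence, 5–9), *low* (cross-sentence substitution).

Real forum corpora cannot be redistributed, so the package ships a
seeded **synthetic corpus generator** that plants ground truth:
~70 % relevant posts, configurable rates of recoverable misspellings,
negations, cross-sentence anaphora, hedged ambiguous posts, and
off-label vs on-label pairings consistent with the label map.

## Worked example

```bash
ohcmine generate --n-posts 500 --seed 7 \
    --out-posts posts.jsonl --out-truth truth.jsonl
cat > cfg.yaml <<'YAML'
paths: {posts: posts.jsonl, labels: truth.jsonl, output: records.csv}
seed: 7
YAML
ohcmine run-all --config cfg.yaml
ohcmine evaluate --records records.csv --truth truth.jsonl
```

prints the stage funnel and the score against planted truth:

```
{"input": 500, "relevant": 362, "with_drug_mention": 362, "with_pairs": 362, "flagged_off_label": 66}
{"cells": {"tp": 66, "fp": 0, "fn": 0, "tn": 296},
 "metrics": {"accuracy": 100, "precision": 100, "recall": 100, "f1": 100},
 "n_scored": 362, "n_excluded_ambiguous": 0, "n_excluded_unpairable": 138}
```

Of 500 posts, 362 survive the relevance filter, all retain a drug
mention and a within-threshold pair, and 66 posts are flagged
off-label — exactly the planted off-label truths (the 138 excluded
posts are irrelevant ones carrying no drug–indication pair). The first
record lines show the per-pair evidence:

```
post_id,drug,indication,off_label,confidence,jump_distance,same_sentence,substitution_used,negated
p00000,celecoxib,tendonitis,False,high,4,True,False,True
p00002,natalizumab,fatigue,True,high,3,True,False,False
```

`p00000` pairs celecoxib with tendonitis but is negated ("was not
given…"), so it is *not* off-label; `p00002` pairs natalizumab (approved
only for multiple sclerosis) with fatigue at jump distance 3 → off-label,
high confidence.

Library use mirrors the CLI: `generate_synthetic_corpus`,
`train_relevance_classifier`, `correct_text`, `recognize_entities`,
`extract_pairs`, `flag_off_label`, `evaluate_end_to_end`, and
`run_pipeline` are all importable from `ohcmine`.

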