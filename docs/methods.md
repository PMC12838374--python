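# Methods

This note records the models, parameter choices, and numerical conventions
behind `pathocode`, and what the synthetic experiments do and do not show.

## Data model and tagging conventions

Reports store raw text with 0-based half-open character offsets; annotation
files never store tokenized text, so tokenizers can change without
re-annotation. Text is NFC-normalized at load. The three entity types are
assumed disjoint (overlapping gold spans are rejected at load), matching
how specimen / technique / diagnosis mentions occur in pathology prose.

BIO tagging uses 7 labels. Span→tag conversion assigns `B-` to the first
word overlapping an entity by at least one character and `I-` to
subsequent overlapping words; tag→span decoding repairs illegal sequences
(`I-t` after `O`, after sequence start, or after a different type) as
`B-t`, so any tag sequence decodes to a valid span set. Subword alignment
follows the first-subword convention: the first subword of a word carries
the word's label id, continuations and special positions carry −100; an
all-subwords mode (continuations get the `I-` variant) is available. The
−100 value is excluded from loss and from every metric.

## Reference models

Both trainable components are multinomial softmax-regression heads trained
with minibatch AdamW (β₁ = 0.9, β₂ = 0.999, decoupled weight decay on the
weight matrix only) on masked cross-entropy (natural log). A single seed
drives initialization and batch shuffling, making training trajectories
bit-reproducible. This linear reference keeps the full protocol runnable
on one CPU in seconds; the `TokenClassifier` / `Encoder` contracts are the
extension points for transformer-based components, which are deliberately
out of scope here (an adapter for external transformer encoders exists but
is exercised only when such a model is installed).

* **Tagger**: features are the concatenated embeddings of a token and its
  ±2 neighbors (zero padding past sentence edges). Defaults: 3 epochs,
  batch 8, weight decay 0.01, learning rate 0.05 (a short fine-tuning
  recipe with the rate scaled to a from-scratch linear model), encoder
  dim 96. Evaluation is token-level, the primary view collapsing BIO
  prefixes to entity classes; micro averages are computed over non-O
  tokens.
* **Code classifiers**: one single-label softmax head per terminology over
  mention-surface embeddings (dim 256). Up to 10 epochs with early
  stopping once the validation loss (an internal 10% split) fails to
  improve for 2 consecutive epochs. The "multi-label" view of coding is
  realized as independent per-terminology heads, because each mention
  receives exactly one code per routed terminology.

The shared text encoder is seeded character-n-gram (3–5) feature hashing
into 256 signed buckets (keyed blake2b, stable across platforms), rows
L2-normalized. It is deterministic, has no external weights, and is robust
to single-character corruption — the property the retrieval experiments
rely on. It does not model word order or deep semantics; conclusions about
absolute accuracy therefore do not transfer to transformer encoders,
though the architecture comparisons (classifier vs retrieval vs fusion)
exercise the same mechanisms.

## Terminologies and retrieval

Concept tables are opaque-code collections with label, synonyms, a group
tag (hierarchy root / class / chapter), and optional parent links. Subset
selection is flat on the group tag, except for SNOMED CT-style tables
where the subset closes transitively over parent links, mirroring
hierarchy-based subsetting. Every label and synonym is indexed as its own
entry; a code's retrieval score is the max over its entries (concatenating
synonyms into one document dilutes rare surface forms and was rejected).

Dense retrieval is exhaustive cosine search (exact by construction);
BM25 is Okapi with k₁ = 1.5, b = 0.75 and idf kept non-negative by the
+1-inside-log form. Ties break to the lexicographically smaller code,
which makes every ranking deterministic.

## Fusion

Fused score: `s(c) = w·p_clf(c) + (1−w)·sim01(c)` over the union of both
candidate pools, missing components read as 0. Dense cosines map to [0,1]
affinely (`(cos+1)/2`); BM25 scores, being unbounded, are normalized by
the maximum score within the candidate set (rank-preserving), and an
all-zero BM25 pool contributes nothing — a deliberate guard so that a
lexical whiff degrades the system to the classifier instead of overriding
it. Fallback: when the classifier's top probability is below τ, the
retrieval rank-1 code is returned outright; this is the path that handles
codes outside the classifier's label space. `(w, τ)` are learned by
exhaustive search over w ∈ {0, 0.1, …, 1} × τ ∈ {0, …, 0.9} maximizing
mean 5-fold CV accuracy, folds stratified by code (round-robin within each
code's occurrences), ties preferring smaller τ then smaller w — so the
degenerate corners are reachable and preferred when nothing beats them.
The threshold is per-terminology.

Comparison protocol: the fusion config is learned once with the dense
channel (the proposed system); the classifier-only baseline is the
`w=1, τ=0` corner, and the BM25 ablation swaps the retrieval channel into
the same learned config. This isolates the retrieval type as the only
difference between the two retrieval-augmented variants.

A consequence worth stating: because zero-match BM25 is harmless under
this rule, the sparse ablation cannot fall far below the classifier —
it behaves like the classifier plus BM25's gains on unseen codes. Fusion
designs without such a guard can be actively damaged by confidently-wrong
sparse matches (e.g. when mention language and terminology language
differ); this package chooses the graceful rule and documents the
difference rather than reproducing the pathology.

## Synthetic corpus generator

The generator emulates a 560-report single-site corpus: 1–5 template
sentences per report (French/English boilerplate, 70% French by default),
each embedding one mention whose entity type cycles specimen → technique →
finding; concept usage is Zipf-distributed (exponent 1.1) over 25 concepts
per terminology by default; finding concepts are dually coded (SNOMED CT +
ICD-11 twins by label). Surfaces are drawn from the concept's label or
synonyms (synonym rate 0.5) and then corrupted: abbreviation substitution
from a fixed table (rate 0.1), per-word single-character edits (rate 0.05
by default; each corrupted word receives exactly one insert/delete/swap),
and case perturbation (rate 0.05). `unseen_fraction` reserves the rarest
concepts of each pool for the test segment (the last 20% of report
indices, used with an in-order split), where they are oversampled at 1/4
per mention slot — yielding roughly 20–25% of test mentions with codes the
classifier never saw, the rare-code regime the fusion is meant to address.

What the generator does **not** emulate: discourse structure and
multi-sentence context, boundary-ambiguous compound mentions, mention
surfaces absent from the terminology's synonym list, inter-annotator
noise, and genuinely cross-lingual mention↔entry mismatch. Tests passing
on this corpus therefore demonstrate mechanism (recovery, determinism,
the unseen-code advantage of retrieval), not clinical-grade accuracy.

## Statistical harness

* PRF and error rates come from the multiclass confusion matrix;
  zero-denominator metrics are 0 with a warning; macro averages are
  unweighted. Report formatting conventions: 2 decimals for tagging
  tables, 4 for coding tables.
* Bootstrap CIs are percentile intervals (default 10⁴ resamples); the
  resampling unit is whatever one score represents — reports for tagging
  metrics, mentions for coding metrics. Undefined resamples are redrawn
  and counted.
* McNemar is the exact binomial test on discordant pairs; the default
  two-sided p is `min(1, 2·min-tail)`, with a one-sided mode (the min
  tail) because published comparisons mix both conventions.
* The permutation test swaps each item's paired outcomes with probability
  ½ (10⁴ iterations default) and reports the raw proportion of permuted
  |accuracy differences| at least the observed one; add-one smoothing is
  available by flag.
* No multiple-testing correction is applied.
* Calibration (checked in the test suite, 500 replications at n = 53):
  both paired tests hold type-I error within ±0.02 of 0.05 under
  independent-null simulation, and the bootstrap covers a Gaussian mean
  at 0.95 ± 0.02.

## Problem sizes

The acceptance script and end-to-end tests run 500-report corpora (about
1500 mentions), 25–40 concepts per terminology, 5-fold fusion CV, and
10³–10⁴ iteration resampling — sizes chosen so the whole battery completes
in a few minutes on one CPU while leaving the Zipf tail populated enough
to exercise the unseen-code path.

## Known limitations

* The hashing encoder cannot separate mentions that differ only by word
  order beyond n-gram effects, and has no cross-lingual ability.
* Single-label-per-terminology coding; true multi-label assignment is an
  extension point.
* SNOMED CT hierarchy handling is limited to parent-closure subsetting;
  no semantic distance between codes is modeled (a near-miss ancestor
  counts as wrong).
* The fusion weight is a scalar per terminology, not per class.
* `run_pipeline` consumes generated corpora (or corpora previously written
  by `simulate`); external corpora with licensed terminologies go through
  the library API with user-supplied concept tables.
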