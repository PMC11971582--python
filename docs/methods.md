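# Methods

## Problem and scales

Admission notes document a clinician's reasoning about the presenting
problem. The Revised-IDEA rubric rates that documentation on ordinal
scales; this package covers two of them. The **D** scale asks whether
the note states an explicitly prioritized differential of *specific*
diagnoses: D0 when fewer than two unique diagnoses appear, D2 when at
least two unique diagnoses appear together with prioritization
language, D1 otherwise. Organ-system category words ("cardiac",
"infectious") are annotated separately (`DC`) precisely because they do
not count as diagnoses. The **EA** scale rates how well the reasoning
is explained — whether clinical data are linked to the diagnoses under
consideration — and is modeled here only in its binarized form, EA2 vs
not-EA2, because the finer one-vs-rest EA0/EA1 decompositions are not
reliably learnable from note text.

## Entity→score logic

`d_score_from_entities` is total and deterministic. Diagnosis
uniqueness is equality of normalized surface forms: Unicode casefold,
strip leading/trailing punctuation, collapse internal whitespace. No
synonym or ontology merging is attempted ("CHF" and "congestive heart
failure" count as two diagnoses); this is the minimal reproducible
convention, and the normalization function is the single place to
change it. "At least 2 unique diagnoses" is deliberately read as ≥2 —
a threshold rather than exact equality — since a three-diagnosis
differential must remain scorable. "Explicit prioritization" means at
least one `Prior` span anywhere in the note; no positional relationship
to the diagnoses is required.

The multi-class D prediction from binary classifiers uses the ordered
stepwise rule: if the D0 model fires, D=0; else if the D2 model fires,
D=2; else D=1. The rule is asymmetric by design — it encodes the
empirical finding that direct D1 models are the weakest of the three
one-vs-rest decompositions, so D1 is defined residually.

## Synthetic note generator

Real corpora for this task are private EHR data, so the generator
produces stand-ins that preserve what the models actually consume:
sentences assembling diagnosis mentions, category words, prioritization
phrases, clinical-data phrases and linkage terms, surrounded by filler
prose. Packaged lexicons (100 diagnoses, 12 category words, 10
prioritization phrases, 40 data phrases, 15 linkage terms) are pairwise
disjoint at the phrase level, so in the clean regime a longest-match
dictionary tagger is a perfect oracle; token-level overlap between
lexicons ("pulmonary" inside "pulmonary embolism") is retained so the
trained tagger still has a disambiguation problem.

Gold D labels are not sampled independently of the text: the generator
plans a mention structure for the requested score, renders it, then
re-derives the label by running the same `d_score_from_entities` logic
the scorer uses, and fails loudly on any mismatch. Label/logic
consistency therefore holds by construction on every generated corpus.

**EA convention.** The rubric's EA semantics are not formalized
anywhere as span logic (the entity-based EA route was abandoned as
unworkable; only classifiers model EA). The generator therefore needs
its own convention, and uses: a diagnosis is *supported* when one of
its mentions shares a sentence with at least one `Data` span and at
least one `Link` span; the EA score is the number of distinct supported
diagnoses, capped at 2. This mirrors "explanation of lead and
alternative diagnoses": EA2 requires two *different* diagnoses to be
explained. A consequence is that D0 (≤1 unique diagnosis) cannot
co-occur with EA2, so the corpus sampler draws (D, EA) pairs from a
coupled joint distribution: starting from the product of the configured
marginals, the infeasible (D0, EA2) mass is moved to (D0, EA1) and
compensated by moving equal mass from (D≥1, EA1) to (D≥1, EA2). Both
configured marginals are preserved exactly; configurations where no
such coupling exists (e.g. all-D0 with nonzero EA2) raise a config
error. The alternative mention-counting reading (the same diagnosis
explained twice scores EA2) was rejected: it has no "alternative
diagnosis" semantics, and it manufactures a synthetic class whose
surface form is nearly indistinguishable from two-diagnosis notes.

**Default class mix.** D proportions default to 109/154/437 of 700
(15.6/22/62.4%) and EA proportions to 73/255/372 of 700, the observed
mix of the retrospective development note set this generator emulates.

**Noise model.** `noise` is a per-character corruption rate (deletion,
duplication, substitution, case flip) applied to connective prose; the
hard regime also corrupts entity surfaces. Diagnosis surfaces are
corrupted once per note and reused, so two mentions of the same
diagnosis stay string-identical and the gold D label is unaffected.

**What the generator does not emulate:** clinically coherent diagnosis
combinations, longitudinal patient structure, copy-forward text,
templated EHR boilerplate, abbreviation variance, or annotator
disagreement. Perfect scores in the clean regime certify the machinery
(offset fidelity, logic, metrics), not performance on real notes; the
noisy regime restores a nontrivial gap between the trained tagger and
the dictionary baseline, which is the regime to use when exercising
model comparisons.

## Preprocessing

`truncate_assessment` extracts the span from the first assessment-style
header (line-anchored, case-insensitive) to the first plan marker
("plan:" or a numbered-list line). Institutions differ in header
vocabulary, so the header/marker tables are per-site "dialects"; the
shipped `nyu`/`uc`/`default` tables are editable placeholders rather
than faithful reconstructions of any institution's rules. The output is
always a contiguous substring of the input, and a note with no
recognizable header falls back to the whole text with a warning — a
deliberate fail-open choice, since downstream models prefer extra
context over silent truncation to nothing.

## Recognizers

The reference tagger is per-token multinomial logistic regression over
BIO-encoded labels with window features (lowercased token, shape,
prefix/suffix, neighbors at ±1 and ±2, adjacent bigrams), decoded by
maximal same-type runs; an I- tag opening a run is tolerated as B-.
Tokenization is whitespace/punctuation splitting with recorded
character offsets so decoded spans are offset-exact — a requirement of
the overlap-based Type matcher, not a nicety. Regularization C=5,
lbfgs, 300 iterations; training is deterministic given the seed. This
is a desk-scale recognizer: the contract it satisfies (annotated spans
in, offset-faithful spans out) is the same one a heavier
embedding-based tagger would implement behind `RecognizerModel`.
Overlapping predictions are resolved longest-first with ties to the
earlier start; gold spans are assumed non-overlapping (the generator
enforces this, and nested annotation is out of scope).

## Classifiers

The reference backend is bag-of-words (unigram+bigram counts) logistic
regression; backends are registered by name so heavier models can be
slotted in without touching training, thresholding or composition.
Augmentation applies, in a fixed order, synonym replacement, random
insertion, random swap (defaults: 15 words each), then per-word
deletion at 15% — the order is a package convention since only the
operation set and intensities are prescribed. Counts cap at the number
of eligible words. Synonyms come from a packaged table; no external
corpus is needed. Oversampling draws training examples with weights
proportional to inverse class frequency, equalizing expected class
mass. Threshold selection maximizes F1 of the positive class over the
unique observed validation scores (Youden's J behind `--criterion`),
ties broken toward the higher threshold; the exact criterion used in
the original deployment is unpublished, so it is exposed as
configuration rather than hard-coded.

## Metrics

**Type matching.** A predicted span is credited iff its type equals a
gold span's type and their character intervals overlap by ≥1, under a
one-to-one assignment. The assignment is computed by optimal bipartite
assignment maximizing (in order) matched-pair count, total character
overlap, earlier gold position — implemented as a single
`linear_sum_assignment` with a large per-match constant. A greedy
left-to-right matcher was considered and rejected: it is suboptimal on
crossing-overlap configurations (gold `[0,10)`,`[5,6)` against
predictions `[0,10)`,`[9,11)` strands one gold span), whereas the
optimal assignment provably agrees with an exhaustive maximum-matching
oracle, which the tests assert on random span sets. A type with no gold
and no predicted spans scores P=R=F1=1.0 (vacuous truth); the report
always carries a `support` column so such types are visible.

**Ranking metrics.** AUROC and AUPRC delegate to scikit-learn
(`roc_auc_score`, `average_precision_score` — step-wise summation, no
interpolation) with explicit `UndefinedMetricError`s for single-class
inputs; both are cross-checked in tests against independent oracles
(all-pairs win probability; step-sum identities). CIs across CV folds
use mean ± t(0.975, k−1)·SE; on a single held-out set, a seeded
percentile bootstrap (2,000 resamples). Both are reported because the
CI convention of the numbers this package's reports mimic is not
stated.

**Cross-validation.** Stratified k-fold with shuffling; per-fold class
counts deviate from perfect stratification by ≤1. When k exceeds the
smallest class count (leave-one-out), the split degrades to plain
shuffled folds with a warning. The trainer callable receives only the
training folds — leakage-freedom is structural, and a test verifies
that blanking the held-out fold leaves the training material
byte-identical.

**ICC.** Inter-rater reliability uses the two-way mixed-effects,
consistency, single-rater form ICC(C,1) = (MS_subjects − MS_error) /
(MS_subjects + (k−1)·MS_error), CI from F-distribution bounds; the
absolute-agreement variant ICC(A,1) is available behind a flag. Both
are computed closed-form from the ANOVA decomposition and cross-checked
against pingouin in the test suite. A constant-subject matrix raises
rather than returning a conventional value.

## Problem sizes

The packaged benchmark regime is 600 clean notes with an 80/20 split
for held-out evaluation and 1,000 notes for distributional checks —
sizes chosen to mirror the few-hundred-note corpora this tooling is
designed for while keeping any single train/evaluate cycle in seconds
on one CPU. The benchmark floors asserted on this regime (tagger
micro-F1 ≥ 0.90, logic-pipeline macro-F1 ≥ 0.85, D0 AUROC ≥ 0.95, EA2
AUROC ≥ 0.80) certify the machinery, not performance on real notes.

## Known limitations

- Synthetic prose is templated; classifier performance partially
  reflects template glue, which is why the clean regime saturates.
- The dictionary tagger's perfection in the clean regime depends on
  phrase-level lexicon disjointness; user-supplied lexicons that embed
  one lexicon's phrase mid-phrase in another's could break it.
- Surface-form diagnosis uniqueness over-counts synonymous diagnoses
  and under-counts misspelled repeats (hard regime keeps repeats
  consistent within a note for exactly this reason).
- Truncation dialects are heuristic placeholders; real deployments
  should supply site-specific header tables.
- The EA span convention is a generator-side formalization; human EA
  ratings encode judgment it does not capture.
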