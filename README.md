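# crscore

Automated assessment of clinical-reasoning (CR) documentation quality in
admission notes. Residents' assessment sections are scored on two
Revised-IDEA rubric scales — differential diagnosis (**D**, 0–2) and
explanation of reasoning (**EA**, 0–2) — and this package implements the
full modeling and evaluation stack for that task: entity recognition,
deterministic rubric logic, one-vs-rest classifiers, and the metric
suite, all exercisable end to end on synthetic annotated notes (real
note corpora are private EHR data).

## What it computes

**Entity recognition.** Five entity types are annotated in assessment
text: specific diagnoses (`Dx`), diagnostic-category words (`DC`, e.g.
"cardiac" — these never count as diagnoses), prioritization language
(`Prior`), supporting clinical data (`Data`), and linkage terms
(`Link`). Recognizers share one contract (text → character-offset
spans); the package ships a trainable window-feature logistic-regression
BIO tagger, a longest-match dictionary tagger, and a gold-replay oracle.

**Rubric logic.** The D score is derived from recognized entities:

- **D0** — fewer than 2 unique diagnoses,
- **D2** — ≥2 unique diagnoses *and* explicit prioritization language,
- **D1** — everything else.

Diagnosis uniqueness is equality of normalized surface forms (casefold,
strip edge punctuation, collapse whitespace); no synonym merging.

**Classifiers.** The D scale is decomposed one-vs-rest; thresholded D0
and D2 decisions recompose via the ordered stepwise rule (D0 fires → 0;
else D2 fires → 2; else 1). EA is handled as a single binary EA2 vs
not-EA2 model. Training supports runtime text augmentation (synonym
replacement / insertion / swap, 15 words each, then 15% per-word
deletion) and random minority oversampling with inverse-class-frequency
weights. Backends are pluggable; the reference backend is bag-of-words
logistic regression.

**Evaluation.** Type-mode NER matching (a prediction is credited when
its type matches a gold span and their intervals overlap by ≥1
character, one-to-one), per-class F1, AUROC/AUPRC with bootstrap or
across-fold CIs, leak-free stratified k-fold cross-validation, and the
two-way mixed-effects consistency ICC for inter-rater reliability.

## Worked example

```sh
crscore generate --n 200 --seed 7 --out corpus.jsonl
crscore train-ner --in corpus.jsonl --out tagger --seed 7
crscore tag --model tagger --in corpus.jsonl --out tagged.jsonl
crscore score-d --in tagged.jsonl --out dscores.csv
crscore cv --in corpus.jsonl --out folds.csv --k 5 --seed 7
```

This prints, in order:

```
wrote 200 notes to corpus.jsonl
trained reference tagger on 200 notes -> tagger
tagged 200 notes -> tagged.jsonl
scored 200 notes -> dscores.csv
d_macro_f1: mean 1.0000 (95% CI 1.0000-1.0000)
ner_micro_f1: mean 1.0000 (95% CI 1.0000-1.0000)
```

`dscores.csv` holds the entity counts behind each score:

```
note_id,unique_dx_count,prior_count,d_score
synthetic-0000,4,1,2
synthetic-0001,3,1,2
synthetic-0002,2,1,2
```

The first note begins "The patient progressive poor appetite. acute
pericarditis is unlikely but possible, consistent with positive murphy
sign. …" — four distinct diagnoses plus a prioritization phrase, hence
D2. On this clean regime (disjoint lexicons, zero noise) the trained
tagger recovers every gold span, so 5-fold cross-validated NER micro-F1
and D macro-F1 are both 1.0; the noisy regime (`--noise 0.08
--noise-in-spans`) degrades the dictionary baseline far below the
trained tagger.

## Layout

- `src/crscore/corpus.py` — JSONL corpora, standoff spans, validation
- `src/crscore/synthetic.py` — synthetic note generator (gold spans + labels)
- `src/crscore/preprocess.py` — assessment-section truncation dialects
- `src/crscore/ner.py` — the three recognizers
- `src/crscore/rubric.py` — D logic, stepwise rule, EA2 binarization
- `src/crscore/classify.py` — one-vs-rest training, augmentation, thresholds
- `src/crscore/evaluation.py` — NER matching, AUROC/AUPRC, CV, ICC
- `src/crscore/cli.py` — `crscore` command-line interface
- `docs/methods.md` — modeling assumptions and design notes
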