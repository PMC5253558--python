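# smisym

Extraction of severe-mental-illness (SMI) symptomatology from free-text
clinical documents.

Most of what clinicians record about psychosis — hallucinations, paranoia,
poverty of speech, elevated mood — lives in unstructured narrative, not in
coded fields. `smisym` implements a sentence-classification pipeline that
turns such narrative into structured symptom data for research use:

1. **Lexicon matching.** A 50-concept symptom lexicon (keywords with
   trailing-wildcard token patterns, plus optional/mandatory *modifier*
   terms that must fall within eight words of the keyword) defines a
   *candidate instance*: a sentence containing a symptom keyword, e.g.
   "There was some **poverty** of **speech**".
2. **Contextual rules.** A ConText-style trigger layer assigns negation
   ("did **not** have poverty of speech"), experiencer ("his **mother**
   has delusions") and temporality ("examined the patient **for**
   poverty of speech") to each mention. On their own these rules give a
   high-recall baseline label.
3. **Per-concept SVM.** Each symptom gets a binary linear SVM over sparse
   bag-of-words features (uni/bigrams, keyword, positional tokens, coarse
   POS tags, modifiers) plus the context flags, tuned by stratified
   10-fold cross-validation. A *confidence margin filter* then demotes
   low-margin positive predictions to negative, trading recall for
   precision: the margin threshold is calibrated on held-out data to a
   target precision (0.85 by default), because clinical records restate
   symptoms often enough that recall losses are recoverable.
4. **Evaluation.** Positive-class precision / recall / F1 against gold
   annotation (P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R), with
   undefined ratios reported as missing, never zero), Cohen's κ
   = (p_o − p_e)/(1 − p_e) for inter-annotator agreement, and paired
   hybrid-vs-rules comparisons.
5. **Cohorting.** Patient-level profiles (a patient has a symptom iff ≥ 1
   positive instance in any document), ICD-10 diagnosis grouping
   (F20 / F25 / F31 / Multiple / non-SMI, with psychotic-depression codes
   F32.3 and F33.3 excluded from the non-SMI side), domain × diagnosis
   crosstabs and coverage statistics.

Because real mental-health records cannot ship with a package, a seeded
synthetic discharge-summary generator (`smisym.syncorpus`) plants gold-
labelled mentions — affirmed, negated (partly in UK dialect the base
trigger table misses), hypothetical, other-experiencer and homograph — so
the whole pipeline is testable and demonstrable offline.

## Worked example

```sh
smisym synth   --seed 11 --out demo/synth
smisym train   --corpus demo/synth/corpus.jsonl --ledger demo/synth/ledger.jsonl \
               --concept Paranoia --concept "Poor rapport" --out demo/models --seed 11
smisym evaluate --corpus demo/synth/corpus.jsonl --ledger demo/synth/ledger.jsonl \
               --models demo/models --out demo/eval
```

which prints (abridged):

```
wrote 926 documents, 3655 planted mentions to demo/synth
Paranoia: n=546 C=0.01 margin=0.000 calib precision=1.000 recall=1.000
Poor rapport: n=536 C=0.01 margin=0.000 calib precision=1.000 recall=1.000
   arm    metric  n_concepts     mean   median
hybrid precision           2 1.000000 1.000000
hybrid    recall           2 1.000000 1.000000
hybrid        f1           2 1.000000 1.000000
 rules precision           2 0.785070 0.785070
 rules    recall           2 1.000000 1.000000
 rules        f1           2 0.879588 0.879588
```

Read this as: on the stylised synthetic corpus the trained classifiers
separate affirmed from non-affirmed mentions essentially perfectly, while
the rules-only arm keeps perfect recall but loses precision — it affirms
the UK-dialect negations ("Nil paranoia reported today.") and the
homograph mentions ("A leaflet on paranoia was given at discharge.") that
its trigger table cannot see. That is the qualitative trade-off the hybrid
design exists to fix, reproduced mechanistically. Synthetic text is far
easier than real clinical prose, so absolute numbers here say nothing
about performance on real records (see `docs/methods.md`).

The same objects are available as a library:

```python
from smisym import GeneratorConfig, run_experiment
result = run_experiment(GeneratorConfig(n_patients=150, seed=5), target_precision=0.85)
print(result.summary)                    # per-arm mean/median P, R, F1
print(result.models["Paranoia"].summary())  # statsmodels-style results object
```

## Layout

| module | role |
| --- | --- |
| `smisym.lexicon` | load/validate/compile the 50-concept lexicon (two shipped editions) |
| `smisym.textproc` | sentences, tokens, keyword + modifier matching, candidate instances |
| `smisym.context` | ConText-style negation / experiencer / temporality rules |
| `smisym.classifier` | features, per-concept SVM model + results objects, margin calibration |
| `smisym.evaluation` | P/R/F1 scoring, Cohen's κ, gold-standard checks, cross-arm summaries |
| `smisym.cohort` | diagnosis groups, patient profiles, crosstabs, coverage |
| `smisym.syncorpus` | seeded synthetic corpus generator with gold ledger |
| `smisym.experiment` | end-to-end two-arm experiment driver |
| `smisym.cli` | `smisym` command-line interface |
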