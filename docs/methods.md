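# Methods

This note records the modelling decisions behind `smisym`: what each stage
assumes, which parameters matter, what the synthetic corpus does and does
not establish, and where the design was genuinely open.

## The extraction model

The unit of classification is the **sentence**. A *candidate instance* of
a symptom concept is a sentence containing one of the concept's keyword
patterns; concepts whose modifier mode is *mandatory* additionally require
a modifier term within the eight-word window. This deliberately targets
clinician-assigned constructs (the recorded word "hallucination") rather
than descriptions of experience ("hearing voices"): clinical training
standardises symptom documentation, and chasing synonyms would trade a
known false-negative mode for a much less quantifiable false-positive one.
For the same reason the lexicon ships without synonym expansion.

### Matching rules

* Patterns are token sequences; a trailing `*` makes a token a prefix
  match, otherwise matching is exact. Everything is case-insensitive.
* Tokenization splits on whitespace and peels leading/trailing punctuation
  into separate tokens; hyphenated words stay whole. Sentence boundaries
  fall after sentence-final punctuation followed by whitespace, and at
  hard line breaks; offsets always slice back to the source text.
* The eight-word modifier window counts only tokens containing a letter or
  digit (clinical text is punctuation-heavy; counting commas would shrink
  the window arbitrarily), measured between the nearest span edges in
  either direction, within one sentence. The same-sentence restriction
  follows from the sentence being the classification unit.
* Within one concept, overlapping keyword matches reduce to the
  leftmost-longest (one instance per locus); matches of *different*
  concepts are never deduplicated against each other — shared keywords
  such as `speech*`, `withdraw*` or `mood` legitimately feed several
  concepts, and disambiguation is each concept's classifier's job.

### Context rules

The trigger table implements the standard pre/post trigger-with-scope
scheme: a forward trigger's scope runs to the end of the sentence, a
backward trigger's from its start, termination terms ("but", "however",
…) cut scopes short, and pseudo-negation phrases block negation by
consuming the tokens of would-be shorter negation triggers
(leftmost-longest match resolution, pseudo-negation winning length ties).
No fixed token-count scope cap is applied — again because the sentence is
the classification unit. When historical and hypothetical triggers both
cover a keyword, hypothetical wins as the more conservative reading.

Two table layers ship:

* a **base** table in the spirit of the published US-English term lists,
  extended with a screening/indication set ("examined the patient for …",
  "screen for …") so that examination statements are flagged irrelevant
  rather than affirmed;
* a **UK-dialect overlay** ("nil …", "denies any …"), off by default. UK
  clinical prose negates in ways the base lists miss; keeping the overlay
  separate makes that gap measurable instead of silently patched.

The rules-only label is positive iff the mention is non-negated,
patient-experienced and non-hypothetical. Historical mentions stay
positive: the binary annotation scheme has no "past symptom" class.

## The classifier

One binary linear SVM per concept. Features: sentence uni/bigrams, the
matched keyword string, position-indexed tokens within ±5 of the keyword,
coarse POS tags in that window, modifier presence and surfaces, and the
three context flags. The POS tagger is a small deterministic
closed-class/suffix heuristic; tags only ever feed features and never gate
matching, so coarse coverage suffices.

* **Kernel:** linear only — standard for sparse bag-of-words, and the
  weights stay interpretable (the results object's `summary()` prints the
  top positive/negative features).
* **Regularisation:** C ∈ {0.01, 0.1, 1, 10, 100}, chosen by stratified
  10-fold cross-validation on positive-class F1, ties to the smaller C.
  The final model refits on all training data. Fold assignment is
  stratified and seeded; document-level grouping is off by default but
  the patient-level splits used by the experiment driver prevent
  cross-partition leakage anyway. The liblinear solver runs with a fixed
  iteration cap and seed, so fits are deterministic.
* **Abstention:** a prediction is positive iff its decision value is
  positive *and* at least the margin threshold; filtered positives fold
  into negative, because the downstream evaluation is strictly binary.
  `calibrate_margin` sweeps the observed positive decision values in
  ascending order and returns the smallest threshold reaching the target
  precision on held-out data (maximum observed value, with a warning, if
  unreachable). The default target precision is 0.85, the working
  criterion for an acceptable model; raising the margin can only shrink
  the predicted-positive set, so recall is monotonically non-increasing
  in the threshold (asserted in tests).

## Evaluation

Metrics are positive-class only. Undefined ratios (no predicted
positives, no gold positives) propagate as missing values and are
excluded from cross-concept means/medians with a footnote count —
averaging in zeros would bias the summaries downward. Gold and predicted
sets must align exactly on (document, sentence span, concept); mismatches
are errors, not misses. Cohen's κ uses the marginal-frequency chance
correction; when both raters are constant and identical κ is reported as
1 by convention and flagged. Cross-concept κ aggregation is reported both
unweighted and instance-weighted, since either average is defensible. A
gold standard *passes* with ≥ 100 positive mentions.

## The synthetic corpus

The generator emulates the mechanics of discharge summaries, not their
language: stylised mental-state-examination templates instantiated with
lexicon keyword/modifier surfaces, shuffled among keyword-free filler
sentences. Per document and concept, mention counts are Poisson; each
mention draws a context class from the configured mix. Defaults — 300
patients, documents per patient 1 + Poisson(2), mention rate 0.8 per
concept per document, context mix (0.55 affirmed, 0.20 negated, 0.10
hypothetical, 0.075 other-experiencer, 0.075 homograph), a diagnosis mix
spanning all six groups — were chosen once as plausible conditions for a
mixed SMI/non-SMI discharge corpus. Five default concepts exercise the
main matching modes: plain keyword (Paranoia, Poor rapport), optional
modifier (Hallucinations), and mandatory modifier with an ambiguous
keyword (Poverty of speech, Elevated mood).

Two plant classes are deliberately invisible to the base rules: a third
of negated templates use UK dialect ("Nil paranoia reported today."), and
homograph plants use keywords in non-clinical senses. Both are gold
negative, so the rules-only arm loses precision on exactly the
mechanisms — dialect and sense ambiguity — that motivate the hybrid
design, and the SVM recovers them from lexical cues. This is why the
two-arm comparison reproduces directionally on synthetic data: rules keep
recall ≈ 1 while the hybrid arm trades recall for precision.

All randomness flows from one seed through named child streams (patients,
docs, mentions, context, templates, fillers, shuffle — spawned in that
fixed order), so extending one template bank never shifts other draws.
The ledger records every planted mention with its context class; expected
label is positive only for affirmed plants, and the per-patient truth
table marks a symptom present iff some affirmed plant of it exists.

**What passing tests show — and don't.** Perfect or near-perfect synthetic
scores certify the mechanics: the matcher finds what the instance
definition says it should (≥ 99% planted-mention recovery, exact
agreement with a brute-force oracle), calibration enforces its target,
and the arm comparison moves in the expected direction. They say nothing
about real clinical text, which has misspellings, section headers,
coreference, de-identification artefacts and unbounded phrasing the
templates intentionally avoid.

## Problem sizes and numerics

The shipped experiment driver and acceptance script use 400 patients ×
~3 documents × 5 concepts (≈ 575 training instances per concept after the
60/20/20 patient-level train/calibration/evaluation split), which keeps a
full run around a minute on one CPU; unit tests use 25–150-patient
corpora. Percentages round half-away-from-zero to integers. Calibration
thresholds are taken from observed decision values only (no
interpolation). Degenerate inputs fail loudly: empty lexicons, single-class
training data, too-few instances for the fold count, unaligned evaluation
sets and empty cohorts all raise with instructions rather than returning
defaults.

## Known limitations

* No section awareness ("Mental state examination:" headers), spelling
  correction, coreference or cross-sentence context.
* Modifier-based subclassification (e.g. auditory vs visual
  hallucinations) is matched and recorded but not separately classified
  or evaluated.
* Four lexicon concepts (loosening of associations, stereotypy, low mood,
  poor motivation) are shipped `excluded`: their keywords are too
  ambiguous for reliable modelling with bag-of-words features. Catalepsy
  and echopraxia are flagged for hand annotation (too rare to model);
  mutism is keyword-only.
* Temporal modelling of symptom course is out of scope; historical
  mentions count as positive.
* The two lexicon editions differ where the source keyword table and its
  worked examples disagree (`hallucinate*` vs `hallucinat*`, `flight of
  idea` vs `flight of idea*`); the curated edition is the default because
  the worked examples use the widened forms, and `Perseverance` keeps its
  transcribed keyword `persever*` although the clinical construct is
  perseveration.
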