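# Methods

`oncotext` reimplements, end to end and on synthetic data, a clinical-NLP
outcome-annotation pipeline for oncology cohorts: per-document classifiers
extract PRISSMM outcomes (any cancer; progression/worsening;
response/improvement; metastatic sites) from imaging reports and oncologist
notes; per-document calls are binarized and turned into patient-level
progression-free-survival (PFS) endpoints; and those endpoints feed
left-truncated, time-varying survival analyses. Real clinico-genomic corpora
are protected health information, so the package ships a generative model of
such a cohort with known latent truth, and every downstream claim is
validated against that truth.

## The synthetic cohort generator

**Disease model.** Each patient carries a continuous-time Markov process
over `{responding, stable, progressing}` with per-month intensities
(defaults: stable→progressing 0.15, stable→responding 0.10,
responding→stable 0.03, responding→progressing 0.03, progressing→stable
0.02, progressing→responding 0.01). A separate *disease present* indicator
starts true; while responding with no metastatic sites, the disease may
clear (rate 1.0/month) into a no-evident-disease state, from which it
relapses (rate 0.03/month) directly into `progressing`. Seven metastatic
sites switch on (never off) at rate 0.005/site-month, six-fold higher while
progressing; a site may also be present at baseline (probability 0.05
each). These remission dynamics exist so that a realistic share of
documents (~30%) is any-cancer-negative — on an advanced-cancer cohort with
no remission, a 5% annotation-noise floor makes the any-cancer label nearly
unlearnable as a ranking task because almost all observed negatives are
flipped positives.

**Treatment.** Line 1 starts at month 0 (palliative in 90% of patients).
Switching is progression-triggered: when the disease enters `progressing`
and another line is available (maximum 3), the next line starts after a
restaging delay of 1 + Exp(3) months, at which point the assessment
re-baselines (the progressing state returns to stable). For 6 months after
each line start, intensities into `responding` are doubled and into
`progressing` halved. Each palliative line contains an immune checkpoint
inhibitor (ICI) with probability 0.4; while an ICI line is the active line,
every intensity into `progressing` (including relapse) is multiplied by
0.6 for TMB-high patients.

**Death.** The death hazard is piecewise constant:
`0.015/month x 2.0^(ever progressed) x 0.4^(ever responded)`. Both effects
are absorbing and multiplicative, exactly matching the downstream
time-varying Cox encoding (`progressed_yet`, `responded_yet`), so a Cox fit
on the *true* first-transition times is consistent for the multipliers —
the package's central parameter-recovery oracle. Administrative censoring
occurs at 36 months or the study end date (diagnoses are placed uniformly
over 2013–2019, study end early 2021), whichever is first.

**TMB.** Tumor mutation burden is a mixture: 15% of patients are TMB-high
(≥ 20 mutations/megabase, the standard dichotomization cutoff), drawn as
20 + Exp(15); the rest are lognormal (median ≈ 6) truncated below 20.

**Observation process.** Imaging reports arrive as a Poisson process at
0.4/month and oncologist notes at 0.8/month between month 0 and
death/censoring — roughly restaging every ten weeks and a monthly-ish
clinic note. In addition, because switches are triggered by documented
progression, each later line start is preceded (with probability 0.9) by a
dedicated restaging imaging report and note dated just before the switch.
Document labels equal the latent state at the document date (progression ⇔
progressing, response ⇔ responding, any-cancer ⇔ disease present, site
flags ⇔ onset reached), then each flag is flipped independently with
probability `label_noise` (default 0.05) under the PRISSMM consistency
rules (progression and response never both set; any positive flag implies
any-cancer). Every patient uses two independent RNG substreams — trajectory
vs. observation — so changing visit rates provably never changes anyone's
latent course or survival.

**Text.** Documents are rendered from small phrase banks: imaging reports
have EXAM/HISTORY/COMPARISON/FINDINGS/IMPRESSION sections with the
outcome-bearing sentence in the impression; notes have boilerplate sections
followed by a header-delimited assessment/plan (headers drawn from the same
configurable list the sectioner uses) holding the outcome sentence and a
plan sentence. With probability `lexicon_overlap` (default 0.1) a document
carries a distractor — a cue phrase from the *opposite* outcome's bank
wrapped in historical context ("prior imaging at that time demonstrated
...") — placed outside the outcome-bearing section. The generator makes no
attempt at clinical prose beyond these templates; in particular the
vocabulary is tiny (hundreds of types), sentence structure is rigid, and
cue phrases are unambiguous. Passing tests therefore demonstrate the
*pipeline mechanics* (leakage-free cross-validation, correct ensembling,
faithful endpoint derivation, calibrated inference), not clinical NLP
performance on real reports.

**What the defaults represent.** Effect sizes are set to the magnitudes the
method is expected to recover: progression→death 2.0, response→death 0.4,
TMB-high on ICI progression 0.6. The generator's absolute timescale is
slower than a real heavily pretreated ICI cohort (synthetic median PFS is
~15–20 months rather than 3–7); the validation targets are hazard ratios
and discrimination, which are timescale-free. Per-document label
prevalences (any-cancer ≈ 0.7, progression ≈ 0.17, response ≈ 0.27) are
modeling assumptions, not published facts.

## Sectioning

The assessment/plan extractor has two implementations with one contract: a
rules labeler (first matched A/P header from a configurable,
case-insensitive list, through the next recognized section header or end of
note) and a small Elman recurrent tagger (embedding 16, hidden 32, Adam,
trained on rules-labeled notes) that predicts an in/out tag per token from
the running left context. Extraction concatenates the in-section span; a
note with no detected section falls back to the full text rather than being
dropped, so no document is silently censored. The header list is a
stand-in; real section inventories are messier.

## Outcome classifiers

Each (outcome, document kind) cell is a Kim-style 1-D convolutional network
over learned token embeddings: widths {2,3,4,5}, 8 filters per width,
embedding 16, ReLU, global max pooling, dropout 0.5, dense sigmoid
output(s); inputs are the full imaging text (≤128 tokens) or the extracted
A/P (≤64 tokens), with vocabulary built from training-split documents only
(min count 2; index 0 padding, 1 unknown). The any-cancer model has a
single output; every other model is dual-output with a shared any-cancer
auxiliary head, trained with the unweighted sum of the two binary
cross-entropies. These sizes are deliberately small — the templated
vocabulary saturates tiny models, and the whole 60-member training run must
fit a single CPU desk budget; every size is config-exposed for larger
corpora. Training is plain Adam (lr 0.01, 3 epochs, batch 64) in float32
numpy with manual backpropagation; fixing the seed fixes initialization,
shuffling and dropout masks, making training bit-reproducible.

**Cross-validation ensembling.** The training split is cut into ten
patient-level folds. One member trains per held-out fold; validation/test
and unlabeled documents are scored by mean-pooling the members' pre-sigmoid
log-odds and applying one logistic (mean-pooling probabilities is a
different operator, and a test asserts the two disagree); training-split
documents are scored only by the member whose held-out fold contains the
patient. The fold map and each member's training-patient set are retained
so leakage audits are mechanical.

## Evaluation

AUROC (tie-aware rank probability) and AUPRC (step-wise interpolation — the
average-precision rule; linear interpolation overestimates) are computed via
scikit-learn behind the package surface and are cross-checked in tests
against O(n²) pairwise counting and explicit step integration. Calibration
curves use equal-width bins with empty bins omitted. Operating points scan
the midpoints of adjacent distinct scores plus ±∞ and break ties toward
higher sensitivity (a screening-oriented choice), then the lower threshold.
Groups whose labels have no variation report a "not enough variation"
marker instead of a number. Binarization thresholds for the survival
analyses are best-F1 points selected on the validation split and frozen
before any test or downstream use; which split defined the original
thresholds is ambiguous, so the choice is configuration with validation as
default. The false-positive attribution table counts per-patient
false-positive documents at a threshold and recomputes the evaluation-set
AUROC with each patient removed, surfacing systematic annotation
disagreements.

## Endpoints and survival analysis

Per-document binary calls become per-patient event timelines; events before
the index date are ignored (with a debug log of the count). PFS variants:
PFS-I (first imaging progression or death), PFS-M (first note progression
or death), PFS-I-or-M (first from either source, or death), PFS-I-and-M
(the *later* of the two sources' first progressions — both must have
occurred by time t; the literal "both documented" reading — or death);
otherwise censoring at last contact. Same-day events are clamped to 0.5
days of at-risk time before model fits.

Counting-process rows `(start, stop]` cut at the first binarized
progression and first response; both covariates are absorbing. Entry starts
at `max(0, NGS date − index)`: genomic testing is a cohort eligibility
criterion, so person-time before testing is not at risk (left truncation;
patients whose testing postdates their terminal date contribute nothing).
Cox fits use the Andersen–Gill form via lifelines' `CoxPHFitter` with
`entry_col` (each row a delayed-entry subject — the identical partial
likelihood), Efron ties, and a clustered robust sandwich (`cluster_col`)
when patients contribute multiple treatment lines. Kaplan–Meier estimation
honors delayed entry through lifelines' `entry` argument; the median is the
earliest time survival reaches ≤ 0.5 (NaN if never).

**OS association.** Index at first palliative line; separate models per
document kind with progression/response time-varying covariates plus cancer
type.

**TMB analysis.** Every palliative ICI line is an observation indexed at
its start; the event is PFS-I-and-M. Cox models treat TMB continuously and
dichotomized at 20 mut/Mb, adjust for cancer type and line number, and
cluster on patient. KM PFS curves are unadjusted and *not* left-truncated
(progression can be documented before genomic testing); OS medians are
left-truncated at NGS.

**Censored correlation.** The PFS–OS correlation uses a Gaussian copula
over normal scores: each margin's distribution function is the
Kaplan–Meier estimate; an event time maps to the probit of the midpoint of
its KM jump (reducing plug-in bias), a censored time to the probit of
F(t) as a lower bound on the latent score. The likelihood combines the
copula density (both events), conditional normal tails (one censored), and
bivariate normal orthant probabilities (both censored); ρ is estimated by
bounded maximization on the Fisher-z scale, with the CI from the numerical
observed information at the optimum, transformed back. Degenerate inputs
(< 10 pairs, no events on an axis, all pairs doubly censored) raise.

## Validation design and problem sizes

The validation studies run at desk scale, chosen to keep the complete suite
on one CPU within tens of minutes: discrimination on a 1000-patient corpus
(≈30k documents; six ensembles of ten members each); leave-one-type-out
retraining demonstrated on one cell (imaging progression, breast excluded);
the survival-association chain scoring a fresh 2000-patient cohort with the
trained ensembles; TMB recovery at ≈1500 ICI lines; calibration studies
(null TMB, null chain, correlation coverage) at 100 replicates each with a
reduced four-type cancer mix so every cancer-type dummy stays estimable at
small n. Replicate-based checks use a 93/100 CI-coverage bar for nominal
95% intervals.

## Numerical and degenerate-input choices

Durations are day-resolution; months are days/30.44 exactly. Padding
embeddings are frozen at zero and excluded from gradients; documents
shorter than the widest convolution are padded up. CSV readers use
round-trip float parsing so write∘read∘write is byte-identical. The
trajectory simulator is event-driven over piecewise-constant intensity
segments (competing exponentials with re-sampling at deterministic rate
breakpoints — valid by memorylessness). Cox fits drop constant design
columns before fitting; non-convergence surfaces as an error with the
lifelines diagnostic attached.

## Known limitations

* Template text with disjoint cue vocabularies is far easier than clinical
  prose; absolute AUROCs here say nothing about real-world performance.
* The latent three-state model has no measurement error beyond label flips
  and no inter-annotator disagreement structure.
* The copula correlation assumes the latent dependence is bivariate
  normal after marginal transforms; margins estimated by KM ignore the
  uncertainty of that first stage in the CI.
* Site-outcome models share the machinery of the core outcomes and are
  exercised in unit tests, but the shipped validation studies train only
  the three core outcomes per document kind.
* The left-truncation design assumes the NGS date is error-free and that
  eligibility is fully captured by testing; competing risks are out of
  scope.
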