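# Methods

## Outcome construction

Pain observations arrive as numeric NRS values in [0, 10] or as one of six
text categories mapped to the even values: "no pain" 0, "mild pain" 2,
"moderate pain" 4, "severe pain" 6, "very severe pain" 8, "worst possible
pain" 10. Matching is case-insensitive and trimmed; numeric values supplied
as text (EHR exports mix types) are parsed as numbers first; anything else
is a hard conversion error, surfaced per row in the readers' rejects file
rather than silently dropped. The outcome for day *d* ∈ {0..4} (day 0 = day
of surgery; day boundaries are calendar-day offsets) is the maximum over
that day's numeric and converted values; days with no observation are
flagged unavailable and masked from loss and metrics. Moderate and severe
pain are *strictly* above 4 and above 6 respectively. Cohort exclusions:
intraoperative death, immediate ICU admission, and no pain observation
anywhere in days 0–4 (the operationalization of "at least one recorded
pain score"); each exclusion is logged with its reason.

## Dictionary and features

A code enters the dictionary iff it appears in at least `min_frequency`
(default 10⁻⁴, i.e. 1 in 10,000) of records, counting each record once
regardless of within-record repetition. Indices are 1..V in descending
record frequency with lexicographic tie-break; 0 is the pad index. A
record's indexed set is padded/truncated to `max_set_size` (default 130);
when a record exceeds it, the lowest-frequency codes are kept, on the view
that rarity proxies specificity — the common codes dropped first carry the
least patient-specific information. Structured features are z-scored with
training-split means/SDs (missing continuous values imputed with training
medians) and one-hot encoded against training vocabularies with a trailing
other/unknown slot; normalization statistics never touch validation or
test data.

## Network

Embedding table (V+1) × d with the pad row pinned to zero; masked
multi-head scaled-dot-product self-attention (additive −10⁹ logits on pad
keys, so exclusion is exact and padding-invariant); head outputs
concatenated and linearly mixed; mean pooling over *present* positions
only (pooling over all 130 slots would make the embedding depend on the
amount of padding); concatenation with the feature vector; ReLU
feed-forward layers; five linear outputs. Binary objectives apply a
logistic link; continuous predictions are clamped to [0, 10] at inference
only, keeping training gradients unbiased. Defaults follow the reference
design where it is explicit (d = 256, 130 slots, batch size 128) and are
otherwise our own choices, all configurable: 4 heads, hidden widths
(256, 128), ReLU, dropout 0.1, no residual connections, no positional
information of any kind. With one code present the attention distribution
is the point mass, and the set embedding is that code's attended
representation; with no codes present the set embedding is the zero vector
— patients with no in-dictionary codes remain scorable rather than being
errors.

The implementation is NumPy with hand-written reverse-mode gradients,
verified against central finite differences in the test suite (worst-case
scaled error below 10⁻⁶ at the checked coordinates). The embedding pad row
is excluded from gradient updates.

## Training

Splits are uniform at random into 81/9/10% train/validation/test (floor
allocation, remainder to the largest part, seeded). The training split —
and only the training split — is augmented by duplicating every patient
who carries CPT codes with those CPT codes removed; this exposes the model
to realistic no-procedure inputs instead of only the rare patients whose
procedures fall outside the dictionary, which stabilizes the estimated
contribution of CPT codes. Optimization is mini-batch Adam (batch 128,
learning rate 10⁻³ by default, final partial batch kept); the objective is
masked MSE or masked binary cross-entropy, normalizing by the number of
available (patient, day) cells so unavailable days contribute exactly
nothing. The output bias is initialized to the per-day training-target
mean (logit of the event rate for binary objectives), so the starting
model is the population-mean predictor and optimization only has to learn
structure on top of it. After each epoch the masked validation loss is
computed; the best-epoch weights are kept and training stops after
`patience` (default 5) epochs without improvement. Runs are exactly
reproducible given the seed. "One model per objective": continuous,
binary@4 and binary@6 are separately trained models sharing the
architecture, not a joint loss.

## Interpretability

The effect of code *c* on patient *p* is Δ(c, p) = ŷ(p) − ŷ(p − {c}), two
forward passes on otherwise identical inputs, positive meaning the code
raises predicted pain. Point estimates come from the primary model;
uncertainty comes from B models refitted on nonparametric bootstrap
resamples of the training patients (resample with replacement to the
original size, then augment, then fit, each member with its own derived
seed), summarized by percentile intervals with linear interpolation
between order statistics. A per-day effect is flagged significant when its
interval excludes zero. What the original analysis bootstrapped for its
CIs is not something we can know from the outside; resampling the training
patients is our choice, and it propagates both sampling and refitting
variability. Attention weights are the post-softmax attention paid to each
code, averaged over heads and present query positions; they are
nonnegative and sum to 1 within a patient. All of this is associational:
collinear codes can share or swap importance, and deltas are not causal
effects.

## Validation statistics

- **AUC** is the Mann–Whitney probability with ties at ½, computed from
  midranks, and is tested against exhaustive pair counting.
- **DeLong's test** for paired AUCs uses placement values via the midrank
  identity; its variance is cross-checked against a leave-one-out
  jackknife and its type-I error verified by simulation.
- **RMSE comparison** applies the Wilcoxon rank-sum test to the two
  samples of per-patient squared errors — deliberately reproducing the
  published procedure even though the data are paired; a paired
  signed-rank alternative sits behind `paired=True`.
- **Williams' test** compares two dependent Pearson correlations sharing
  the outcome variable, n − 3 degrees of freedom.
- **Calibration**: O/E = observed event rate / mean predicted probability;
  the intercept is estimated with the slope fixed at 1 (logistic model
  with offset logit p̂), then the slope estimated freely — the standard
  two-step recalibration report. For continuous predictions the analogue
  (mean residual; least-squares slope; mean observed / mean predicted) is
  an extension and flagged as such in the output. Constant predictions
  are flagged, not silently given slope 0.
- **Bootstrap CIs** resample at the patient level (all of a patient's days
  move together, respecting within-patient correlation); resamples on
  which a metric is undefined (e.g. single-class AUC) are redrawn and
  counted.
- **Power analysis**: the required n for a paired signed-rank comparison
  of two residual-magnitude distributions is found by bracketing plus
  binary search, estimating power at each candidate n by Monte-Carlo
  (default 2,000 replicates). On normal shifts it lands near the paired-t
  closed form inflated by π/3, the inverse of the signed-rank ARE under
  normality. Identical distributions raise rather than returning a
  pseudo-answer.

## Synthetic cohorts

The generator plants known structure in records with the same shape as a
perioperative EHR extract. Defaults are anchored to published cohort
descriptives: baseline daily mean maximum pain (5.2, 5.3, 5.5, 5.2, 5.2),
~9% of observations as pain strings, ~4 observations per in-hospital day,
ICU-admission rate 0.068, intraoperative death rate 1.7 × 10⁻⁴, age
55.9 (17.0) years, weight 81.4 (24.5) kg, height 1.69 (0.11) m, and the
published sex/race/service/urgency marginals. Quantities with no published
anchor are fixed once at plausible values: Zipf exponent 1.1 over each
code family, 6 codes per patient on average (one procedure code plus
Poisson comorbidities drawn without replacement), latent-pain noise SD 1.5,
observation noise SD 1.0, geometric discharge hazard 0.35/day (an optional
logistic coupling lets higher latent pain prolong stay; off by default).
Latent pain is baseline + planted additive code effects + linear effects
of standardized age and preoperative pain + Gaussian noise, clamped to
[0, 10]; observations are noisy draws around it, a configured fraction
rendered as strings by rounding to the nearest even value and inverting
the six-category map (exactly invertible, by design, for testing).

What the simulator does *not* emulate: real ICD-10/CPT ontology structure,
inter-code correlation beyond Zipf co-occurrence, informative missingness
within a day, site effects, or drift over time. Passing recovery tests
therefore shows the machinery is correct — planted additive effects are
recovered, ranking surfaces informative codes — not that comparable
performance would be achieved on real EHR data.

## Problem sizes

Tests and the acceptance script run desk-scale configurations chosen as
the package's own defaults for simulation studies: cohorts of 300–2,000
patients, a 200-code universe, 32-dimensional embeddings with a 20-slot
set size, and 40-epoch training budgets; statistical simulations use
2,000 null replicates (DeLong), 500 coverage replicates (bootstrap), and
n = 20,000 (calibration). The architecture defaults remain the reference
256/130 design; nothing in the code depends on the smaller sizes.

## Known limitations

Attention weights are a heads/queries average; alternatives (max, rollout)
are out of scope. The point-estimate delta can fall outside the ensemble
CI for weakly trained models, since they come from different fits — the
separation is deliberate and documented above. Opioid-exposure history and
ASA status are not model inputs by default (the default variable list
omits them); the feature schema accepts extra fields if a cohort provides
them. Hospital-specific retraining is achieved by running the pipeline on
cohort subsets, not by dedicated code.
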