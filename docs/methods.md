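# Methods

This note documents the models, the synthetic-data mechanism, the numerical
choices and the known limitations of the package. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Data model and inclusion criteria

The unit of prediction is one ICU encounter. All times are real-valued
hours since ICU admission; de-identified extracts carry no reliable wall
clock, and every downstream quantity (hourly grid, prediction hours,
evaluation alignments) is hour-indexed anyway. An encounter enters the
analysis if the patient is at least 18 years old, the ICU stay lies in the
closed interval [4 h, 720 h] ("between 4 hours and 30 days" read as
inclusive, the ordinary English convention), and the stay has at least one
mean-arterial-pressure measurement plus at least one PaO2 or SpO2
measurement. Two patient-level de-duplication modes support sensitivity
analyses: keep only each patient's first stay, or drop multi-stay patients
entirely (encounter ids order stays within a patient, since the CSV schema
has no absolute admission time).

The outcome is in-hospital mortality; discharges to hospice with death
within 7 days of hospital discharge count as mortalities. A hospice
discharge with an unknown death date is labelled a non-mortality — the
conservative choice — and logged for audit.

### Channels

Fourteen hourly channels: MAP, FiO2, PaO2, SpO2, GCS, urine output,
platelets, bilirubin, creatinine, four vasopressor dose rates (dopamine,
dobutamine, epinephrine, norepinephrine) and mechanical-ventilation status.
Thirteen of these feed the SOFA score; SpO2 rides along because it is the
usual respiratory measurement when PaO2 is absent. Raw events may also
carry `o2_device`/`o2_flow`, which exist only to impute FiO2. The 84
aggregate features of the conventional-ML baseline are 6 statistics × all
14 channels.

## 2. Preprocessing

Order of operations per cohort: FiO2 imputation → outlier removal → hourly
resampling → gap filling → normal-value imputation.

- **FiO2 imputation.** Where FiO2 was not charted, oxygen device + flow
  observations are converted with a configurable table
  (`fio2_table.yaml`): room air → 21%; nasal cannula → 21 + 4·flow, capped
  at 45%; simple mask → 35–60% by flow; non-rebreather → 80%; ventilator
  and high-flow systems chart FiO2 directly and pass through. Estimates are
  clamped to [21, 100].
- **Outlier removal.** Expert-style valid ranges per variable
  (`cleaning_rules.yaml`; the clinical-variable bounds follow the cohort
  summary minima/maxima, e.g. MAP (1, 300), GCS (3, 15)), then a modified
  Z-score screen `0.6745·(x − median)/MAD > 3.5` (Iglewicz–Hoaglin)
  computed per variable across the cohort, applied to continuous labs and
  vitals only — not to bounded ordinal, dose or flag channels. When MAD is
  zero the standard mean-absolute-deviation fallback
  `(x − median)/(1.253314·meanAD)` is used; with zero spread the screen is
  skipped.
- **Resampling.** Hour `h` covers the left-open interval `(h−1, h]`
  (events at offset exactly 0 land in hour 1); multiple in-window values
  are averaged — except urine, which is **summed**, because it is a volume
  and the renal SOFA component needs conserved 24-h totals; a per-hour mean
  would corrupt them.
- **Gap filling.** Forward fill for vitals and labs; zero for vasopressor
  rates and ventilation status (absence of a rate means "off"). Remaining
  cells — leading hours, or variables never measured in the stay — receive
  configurable clinically normal defaults (`normal_values.yaml`: MAP 80,
  FiO2 21, PaO2 95, SpO2 98, GCS 15, urine 100 mL/h, platelets 250,
  bilirubin 0.6, creatinine 0.9, doses 0).
- Every cell carries a provenance flag (`measured_mean`, `forward_filled`,
  `zero_filled`, `normal_imputed`); grids are complete by construction.
  GCS is rounded to an integer in [3, 15] and ventilation thresholded to
  {0, 1} after averaging.

The shipped cleaning ranges, normal values and FiO2 device map are
explicit stand-ins for institution-specific tables and are meant to be
replaced via the YAML configs for any real deployment.

## 3. SOFA scoring

Components are scored from trailing-24h worst values, recomputed at every
hour (windows shorter than 24 h early in the stay use all available
hours). Worst directions: minimum for MAP, PaO2/FiO2 ratio, platelets,
GCS; maximum for bilirubin, creatinine, doses; urine is the window total
scaled to a 24-h equivalent (so hour 3 of a stay is not spuriously
oliguric); ventilation counts if present anywhere in the window. The
PaO2/FiO2 ratio is formed per hour and then minimized.

Thresholds (`sofa_thresholds.yaml`) are a transcription of the original
SOFA definition: respiratory ratio cuts 400/300/200/100 with scores 3–4
requiring respiratory support (ventilation being the only support indicator
among the channels — an unsupported ratio below 200 scores 2); platelet
cuts 150/100/50/20; bilirubin 1.2/2.0/6.0/12.0; cardiovascular MAP < 70 or
dose tiers (dopamine ≤5 / >5 / >15; any dobutamine ≥ 2; epinephrine or
norepinephrine ≤0.1 → 3, >0.1 → 4 µg/kg/min); GCS bands 15 / 13–14 /
10–12 / 6–9 / <6; renal creatinine 1.2/2.0/3.5/5.0 or 24-h urine
<500 / <200 mL. An SpO2/FiO2 fallback for stays with no PaO2 at all is
implemented but **off by default** — there is no published SOFA cut set
for it; the shipped cuts are literature-style equivalents and clearly
optional.

A brute-force rescorer (window rescan with independently hand-coded
thresholds) lives in the test suite and the acceptance script; the
vectorized implementation must match it exactly.

## 4. Baselines

- **Bedside SOFA**: current total → band probability. The shipped band
  table (`bedside_table.yaml`) is a **synthetic placeholder** — monotone,
  width-2 bands — because the published score-to-mortality table is not
  reprintable here; it is annotated as such and config-driven. Band lookup
  only coarsens the total, so its AUC can never exceed Traditional SOFA's;
  this ordering is machine-checked.
- **Traditional SOFA**: the raw total as the ranking statistic (no refit);
  the retrospective-AUC reading is the only one consistent with the two
  SOFA baselines differing at all.
- **Aggregate-feature models**: logistic regression (standardized) or
  random forest on the 84 causal statistics over hours `1..h`,
  re-predicted every hour; training subsamples every 4th hour row by
  default purely for fitting cost.

## 5. Sequence model

`DeepSofaClassifier` — GRU (default: 1 layer, hidden 32) over per-channel
z-scored inputs (statistics fitted on training data and persisted with the
checkpoint), additive-attention head (dim 16), prediction head on
`[h_t ; c_t]`. Additive (tanh) scoring with the current hidden state as
query is the conventional choice satisfying the stated constraints (causal,
column-normalized); any head honoring the trajectory invariants would do.
Causality is architectural — at hour `t` nothing after `t` enters the
computation — and is verified by mutation tests rather than assumed.

Training: per-hour binary cross-entropy with the stay label broadcast to
every in-stay hour; padded hours are masked out, and each stay is weighted
inversely to its length so that one 700-hour survivor does not out-vote
twenty short stays. Adam (lr 1e-3), batches of 32 bucketed by length,
dropout 0.1 on GRU outputs, training sequences truncated to the first 120
hours (inference always runs full stays). Model selection and early
stopping (patience 5) use the validation AUC **averaged over the hourly
carry-forward curve** on a stratified 15% split: a single final-hour AUC
on a split with ~20 deaths proved noisy enough to select badly
under-trained weights, while the curve average tracks held-out performance
and is exactly the statistic the evaluation protocol reports. Training is
deterministic given the seed (fixed init, fixed batch order, seeded
dropout).

The organ-system channel subsets (`channel_subset="cns"` trains on GCS
alone, etc.) reproduce the per-system model variants.

## 6. Synthetic cohort

The simulator is a test bed, not a patient model. Per encounter, six
latent organ severities follow a mean-reverting AR(1) process
(ρ = 0.95, innovation sd 0.18) around a patient baseline (N(−0.45, 0.55))
plus a per-patient linear trend (N(0, 0.012)/h). Death in the ICU fires at
the first hour `t > 5` where a Bernoulli draw with
`logit p = −7.70 + 2.2 · mean severity` succeeds, truncating the stay
there; survivors keep a log-normal planned stay (median 69.6 h,
log-sd 1.0, clamped to [5, 719] h so every stay passes the inclusion
filter). A post-ICU logistic draw on discharge severity adds in-hospital
deaths after ICU discharge; ~2.5% of live discharges become hospice cases
with a death delay uniform on [0, 14] days (5% with the date missing), so
the 7-day labelling rule is exercised in both directions.

Channels are fixed monotone maps of their organ's severity plus noise
(multiplicative log-normal for labs, additive Gaussian for vitals, GCS
rounded into [3, 15]); each is subsampled at its configured median
interval with exponential gaps and per-stay missingness matching the
target cohort's structure (urine ~1 h / 3%, bilirubin ~24 h / 48%,
creatinine ~15 h / 5%, PaO2 ~4 h / 45%, MAP and SpO2 hourly / 0%, GCS
every 3 h). Vasopressors switch on above cardiovascular severity 1.28
(~18% of stays), ventilation above respiratory severity 0.85 (~31%); about
a third of encounters chart oxygen as device + flow events instead of
FiO2, exercising the imputation path. The hazard intercept −7.70 was set
by bisection against the 10.4% labelled-mortality target at n = 3,000–4,000
over several seeds and then frozen; the two thresholds were chosen the
same way against their target fractions.

What the simulator does **not** emulate: inter-variable correlation beyond
the shared severity factor, measurement batching (labs drawn together),
circadian patterns, treatment feedback (therapy lowering severity), or
informative missingness. Passing tests on this cohort therefore
demonstrate that the pipeline, scoring, training and evaluation machinery
behave as specified and that the sequence model can exploit temporal
signal where it exists — they say nothing quantitative about real ICU
performance.

## 7. Evaluation protocol

Predictions are issued at every hour from 1 to ICU discharge or death.
The hourly AUC curve is computed under two alignments: hours since
admission, with ended encounters contributing their final prediction
(carry-forward — the evaluated cohort is identical at every hour), and
hours before discharge/death (hour `k` uses the prediction at
`max(1, T−k)`). Confidence intervals are percentile bootstrap over
encounters with 100 resamples at level 95%; hours where a resample or the
point estimate is single-class are skipped with a warning, never imputed.
Model comparison is a paired bootstrap — the same encounter resample is
applied to both models per iteration — with a two-sided p-value from the
tail mass of the difference distribution crossing zero; the protocol's own
"p < 0.05" leaves the test unspecified, and the paired bootstrap is the
choice consistent with the surrounding CI machinery. AUC itself is the
tie-corrected rank statistic (scikit-learn's `roc_auc_score`), checked
exactly against O(n²) pair counting.

Cross-validation partitions encounters (not patients) into 5 folds,
refolding with a new seed if a fold is single-class; each encounter is
predicted exactly once by the model that held it out. External validation
trains on the entirety of one cohort and tests on the other; baselines
need no training and are applied to the identical test encounters;
normalization statistics always come from the training cohort.

## 8. Problem sizes and numerical choices

The default study runs in the tests and the acceptance script use a
2,000-encounter evaluation cohort and a 1,500-encounter training cohort
(~15 epochs with early stopping), sizes at which the full pipeline
completes in a few minutes on one CPU while leaving the qualitative model
ordering stable across seeds. Attention archives are written as `.npz`
keyed by encounter id. Probabilities are clipped only inside the logistic
(|logit| ≤ 60); BCE uses an epsilon of 1e-7; attention softmax subtracts
the column maximum. Ties in band lookups are resolved by construction
(bands tile 0..24 exactly once, validated at load).

## 9. Known limitations

- The Bedside band table and the expert cleaning/normal-value/FiO2 tables
  are documented stand-ins; results involving their absolute values (not
  orderings) should not be quoted.
- The SOFA threshold table is a transcription of the original definition
  and should be reviewed against it before clinical use of any kind.
- The numpy implementation trains small models fine but is not a GPU
  framework; hidden sizes beyond ~128 or cohorts beyond ~10⁴ stays will be
  slow.
- Simulated performance numbers are properties of the simulator's
  mechanism, not of any real ICU population.
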