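# Methods

## The pipeline in one paragraph

`synlhs` simulates a data-centric learning health system for disease-risk
screening. A synthetic EHR generator produces per-domain coded event tables
for populations of adults (30–90 years); all events collapse into a uniform
longitudinal record stream; per-patient profiles compress that stream
asymmetrically for cases (pre-diagnosis latest values) and controls
(age-windowed mode/mean); a sparse patients × codes table is balanced,
categorized and reduced to frequently occurring variables; classifiers are
trained and tested on disjoint splits; and a cycle driver repeats the whole
build on accumulating data to measure how performance grows with data volume.

## The synthetic-EHR generator

### What it emulates

The generator reproduces the *shape* of a Synthea CSV export — eight domain
tables, SNOMED-CT-style condition codes, LOINC-style observation codes with
values and units, encounters grouping same-day events — plus a controllable
risk signal. It deliberately does not re-implement Synthea's state-machine
disease modules, geography, payers or care plans.

### Population and history

Ages are uniform on `[min_age, max_age]` (default 30–90; screening populations
are adults aged 30 or older). Each patient has an event history covering at most
the configured calendar span (default 1990–2020) and at least 5 years,
starting no earlier than age 25. Nuisance events arrive at
`events_per_patient_year` (default **3.6 coded events/patient-year**), with
the planted screening observations (one to three records each for ~16
high-coverage codes) on top.
This density was calibrated once so that the "keep controls with ≥ 100
distinct shared codes" balancing rule reproduces a post-balance positive
share of ≈ 25%, the figure such case-control balancing reaches in practice.
Density and code-popularity together determine how many controls survive
balancing; they are study conditions, not free parameters of the tests.

### Vocabulary

760 nuisance codes partitioned over the seven event domains; numeric
observations carry per-code Normal value distributions and units, categorical
observations draw from small per-code category pools, and all other domains
record presence. Popularity follows a Zipf-like law (`weight ∝ (rank+3)^-0.85`)
so patient-occurrence counts span the variable-selection cutoff. The
vocabulary is a fixed deterministic function of its size — part of the
schema, not of any random draw.

### Planted risk structure

Disease status follows a logistic model over binary exposures:
smoking status, cigarettes/day, FEV1/FVC, COPD, chronic bronchitis, family
history, occupational exposure, alcohol use, vitals, lipids, HbA1c,
creatinine, and the indicator age ≥ 50. Most risk lives in pairwise and
three-way **synergies** (smokers over 50, smokers with COPD, combined
metabolic exposures …): main-effect coefficients are 0.5–1.0 log-odds,
interaction terms 1.5–3.5. Two consequences are intended. First, tree
ensembles — which model interactions natively — outperform isotropic
nearest-neighbour methods, while random subspacing (random forest) still
finds signal because many common codes are informative. Second, rare
synergy subgroups (0.5–2% of patients) are unlearnable from a few hundred
training rows but learnable from a few thousand, which is precisely the
mechanism by which accumulating data keeps improving the model.

Exposure indicators are drawn independently per feature (no exposure
correlation matrix); the risky/benign *values* of the screening observations
(e.g. systolic BP ~ N(155, 10) vs N(118, 12)) carry the signal into the
value-conversion stage. The working intercept is re-calibrated by
root-finding at generation time so the mean case probability equals the
configured prevalence (lung cancer 0.037, stroke 0.13); labels are then
Bernoulli draws. With the default coefficients the planted structure's
ranking ceiling (AUC of the true score) is ≈ 0.96–0.98 — the
near-deterministic regime that strongly separable synthetic EHR data
exhibits. `noise_sd = 0` switches to a fully deterministic regime (cases are
exactly the patients above the (1 − prevalence) score quantile), which makes
case status a function of the planted exposures; this is the regime used to
verify that the signal ceiling is reachable (a depth-limited tree attains
recall 1.0).

### Case timing

A case's diagnosis falls uniformly in the last third of their history, so at
least two-thirds of their records — and every planted risk-factor event,
placed in the first two-thirds — precede it. This guarantees non-empty
pre-diagnosis profiles by construction; patients that nevertheless end up
empty are dropped and counted.

## Standard data

One record per source event, nine fields, no terminology mapping. Ties at
identical (patient, time) keys keep the canonical domain order (conditions,
observations, procedures, medications, immunizations, allergies) via stable
sorting, making "latest value per code" deterministic. Non-observation
domains have no measured value and carry the categorical value `present`;
the `status` field defaults to `final`. Timestamps are naive UTC at second
resolution, written as ISO-8601.

## Profiles

*Final diagnosis* is read as the **first** occurrence of any target-disease
code: every feature record must strictly precede it, and the disease codes
themselves never enter the feature space. The stricter reading avoids
leaking post-onset care into the features. Case profiles are **not** age
windowed; the 30–70-year window applies to controls only, whose age is the
age at the last in-window record. Compression rules: latest value per code
for cases (stable tie-break: last in sort order); per-code mode for
categorical and mean for numeric control data (mode ties break
lexicographically). Every profile gains a pseudo-code `age` (numeric, years)
so age can act as a model variable. Population-scale profile construction is
a vectorized groupby pipeline verified against the single-patient reference
functions and against brute-force oracles.

## ML table

The feature space is the intersection of case and control codes, ordered by
descending patient count. Cells hold raw profile values; missing stays
missing (gradient boosting handles it natively; other algorithms receive a
dedicated missing level or all-zero indicator group). Balancing keeps every
case and only controls with ≥ 100 distinct non-missing shared-code variables
("distinct codes" is the deterministic reading of "at least 100 standard
data or codes" on a compressed profile). Conversion maps continuous columns
onto named clinical bins with ≥-semantics at breakpoints (age < 50 / ≥ 50;
total cholesterol < 200 mg/dL "normal"; systolic BP 140 mmHg; fasting
glucose 126 mg/dL; FEV1/FVC 0.7; BMI 30). Unmapped numeric columns get a
median split with a warning. Variable selection keeps codes occurring in at
least `patient_count_cutoff` patients of the table it is given (the balanced
table in the pipeline), sorted by occurrence, optionally truncated to the
top `n_top`.

## Modeling

Splits are stratified 70/15/15 by default (train/validation/test are the
three named subsets; the fractions are this package's choice); the validation set is held out and
unused by base models — gradient-boosting early stopping against it exists
but is off by default. Encoders are fitted on training rows only: ordinal
with missing/unseen → −1 for the tree ensembles, standardized one-hot with
missing as an all-zero group for SVM and k-NN. "Base model" means library
default hyperparameters throughout. Metrics are computed from confusion
counts at the fixed probability threshold 0.5, AUC from the full score
ranking; accuracy is reported for completeness, but it is
majority-class-dominated on imbalanced data and should not drive
comparisons. Reliability curves use 10 equal-width probability bins; the
summary statistic is the maximum |observed − predicted| over non-empty bins.
Grid search is exhaustive with stratified k-fold CV (default tenfold) and an
AUC objective; single-class folds score NaN rather than aborting.

## Learning-cycle simulation

Each cycle adds one independently generated batch (distinct derived seed),
rebuilds profiles/table/variables on the union of all data with the plan's
fixed cutoffs, retrains every algorithm **from scratch**, and evaluates on a
freshly drawn split — there is no warm starting and no frozen test set.
All randomness is derived from
`(base_seed, cycle_index)` via seed sequences, so a simulation is a pure
function of its plan. As an optimization, profiles are built per batch and
concatenated; because profiles are per-patient functions and batches hold
disjoint patients, this is exactly equivalent to rebuilding from the merged
record stream (asserted by a test). Hyperparameter tuning is available but
off inside cycles.

### Scaled study conditions

The full-scale protocol (30,000-patient batches, occurrence cutoff 500, five
cycles) is expensive; the package's scaled condition uses 5,000-patient
batches with the cutoff scaled proportionally (85), the balancing threshold
and age window unchanged, ten seed replicates, and the 50-variable model
protocol of the algorithm-comparison experiments. Under these conditions the
median gradient-boosting recall and AUC at cycle 5 are at or above their
cycle-1 values, the count of cutoff-passing variables grows monotonically, and k-NN has the lowest median recall of the four
algorithms. Single seeds may dip between adjacent cycles, as real learning
trajectories do.

## Overfitting demonstration

The package contrasts the base gradient-boosting model with one
*aggressively tuned for recall*: candidates upweight the positive class
(`scale_pos_weight` 4 or 6) and extend boosting to 300 rounds, and the
winner is chosen by 5-fold cross-validated recall — recall being the
deployment metric of a screening system. Positive upweighting inflates every
predicted probability, so the tuned model catches more cases at the 0.5
threshold while its reliability curve sags systematically below the
diagonal. An AUC-objective search cannot exhibit this trade-off here: the
planted task leaves the default booster fully converged, so added capacity
only costs test recall, and AUC is nearly invariant to the monotone shift
that upweighting induces. The comparison runs on a 30,000-patient population
with a 50/20/30 split because the max-deviation statistic needs a few
thousand test rows before systematic miscalibration separates from
sparse-bin noise.

## What the generator does not emulate

Real EHR properties deliberately out of scope: code co-occurrence structure
beyond the planted synergies, visit-level clinical coherence (a generated
encounter mixes unrelated codes), measurement drift and unit heterogeneity,
demographic confounding (exposures are independent of age except the age
feature itself, and of sex/race entirely), censoring and irregular
follow-up, and duplicate/erroneous coding. Passing tests therefore show that
the *pipeline* — transforms, compression, balancing, training, cycle
orchestration — behaves correctly and that the data-centric improvement
mechanism operates when risk is subgroup-structured; they do not show that
any trained model transfers to real patients, and the models are research
artifacts only.

## Numerical choices and degenerate inputs

Mode ties break lexicographically; latest-value ties by stable sort order;
variable-order ties lexicographically. Breakpoint boundaries bin upward
(≥ semantics). Intercept calibration uses Brent root-finding on
mean-probability − prevalence with |b| ≤ 60. Empty profiles, single-class
splits/folds/test sets, empty shared-code intersections, zero surviving
controls and zero passing variables all raise typed errors with context
rather than degrading silently. Derived seeds come from `SeedSequence` and
stay below 2³¹.
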