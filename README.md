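# synlhs

A simulated, machine-learning-enabled **learning health system** (LHS) built
entirely on synthetic longitudinal EHR data.

Hospitals that want ML-based risk prediction in preventive screening face a
bootstrap problem: the models need EHR data, but patient data cannot be shared
while the pipeline is being developed and the team trained. `synlhs`
demonstrates the full data-centric LHS workflow on generated patients:

1. **Generate** Synthea-schema synthetic populations (eight per-domain CSV
   tables: patients, encounters, conditions, observations, procedures,
   medications, immunizations, allergies) with a planted, configurable
   disease-risk structure (lung cancer and stroke presets).
2. **Standardize** every coded event into one uniform 9-field record stream
   (`patient_id, time, code, name, value, unit, datatype, encounter_id,
   status`), sorted by patient and time.
3. **Profile** each patient: cases get a patient-diagnosis-journey (PDJ)
   profile — the latest value per code strictly *before* the first diagnosis —
   and controls get a 30–70-year age-window profile (modal value for
   categorical codes, mean for numeric ones).
4. **Assemble** the ML table over the codes shared by cases and controls,
   balance it by keeping code-rich controls (≥ 100 distinct shared codes),
   convert continuous values to clinical categories (e.g. total cholesterol
   < 200 mg/dL → "normal", age < 50 / ≥ 50), and select variables by
   patient-occurrence cutoff.
5. **Train and evaluate** risk classifiers — an XGBoost base model with
   library defaults, plus random-forest, SVM and k-NN comparators — reporting
   recall (the screening metric), precision, AUC, accuracy and reliability
   curves.
6. **Simulate learning cycles**: add a fresh patient batch, rebuild
   everything on the accumulated data, retrain from scratch, and watch the
   metric trajectory improve as data accumulates.

The planted signal is a logistic risk model over exposure indicators
`x_j` (smoking status, obstructive disease, blood pressure, age ≥ 50, ...):

```
P(case | x) = expit( b + Σ_j β_j x_j + Σ_{jk} γ_{jk} x_j x_k (+ 3-way terms) + ε ),   ε ~ N(0, σ²)
```

with the intercept `b` calibrated at generation time so the population
prevalence matches the configured target (3.7% for lung cancer, 13% for
stroke). Risk concentrates in subgroup synergies (e.g. smokers over 50 with
COPD), which is what lets tree ensembles keep discovering new high-risk
subgroups as the dataset grows.

## Worked example

```python
from synlhs import (PopulationConfig, LUNG_CANCER, generate_population,
                    to_standard_records, build_profiles)
from synlhs.ml_table import (shared_codes, build_table, balance, convert_values,
                             select_variables, positive_rate,
                             BalanceConfig, VariableSelection)
from synlhs.modeling import fit_and_evaluate, ModelSpec, SplitSpec

bundle = generate_population(PopulationConfig(n_patients=20000, seed=77))
records = to_standard_records(bundle)
targets, backgrounds, report = build_profiles(records, bundle.patients, LUNG_CANCER)
table = build_table(targets, backgrounds, shared_codes(targets, backgrounds))
print(f"pre-balance positive rate: {positive_rate(table):.3f}")
table = balance(table, BalanceConfig(min_shared_codes=100))
print(f"post-balance positive rate: {positive_rate(table):.3f}")
table = convert_values(table)
variables = select_variables(table, VariableSelection(patient_count_cutoff=85, n_top=50))
run = fit_and_evaluate(table, variables, ModelSpec("gbt"), SplitSpec(seed=0), seed=0)
print(f"recall={run.metrics.recall:.3f} precision={run.metrics.precision:.3f} "
      f"auc={run.metrics.auc:.3f}")
```

prints

```
pre-balance positive rate: 0.038
post-balance positive rate: 0.236
recall=0.646 precision=0.760 auc=0.943
```

Of 20,000 generated patients, 3.8% carry the lung-cancer label (the
configured prevalence is 3.7%); keeping only code-rich background patients
raises the positive share to 23.6% — close to the ~25% a real screening
case-control table reaches with the same rule. The base XGBoost model then
recovers most planted cases (recall 0.65 on held-out patients) with an AUC
of 0.94; both keep rising as more batches accumulate (see the simulation
below).

The continuous-learning simulation and the thin CLI:

```python
from synlhs import CyclePlan, run_simulation
plan = CyclePlan(population=PopulationConfig(n_patients=5000, seed=0),
                 n_cycles=5,
                 selection=VariableSelection(85, n_top=50), base_seed=1)
print(run_simulation(plan).trajectory.head())
```

```bash
synlhs generate --n-patients 5000 --seed 1 --outdir batch1/
synlhs transform --indir batch1/ --out standard.csv
synlhs profile --indir batch1/ --outdir profiles/
synlhs simulate --config plan.yaml --seed 1 --outdir sim/
```

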