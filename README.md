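# ugtphen

Probe-drug phenotyping of UGT1A1 activity from population pharmacokinetics
of oral raltegravir and its glucuronide.

## The problem

Irinotecan's active metabolite SN-38 is cleared by UGT1A1, and low UGT1A1
activity predicts severe neutropenia under FOLFIRI chemotherapy. Promoter
genotyping (UGT1A1\*28) works poorly in East Asian populations where that
allele is rare. An alternative is *phenotyping*: dose a safe probe drug
cleared by the same enzyme — raltegravir, glucuronidated by UGT1A1 — and
measure each patient's in vivo glucuronidation rate directly from the
parent and metabolite concentration–time curves.

`ugtphen` implements that analysis end to end for pharmacometricians and
clinical-pharmacology researchers:

* a **transit-compartment population PK model** of raltegravir and its
  glucuronide: gamma-density transit absorption (mean transit time `MTT`,
  a continuous number `NN` of compartments, `ktr = (NN+1)/MTT`), first-order
  absorption `ka`, one-compartment parent disposition (`CL/F`, `V/F`), and
  fractional conversion `FMET` to a glucuronide compartment of fixed 1 L
  volume with clearance `CL_GLU`;
* **nonlinear mixed-effects estimation** (FOCE/Laplace-type approximate
  marginal likelihood; log-normal inter-individual variability on six
  parameters with a CL–V correlation; additive residual error on log
  concentrations) with RSEs, empirical Bayes estimates, η-shrinkage, and a
  forward/backward stepwise covariate search (ΔOFV ≥ 3.84 in, ≥ 10.8 to
  stay);
* the **phenotyping constants** `k23 = FMET·(CL/F)/(V/F)` (UGT1A1 pathway)
  and `k12 = 0.6·CL/V` (CYP3A4 pathway via midazolam);
* **non-compartmental analysis** (linear-up/log-down AUC, automated
  terminal-slope selection, `CL/F = dose/AUC_inf`, metabolite/parent AUC
  ratios);
* the **statistical layer**: Pearson correlation, OLS (the neutrophil-nadir
  regression `ANC = 129.2 + 89461.5·k23`), Wilcoxon rank-sum and
  Kruskal–Wallis tests, and Fisher-z power for correlation designs;
* a **synthetic cohort generator** reproducing the 24-patient study
  structure (covariate ranges, genotype frequencies, sampling schedule,
  ANC calibrated to the published correlation of 0.598) so the full
  pipeline runs and is tested without any patient-level data.

See `docs/methods.md` for the model, its assumptions, and every numerical
design choice.

## Worked example

```python
import numpy as np
from ugtphen import DoseEvent, simulate_profile
from ugtphen.cohort import CohortConfig, default_population, generate_cohort
from ugtphen.association import pearson, correlation_power
from ugtphen.model_core import k23

pop = default_population()          # published final-model estimates
print(f"typical k23 = {k23(pop.theta):.6f} 1/h")

parent, metab = simulate_profile(pop.theta, [DoseEvent(0.0, 400.0)],
                                 np.array([0.5, 1, 2, 4, 6, 8, 24]))
print("parent mg/L:", np.round(parent.concentrations, 3))

cohort = generate_cohort(CohortConfig(n_subjects=5000), seed=7)
r = pearson(cohort.covariates["nadir_anc"], cohort.covariates["k23"])
print(f"r(ANC, k23) = {r.estimate:.3f}  (p = {r.p_value:.2e})")
print(f"power to detect r=0.6 at n=19: {correlation_power(0.6, 19):.3f}")
```

prints

```
typical k23 = 0.008606 1/h
parent mg/L: [0.296 0.989 1.675 1.246 0.742 0.437 0.006]
r(ANC, k23) = 0.593  (p = 0.00e+00)
power to detect r=0.6 at n=19: 0.792
```

`k23` is the phenotyping metric: the subject-level rate constant of
glucuronide formation, i.e. UGT1A1 activity in vivo. In the synthetic
cohort it correlates with nadir absolute neutrophil count at the
calibrated strength (0.593 ≈ the 0.598 target), and the Fisher-z power for
the study's design point (r = 0.6, n = 19, α = 0.05) is 79%.

## Command line

```bash
ugtphen simulate --seed 7 --out run1          # cohort + dataset bundle
ugtphen run --config config.yaml --out run2   # generate, fit, NCA, associations
ugtphen nca --dataset run1/dataset.csv --out run3
```

Every subcommand reads one YAML `RunConfig` (schema-validated, unknown keys
rejected); `--seed` overrides the config. Outputs carry the config hash and
seed, and two runs with the same config are byte-identical. Exit codes:
0 ok, 1 validation error, 2 runtime failure.

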