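# Methods

`ugtphen` implements a probe-drug phenotyping analysis for UGT1A1: a
population pharmacokinetic model of oral raltegravir and its glucuronide,
non-compartmental exposure summaries, the derived phenotyping constants,
and the statistical layer that relates glucuronide-formation rate to
chemotherapy-induced neutropenia. A synthetic-cohort generator reproduces
the statistical structure of the 24-patient study the analysis assumes, so
every stage runs and is testable without patient data.

## Structural model

Raltegravir absorption is delayed through a chain of `NN` hypothetical
transit compartments with mean transit time `MTT`. `NN` is continuous, so
the chain is realized analytically: the input rate into the absorption
depot is the gamma density

    input(t) = D·F·ktr·(ktr·t)^NN·exp(−ktr·t) / Γ(NN+1),   ktr = (NN+1)/MTT,

whose integral over `[0, ∞)` is exactly `D·F`. The depot empties into a
single central compartment at rate `ka`; the parent is eliminated with
apparent clearance `CL/F` from apparent volume `V/F`. A fraction `FMET` of
parent clearance forms the glucuronide, which is modelled directly in
concentration units against a distribution volume fixed to 1 L and cleared
with first-order clearance `CL_GLU`:

    dA_d/dt = input(t) − ka·A_d
    dA_c/dt = ka·A_d − (CL/V)·A_c
    dC_m/dt = FMET·(CL/V)·A_c/V_GLU − (CL_GLU/V_GLU)·C_m

Because `V_GLU ≡ 1 L` is a convention rather than a measurement, `FMET` is
a formation-rate-to-volume ratio; its literal "fraction" reading is
unit-dependent. No molecular-weight correction is applied between parent
and metabolite. Units throughout: hours, mg, litres, mg/L. Doses are at
`t = 0` by default and the pre-dose concentration is 0.

Everything downstream of the transit input is linear with constant
coefficients, so the system has an exact solution by partial fractions:
all states are linear combinations of convolutions of the gamma density
with single exponentials, `G_a(t) = ∫ g(s)·e^{−a(t−s)} ds`. `G_a` is
evaluated through the regularized lower incomplete gamma function
(`a < ktr`), Kummer's 1F1 (`a > ktr`, moderate argument), or an
integration-by-parts asymptotic series in log space (large argument); a
series limit handles `a ≈ ktr`. The implementation was validated to
~4·10⁻¹³ relative error against 60-digit arbitrary-precision quadrature
over wide random parameter ranges, and the default "analytic" simulation
path agrees with a stiff-capable numerical integrator (`LSODA`,
rtol 1e-10) to ~1e-8. Near-coincident rate constants are separated by a
relative nudge of 2e-7 to avoid catastrophic cancellation in the partial
fractions; this bounds the induced error at about the same order.

The phenotyping constants are `k23 = FMET·(CL/F)/(V/F)` for the
glucuronidation pathway and, for the CYP3A4 probe midazolam,
`k12 = 0.6·CL/V` with 0.6 the assumed midazolam-to-1-OH-midazolam
conversion fraction. Both are invariant under joint rescaling of clearance
and volume.

## Random effects and residual error

Six parameters carry inter-individual variability — `CL/F`, `V/F`, `MTT`,
`F`, `FMET`, `CL_GLU` — with the exponential model `p_i = θ·exp(η_i)`,
`η ~ N(0, Ω)`. Ω is diagonal except a single correlation between the
`CL/F` and `V/F` effects (default 0.57). IIV magnitudes are configured in
%CV; the default conversion is the exact log-normal relation
`ω² = ln(1 + (CV/100)²)`. At 30% CV this is indistinguishable from the
naive `ω = CV/100`, but at the bioavailability term's 124% CV the two
differ materially (ω 0.96 vs 1.24), so the convention is explicit, a
config switch, and recorded in every output. `F` has IIV around a fixed
typical value of 1 and sampled individual values are not capped at 1
(relative-bioavailability reading).

Residual error is additive on log concentrations (log-normal
multiplicative on the natural scale), one SD per analyte (defaults 0.15
parent, 0.18 glucuronide). Pre-dose and zero concentrations carry no
log-scale information and are excluded from all likelihoods; simulated
observations below a configurable quantification limit are flagged, not
silently dropped (limit 0, i.e. disabled, by default).

## Estimation

The mixed-effects estimator is a FOCE-style approximate marginal
likelihood. Per subject, the conditional mode of η minimizes the penalized
weighted sum of squared log residuals; the marginal likelihood is the
Laplace formula with either the Gauss-Newton curvature
(`method="foce_i"`, default) or a finite-difference Hessian
(`method="laplace"`). The OFV is −2 log L including all constants.
Agreement between the two curvature choices on rich data is ~1–2%
relative; exact numerical equality with any specific commercial
implementation is not a goal — statistical recovery of generating
parameters is the contract, and is what the acceptance experiment
measures.

Numerical design, all of which proved load-bearing at this model's very
large IIV (up to 124% CV):

* **Inner problem.** The conditional modes for the whole cohort are found
  by a vectorized Levenberg-Marquardt iteration (finite-difference
  Jacobians of the log-predictions, per-subject adaptive damping,
  backtracking Armijo search). Convergence is declared at first-order
  stationarity (`‖∇U‖∞ < 1e-4`), not at small progress: a
  progress-based stop makes the found modes a discontinuous function of
  the structural parameters and the outer likelihood surface becomes
  jagged. Converged subjects leave the working set so stragglers do not
  force whole-batch model evaluations.
* **Mode multimodality.** With large η variances the per-subject joint
  density can be multimodal, and a zero-started search occasionally lands
  in a shallow mode (worth tens of OFV points across a cohort, enough to
  visibly bias the fixed effects). The mode search therefore runs two
  deterministic starts side by side — η = 0 and the "anchor"
  η = log(p̂_i) − log(θ_i), where p̂_i are per-subject individual NLS
  estimates computed once per fit — and keeps each subject's deeper mode.
* **Outer problem.** Fixed effects and IIV SDs are optimized on the log
  scale and the CL-V correlation through atanh, so the outer problem is
  unconstrained. The driver is a damped-BFGS with Armijo backtracking:
  unlike Wolfe-based quasi-Newton drivers it needs only the (cheap)
  function value at line-search trial points and evaluates the gradient
  once per accepted iterate. Gradients are central finite differences
  (step 1e-5) over all free parameters, computed in one batched inner
  solve: the 2p perturbed problems are stacked along the subject axis and
  warm-started from the base point's modes, which by the envelope
  property of the conditional modes makes the differences first-order
  exact at a fraction of the naive cost.
* **Initialization.** `init_strategy="two_stage"` (the default in the
  shipped pipeline config) derives starting values from the individual
  NLS fits: geometric medians for θ, MAD-based spreads for ω, the
  empirical log CL-V correlation, and a pooled residual SD. Because
  individual `F` is not identifiable, its variability contaminates the
  CL/V/FMET spreads; half the smallest shared variance is reassigned to
  the `F` term so the starting point is not adjacent to a label-swapped
  local optimum in which `F`-variability is re-expressed as correlated
  CL/V/FMET variability. Multi-start (jittered 20% log-normally, default
  3 starts in the library API) remains available; the acceptance
  experiment uses a single two-stage start.
* **Standard errors.** RSEs come from the inverse finite-difference
  Hessian of the OFV at the optimum (covariance `2·H⁻¹`), reported as
  100·SE on the log scale (≈ SD/estimate); the correlation SE is
  delta-transformed. Empirical Bayes estimates and η-shrinkage
  (`100·(1 − SD(EBE)/ω)`, sample SD) are evaluated at the final
  estimates.

Failure to improve the OFV never raises: the fit returns best-so-far
results with a `"failed"` convergence flag.

## Covariate search

The stepwise procedure: greedy forward inclusion, admitting per round the
candidate with the largest OFV drop ≥ 3.84 (χ², p < 0.05) that also
reduces the affected parameter's unexplained IIV (ties break by larger
IIV reduction, then label); then backward elimination of any covariate
whose removal costs < 10.8 points (p < 0.001), weakest first. Candidate
forms: power `(cov/ref)^β` and linear `1 + β·(cov − ref)/ref` for
continuous covariates (ref = cohort median), fractional `1 + β` per
non-reference category for categoricals. Candidate fits are warm-started
from the current model. Candidates with missing covariate values are
excluded with a warning.

## Non-compartmental analysis

Default AUC rule is linear-up/log-down (linear trapezoid on rising or flat
segments, log trapezoid on strictly decreasing positive segments — exact
for mono-exponential decline); pure linear is a config option. The
terminal slope λz maximizes adjusted R² of the log-linear regression over
candidate terminal windows of ≥ 3 positive post-peak points, always
including the last; this automates what is a per-profile manual choice in
interactive NCA tools. `AUC_inf = AUC_last + C_last/λz` by construction;
`CL/F = dose/AUC_inf`. Zeros before the first quantifiable concentration
are kept for the AUC; log-down segments never span zeros. The
metabolite/parent AUC ratio prefers `AUC_inf` and falls back to
`AUC_last`, flagging which basis was used (which of the two the original
analysis used is not stated anywhere, so reports carry both).

## Association layer

Pearson correlation (two-sided t, n−2 df), OLS regression, Wilcoxon
rank-sum (exact null distribution up to 12 per group and no ties,
tie-corrected normal approximation otherwise), Kruskal-Wallis
(tie-corrected, χ² reference), and the Fisher-z power formula for
detecting a nonzero correlation. No multiple-testing adjustment is applied
anywhere (matching the analysis this package reproduces); the association
report prints raw p-values with an explicit note. Nadir ANC can be
analysed raw or log10-transformed; the pipeline config records which.

## Synthetic cohort

The generator emulates the study design: 24 subjects (default), one
400 mg oral dose, sampling at 0, 0.5, 1, 2, 4, 6, 8 and 24 h. Continuous
covariates are drawn uniformly within the published cohort's ranges and
genotypes from its class frequencies (UGT1A1*6 and *28: 17/7/0 of 24;
UGT1A1*60: 12/9/3; CYP3A5*3: 6/7/11; 19/24 male). Individual parameters
come from the population model above; profiles carry the configured
residual error.

Nadir absolute neutrophil count is generated from the published linear
relation `ANC = 129.2 + 89461.5·k23` plus Gaussian noise whose SD is
calibrated in closed form to a target correlation (default 0.598):
`σ = |slope|·SD(k23)·sqrt(1/r² − 1)`, with `SD(k23)` estimated by
Monte-Carlo from the population model (20 000 draws by default). This
noise model is a generative completion — only the fitted line and its
correlation are published — and two of its consequences are deliberate:
ANC stays on the arbitrary count scale of the published regression (its
units are not stated), and calibrated noise (SD ≈ 1000 on that scale) puts
a minority of draws below zero. A positivity floor exists but is off by
default, because truncation would distort the calibrated correlation that
downstream checks rely on.

A dose-delay indicator is drawn from a logistic model in standardized ANC
(slope −0.8 per SD, intercept set to the published 16/24 delay rate at
the median). The published delay contrast was not significant, so no
generative effect size is derivable; the mechanism is illustrative only.
Genotypes are independent of PK by default (the original analysis found no
genotype covariate); an optional knob injects a per-variant-allele FMET
multiplier for covariate-search power experiments. Covariate marginals
are sampled independently — no covariate-covariate correlation is
published — which is a known simplification relative to real cohorts.
Irinotecan/SN-38/SN-38G profiles for NCA exercises come from a simple
one-compartment + sequential-metabolite stand-in, labelled synthetic-only.

What passing tests on these cohorts show: that the pipeline's statistics
recover the generative structure they assume. What they cannot show:
robustness to model misspecification, assay artefacts, dropout, or
covariate correlation structures absent from the generator.

## Problem sizes and tolerances

The simulation-estimation experiment uses 100 subjects × 12 samples × 2
analytes per replicate and 5 replicates, a size at which the estimator's
sampling scatter is a few percent for well-identified fixed effects while
one replicate fits in about one to three minutes on a single core; the
per-fit budget is one two-stage start with 120 outer iterations plus a
25-iteration fresh-memory restart. Monte-Carlo calibration checks use
10⁴–2·10⁴ draws (sampling error ≲ 1% of the checked quantities). Oracle
tolerances: transit-input mass balance and closed-form limits at 0.1%,
AUC-ratio mass balance at 2%, trapezoid-vs-quadrature at 0.5%, type-I
error rates at ±0.01 absolute over 10⁴ replicates.

## Known limitations

* One-compartment parent disposition; no enterohepatic recirculation; no
  saturable glucuronidation; no inter-occasion variability; Ω covariance
  restricted to the single CL-V term.
* The FOCE-style objective is an approximation; its small-sample bias at
  very large IIV is mitigated (mode anchoring, exact-curvature option)
  but not eliminated.
* The ANC noise model and the dose-delay mechanism are generative
  completions, not published findings.
* Bootstrap confidence intervals, SAEM, and visual predictive checks are
  out of scope.
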