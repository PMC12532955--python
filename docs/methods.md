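# Methods

This note documents the statistical model behind `methyldx`, the parameter
choices that matter, and what the simulation-based tests do and do not
establish about real methylation data.

## Generative model of the simulator

For probe *j* and sample *i* the simulator draws

    beta_ij = logistic( mu_j + d_ij + eps_ij ),   eps_ij ~ N(0, noise_sd^2)

on the logit scale, where `mu_j` comes from a three-component mixture of
probe baselines (means −3, 0, +3 logits; weights 0.4 / 0.2 / 0.4) that mimics
the bimodal beta-value distribution of methylation arrays, and `d_ij` sums
the planted effects applicable to sample *i*:

* **RA-specific** probes add `delta_ra` for seropositive and seronegative RA;
* **shared-inflammation** probes add `delta_inflam` for every inflammatory
  group (RA, IBD, MS, sepsis) and `delta_inflam/2` for other arthritides, so
  RA-vs-arthritis discrimination is deliberately harder than RA-vs-healthy;
* **age** probes add `age_slope · (age − 45)` logits per year and **sex**
  probes add `sex_delta` for female samples (confounders for the EWAS);
* the four planted sets are disjoint; all remaining probes are null.

The logit-normal error keeps beta strictly inside (0,1) and makes the
M-value matrix (M = log₂ β/(1−β) = logit(β)/ln 2) exactly linear-Gaussian,
so the ordinary-least-squares EWAS is correctly specified under the
simulator and its p-values are exactly calibrated — a property the test
suite verifies by Kolmogorov–Smirnov tests on null t-statistics and by
family-wise error simulations.

Group sizes default to the multi-disease discovery design the package
emulates (354 seropositive RA, 521 healthy, 204 IBD, 52 MS, 17 sepsis);
ages are uniform within group-specific adult ranges, sepsis samples are
newborns (age 0) and are excluded from age-adjusted association models by
default. Seropositive RA samples draw ACPA⁺ with probability 0.87 and RF⁺
with 0.93, rejection-sampled so at least one marker is positive;
seronegative RA and all non-RA groups are negative for both. Two array
versions are modeled as probe masks: EPIC covers all probes, 450K a seeded
random 80% subset; samples carry an array version and harmonization
restricts to the probe intersection.

Defaults: `n_probes` 20,000 (a desk-scale stand-in for the ~450k–850k probes
of real arrays; pipeline-level tests use 2,000), `noise_sd` 0.5 logits,
`delta_ra = delta_inflam = 1.0`, `age_slope` 0.02/year, `sex_delta` 0.5.
With `noise_sd` 0.5 a delta of 1.5 corresponds to a per-probe standardized
effect of d ≈ 3 — an intentionally strong planted signal used by the
recovery tests; null-calibration tests set all deltas to zero.

What the simulator does **not** emulate: probe-type chemistry and dye bias,
background-correction artifacts, cell-type composition differences, batch
effects, and spatial/genomic correlation between CpGs (probes are
conditionally independent given covariates). Passing recovery tests
therefore demonstrates that the pipeline's inference machinery is correct
and leak-free under its own assumptions, not that comparable performance
would be achieved on real cohorts.

## Feature extraction

**EWAS.** Each probe's M-values are regressed on an intercept, the binary
case indicator and optional age and female-sex covariates; the case
coefficient is tested two-sided against t(n − k). The design matrix is
shared across probes, so the fit is a single QR solve. Probes with zero
residual variance are retained with p = 1 (rather than dropped) so probe
accounting is conserved. Family-wise error is controlled by Holm–Bonferroni
step-down at α = 0.05, implemented exactly as
adjusted₍ᵢ₎ = maxⱼ≤ᵢ min(1, (m−j+1)·p₍ⱼ₎) with rejection while
adjusted ≤ α; the test suite checks it against an independent
implementation and verifies it dominates Bonferroni.

**Stability selection.** B complementary pairs of disjoint, class-stratified
half-samples (default B = 50, i.e. 100 half-fits); on each half an
L1-penalized (`alpha_mix` = 1, configurable toward elastic net) logistic
path is fitted over a common decreasing λ grid on within-half standardized
features; π_j is the fraction of half-fits selecting probe *j*, maximized
over the path. The default grid spans one decade below λ_max in 10
log-spaced points — a deliberately sparse regime in which selection
probabilities separate signal from noise; a grid reaching far smaller λ
would let large numbers of null probes enter the path and inflate π
uniformly. Probes with π strictly greater than 0.1 pass; the final panel is
the union of the EWAS and stability sets with provenance flags.

## Penalized-logistic solver

The classifier requires an elastic-net logistic regression in which the
serology covariate is *unpenalized* while probe features are penalized —
per-feature penalty factors that scikit-learn's solvers do not expose. The
package therefore ships a small FISTA (accelerated proximal gradient)
solver (`methyldx._enet`) minimizing

    (1/n) Σ log-loss + λ Σ_j v_j ( α|w_j| + (1−α)/2 w_j² ),

with the ridge term folded into the smooth part, soft-thresholding as the
proximal step, a step size of 1/L from the exact logistic Lipschitz bound,
and warm starts along the λ path. Coefficients are exactly zero below the
soft threshold, which makes "selected" well-defined for stability
selection. Path fits use the sequential strong rule (screening features
whose gradient at the previous solution is below α·v_j·(2λ_k − λ_{k−1}))
with KKT verification of excluded features, so screened and unscreened
paths agree to solver tolerance (regression-tested). For uniform penalties
the solver matches scikit-learn's saga elastic net to ~1e−9 in the tests,
which keeps an independent reference implementation in the loop without
using it as the implementation.

## Classifier and cutoff

Hyperparameters are chosen by stratified k-fold CV (default k = 5) over
`alpha_mix` ∈ {0.1, 0.5, 0.9, 1.0} and 30 λ values log-spaced four decades
below the α-specific λ_max, maximizing the mean out-of-fold Mann–Whitney
AUC. Probe standardization parameters are computed inside each training
fold only — the CV never sees held-out statistics. Ties are broken toward
larger λ, then smaller α, which makes training deterministic given the
seed; the practical consequence, visible in the smoke tests, is that when
several grid points tie at the maximum AUC the sparsest qualifying model is
returned. Serology enters as a single unpenalized binary column (ACPA⁺ OR
RF⁺, with unmeasured serology counted negative); it cannot be shrunk away,
reflecting its deliberate inclusion alongside the methylation features. A
two-column variant is not provided; the combined encoding is the package's
choice. Age and sex can be supplied as extra covariates but are off by
default.

The continuous score s = logistic(w₀ + Σ w_j z_j + w_sero·sero) is
dichotomized at the Youden-optimal cutoff computed on training scores:
candidates are the midpoints of adjacent distinct scores plus the
all-positive boundary, the rule is "score ≥ c ⇒ RA", and ties are broken by
higher sensitivity, then smaller c.

## Evaluation

Sensitivity and specificity carry exact Clopper–Pearson intervals
(beta-quantile form; lower 0 at x = 0, upper 1 at x = n). This interval
form reproduces, at two-decimal rounding, all published interval pairs used
as worked examples in the test suite (e.g. 19/21 → 0.70–0.99,
22/25 → 0.69–0.97, 5/6 → 0.36–1.00, 11/14 → 0.49–0.95, 14/15 → 0.68–1.00),
which no Wald-type interval does. The AUC is the Mann–Whitney statistic
with half-credit for ties (equal to trapezoidal ROC integration, verified
against scikit-learn on tied data); its CI and the balanced-accuracy CI use
a class-stratified percentile bootstrap (default B = 2000, seeded). Score
comparisons use the pooled-variance Student's t-test; correlations are
gated by Shapiro–Wilk normality at α = 0.05 (Pearson if both variables
pass, Spearman otherwise). Display rounding is two decimals, half-up.
Balanced accuracy = (sensitivity + specificity)/2 holds exactly by
construction.

Quartile correctness reports the fraction of correct calls among the
⌊n/4⌋ lowest- and highest-scoring samples (at least one each) — a
readable summary of whether the extremes of the score are reliable.

## Pipeline

The discovery and modeling cohorts are distinct simulated datasets
(different seeds; discovery mixes 450K and EPIC samples and is harmonized
by probe intersection, modeling is single-array), reproducing the
two-dataset design and the harmonization step between array generations.
The modeling sheet is split ~4:1 into training and holdout within
diagnosis × sex × age-tertile strata; per-stratum training counts use
largest-remainder rounding against a total of round(frac·n), and singleton
strata go to training with a warning. Feature extraction uses discovery
samples only; the manifest records the config hash, all seeds, and an audit
that discovery/modeling and training/holdout sample sets are disjoint.
Rerunning an identical configuration reproduces `report.json`
byte-for-byte.

## Problem sizes in the tests

The shipped tests run at desk scale by design: 2,000 probes for
pipeline-level properties, cohorts of 200–440 samples, 200 replicate
cohorts for family-wise-error calibration, 10 seeds for the
recovery/specificity suites, B = 50 for stability selection. The
disease-specificity test uses a discovery cohort whose controls are
dominated by other inflammatory diseases (120 RA vs 80 IBD + 40 MS +
8 sepsis + 12 healthy): when controls share the inflammation signal, the
case-control contrast at shared-inflammation probes shrinks by the factor
(1 − inflamed fraction of controls), which is the design rationale for
multi-disease discovery controls. With healthy-dominated controls that
factor is large and shared probes remain epigenome-wide significant at any
usable sample size — an inherent property of a single case-vs-rest
contrast, not an implementation artifact.

## Known limitations

* No IDAT-level processing, background correction, normalization, probe
  annotation, cell-type deconvolution or batch correction; inputs are
  assumed to be cleaned beta matrices.
* The EWAS is a fixed-effects OLS on M-values; no mixed models, surrogate
  variables or genomic-control inflation adjustment.
* Stability selection exposes B, the λ grid and the mixing parameter but
  implements only complementary-pairs subsampling (no randomized-lasso
  weights, no theoretical error bounds).
* Score calibration (Platt/isotonic) is out of scope; the probability
  score is used only through its ranking and the Youden cutoff.
* All performance claims in the tests are conditional on the simulator's
  assumptions listed above.
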