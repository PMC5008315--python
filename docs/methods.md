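# Methods

`modsurv` implements a multi-study prognostic analysis of gene-expression
modules against distant-metastasis-free survival (DMFS) in breast cancer,
together with a synthetic cohort generator that reproduces the statistical
structure the analysis assumes. This note records the models, the defaults
and why they were chosen, and what the synthetic data can and cannot show.

## Module scores and robust rescaling

For a module M with signed gene weights w_i (±1 for published modules) and
log2 expression x_is of gene i in sample s, the score is

    score_s = Σ_{i∈M} w_i x_is / Σ_{i∈M} |w_i|.

Signature genes absent from a study are dropped and both sums restricted to
the genes present; this preserves the score's range (a weighted average of
log-expression) at the cost of a slightly different gene set per platform.
Imputation was rejected because it would manufacture expression values on
exactly the genes for which the platform carries no information.

Raw scores are rescaled within each study so that the 2.5%, 50% and 97.5%
percentiles equal −1, 0 and +1, making scores comparable across studies
profiled with different technologies and normalisations. Three anchors
cannot be matched by one affine map, so a two-piece linear map hinged at
the median is used:

    y = (x − q50)/(q50 − q2.5)   if x < q50
    y = (x − q50)/(q97.5 − q50)  if x ≥ q50.

The map is strictly monotone where the spread is non-degenerate (equal
anchor quantiles raise an error naming the study), so within-study ranks are
preserved and a one-unit increase of the scaled score spans half the
central 95% score range of the study.

**Quantile convention.** Quantiles are taken as order statistics (numpy
`method="lower"`, exposed as `modsurv.anchor_quantiles`). With an
interpolated median the two central order statistics of an even-sized study
fall on opposite sides of the hinge, and the empirical median of the scaled
scores then misses 0 by O(1/n); with order statistics the hinge is a data
point and all three empirical anchors are exact to machine precision for
any sample size. This exactness is asserted at 1e-9 in the test suite.

## Molecular subtyping

A generic nearest-centroid classifier stands in for PAM50-style assignment:
expression is restricted to the genes shared with the centroid matrix
(at least 50% of centroid genes must be present), median-centered per gene
within the study, and each sample is correlated against each subtype
centroid. Spearman correlation is the default (robust to per-study scale
and monotone distortions); Pearson is available. The label is the
best-correlated subtype; exact ties break by centroid column order and are
flagged; a flat expression vector is unclassifiable ("NA"). The classifier
is validated only against the synthetic generator's latent labels (≥95%
recovery at centroid-shift/noise ≥ 3); no claim is made of probe-level
agreement with any published PAM50 implementation. Downstream analyses
keep the basal-like, HER2+, luminal A and luminal B subtypes and drop
normal-like.

## Preprocessing

* **Probe collapsing.** Duplicate gene rows (multiple probes per symbol)
  are replaced by their per-sample arithmetic mean — the "average
  expression" rule — rather than a max-mean representative probe. The
  operation is idempotent and order-preserving.
* **Censoring.** All DMFS data are administratively censored at 10 years:
  times beyond the horizon are truncated to it with events zeroed; an event
  exactly at the horizon is kept.
* **Receptor dichotomisation.** ER and HER2 status are derived per study by
  fitting a two-component univariate Gaussian mixture to the receptor
  gene's expression (EM, k-means initialisation, 5 restarts keeping the
  best log-likelihood; sklearn's `GaussianMixture` does the fitting) and
  cutting where the posterior probability of the high component is 0.5
  (equal weighted densities, solved between the component means by Brent's
  method). Degenerate fits — a component weight below 1e-3 or coincident
  means — fall back to the study median with `converged=False` and a
  warning; how such failures were handled on real data is not documented
  anywhere we know of, so the fallback is this package's own conservative
  choice. A value exactly at the cutoff is called negative (strict
  inequality), so a constant gene yields all-negative calls.

## Survival models

The central model is a dataset-stratified Cox proportional-hazards model:

    h_ks(t) = h_0k(t) · exp(β·Z_s + γ'C_s)

with an unestimated baseline hazard h_0k per study k, the module score Z
(scaled; HRs are per one-unit increase), and optional clinical covariates
C. Fitting goes through lifelines (`CoxPHFitter`, Efron tie handling,
Newton precision tightened to 1e-9 so that small-sample MLEs agree with a
brute-force partial-likelihood oracle within 1e-4). Wald tests and
normal-theory 95% CIs (exp(β ± 1.96·SE)) are reported.

Covariate selection fits one multivariate stratified Cox on all candidates
(age group, nodal status, grade, treatment; reference levels age <50,
node-negative, grade 1, treatment both) on complete cases (≥10 events
required) and keeps every covariate with at least one level at Wald
p < 0.05. For a binary covariate the null selection rate is the nominal
alpha; for a k-level covariate the any-level rule inflates it to
≈ 1−(1−alpha)^(k−1), which is why the type-I-error suite measures the rate
on the binary covariates.

Scanning many modules applies Benjamini–Hochberg FDR across the modules
that produced a fit (failed modules are reported NA and excluded from the
multiplicity count); significance is flagged at FDR < 0.05. Risk
stratification splits samples at the score median (ties at the median go
to the low group; a split that empties a group is an error) and compares
the two Kaplan–Meier curves with the two-group log-rank test.

The scan is exposed as `ModuleDMFSModel(...).fit() → ModuleDMFSResults`
with a `summary()` table, in the fashion of statsmodels' model/results
split; `module_dmfs_scan` is the functional shorthand.

## Subtype-specific signature derivation

Within one analysis cohort (typically one subtype pooled across studies):

1. **Per-gene meta-analytic Cox.** Each gene is dichotomised at its
   within-study median (high vs low) and a univariate Cox model fitted per
   study; a study contributes only if it has ≥5 events in the cohort, and
   ≥2 contributing studies are required. Study estimates are combined by
   fixed-effect inverse-variance weighting (SE = (Σ 1/SE_k²)^−1/2). The
   median split makes per-gene HRs comparable across genes and robust to
   study scale; a continuous variant (expression minus the within-study
   median) is available via `method="median_centered"` for users who read
   "divided by its median" as a ratio on the intensity scale. The gene
   universe is the intersection across studies, so every study can inform
   every gene. These thousands of single-covariate fits use a vectorised
   Newton solver on the Efron partial likelihood (`modsurv._fastcox`),
   cross-checked against lifelines in the tests; MLEs beyond |β|>10
   (separation) or degenerate covariates are dropped per study, and genes
   failing in every study are dropped.
2. **Candidate sweep.** Genes ranked by combined p (ties by |combined
   log-HR| descending, then symbol — a total order, so the sweep is
   invariant to input order) form nested candidates of sizes
   10, 20, …, 200 (size_n = 10 + (n−1)·10), each gene weighted +1 iff its
   combined HR exceeds 1. Fewer than 200 usable genes truncate the sweep
   with a warning; fewer than 10 is an error.
3. **Selection.** Every candidate is scored, rescaled within study over
   the cohort samples, and assessed by stratified Cox univariately and
   adjusted for the selected covariates. The selected module maximises
   min(univariate HR, adjusted HR) — the most conservative way to demand
   the module be strong in both analyses — with ties going to the smaller
   module. The full sweep table is kept for audit.

Because the size is chosen to maximise the in-sample HR, the selected
module's in-sample HR is optimistic; `evaluate_signature` labels
evaluations in- vs out-of-sample, and the test suite confirms the optimism
on replicated synthetic cohorts. Derived signatures should be validated on
independent data before any substantive use.

## Synthetic cohort generator

The generator is the package's study-condition definition, not a tuning
knob. Per sample: a latent subtype drawn from fixed proportions
(0.273/0.382/0.064/0.217/0.064 for luminal A/luminal B/HER2+/basal-like/
normal-like, the subtype mix of a 2027-patient multi-study breast-cancer
compendium); expression = subtype centroid (block design: gene i marks
subtype i mod K, elevated by `centroid_shift`, default 3) + per-study
location shift (N(0, 0.5), scale jitter available but 1 by default) +
N(0, 1) noise. Genes of a planted module additionally carry w_i times a
per-sample N(0,1) pathway activity in their noise-free signal, so the true
module score varies continuously across samples and the planted log-HR is
well defined; measurement noise then attenuates the recoverable effect
(by a factor ≈ var(score)/(var(score)+σ²/m) for an m-gene module) without
redefining it. Receptor genes (ESR1-like, ERBB2-like) draw from a
two-component normal mixture whose component is tied to the subtype
(means 5/10 and 5/9.5, sd 1), giving the bimodal marginal that receptor
dichotomisation relies on.

Event times are exponential with per-study baselines (0.05–0.14
events/year by default — constant baselines satisfy proportional hazards
and the analysis never uses baseline shape) multiplied by
exp(Σ β_m·score_m + covariate effects); independent exponential censoring
(0.04/year) and administrative censoring at 10 years follow. Clinical
covariates are drawn independently of expression with realistic margins
and act on the hazard only through explicitly configured
`covariate_log_hr` terms. One global seed expands to per-study substreams
(`SeedSequence.spawn`), so adding a study never perturbs earlier studies.

What the generator does **not** emulate: probe-level structure, batch
effects beyond per-study location/scale, correlated clinical covariates,
non-proportional hazards, platform-specific missingness. Passing tests
therefore demonstrate correctness of the estimators under the assumed
model, not robustness to the violations real cohorts exhibit.

## Problem sizes used in the test suite

The heavier checks run at: 50 replicates of 4 studies × 250 samples for
log-HR recovery (planted β=0.7 recovered within ±0.15 in ≥90%); 25
replicates of 4 × 300 with 250 genes for planted-signature recovery
(Jaccard ≥ 0.5 against the 20 planted genes in ≥80%); 75 null replicates
for covariate-selection calibration and 20 × 21-module null scans for FDR
control. These sizes give the binomial success counts enough margin that
the seeded runs sit well inside the acceptance bands.

## Known limitations

* The nearest-centroid subtyper is generic; real PAM50 calls involve a
  specific gene list, centroids and normalisation not reproduced here.
* Fixed-effect meta-analysis assumes one common per-gene effect across
  studies; heterogeneity inflates neither the SE nor any diagnostic.
* The per-gene fast Cox solver handles a single covariate only, by design.
* Complete-case multivariate analysis can shrink cohorts substantially
  when clinical annotation is sparse.
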