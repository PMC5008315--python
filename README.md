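# modsurv

Gene-module scoring and stratified survival analysis for multi-study
breast-cancer expression cohorts.

## The problem

Breast cancer is molecularly heterogeneous: tumors of the luminal A,
luminal B, HER2-enriched and basal-like intrinsic subtypes differ in
biology, prognosis and treatment response. Published gene signatures —
proliferation indices, oncogenic-pathway modules (RAS, E2F3, PTEN loss,
MYC, IGF1, …), receptor-signaling modules — summarise that biology as a
per-sample *module score*, and a natural clinical question is which
modules carry prognostic information for distant-metastasis-free survival
(DMFS) *within* each subtype, beyond standard clinical covariates.

`modsurv` is a reusable pipeline for that analysis across many expression
studies at once:

* **Module scores.** For a module with signed weights w_i ∈ {−1, +1},
  `score_s = Σ w_i x_is / Σ |w_i|`, rescaled within each study so its
  2.5%/50%/97.5% percentiles equal −1/0/+1 (a two-piece linear map hinged
  at the median), making scores comparable across platforms.
* **Subtyping.** A nearest-centroid classifier (Spearman or Pearson, after
  per-gene median centering) assigns each tumor to a subtype.
* **Survival association.** Cox proportional-hazards models stratified by
  dataset, `h_ks(t) = h_0k(t)·exp(β·Z_s + γ'C_s)`, report the hazard ratio
  per one-unit scaled-score increase, with data-driven clinical covariate
  adjustment (Wald p < 0.05) and Benjamini–Hochberg FDR across modules.
* **Signature derivation.** Per-gene Cox fits (median-split, per study)
  combined by fixed-effect inverse-variance meta-analysis rank genes;
  nested candidate modules of sizes 10, 20, …, 200 are scored and the one
  maximising min(univariate HR, adjusted HR) is selected, with
  median-split Kaplan–Meier risk stratification of the result.
* **Synthetic cohorts.** A generator with latent subtypes, planted
  prognostic modules of known log-HR, bimodal receptor genes, per-study
  baselines and 10-year administrative censoring makes the whole pipeline
  testable without any external download.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

```python
from modsurv import (SimulationConfig, ModuleSpec, make_signature,
                     simulate_cohort, score_signatures, module_dmfs_scan,
                     SubtypeSignatureModel)

sig = make_signature("proliferation", [f"G{i:04d}" for i in range(20)],
                     [1]*10 + [-1]*10)
cfg = SimulationConfig(n_studies=4, samples_per_study=250, n_genes=60,
                       module_specs=(ModuleSpec(sig, 0.7),), seed=11)
studies, clinical, truth = simulate_cohort(cfg)

scores = score_signatures(studies, [sig])          # raw + scaled scores
res = module_dmfs_scan(scores, clinical)           # stratified Cox + FDR
print(res.summary().to_string(index=False))
```

```
    predictor cohort    n  n_events       HR   CI_low  CI_high            p          FDR  significant
proliferation    all 1000       515 3.936866 3.285519  4.71734 6.853903e-50 6.853903e-50         True
```

The planted module (true log-HR 0.7 per unit *raw* score) is recovered as
HR 3.94 per unit *scaled* score — the rescaling maps half the central 95%
score range to one unit, so the scaled-score HR is correspondingly larger
than exp(0.7); the association is unambiguous (p ≈ 7×10⁻⁵⁰).

Deriving a prognostic module from scratch on the same cohort:

```python
fit = SubtypeSignatureModel(studies, clinical, subtype="all").fit()
print(fit)                      # selected size and selection criterion
ev = fit.evaluate()             # in-sample Cox + median-split KM
print(f"log-rank chi2={ev.km.chi_square:.1f}, p={ev.km.p:.2e}")
```

```
<SubtypeSignatureResults subtype='all' size=30 criterion=3.988>
log-rank chi2=128.5, p=8.84e-30
```

The candidate sweep picks a 30-gene module (the 20 planted genes plus 10
borderline nulls); splitting patients at its median score separates the
Kaplan–Meier curves decisively. `fit.summary()` shows the full sweep
table, and `fit.evaluate(studies2, clinical2, in_sample=False)` gives the
honest out-of-sample assessment.

A `modsurv` command-line tool wraps the same library (`simulate`,
`preprocess`, `subtype`, `score`, `scan`, `derive`, `run`); `modsurv run
--config config.yaml` executes the whole pipeline from one YAML file and
writes provenance-stamped TSVs.

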