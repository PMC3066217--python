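# ovasig

Integrative survival-signature analysis for multi-cohort gene-expression
studies, modeled on the workflow used to build reproducible prognostic
classifiers in advanced ovarian cancer: several microarray cohorts from
different laboratories are merged into one training set with empirical-Bayes
batch adjustment, a small prognostic gene signature is learned with
supervised principal-component survival analysis, its significance is
established by cross-validation and survival permutation, and the resulting
high/low-risk phenotypes are characterized by subclass mapping across
cohorts, gene-set analysis and oncogenic-pathway activation scoring.

It is aimed at computational biologists who want each stage of that workflow
as a tested, reusable library function rather than a one-off script.

## The model at the core

Given log2 expression `x_gj` (gene g, sample j) and overall survival
`(T_j, δ_j)`:

1. **Screen**: per gene, a univariate Cox proportional-hazards fit on
   standardized expression; keep genes with Wald p < α and rank by |β̂_g|.
2. **Summarize**: principal components of the standardized top-k gene
   submatrix; the risk score is the Cox linear predictor on the first
   components, `s_j = Σ_c γ̂_c · PC_cj`, oriented so that larger s means
   larger hazard.
3. **Split**: high vs low risk at the median score; survival difference by
   the log-rank test and Kaplan-Meier medians.
4. **Validate honestly**: leave-one-out cross-validation re-runs the entire
   pipeline (screen, rank, PCs, Cox) on every fold; a permutation test
   repeats the whole cross-validated procedure on survival data reassigned
   at random, giving a calibrated p-value for the split.
5. **Transfer**: the frozen model (gene list, standardization, loadings,
   coefficients, threshold) is applied without modification to independent
   cohorts after batch co-adjustment.

Batch adjustment follows the location/scale empirical-Bayes model
(per gene g, batch i: `Y = α_g + Xβ_g + γ_ig + δ_ig ε`), with parametric
(normal / inverse-gamma priors, method-of-moments hyperparameters) and
nonparametric (likelihood-weighted posterior means) shrinkage. Subclass
mapping quantifies cross-cohort correspondence of sample groups by mutual
marker-gene enrichment (KS running-sum scores, label-permutation p-values,
Fisher inverse-chi-square combination, BH-FDR). Pathway characterization
offers the Efron-Tibshirani maxmean gene-set statistic with
restandardization, EASE-style jackknifed Fisher over-representation, and
Bayesian probit pathway-activation probabilities built on a rank-1 metagene.

## Worked example

```python
from ovasig import synthdata, integrate, sigmodel, survstats

cfg = synthdata.SimulationConfig(seed=3)          # 4 batches x 60 samples, 2000 genes
em, clinical, truth = synthdata.simulate_integration_study(cfg)

adjusted, model = integrate.combat_adjust(em)     # remove inter-cohort batch effects
assignment, loocv = sigmodel.loocv_risk_groups(adjusted, clinical, top_k=19)
print(f"LOOCV log-rank p = {loocv.p_value:.3g}")

spc = sigmodel.fit_superpc(adjusted, clinical, top_k=19)
cfg_v = synthdata.SimulationConfig(n_batches=2, samples_per_batch=60, seed=77)
em_v, clin_v, _ = synthdata.simulate_integration_study(cfg_v)
adj_v, _ = integrate.combat_adjust(em_v)
risk = sigmodel.apply_model(spc, adj_v, threshold_source="cohort_median")
res = survstats.logrank_test(risk.group.to_numpy(), clin_v.os_months, clin_v.event)
km = survstats.km_estimate(clin_v.os_months, clin_v.event, risk.group.to_numpy())
print(f"validation log-rank p = {res.p_value:.3g}")
print({g: round(c.median, 1) for g, c in km.items()})
```

Output:

```
LOOCV log-rank p = 1.07e-09
validation log-rank p = 2.01e-05
{'low': 52.2, 'high': 14.8}
```

The 19-gene model learned on the simulated training set splits an
independent simulated cohort into risk groups whose median overall survival
differs by a factor of ~3.5 (14.8 vs 52.2 months) — the planted prognostic
program transfers across cohorts once batch effects are adjusted.

A thin CLI mirrors the library (`ovasig simulate`, `ovasig integrate`,
`ovasig train`, `ovasig apply`, `ovasig submap`, `ovasig pathways`).

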