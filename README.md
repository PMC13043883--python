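# substage

Data-driven disease subtyping and staging for cross-sectional cohorts,
with permutation-based stage-association scanning.

Cross-sectional case–control studies usually treat patients as one
homogeneous group, even though individuals differ both in *which* disease
trajectory they are on (subtype) and in *how far* along it they are
(stage). `substage` implements the analysis chain used to disentangle the
two from regional brain volumes, and to relate the inferred stage to
functional-connectivity edges and clinical scores:

1. **Control-referenced z-scoring** — each region's volume is adjusted for
   age, sex and total intracranial volume (TIV = GM + WM + CSF) by OLS
   fitted on controls only; z = (predicted − observed) / control residual
   SD, so atrophy is positive.
2. **Z-score event-based subtype-and-stage model** — a disease *event* is a
   biomarker crossing a z threshold (1, 2, 3 control SDs). A subtype is an
   ordering S = (e₁, …, e_N) of all biomarker×threshold events; a subject
   at stage k has passed events e₁…e_k. Between events the expected
   z-score g_i(k) is piecewise linear toward z_max. The subject likelihood
   marginalises a uniform stage prior,

       P(x | S) = 1/(N+1) · Σ_{k=0..N} Π_i N(x_i ; g_i(k), σ_i²),

   and a mixture over C subtypes Σ_c f_c P(x | S_c) is fitted by EM with a
   greedy event-relocation hill-climb over orderings (multi-start, seeded).
   C is chosen by BIC = −2 log L + [C·N + (C−1)]·log n; subjects get their
   maximum-likelihood subtype and stage.
3. **Stage-association scan** — within a subtype, stage and every candidate
   variable (regional volumes; all n(n−1)/2 connectome edges, e.g. 4560 for
   96 regions) are OLS-residualised on nuisance covariates and
   rank-correlated (partial Spearman ρ). Inference is by permutation of the
   stage residuals (default B = 20,000), with one shared permutation stream
   across all variables: per-unit two-sided p = (1 + #{|ρ_b| ≥ |ρ_obs|}) /
   (B + 1), Benjamini–Hochberg FDR q over the family, and max-statistic
   FWER-adjusted p that respects arbitrary dependence between edges.
4. **Clinical statistics** — Mann-Whitney / chi-square group comparisons,
   stage-adjusted ANCOVA (outcome ~ subtype × stage, type-II SS), and
   within-subtype stage–score OLS slopes adjusting for age and sex.
5. **Synthetic cohorts** — a seeded generator produces demographics,
   ground-truth subtypes/stages, volumes, Fisher-z connectivity with
   stage-coupled edges at requested Spearman targets, and clinical scores
   with planted stage slopes, so the whole chain is validated by parameter
   recovery.

## Worked example

`examples/02_fit_subtypes.py` plants two subtypes that progress through 8
biomarkers (z events at 1 and 2 SD, 16 events) in opposite orders, n = 200
patients, trajectory noise 0.25 SD, and fits models with 1 and 2 subtypes:

```
C=1: logL=  -2616.8  BIC=   5318.3
C=2: logL=  -2036.7  BIC=   4248.3
BIC selects 2 subtype(s)  (2 were planted)
subtype assignment accuracy: 97.5% (label order is arbitrary)
fitted sequence 0: Kendall tau to closest planted ordering = 0.98 (1.0 = exact event order)
fitted sequence 1: Kendall tau to closest planted ordering = 0.95 (1.0 = exact event order)
```

The BIC drop of ~1000 says the two-trajectory model explains the cohort far
better than one; the Kendall taus say the recovered event orderings almost
exactly match the planted ones, and 97.5% of subjects land back in their
generating subtype. The other examples cover normalisation
(`01_simulate_and_normalize.py`), the edge scan with FDR/FWER control
(`03_stage_association_scan.py`) and the end-to-end pipeline
(`04_full_pipeline.py`), which can also be driven from the shell:

```bash
substage run-all --config config.yaml --out results/run1
```

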