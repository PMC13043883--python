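# Methods

## The z-score event-based subtype-and-stage model

The model treats disease progression as an ordered cascade of biomarker
*events*. For biomarkers indexed i with atrophy-positive z-scores x_i
(control-referenced, see below), an event is the crossing of a fixed
threshold z ∈ {1, 2, 3}; with B biomarkers and K thresholds there are
N = B·K events. A subtype is a permutation S of the event set, constrained
so that each biomarker's thresholds appear in increasing order (a marker
cannot reach z = 2 before z = 1). A subject at integer stage k ∈ [0, N] has
passed the first k events.

The expected trajectory g_i(k) of biomarker i under S is piecewise linear
through (0, 0), through each of its event vertices (position of the event
in S, its threshold), and — when its last event is not the final event of
S — through (N, z_max). The subject likelihood marginalises a uniform
stage prior:

    P(x | S) = 1/(N+1) · Σ_{k=0}^{N} Π_i Normal(x_i ; g_i(k), σ_i²)

computed in log space (safe for |z| ≤ 20, N ≤ 60). A C-subtype model is
the mixture Σ_c f_c P(x | S_c).

**Assumptions.** Monotone progression (z-scores only grow along the
cascade), a uniform stage prior including the no-event stage, Gaussian
observation noise with per-biomarker scale σ_i, and cross-sectional
exchangeability (each subject is one independent snapshot). Only patients
enter the fit; controls define the z reference.

**Fitting.** The single-subtype ordering is found by a greedy relocation
hill-climb: every sweep visits each event in random order and moves it to
the position (respecting the threshold constraint) that maximises the
weighted log-likelihood, until a sweep makes no improvement; the best of
`n_restarts` random valid starts is kept. Larger models are built
hierarchically: the currently most populated subtype is split by random
bipartition (best of `split_restarts` splits), then EM alternates
responsibilities/fractions with per-subtype re-optimisation of the ordering
warm-started from the current one. The EM trace is monotone
non-decreasing (asserted in tests to 1e-9). The likelihood is evaluated
through a cached quadratic expansion (‖x/σ‖² − 2(x/σ)(g/σ)ᵀ + ‖g/σ‖²), so
one candidate ordering costs a single small matrix product.

**Model selection and assignment.** BIC_C = −2 log L_C + P_C log n with
P_C = C·N + (C−1) (one positional degree per event per subtype plus the
free mixture weights; the convention is explicit and configurable, ties go
to the smaller model). Subjects are assigned argmax_c f_c P(x|S_c), then
the argmax of that subtype's stage posterior; ties break toward the lower
index/stage and are flagged.

## Volume normalisation

Per region, OLS on controls only: volume ~ intercept + age + female + TIV,
with residual SD using the unbiased n − p denominator (p = 4). All
subjects are scored with the control-fitted coefficients;
z = (predicted − observed)/SD so volume *deficit* is positive — the
orientation the monotone event model requires. Cortical lobes keep
hemispheres separate; subcortical left/right volumes are averaged first
(`average_bilateral`). No winsorising of extreme z: the likelihood's
Gaussian tails handle them, and capping would bias late-stage estimates.
TIV = GM + WM + CSF.

## Stage-association scanning

Within one subtype, the inferred (integer, tied) stage and every candidate
variable are OLS-residualised on nuisance covariates — defaults: age, sex,
handedness, TIV for volumes; age, sex, handedness, scanner for connectivity
edges — and Spearman-correlated with average ranks. Permutation inference
shuffles the *stage residual* vector B times (default 20,000); the same
permutations serve every unit, which is what makes the maximum statistic
over units a valid FWER reference under arbitrary dependence:

    p_unit   = (1 + #{b : |ρ_b| ≥ |ρ_obs|}) / (B + 1)
    p_fwer   = (1 + #{b : max_units |ρ_b| ≥ |ρ_obs|}) / (B + 1)

The add-one form cannot return zero and is a valid p-value at any B; an
exact-proportion mode and an exhaustive mode (all n! permutations, n ≤ 8)
exist, the latter matching direct enumeration bit-for-bit in tests. BH-FDR
q-values are computed over the whole scan family. Units with constant
residual ranks yield NaN (undefined correlation), are excluded from the
max-statistic, and are reported as such rather than erroring.

## The synthetic cohort generator

The generator is first-class, tested code that emulates the statistical
structure the chain assumes, so passing recovery tests is evidence about
the *method*, not about any particular dataset.

- **Demographics** follow the emulated study's margins: control age
  34.5 ± 12.8 years (patients 39.8 ± 10.4, clipped to 18–75), 60.7%/51.8%
  male, 96%/93% right-handed, two scanners at 29%/54% A-usage, TIV drawn
  per sex (1.55/1.37 × 10⁶ mm³, SD 10⁵) — plausible adult intracranial
  volumes.
- **Ground truth**: subtype sequences are uniform random valid orderings
  (or maximally separated opposed biomarker-block orderings via
  `opposed_pair`, which emulates anterior-first vs posterior-first
  progression); stages are uniform on [0, N], matching the model's prior;
  13 biomarkers (8 cortical L/R lobes + 5 bilateral subcortical) by
  default, configurable.
- **Volumes**: controls = linear covariate model (region-scaled defaults:
  ~0.2%/year age loss, TIV proportionality, 3% residual SD) + Gaussian
  residuals; patients are displaced by g_i(true stage) + Gaussian(0,
  noise_sd in z units), times the residual SD — atrophy shrinks volume.
  Bilateral markers can be emitted as left/right pairs straddling the
  bilateral value symmetrically, so averaging recovers it exactly.
- **Connectivity**: per-edge Fisher-z baselines N(0.3, 0.1) plus
  N(0, 0.15) subject noise. A planted edge adds a linear shift in the
  within-subtype stage *rank*, with slope calibrated by the
  bivariate-normal inversion r = 2·sin(πρ/6), a = r·σ/√(1−r²); the
  realised Spearman is verified by Monte-Carlo in the tests (mean absolute
  error < 0.15 at n = 50).
- **Clinical scores**: patient score = baseline + slope[subtype]·stage +
  N(0, noise); Bernoulli missingness (default 4%, mimicking the emulated
  study's per-scale subset sizes); controls missing or norm-referenced.

**What it does not emulate**: spatial correlation between regions beyond
the event cascade, scanner- or site-specific volume offsets, non-Gaussian
residuals, informative missingness, medication effects on volumes, or any
BOLD-level structure (connectivity is generated at the matrix level).
Recovery results therefore demonstrate correctness of the inference
machinery under its own assumptions, not robustness to violations of them.

## Numerical choices and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| z thresholds | 1, 2, 3 | control SD | mild/moderate/severe event grid |
| σ_i | 1 | z units | data are control-referenced z-scores |
| z_max | 5 | z units | plateau above the top threshold |
| n_restarts | 25 | — | multi-start hill-climb breadth |
| EM tolerance | 1e-6 | log-lik | alternation stop |
| B permutations | 20,000 | — | p-value resolution ~5e-5 |
| FDR q / FWER α | 0.05 | — | conventional |
| stage prior | uniform 0..N | — | no staging information assumed |

Tie-breaking is always deterministic (lower stage, lower subtype index,
first-minimum BIC), and every stochastic routine takes an explicit integer
seed; the pipeline derives named sub-streams from one root seed, so a
single integer reproduces every artefact byte-for-byte.

Degenerate inputs are first-class: all-zero z rows stage at 0; a flat
likelihood over orderings (e.g. every patient at stage 0) is flagged
`degenerate` on the fitted model; constant-rank scan units return NaN with
the rest of the family intact; rank-deficient designs name the offending
column.

## Design decisions that were genuinely open

- **Sign convention**: z is flipped so atrophy is positive — required for a
  monotone-increase event model fed by volume loss.
- **Search strategy**: greedy relocation hill-climb with restarts rather
  than MCMC over orderings; the package reports maximum-likelihood
  sequences and ML staging only, so posterior positional-variance
  machinery would add cost without changing any reported quantity.
- **BIC parameter count**: P_C = C·N + (C−1); no canonical convention
  exists for ordinal sequence parameters, so it is documented and
  configurable rather than implicit.
- **Permutation target**: the residualised stage vector is shuffled
  directly; the Freedman–Lane refit scheme is a known alternative and is
  deliberately not implemented.
- **ANCOVA sums of squares**: type II, robust to unbalanced subtype sizes.
- **Chi-square** without Yates correction, **Mann-Whitney** with
  tie-corrected normal approximation (exact for both groups ≤ 12).

## Problem sizes used by the tests and acceptance script

Unit and property tests run on instances small enough for exhaustive
oracles (2 biomarkers × 2 thresholds → 6 valid orderings; n = 6 → 720
permutations). The recovery benchmark uses 13 biomarkers × 3 thresholds
(39 events) at n = 300 with trajectory noise 0.25 SD and reduced restarts
(5 starts, 3 splits, 15 EM iterations); null calibration uses 200
replicate cohorts of 100 units at B = 2000; power checks 50 seeds of one
ρ = 0.7 edge among 99 nulls at n = 40. The acceptance script runs the full
pipeline at 224 controls / 85 patients with a 96-region connectome and
B = 20,000.

## Known limitations

- Subtype labels are arbitrary (mixture non-identifiability); downstream
  consumers must map labels by membership, as the acceptance script does.
- Partial-correlation recovery at subtype sizes n ≈ 35–50 scatters roughly
  ±0.15–0.25 around a planted ρ across seeds: with few subjects, a rare
  binary covariate (e.g. ~7% left-handedness) can chance-correlate with
  stage, and residualising it out removes genuine shared signal. This
  finite-sample attenuation is inherent to the partial-correlation design,
  not to this implementation.
- The hill-climb is a local search; with few restarts on near-flat
  likelihoods it can return a suboptimal ordering (the exhaustive-oracle
  tests bound this only for tiny instances).
- Stages are ordinal positions along an inferred sequence, not calendar
  time; equal stage spacing is a modelling convention.
- BIC with the chosen parameter count is conservative at small n; a
  one-subtype selection at n < 100 does not rule out weakly separated
  subtypes.
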