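# Methods

This note documents the statistical content of `hmbmtc`: the model and its
assumptions, the estimators that feed it, the sampler, the synthetic-data
generator used for validation, and the numerical and design choices that
were genuinely open.

## Outcome definition and unification

The efficacy outcome is the probability that a woman's menstrual blood loss
(MBL) falls below 80 mL per cycle; a Higham pictorial-chart (PBAC) score
below 100 is treated as equivalent, so the PBAC path is computationally
identical to the MBL path up to the threshold (80 mL vs 100 points).

Trials report the outcome in four forms.  Each is converted to an estimated
proportion `p̂` with standard error, then to *effective* binomial counts
`n_eff = p̂(1−p̂)/se²`, `y_eff = p̂·n_eff` (capped at the arm size for
summary-derived estimates), which enter a single continuous-binomial
likelihood.  This keeps one likelihood code path and loses no information
to rounding.

* **Counts.** `p̂ = y/n`, binomial SE.  A continuity constant c = 0.5 is
  applied as `(y+c)/(n+2c)` **only** at y ∈ {0, n}: the logit stays finite
  and interior proportions are not biased.
* **Mean ± SD.** A normal or lognormal distribution is moment-matched to
  (mean, sd) and `p̂ = F(threshold)`.  The SE propagates
  var(mean) = sd²/n and var(sd) ≈ sd²/(2(n−1)) through F by the delta
  method (gradient by central differences; the two inputs are treated as
  independent because their covariance is unrecoverable from aggregate
  data).
* **Median, min, max.** The Hozo-style range estimator recovers
  mean = (min + 2·median + max)/4 and sd from the range with the
  conventional n-dependent divisor (small-sample formula for n ≤ 15,
  range/4 for n ≤ 70, range/6 beyond).  Because median- and range-based
  summaries are less efficient than mean/sd, the propagated input
  variances are inflated: var(mean) by π/2 (asymptotic efficiency of the
  median under normality) and var(sd) doubled.
* **Median, quartiles.** Under the normal family mean = (q1+median+q3)/3
  and sd = IQR/1.349; under the lognormal family the three quartiles are
  matched on the log scale and converted back to arithmetic moments, so
  delegation through the moment-matched CDF reproduces the
  quantile-matched probability exactly.  Same variance inflation.

The exact procedures used by the original analysts were distributed in a
supplement that is not publicly available; the estimators above are
principled stand-ins drawn from standard meta-analytic practice, flagged
by a provenance field in every converted observation, and swappable
(normal vs lognormal is a single config switch).  **Default family:
lognormal** for both scales — blood-loss measurements are strictly
positive and right-skewed — with normal available for sensitivity.

## The hierarchical model

```
y_ijt ~ Binomial(n_ijt, p_ijt)
logit(p_ijt) = α₀ + η_i + θ_ij + γ_jt
θ_ij ~ N(δ_j + α₁ x_ij, τ_j²);   η_i ~ N(0, σ_η²)
```

Priors: α₀, δ_j ~ N(0, 10⁴); γ_jt ~ N(0, 100); α₁ ~ U(−5,5);
τ_j ~ U(0,100); 1/σ_η² ~ Gamma(0.1, 0.1) (shape–rate, the BUGS
convention); missing standardized baselines x_ij ~ N(0,1).

Assumptions worth stating explicitly:

* Class-level, not treatment-level, effects: regimens within a class are
  pooled.  Arms of the same class within a study are merged by summing
  effective counts before model construction.
* A study observed at several follow-up times shares η_i and θ_ij; times
  differ only through γ_jt.  γ_jt exists **only** for observed
  (class, time) pairs — requesting a prediction for an unobserved pair is
  an error, never an extrapolation.
* Baseline mean MBL is standardized by the mean and SD over arms with
  non-missing values; missing baselines are imputed as latent parameters
  with a standard-normal prior (missing at random).  The covariate is
  indexed per (study, class) arm, as the model equations are written.
* The parameterization carries a translation ridge: (α₀+c, θ−c, δ−c)
  leaves the likelihood and the θ-prior kernel unchanged.  Fidelity to the
  published specification is the default (`identifiability="faithful"`);
  reporting is restricted to identifiable sums α₀+δ_j+γ_jt, which are
  invariant.  An optional corner constraint (`"corner"`: δ of the
  reference class and each class's earliest γ pinned at 0) is provided
  for faster mixing; it changes no identifiable functional.

Probabilities inside the likelihood are clipped at 10⁻¹² from each
boundary — a pure numerical guard far below reportable precision.

## Inference

The published protocol (three parallel chains, 60,000 burn-in, 60,000
saved) fixes chain counts and lengths but not the algorithm, so the
contract here is distributional.  The sampler is adaptive
Metropolis-within-Gibbs:

* conjugate draws for δ_j, α₁ (truncated normal), imputed x_ij, and the
  study-effect precision;
* vectorized per-coordinate random-walk Metropolis for α₀, η, θ, γ
  (coordinates within a block touch disjoint observations, so elementwise
  acceptance is exact) and for log τ_j;
* two reparameterization moves that decorrelate the weakly identified
  location structure: a per-class joint shift of (δ_j, θ·j), and a
  translation along the α₀/δ ridge (exact symmetry in the faithful
  parameterization; under the corner constraint the pinned class's
  θ-prior kernel enters the ratio).

Proposal scales adapt toward 0.44 acceptance in batches of 50 during
burn-in (gain min(0.5, b^−1/2)) and are frozen afterwards, so saved draws
come from a fixed kernel.  Initialization draws location parameters
uniformly from [−2, 2] with up to 10 retries on a non-finite density.  All
randomness descends from one `SeedSequence`; identical seed and config
give bitwise-identical draws, and the CLI writes a manifest (seed, config
hash, version) from which every output is regenerable.

Correctness evidence (all in the test suite): a conjugate binomial toy
matches the Beta closed form; a data-free (zeroed-likelihood) run
reproduces the prior SDs of γ (10) and δ (100) within 5%; and credible
intervals attain nominal coverage in the recovery experiment below.

Two sampler presets: `paper` (3 × 60,000 + 60,000) and `desk`
(3 × 2,000 + 2,000) for interactive use and tests.

## Convergence diagnostics

`psrf` implements the Gelman–Rubin statistic with the Brooks–Gelman
correction: R̂ = sqrt((d+3)/(d+1) · V̂/W) with d estimated by method of
moments from the sampling variance of V̂.  Calibration: three iid normal
chains of 10⁴ draws give R̂ ∈ [0.99, 1.02]; deliberately separated chains
give R̂ ≫ 1.2; constant chains are undefined and flagged.  The CLI flags
parameters with R̂ > 1.1, a common-practice threshold (the source protocol
states no numeric criterion).  `trace_summary` provides the numerical
content of trace plots: segment means and lag-1 autocorrelation.

## Posterior summaries

Efficacy per (class, time) is reported as posterior median and equal-tailed
95% credible interval (2.5/50/97.5 percentiles, linear interpolation —
"type 7") of `inverse-logit(α₀ + δ_j + α₁x* + γ_jt)`, i.e. a "typical
study" plug-in prediction with η = 0 and θ at its conditional mean.
Whether the original analysis marginalized over new-study random effects
is unstated; a `mode="marginal"` flag adds N(0, σ_η²) + N(0, τ_j²) noise
per draw for sensitivity.  The default reference baseline is the stored
standardization center; for the digitized network that is 169.64 mL, the
all-study average of reported baseline means.

## Synthetic data and validation scale

The arm-level data behind the original analysis are not deposited, so the
generator emulates the corpus the publication describes: 34 RCTs over the
8 classes; study designs sampled from the published sparse pair/time
pattern (including the trial whose two arms report at disjoint times and
so contribute no direct comparison); outcome forms mixed 11:8:4:11
(MBL counts : mean±SD : median-based : PBAC counts); baseline mean MBL
uniform on 90.3–300 mL, missing for ~56% of studies (15/34 reported it),
with a study-level mask independent of outcomes (MAR by construction);
arm sizes lognormal with median 33 clipped to 9–164.  Summary-form arms
are re-encoded from simulated individual lognormal outcomes (log-scale SD
0.6, a moderate skew typical of blood-loss data) whose below-threshold
probability equals the latent p, so the estimator chain has a well-defined
target.  The default generating truth echoes the qualitative ordering of
the published efficacy table (high LNG-IUS/ablation, low placebo and
luteal-phase progestogens) — illustrative, not a reproduction.

What passing tests show: the full chain (generation → proportion
estimation → model → MCMC → summaries) recovers known truth with
calibrated uncertainty under the model's own assumptions and the real
corpus's sparsity.  What they cannot show: robustness to violations the
generator does not emulate (non-lognormal outcomes, informative
missingness, within-class heterogeneity, time-varying arm sizes).

The recovery experiment runs 50 replicates on 10-study networks with
2 chains × (700 + 700) iterations per fit — sizes chosen so a full
validation pass is a desk-scale computation — and checks that 95%
credible intervals for the identifiable sums α₀+δ_j+γ_jt cover the
generating truth within the binomial band [0.86, 1.00] at n = 50.
Recovery fits use the corner-constrained mode (same identifiable
functionals, better mixing per saved iteration).

## Known limitations

* The summary-to-proportion estimators are re-derivations, not the
  original supplement's procedures; their SE inflation factors are
  documented conventions, not estimates.
* With one or two arms in a class, τ_j is dominated by its U(0,100) prior
  and class-level estimates can span nearly (0, 100)% — faithful behavior
  of the specified model in a thin network, not a software artifact.
* Effective counts treat derived proportions as binomial evidence; the
  alternative normal-on-logit likelihood is not implemented beyond the
  effective-count generalization.
* No treatment ranking, relative effects, or model-comparison statistics
  (DIC/WAIC): absolute efficacy per class-time is the deliverable.
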