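# hmbmtc

Bayesian mixed-treatment-comparison (MTC, network meta-analysis) estimation of
the efficacy of treatments for **heavy menstrual bleeding** (HMB) from sparse
randomized-trial evidence.

## The problem

HMB trials compare eight treatment classes — combined oral contraceptives
(COC), danazol, endometrial ablation, the levonorgestrel-releasing
intrauterine system (LNG-IUS), placebo, luteal-phase progestogens
(< 2 weeks/cycle), long-course progestogens (~3 weeks/cycle), and tranexamic
acid (TXA) — but almost never head-to-head across the whole set.  The efficacy
outcome is the proportion of women achieving menstrual blood loss (MBL)
**below 80 mL per cycle** (alkaline hematin method), with a Higham pictorial
chart score (PBAC) below 100 accepted as equivalent.  Trials report this
outcome inconsistently: as direct counts, as mean ± SD, as median with range,
or as median with quartiles, at follow-up times from 1 to 36 months.

This package provides, for biostatisticians and health-economic modellers:

1. **Evidence-network handling** — validated arm-level I/O, direct-comparison
   tables and per-time connectivity (the network is thinly connected: at some
   follow-up times it splits into disjoint components).
2. **Proportion estimation** — conversion of each reporting form into an
   estimated proportion below threshold with a standard error (normal or
   lognormal outcome family), then into effective binomial counts.
3. **A hierarchical binomial-logit MTC model** with MCMC inference and
   Brooks–Gelman convergence diagnostics.
4. **Posterior efficacy tables** — median and equal-tailed 95% credible
   interval of % MBL < 80 mL per class and follow-up time at a reference
   baseline MBL.
5. **A synthetic-data generator** reproducing the structural quirks of the
   real evidence base, used for end-to-end parameter-recovery validation.

## The model

For study *i*, treatment class *j*, follow-up time *t* (months):

```
y_ijt ~ Binomial(n_ijt, p_ijt)
logit(p_ijt) = α₀ + η_i + θ_ij + γ_jt

θ_ij ~ Normal(δ_j + α₁·x_ij, τ_j²)        x_ij: standardized baseline MBL
η_i  ~ Normal(0, σ_η²)
```

with weakly informative priors: α₀, δ_j ~ N(0, 10⁴); γ_jt ~ N(0, 100);
α₁ ~ U(−5, 5); τ_j ~ U(0, 100); 1/σ_η² ~ Gamma(0.1, 0.1); missing
standardized baselines x_ij ~ N(0, 1) (missing at random).  Summary-derived
outcomes enter as real-valued effective counts (y_eff, n_eff) through a
continuous binomial likelihood.  Only identifiable sums α₀ + δ_j + γ_jt are
reported; predictions at the reference baseline are
`inverse-logit(α₀ + δ_j + α₁·x* + γ_jt)` with x* = 0 at the stored center.

## Worked example

```python
import hmbmtc as h

net, truth = h.generate_network(h.GeneratorConfig(n_studies=12, seed=3))
model = h.MTCModel.from_network(net, identifiability="corner")
res = model.fit(preset="desk", seed=1)   # 3 chains, 2000 + 2000 iterations
print(res.summary(times=[3]))
```

prints

```
Mixed-treatment-comparison fit
  studies: 12  classes: 8  observations: 52
  chains: 3  draws/chain: 2000  burn-in: 2000
  reference baseline MBL: 201.39 mL

| Treatment | Time (months) | % below threshold (95% CrI) |
|---|---|---|
| COC | 3 | 95.6 (0.0-100.0) |
| LNG_IUS | 3 | 85.7 (74.1-93.0) |
| ABLATION | 3 | 85.6 (60.8-96.7) |
| DANAZOL | 3 | 70.6 (0.0-100.0) |
| PROG_3WK | 3 | 43.3 (0.0-100.0) |
| PROG_LT2WK | 3 | 13.2 (0.0-100.0) |
| PLACEBO | 3 | 6.9 (0.0-100.0) |

  max PSRF (Brooks-Gelman): 1.259 [gamma[LNG_IUS@12]]
  PSRF > 1.1: alpha1, gamma[LNG_IUS@12], gamma[LNG_IUS@24], ...
```

Each row is the posterior median (95% credible interval) of the percentage
of women below the blood-loss threshold for that class at 3 months, at the
reference baseline.  Classes observed at month 3 in only one small trial get
very wide intervals — exactly the behavior expected in a thin network.  For
this synthetic network the generating truth for LNG-IUS at 3 months was
87.5%; the fitted estimate is 85.7 (74.1–93.0).  The PSRF lines list
parameters whose Brooks–Gelman potential scale reduction factor exceeds the
1.1 warning threshold on this deliberately short desk-scale run; the
published protocol (`preset="paper"`: 3 chains, 60,000 burn-in + 60,000
saved) is available for production fits.

A command-line pipeline wraps the same stages:

```bash
hmb-mtc summarize-network --input table1 --out report/
hmb-mtc fit --config run.json --seed 1 --out fit/
hmb-mtc recover --config recover.json --seed 1 --out recovery.csv
```

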