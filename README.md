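# lima-mediation

Likelihood-based molecular mediation analysis from GWAS/QTL summary
statistics.

## The problem

Given an exposure *X* with a causal effect θ on an outcome *Y*, and *k*
candidate molecular mediators **M** (metabolites, proteins, transcripts),
mediation analysis decomposes θ = α + ω into a direct effect α and a
mediated effect ω = γ′δ, where γ are the exposure→mediator and δ the
mediator→outcome causal effects. The quantity of interest is the mediation
proportion MP = 1 − α/θ. All estimation uses only standardized association
summary statistics for genetic instruments: β̂ (instrument→exposure),
Ĉ (exposure instruments→mediators), B̂ (mediator instruments→mediators),
ĉ and b̂ (instruments→outcome).

The standard two-step approach — univariable inverse-variance-weighted (IVW)
MR for θ̂, multivariable MR (MVMR) for α̂ — treats the estimated instrument
effects as error-free regressors. When the mediator studies are an order of
magnitude smaller than the exposure/outcome GWAS (n_M ≈ 10⁴ vs n ≈ 3·10⁵),
the resulting regression-dilution (weak-instrument) bias shrinks ω̂ and
badly underestimates MP. This package implements two maximum-likelihood
estimators that model the sampling noise of **every** block of summary
statistics:

* **LiMA** maximizes the joint Gaussian log-likelihood of (b̂, ĉ, Ĉ) given
  (β̂, B̂) over the 2k+1 parameters (α, γ, δ), with measurement-error-inflated
  variances (e.g. Var(ĉᵢ) = 1/n_Y + σ²_c + θ²/n_X).
* **I-LiMA** places a Gaussian prior (γᵢ, δᵢ) ~ N(0, [[σ²_γ, σ_γδ], [σ_γδ, σ²_δ]])
  on the per-mediator effects and maximizes the moment-matched marginal
  likelihood over just four parameters (α, σ²_γ, σ²_δ, σ_γδ), reporting
  ω̂ = k·σ̂_γδ. The (mk+m+l)-dimensional marginal covariance is evaluated with
  low-rank (Sherman–Morrison/Woodbury) identities, so the cost per evaluation
  is O(lk² + k³ + mk) and the parameter count never grows with k.

A two-step `TwoStepMR` baseline, a full generative simulator of the study
design (spike-and-slab mediation effects, Weibull mediator heritabilities,
sample-size-scaled Gaussian estimation noise, IVW mediator selection), a
benchmark driver (bias / coverage / power / type-I error), and an applied
front end (Steiger filtering, candidate selection, correlation pruning) are
included. Estimators are scikit-learn-style classes: `fit(data)` with fitted
attributes `alpha_`, `omega_`, `theta_`, `converged_`, …

## Worked example

Simulate one study from the default conditions (n_X = n_Y = 300,000,
n_M = 10,000, k = 10 mediators, true MP = 0.15, E(θ) = 0.15, Bonferroni
mediator selection) and estimate the mediation proportion three ways:

```python
import numpy as np
from lima import Scenario, TwoStepMR, LiMA, ILiMA, lrt_variances, mp_single
from lima.synth import simulate_selected_replicate

scenario = Scenario(seed=7)
rng = np.random.default_rng(np.random.SeedSequence(scenario.seed))
truth, arch, data, kept, _ = simulate_selected_replicate(scenario, rng)

for name, est in [("MR+MVMR", TwoStepMR()), ("LiMA", LiMA()), ("I-LiMA", ILiMA())]:
    est.fit(data)
    if name == "MR+MVMR":
        var_a, var_t = est.var_alpha_, est.var_theta_
    else:
        var_a, _, var_t, _, _ = lrt_variances(
            est.alpha_, est.omega_, est.profile_loglik_ao(data))
    mp = mp_single(est.alpha_, est.theta_, var_a, var_t)
    print(name, mp.mp_hat, mp.ci)
```

Output:

```
true alpha=+0.1695  omega=+0.0299  theta=+0.1994  MP=0.15  mediators kept=4/10
MR+MVMR  alpha=+0.1876 theta=+0.2026 MP=+0.074  95% CI [+0.028, +0.121]
LiMA     alpha=+0.1790 theta=+0.2026 MP=+0.116  95% CI [+0.069, +0.164]
I-LiMA   alpha=+0.1804 theta=+0.2042 MP=+0.117  95% CI [+0.068, +0.165]
```

All three recover θ̂ ≈ 0.20, but the two-step baseline overestimates the
direct effect (regression dilution of the mediated path) and halves the
estimated mediation proportion; the likelihood methods recover most of it.
Part of the remaining gap is structural: only 4 of the 10 mediators passed
selection in this replicate.

Scenario sweeps and full benchmarks run through `lima.bench`:

```python
from lima.bench import run_scenario, default_scenario
res = run_scenario(default_scenario(seed=1), n_reps=300)
print(res.to_long_frame())
```

or the CLI: `lima bench --methods mr,lima,ilima --seed 1 --out out/`,
`lima simulate --out sim/`, and `lima pipeline --exposure X.tsv
--mediators meds/ --outcome Y.tsv --out model/` for harmonized real
summary-statistic tables (header: `variant_id effect_allele other_allele
beta se p n`).

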