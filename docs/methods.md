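# Methods

## Mediation framework

All traits (exposure *X*, outcome *Y*, mediators *M₁…M_k*) and genotypes are
standardized to zero mean and unit variance, so a marginal genetic effect
estimated in a study of size *n* carries sampling variance ≈ 1/n. The causal
model is θ = α + γ′δ with the mediation proportion MP = 1 − α/θ. Mediator
instruments are assumed to have no effect on the exposure (their design
block is fixed at zero), instruments are assumed independent (pre-clumped),
and pleiotropic instrument effects are assumed independent of instrument
strength with mean zero (the InSIDE condition). Mediator effect estimates
are assumed to come from one sample of common size n_M, disjoint from the
outcome sample.

## Sampling model

Given true effects (β, B, γ, δ, α):

* β̂ ~ N(β, I_m/n_X)
* vec(B̂) ~ N(vec(B), (1/n_M)·Σ⊗I_l)
* vec(Ĉ) ~ N(vec(βγ′), (1/n_M + σ²_C)·Σ⊗I_m)
* ĉ ~ N(β(α + γ′δ), (1/n_Y + σ²_c)·I_m)
* b̂ ~ N(Bδ, (1/n_Y + σ²_b)·I_l)

Σ is the mediator phenotypic correlation matrix (unit diagonal); σ²_C, σ²_c,
σ²_b are optional pleiotropy variance components, zero by default. vec(·) is
column-major throughout, and correlated noise is applied through the
Cholesky factor of Σ.

## Estimators

**TwoStepMR.** θ̂ = (β̂′Λ⁻¹β̂)⁻¹β̂′Λ⁻¹ĉ with Λ = diag(Var ĉᵢ); α̂ and δ̂ from the
weighted regression of (ĉ, b̂) on the stacked design [[β̂, Ĉ], [0, B̂]].
Variances are the known-weights WLS covariances. Var(ω̂) is reported as
Var(θ̂) + Var(α̂): the two steps are separate regressions, so their
covariance is unavailable and ignored — a documented limitation of the
baseline, not of this implementation. With a single instrument the IVW
estimate reduces to the Wald ratio ĉ₁/β̂₁ with the first-order variance
Var(ĉ₁)/β̂₁². An optional LD matrix can replace the diagonal weights
(exposed but not validated at scale).

**LiMA.** Maximizes Σᵢ log p(b̂ᵢ|B̂ᵢ,δ) + Σᵢ log p(ĉᵢ|β̂ᵢ,α,γ,δ) +
Σᵢ log p(Ĉᵢ|β̂ᵢ,γ) with the conditional variances inflated for the
measurement error of the conditioning estimates:
s²_b = 1/n_Y + σ²_b + δ′Σδ/n_M, s²_c = 1/n_Y + σ²_c + θ²/n_X, and row
covariance S_C = (1/n_M + σ²_C)Σ + γγ′/n_X for Ĉ. Optimization is L-BFGS-B
with an analytic gradient (verified against finite differences), warm
started at the two-step estimates, with up to three jittered restarts;
convergence requires optimizer success or a gradient sup-norm below 1e-4.
Σ defaults to the identity inside the likelihood even when the data were
generated with correlated mediators; a user Σ is accepted. Pleiotropy
variances are fixed at zero by default and can be freed through a
log-parameterization. Non-converged fits are flagged and excluded from
group-level MP aggregation. A free-parameter count of 2k+1 (α, γ, δ) is
used.

**I-LiMA.** Under the prior (γᵢ, δᵢ) ~ N(0, [[σ²_γ, σ_γδ], [σ_γδ, σ²_δ]]),
the stacked vector (b̂, ĉ, vec Ĉ) is modeled by the moment-matched Gaussian
marginal with mean (0, β̂(α + kσ_γδ), 0) and covariance blocks
Λ_{μ²_sb} + σ²_δB̂B̂′; Λ_{μ²_sc} + σ²_ωβ̂β̂′;
I_k⊗(s²_M·I_m + σ²_γ(I_m/n_X + β̂β̂′)); plus the b̂↔vec(Ĉ) coupling
σ_γδ(B̂⊗β̂′), where σ²_ω = k(σ²_γσ²_δ + σ²_γδ), μ²_sb = 1/n_Y + σ²_b + kσ²_δ/n_M,
μ²_sc = 1/n_Y + σ²_c + (σ²_ω + (α + kσ_γδ)²)/n_X, s²_M = 1/n_M + σ²_C, and
Σ = I_k is assumed. Two facts matter for interpretation:

* The marginal is a *moment-matched Gaussian*, not the exact integral of
  the joint likelihood over the prior: ω = γ′δ is a sum of products of
  Gaussians, and the conditional variances depend weakly on (γ, δ). The
  quadrature cross-check in the test suite shows agreement in weakly
  outcome-informed regimes and quantifies the gap elsewhere.
* Evaluation never forms the dense covariance. The Ĉ-columns are i.i.d.
  rank-one-perturbed; conditioning b̂ on vec(Ĉ) collapses the coupling to a
  k×k Woodbury solve. The blocked evaluation matches a dense
  element-by-element oracle to ~1e-13.

Fitting is the three-step scheme: σ²_δ from the b̂-only profile likelihood
(1-D bounded search), σ²_γ from the Ĉ-only profile, then (α, σ_γδ) jointly
on the full marginal with the variances fixed. σ_γδ is parameterized as
ρ·σ_γσ_δ with ρ = tanh(·) so the prior stays positive semi-definite; a fit
ending at |ρ| → 1 is flagged. ω̂ = k·σ̂_γδ and θ̂ = α̂ + ω̂. Because ω̂ is a
prior-level quantity, its per-replicate value is a model-based projection
of the realized γ′δ; group-level aggregates are the reliable target.

## Variances and the mediation proportion

For the likelihood methods, Var(α̂) = α̂²/χ²_α and Var(ω̂) = ω̂²/χ²_ω with the
likelihood-ratio statistics χ²_α = −2·log L(0, ω̂)/L(α̂, ω̂) and χ²_ω defined
analogously; Var(θ̂) = Var(α̂) + Var(ω̂). An estimate exactly at its null
yields χ² = 0 and an infinite variance, reported as such. The profile
L(α, ω) treats (α, ω) as **fixed** mean parameters of the outcome block
with its measurement-error-inflated variance — the only likelihood
component that depends on (α, ω) once ω is held fixed. For I-LiMA this is a
deliberate design choice: evaluating the ratio on the full marginal keeps
the σ²_ω β̂β̂′ term, which encodes the prior variability of ω itself;
holding it while testing ω double-counts ω's randomness and makes the test
nearly blind (the Fisher standard error of ω̂ on the marginal is of the
order of ω̂ at desk scales). The marginal variant remains available via
`ILiMA.profile_loglik_ao(data, kind="marginal")`.

Single-pair MP: MP̂ = 1 − α̂/θ̂ with the delta-method variance
(α̂²/θ̂²)(Var(α̂)/α̂² + Var(θ̂)/θ̂²); the α̂–θ̂ covariance is deliberately
omitted, matching the convention of the methods being benchmarked. Var(MP̂)
diverges as |θ̂| → 0, which is what keeps small-total-effect replicates from
producing spurious detections. A configurable |θ̂| ≥ 0.1 reporting filter
exists but is off by default. Group MP over n pairs: the no-intercept
regression MP̂ = 1 − Σα̂ᵢθ̂ᵢ/Σθ̂ᵢ², Var(MP̂) = σ²/Σθ̂ᵢ² with σ² = RSS/(n−1)
(one slope parameter; the n vs n−1 convention is not pinned down
externally, and the choice is immaterial at n = 300).

## Generative model

Mediation effects follow a spike-and-slab: the first k_s = round(p_k·k)
mediators (minimum 1 when MP > 0) draw (γᵢ, δᵢ) jointly Gaussian, the rest
are exactly zero. The slab covariance is solved from the scenario targets:
σ²_δ = σ²_{Y,M}/k_s, σ²_γ = (MP·E(θ))²/(k_sσ²_δ + (k_s² + k_s)ρ²_γδσ²_δ),
σ_γδ = ρ_γδσ_γσ_δ, which enforces E(ω)² + Var(ω) = (MP·E(θ))². E(θ) is thus
the root-mean-square of the realized total effect; with ρ_γδ = 0 the
realized θ is symmetric around zero with RMS E(θ). The direct effect is
α = ((1−MP)/MP)·γ′δ, making MP exact in every replicate; when MP = 0,
α ~ Uniform(0.5·E(θ), 1.5·E(θ)) (the support is configurable — the interval
keeps θ bounded away from zero so MP̂ stays estimable, and its exact width
is a declared choice). In MP = 0 scenarios the solved σ²_γ is zero, so null
mediators have γ = 0 but generally δ ≠ 0: they affect the outcome without
lying on the causal path, which is the realistic null.

Mediator heritabilities are i.i.d. Weibull(shape 0.5, scale 0.05) truncated
to [0, 1] (drawn by inverse CDF), emulating the heavy-right-skewed variance
explained of top cis-QTLs; instrument counts per mediator are zero-truncated
geometric with mean 3 (configurable; an empirical count file can replace
it), matching the skew of pruned cis-QTL counts without requiring the
external dataset. Instrument effects are Gaussian and rescaled post hoc so
that Σβᵢ² = h²_X and each B column's sum of squares equals h²_{M_j}
*exactly*. Σ strategies: identity; `random_vectors` (correlations of
k 10-dimensional Gaussian vectors — intentionally far from identity and
rank-deficient for k > 10, shrunk toward identity with λ = 1e-6 when
needed); or a user-supplied empirical correlation matrix.

Mediator selection mimics the study procedure: per-mediator IVW MR of
exposure→mediator, keep p ≤ P (default Bonferroni 0.05/k); if nothing
passes, the replicate is re-simulated (the count is reported — this is a
deliberate winner's-curse-inducing feature of the emulated design, and in
null scenarios it is the mechanism that inflates type-I error for
estimators that read ω̂ off the selected γ̂). I-LiMA is comparatively
protected because its ω̂ derives from the b̂–Ĉ coupling, which selection on
Ĉ alone cannot fake.

### Default conditions and inferred values

n_X = n_Y = 300,000, n_M = 10,000, E(θ) = 0.15, MP = 0.15, h²_X = 0.35,
Σ = identity, no pleiotropy, 300 replicates; k = 10, p_k = 1,
σ²_{Y,M} = 0.05, ρ_γδ = 0 as declared defaults. The number of exposure
instruments defaults to m = 100, a realistic polygenicity for a
biobank-scale complex trait; group-level bias of the two-step baseline
grows with m at fixed h²_X, so this is the one default the baseline's
headline bias is sensitive to. The ρ_γδ = 0 default is corroborated by the
selection behavior it implies (σ_γ ≈ 0.10, hence roughly 11 of 25 non-null
mediators passing a Bonferroni filter at these settings).

Replicate r uses child r of a `SeedSequence` keyed by the scenario seed, so
results are bit-reproducible and independent of batching. Identical
scenario and seed give bit-identical data.

### What the simulator does not emulate

Individual-level genotypes; LD between instruments (instruments are
independent by design); sample overlap between studies; winner's curse in
*instrument* discovery (instrument effects are true effects plus noise, not
selected on significance); binary outcomes and effect-scale conversions;
population stratification. Benchmarks passing on these simulations
demonstrate correct behavior under the stated sampling model, not
robustness to these real-data phenomena.

## Benchmark metrics

Per scenario and method over n replicates: relative bias
100·(MP − MP̂_group)/MP from the no-intercept group regression; coverage,
power (MP > 0) and type-I error (MP = 0) from per-replicate normal 95% CIs
MP̂ᵢ ± 1.96·√Var(MP̂ᵢ); the variance of MP̂ᵢ; and the non-convergence count.
Rates carry normal-approximation binomial CIs. Replicates run serially; at
the default sizes a 300-replicate scenario through all three estimators
takes seconds, so no parallelism is needed. A reduced-replication mode
(e.g. n_reps = 100) is appropriate for quick checks with correspondingly
wider Monte-Carlo intervals. The benchmark suite and the acceptance script
use 300 replicates, matching the study design.

## Applied pipeline

Harmonized tables (standardized β, one TSV per trait) flow through:
palindromic-SNP removal; genome-wide-significant instrument selection
(p < 5e-8); Steiger filtering, operationalized as removing variants whose
outcome association is both nominally significant (p < 0.05) and stronger
(smaller p) than the exposure association — the variance-explained variant
of the Steiger criterion reduces to this comparison for standardized
effects at comparable sample sizes; candidate mediator selection requiring
nominally significant exposure→mediator and mediator→outcome IVW effects
(Bonferroni in strict mode); forward-stepwise correlation pruning admitting
mediators in decreasing |γ̂_j·δ̂_j| subject to pairwise |r| ≤ 0.1 (0.5 in
relaxed mode); and block assembly with per-variant outcome variances taken
from the reported standard errors. LD clumping is not implemented: inputs
are expected pre-clumped, and a user LD matrix enables only a greedy r²
filter. Instruments shared between mediators are owned by the mediator
where they are most significant.

## Known limitations

* The I-LiMA marginal is a Gaussian approximation (see above); its
  per-replicate ω̂ is a projection, and single-pair CIs inherit that.
* MVMR/IVW variance formulas assume known weights; under strong mediator
  noise the realized residual variance exceeds the nominal one, so the
  baseline's CIs are not calibrated — reproducing that miscalibration is
  part of the benchmark's point.
* Mediator correlations are not modeled inside I-LiMA (Σ = I in its
  likelihood); the benchmark includes a correlated-mediator stress test
  showing group-level bias remains below the baseline's in the
  strongly correlated, many-mediator regime.
* The free-pleiotropy and LD-matrix options are exposed but lightly
  exercised; defaults keep them off.
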