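# Methods

## Model

Observed cycle lengths are whole days; the model works on a continuous
latent length `y_ij` with `o_ij = ⌊y_ij⌉`.  Rounding is treated as a
negligible approximation: the likelihood evaluates the integer lengths as
if continuous.  This inflates the innovation variance by roughly the
variance of a uniform rounding error (1/12 ≈ 0.08 days²), visible as a
small upward shift in the posterior of σ_ε on simulated data; no
interval-censored likelihood is attempted.

Conditional on the overdispersion cells (λ, w) the model is linear
Gaussian.  Two trend structures are supported:

* **random walk** — `m_ij = m_{i,j-1} + η_ij` with `m_i1 ~ N(β₀, σ_η²)`;
  the initial variance is σ_η², not a diffuse prior, so the first cycle is
  informative about β₀.
* **mixed-effects age trend** — `β₀ + b_{0i} + (β₁ + b_{1i}) Age_ij` with
  independent random effects (`G` diagonal; the correlation term is
  omitted because it adds nothing identifiable at these series lengths).

The ARMA(1,1) component uses zero pre-sample values (γ_i0 = ε_i0 = 0), so
`γ_ij = Σ_{t<j} ψ_t ε_{i,j-t}` with ψ_0 = 1, ψ_h = φ^{h-1}(φ+θ).  The
Kalman filter carries the MA part by state augmentation (state
`(z_j, θ ε_j)` with `z_j = φ z_{j-1} + θ ε_{j-1} + ε_j`), never by AR(∞)
truncation.  The overdispersion shock `r_ij` is a per-observation offset
known conditionally during Gibbs; it is never part of the state vector.
For the age trend the random effects are carried as constant states, so
the filter marginalises them exactly; the brute-force oracle
(`dense_loglik`) assembles the same joint covariance explicitly and is the
independent check on all of this.

## Parameters and priors

| parameter | meaning | unit | prior |
|---|---|---|---|
| β₀ | overall level / first-cycle mean | days | N(μ_β0, σ_β²), μ_β0 ~ U(24, 32) |
| β₁ | age slope (lmm trend) | days/year | N(μ_β1, σ_β²), μ_β1 ~ U(−2, 2) |
| α_k | effect per symptom report | days | N(0, 100) |
| π | probability a cycle is overdispersed | — | U(0, 1) |
| φ, θ | AR / MA coefficients | — | N(μ_ar, σ_ar²), μ_ar ~ N(0, 100) |
| σ_η, σ_ε, σ_w, σ_b0, σ_b1, σ_β, σ_ar | scale components | days | precision ~ Gamma(10⁻³, 10⁻³) |

The Gamma(κ, κ) precision priors are vague but proper; κ is configurable
(the Geweke correctness test uses κ = 3 so forward simulation stays
numerically sane).  Stationarity |φ| < 1 is enforced; θ is unconstrained
(a non-invertible MA draw is a valid model and occurs only transiently).

## Posterior computation

One Gibbs sweep (random-walk trend):

1. **Collapsed mixture cells.**  (λ_ij, w_ij) are updated cell by cell
   with *all* Gaussian states integrated out: given Θ the woman's lengths
   are jointly normal with covariance Σ = σ_η² min(j,k) + σ_ε² ΨΨ′, and
   switching one cell on is the rank-1 perturbation σ_w² e_j e_j′, so the
   Bernoulli odds follow from a determinant-lemma identity on Σ⁻¹
   (computed once per series length per sweep).  Conditioning on sampled
   states instead makes outliers that were absorbed into the trend
   invisible and the chain metastable — the collapsed form removes this.
2. **Joint state draw.**  ε_i | λ, w, Θ, y is multivariate normal (m and γ
   are then determined by y); within a series-length group the posterior
   precision is shared, so one Cholesky serves every woman of that length.
   Together with step 1 this is an exact draw of (λ, w, states).
3. **Conjugate blocks.**  π ~ Beta(1+Σλ, 1+Σ(1−λ)); all variances by
   inverse gamma; β₀, α and θ (given φ) by Normals; w_ij | λ_ij = 1 by a
   Normal; hyper-means by truncated Normals.
4. **AR coefficient.**  φ by random-walk Metropolis (scale adapted toward
   0.44 acceptance during burn-in only, then frozen).
5. **Marginal refresh.**  A Metropolis pass over (log σ_η², log σ_ε², θ, φ)
   against the state-marginalised likelihood.  The conjugate draws in
   step 3 are exact but diffuse slowly when conditioned on states; this
   partially collapsed block breaks the coupling.  States are re-drawn at
   the start of the next sweep, which keeps the scheme valid.

Correctness is tested two ways: a Geweke successive-conditional simulation
(forward data simulation alternating with sweeps must preserve the prior;
run at I = J = 4 with κ = 3) and recovery of the generating values on
synthetic cohorts.  The posterior is weakly identified along a
(π ↑, σ_w ↓, σ_ε ↓) ridge — on one 9,000-cycle simulation the exact
2^J-enumeration likelihood separated the true values from a point on the
ridge by under two nats — so single-dataset posterior means can sit a
couple of posterior SDs from the truth while coverage stays nominal.

Default chain layout is the desk-scale preset (3 chains × 1,000 sweeps,
burn-in 500, thinning 5); `McmcConfig.full_scale()` reproduces the
reference analysis layout (burn-in 10,000, thinning 50, 3,000 saved draws
per chain).  Convergence tooling: classic Gelman–Rubin R̂ with its upper
97.5% bound, chain autocorrelation, and simulated-envelope normal Q-Q
plots (used historically to reject heavy-tailed random-coefficient
extensions of φ and θ; those extensions are deliberately not implemented).

The Gibbs sampler supports overdispersion with the age trend only for the
white-noise error structure; the canonical twelve-model grid never needs
the other combinations, and the likelihood path still supports them.

## Forecasting

For each posterior draw the filter is run over the woman's observed cycles
conditional on that draw's (λ, w) history; the one-step predictive is then
an equal-weight mixture of Gaussians over draws, each split into a
standard and an overdispersed component by that draw's π.  One-step
intervals are solved from the exact mixture CDF (deterministic given the
draws); the point forecast is the predictive mean; multi-step forecasts
sample forward paths from the filtered state.  Future covariate offsets
default to zero — next cycle's symptoms are unknown at forecast time — with
a carry-forward option; intervals are equal-tailed (a highest-density
variant was considered and rejected as harder to compare across levels).
Forecasts require the woman to be in the training cohort, because her
overdispersion history is part of the posterior.

## Evaluation and selection

RMSE, Pearson r, Lin's CCC (population 1/n moments, per the original
definition — sample-variance versions differ at small n) and
C_b = CCC/r are computed between held-out last cycles and their one-step
forecasts.  The BIC variant used for fit comparison is
`(N−p) log(N σ_ε²/(N−p)) + p log[(Σ y² − N σ_ε²)/p]` with σ_ε² plugged in
as its posterior mean (configurable to the median) and p a tabulated
parameter count per structure plus one per covariate.  Staged selection
fits the candidate grid, keeps specs within 2% relative RMSE of the best
forecaster, and picks minimal BIC among them; stage 3 retains covariates
whose 95% interval excludes zero.  The attrition-aware evaluation predicts
each test woman's n-th cycle from her first n−1 for n = 3…12, with women
owning fewer cycles remaining in the training fit, and reports Lin's
asymptotic CCC interval per scenario.

Note that this BIC depends on the error structure only through σ_ε² and p,
so it sharply rewards the overdispersion term (which absorbs outlier
variance) but cannot reward a trend that merely re-labels variance between
σ_η² and random effects; on data simulated from the age-trend model both
trends recover the same σ_ε and the random walk wins on parsimony.  The
selection tests therefore assert the robust direction (random-walk data
reject the mixed model).

## Synthetic cohorts

The generator emulates the shape of large athlete cycle-tracking cohorts:
4–53 cycles per woman (uniform), starting ages uniform on 18–47 advancing
by the realised cycle length / 365.25, symptom counts independent Poisson
with sparse default rates (most cells zero; flow levels a few reports per
cycle), and model parameters defaulting to the published posterior means
(β₀ = 27.41 d, π = 0.2636, θ = −0.0915, σ_η = 1.04 d, σ_w = 4.78 d,
σ_ε = 1.54 d, α per symptom).  Each woman has her own deterministic
substream, so cohorts are reproducible when the cohort grows.  What the
generator does not emulate: reporting-engagement effects (symptom counts
correlated with cycle phase or user behaviour), missing BMI patterns,
age-correlated cycle change, or within-cycle daily structure — so passing
recovery and calibration tests demonstrates internal consistency of model
and inference, not fidelity to any real cohort.

## Validation studies and problem sizes

The reproduction script runs, at sizes chosen to finish in minutes on one
CPU: oracle agreement on 200 random small instances across all twelve
structures (tolerance 10⁻⁸ nats); recovery coverage over 5 replicates of
300 women × 4–12 cycles at the desk-scale chain layout; forecast-interval
coverage on 500 held-out cycles; detection of 40 injected outlier cycles
(|w| ≥ 4σ_ε, reported as the mean posterior probability over injected and
clean cells); and selection over a reduced four-spec grid, 5 replicates of
120 women.  Known limitations: sparse covariates (e.g. an injury rate of
0.1 reports/cycle) are weakly identified at these sizes, and the
desk-scale chains leave mild residual autocorrelation in θ — both shrink
at the full-scale settings.
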