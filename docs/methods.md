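# Methods

## Probabilistic model

Two circular stimulus features s₁, s₂ ∈ (−180°, 180°] generate cues x₁, x₂
with von Mises likelihoods M(x_m; s_m, κ_m); the prior
p(s₁,s₂) ∝ exp[κ_s cos(s₁−s₂)] encodes that features from a common cause
coincide. Marginalizing gives p(s₁|x₁,x₂) ∝ M(s₁;x₁,κ₁)·M(s₁;x₂,κ₂ₛ) where
κ₂ₛ solves A(κ₂ₛ) = A(κ₂)A(κ_s), A(κ) = I₁(κ)/I₀(κ). That step is an
approximation: the convolution of a von Mises likelihood with a von Mises
prior is not itself von Mises, and we match it by equating mean resultant
lengths. The package implements only this matched form; in the sharp limit
it reduces to the Gaussian rule κ₂ₛ⁻¹ ≈ κ₂⁻¹ + κ_s⁻¹ (the unit tests
quantify the residual against a quadrature oracle, they do not correct it).

Products of von Mises densities are vector sums of κe^{jμ} vectors, so
integration is a vector sum, the disparity distribution
p_d(s₁|x₁,x₂) ∝ p(s₁|x₁)/p(s₁|x₂) a vector difference, and the two together
satisfy a parallelogram law |v₊|² + |v₋|² = 2(κ₁² + κ₂ₛ²). The direct-cue
posterior is the half-sum of the two vectors — recovered exactly, which the
suite asserts for 1000 random cue pairs. The Gaussian-approximation
information loss of cue 1 after integration is
κ₁⁻¹/(κ₁⁻¹ + κ₂⁻¹ + κ_s⁻¹), increasing in κ_s.

Degenerate cases are explicit rather than silent: a zero resultant (e.g.
equally reliable cues exactly 180° apart) returns the uniform distribution
with an `mu_defined = False` flag, and sample-based concentration estimates
saturate at κ = 10⁸ for all-identical samples. Infinite concentrations are
represented by the sentinel 10¹² whose resultant is treated as 1.
`inv_resultant` is bracketed Brent root finding (no closed form exists),
tolerance 10⁻¹⁰; `effective_kappa` is memoized.

## Network model

Two modules, each with one congruent and one opposite group of N = 180
rate neurons on the ring θ_i = −180° + i·360/N (i = 1…N). Dynamics per
group:

τ du/dt = −u + W_rc r + W_rp r_other + I,  r = [u]₊² / (1 + ωD),

with D = Σ[u]₊² + J_int·Σ[u′]₊² pooling the group's own rectified-squared
input and a J_int-weighted share of the sibling group's. All kernels are
von Mises with width a: W_rc = J_rc exp[a cos Δθ]/(2π I₀(a)) within a
group; reciprocal kernels have strength J_rp and are either aligned
(congruent groups) or offset by 180° (opposite groups) — the offset is the
entire mechanism behind opposite tuning. Feedforward drive to module m is
α_m U₀ exp[a(cos(θ−x_m)−1)/2] plus background I_b, with multiplicative
noise of Fano factor F: per Euler step the noise SD is √(F·mean/dt), the
Euler–Maruyama scaling under which the time-integrated input has
variance/mean = F. Cue noise is shared by the two groups of a module;
background noise is private per group. One master seed spawns named
streams (two cue fields, four backgrounds, jitter) so toggling one noise
source leaves the others' draws unchanged.

Defaults (dimensionless time in units of τ = 1): a = 3 (≈40° tuning
width), ω = 3×10⁻⁴, J_int = 0.5, I_b = 1, F = 0.5, dt = 0.01, J_rc = 0.3 J_c,
J_rp = 0.5 J_rc, cue intensities α ∈ [0.3, 1.5] in units of
U₀ = J_c e^{a/2}/[2πω(1+J_int)I₀(a/2)].

**Critical coupling J_c.** J_c — the smallest recurrent strength at which
an isolated module holds a persistent bump after its drive is removed —
has no closed form we consider trustworthy for this discrete system, so it
is a configuration constant with an empirical estimator attached:
`estimate_critical_strength` bisects the absolute recurrent strength,
driving both groups of one module (shared inhibition fully engaged),
removing the drive, and testing bump survival over 200τ. The default
J_c = 0.01258 is the estimator's value at the default a, ω, J_int (hold
400τ); all coupling strengths and U₀ scale linearly with it.

**Discretization.** The model equations are written as plain sums over
N = 180 neurons (with ω = 3×10⁻⁴ this is what puts the saturation rate
near 50 Hz). To make behaviour independent of the grid, every population
sum (recurrent, reciprocal, and the pools D) carries a density weight
180/N: parameters are quoted at the reference density of 180 neurons per
2π, and at N = 180 the weight is exactly 1. Tests verify that halving N
leaves bump positions and heights essentially unchanged.

**Reciprocal jitter.** Intermediate-tuned neurons are produced by adding
random components to the reciprocal connections: each entry receives an
independent additive term η·(kernel peak), η ~ Uniform(−g, g), clipped at
zero, default g = 0.9. The component must be *additive*: perturbations
proportional to the kernel profile leave every row's peak in place and
average out under the activity bump, and measurably produce no
intermediate neurons at all, whereas an additive component can relocate a
row's effective peak, giving the observed bimodal preferred-direction-
difference histogram (modes at 0° and 180°) with a few percent of mass in
between at g = 0.9.

**Integration details.** Euler steps with dt = 0.01τ (validated ≤ 0.1τ);
noise drawn in fixed 512-step blocks for speed (the draw order, hence the
trace, is seed-deterministic); burn-in of 50τ (30τ for shorter protocols)
discarded before sampling; traces sampled every step, stored float32.
Non-finite states abort with a diagnostic exception. Simulations of
reduced grids (N = 36, dt = 0.05) are used as fast test fixtures; all
headline checks run at N = 180, dt = 0.01.

## Decoding and optimality checks

Bump positions are read out per sample by population vector
z = arg Σ_θ r(θ)e^{jθ}; a stationary stretch of z-samples is summarized by
its circular mean and κ = A⁻¹(resultant). The standard error of the mean
uses batch means (20 contiguous blocks), which absorbs the ≈1–3τ
autocorrelation of the bump position.

The optimality predictions are vector algebra on single-cue estimates:
sum for congruent groups, difference (equivalently the sum of the opposite
group's own single-cue estimates — both forms implemented and
cross-checked) for opposite groups. Equality of decoded and predicted
estimates is tested as |Δmean| ≤ max(2·√(SE_obs² + SE_pred²), 360°/N) —
two standard errors with a floor of one grid spacing, since decoded means
carry a systematic quantization of that order — and reliabilities as the
κ ratio within [0.8, 1.25] evaluated per sweep (geometric mean over the
sweep's conditions): individual κ estimates from T ≈ 400τ of samples have
≈10–15 % sampling noise, so the band is resolved at the sweep level, not
per condition. Sweeps cover α₁ ∈ {0.4, 0.7, 1.0, 1.3} U₀, cue 2 direction
∈ {40°, 90°, 160°}, and J_rp ∈ {0.2, 0.35, 0.5} J_rc at α = 0.7 U₀. At
stronger reciprocal coupling (J_rp ≳ 0.6 J_rc) the opposite group's
combined-cue mean deviates systematically by ~2–4° from the vector-sum
prediction: its two inputs are nearly antipodal and the normalization-
mediated competition between groups breaks the additivity the prediction
assumes; the analogous effect sharpens congruent estimates slightly beyond
the prediction at very small disparities. These are properties of the
model itself, not decoding artifacts (the congruent prediction matches to
a fraction of a degree at the same operating points).

Single-cue recovery uses the rate-weighted form
ŝ₁(t) = arg[(Σr_c)e^{jz_c} + (Σr_o)e^{jz_o}] — summed firing rate stands
in for the concentration of the represented distribution. Its quality is
summarized by R² with residuals wrapped to (−180°, 180°] about the
identity line and total variance about the circular mean of the reference
(the plain-R² convention applied to circular data).

## Neurometrics

Tuning curves come from one long equilibrium run per probe, time-averaged.
Preferred direction is the rate-weighted circular mean of the probe grid.
Disparity discrimination follows the fixed-center protocol: x₁ + x₂ = 0,
disparity swept over ±32°, 30 trials per condition realized as contiguous
equilibrium segments of one long run (stationarity makes segments
exchangeable with independent trials at a fraction of the burn-in cost).
The ROC fraction is the Mann–Whitney probability P(rate_a > rate_b) with
half-credit ties, pairing +d against −d (the "was x₁ > x₂" task); for the
heading task the reference is the 0°-heading trial distribution — the
construction leaves the reference implicit, and this is our documented
choice. Neurometric points are fitted by unweighted least squares with
Φ((d−μ)/σ), multi-start, σ bounded positive; σ is the discrimination
threshold, and degenerate data return a flagged result rather than a fake
fit. The optimal combined-cue threshold is σ₁σ₂/√(σ₁²+σ₂²). The
integration-vs-segregation boundary is the interpolated crossing of the
congruent and opposite rate-vs-disparity curves; the rate statistic is the
peak of the temporally averaged population profile (bump height), which
carries the represented reliability — the population mean is also
available (`statistic="mean"`).

The classification bands used when reporting intermediate neurons
(congruent |Δpref| < 60°, intermediate 60–120°, opposite > 120°) are a
reporting convention; raw differences are always emitted.

## What the synthetic protocols do and do not show

All inputs are generated by the package itself (stochastic feedforward
drives under configured protocols); there is no external data. Passing
tests therefore show that the network implements the stated probabilistic
computations under its own idealized noise model — independent Gaussian
white noise with Poisson-like scaling, perfectly symmetric modules,
stationary cues. They do not show robustness to structured cortical noise
correlations, asymmetric module sizes, temporal cue dynamics, or the
monkey electrophysiology the model is meant to explain; comparisons to
recorded data are out of scope.

## Problem sizes

The test suite and the acceptance script run the full-size network
(N = 180, dt = 0.01τ) with run lengths of 60–500τ per condition and
reduced sweep grids (e.g. 30–32 random configurations for the recovery
R², probe steps of 15–30°, 9 disparities × 30 trials for ROC); these
sizes are the package's defaults for desk-scale reproduction and are
recorded in each experiment preset. Known limitations: optimality is
approximate near winner-take-all competition (large J_rc + J_rp) and the
κ-ratio checks need sweep-level aggregation at these run lengths; the
N-cue generalization and the two-component causal-inference prior are
documented extension points, not implemented.
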