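# multicue

Concurrent multisensory integration and segregation with congruent and
opposite neurons: a von Mises Bayesian model of circular cue combination and
a decentralized two-module continuous attractor network (CANN) that
implements it, with population-vector decoding and ROC neurometric analyses.

## The scientific problem

When two sensory cues (say, the optic-flow and vestibular estimates of
heading direction) come from the same event they should be *integrated* for
a sharper percept; when they come from different events they should be
*segregated*. The brain does not know in advance which situation it is in —
and once cues are integrated, the single-cue information is lost. This
package models a proposed resolution: two interconnected multisensory
modules (MSTd- and VIP-like), each containing *congruent* neurons (same
preferred direction under either cue) that integrate the cues, and
*opposite* neurons (preferred directions 180° apart) that simultaneously
encode the cue *disparity*, so that the validity of integration can be
judged and single-cue estimates recovered on demand.

## Model

Heading is circular, so cues are modelled with von Mises likelihoods
p(x_m|s_m) = M(x_m; s_m, κ_m) ∝ exp[κ_m cos(x_m − s_m)] and a prior
p(s₁,s₂) ∝ exp[κ_s cos(s₁ − s₂)] that favours coincident features.
Writing each distribution as the vector κ e^{jμ}:

- **integration** — κ̂₁ e^{jŝ₁} = κ₁ e^{jx₁} + κ₂ₛ e^{jx₂} (vector sum),
- **segregation** — Δκ̂₁ e^{jΔŝ₁} = κ₁ e^{jx₁} − κ₂ₛ e^{jx₂} (vector
  difference),

where the indirect cue acts through an effective concentration κ₂ₛ defined
by A(κ₂ₛ) = A(κ₂)A(κ_s), with A(κ) = I₁(κ)/I₀(κ) the mean resultant
length. Because ln p(s₁|x₁) = [ln p(s₁|x₁,x₂) + ln p_d(s₁|x₁,x₂)]/2, the
direct-cue posterior is recoverable exactly from the integrated and
disparity distributions.

The network realizes this with two modules of rate neurons on a ring,
divisive normalization r = [u]₊²/(1 + ωD) with partially shared inhibition
pools, von Mises recurrent connections, and reciprocal connections between
modules that are congruent for congruent groups and offset by 180° for
opposite groups. Bump positions decoded by population vector
z = arg Σ_θ r(θ)e^{jθ} sample the posterior the population encodes.

## Worked example

```python
from multicue import (CuePair, NetworkParams, CueStimulus, simulate,
                      posterior_integrated, posterior_disparity,
                      recover_single_cue, population_vector)
from multicue.circstats import circ_estimate

# Bayesian layer: cues at 0 and 20 degrees, kappa1 = kappa2 = kappa_s = 50
c = CuePair(x1=0.0, x2=20.0, kappa1=50.0, kappa2=50.0, kappa_s=50.0)
integ, disp = posterior_integrated(c), posterior_disparity(c)
print(f"integrated: mu={integ.mu:.2f} deg, kappa={integ.kappa:.1f}")
print(f"disparity:  mu={disp.mu:.2f} deg, kappa={disp.kappa:.1f}")
rec = recover_single_cue(integ, disp)
print(f"recovered direct cue: mu={rec.mu:.2f} deg, kappa={rec.kappa:.1f}")

# Network layer: cue 1 alone at -30 degrees, intensity 0.35 U0
p = NetworkParams(seed=3)
trace = simulate([CueStimulus(-30.0, 0.35, module=1)], p,
                 duration=100.0, burn_in=50.0)
z = population_vector(trace.rates(2, "o"), p.theta_deg)
est = circ_estimate(z)
print(f"module-2 opposite bump: mean={est.mu:.1f} deg, kappa={est.kappa:.0f}")
```

prints

```
integrated: mu=6.68 deg, kappa=74.2
disparity:  mu=-18.20 deg, kappa=27.7
recovered direct cue: mu=0.00 deg, kappa=50.0
module-2 opposite bump: mean=150.0 deg, kappa=75
```

The integrated estimate lies between the cues but closer to the direct one
(κ₁ > κ₂ₛ); the disparity distribution points near the negative cue
difference; the recovery identity returns (0°, 50) exactly; and the
opposite population in the *other* module represents the cue shifted by
180° (−30° + 180° = 150°), which is what lets it encode disparity under
combined cues.

Experiment presets (tuning curves, optimality sweeps, decision boundary,
recovery, ROC discrimination) are available from the command line:

```bash
multicue list-presets
multicue run --preset decision --seed 1 --out runs/decision
multicue plot --run-dir runs/decision
```

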