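# wtdepr

**Entropy-production lower bounds from waiting-time distributions of
coarse-grained active oscillators.**

Living systems dissipate energy, and the entropy production rate (EPR)
quantifies how far from equilibrium they operate.  Measuring the EPR is
hard when only part of the system is observable: in spontaneously
oscillating auditory hair bundles, the bundle tip position `X1` can be
recorded, but the molecular motors driving the oscillation (`X2`) are
hidden, and the observed coordinate alone carries no net current.  This
package implements a non-invasive estimator for exactly this situation,
aimed at researchers in stochastic thermodynamics and active-matter
biophysics.

## Method

The pipeline has three stages:

1. **Simulate** the active hair-bundle model — two coupled overdamped
   Langevin equations

   λ₁ Ẋ₁ = −∂V/∂X₁ + √(2 k_B T λ₁) ξ₁
   λ₂ Ẋ₂ = −∂V/∂X₂ − F_act(X₁,X₂) + √(2 k_B T_eff λ₂) ξ₂

   with a gating-spring potential `V`, motor force
   `F_act = F_max (1 − S P₀)` regulated by the channel open probability
   `P₀`, and motor noise at an effective temperature `T_eff > T`.  The
   total EPR follows from the Stratonovich heat and active-work currents,

   EPR_tot = −⟨Q̇₁⟩(1/T − 1/T_eff) + ⟨Ẇ_act⟩/T_eff.

2. **Coarse-grain** the observed coordinate `X1` into `N` discrete states
   (equal-width bins, or wide boundary bins with narrow interior bins).
   The resulting jump chain is linear — it supports no cycles, hence no
   net current — but it is *not* Markov: the dwell time at a state depends
   on the previously visited state (second-order semi-Markov statistics).

3. **Estimate** irreversibility from passages `i → j → k`.  Two additive
   contributions bound the total EPR from below:

   EPR_aff = (1/τ) Σ p(ijk) ln[ p([ij]→[jk]) / p([kj]→[ji]) ]
   EPR_WTD = (1/τ) Σ p(ijk) D[ Ψ(t|ijk) ‖ Ψ(t|kji) ]

   where `Ψ(t|ijk)` is the conditional dwell-time density at `j`,
   `D[·‖·]` the Kullback–Leibler divergence (k-nearest-neighbour
   estimator), `p(ijk) = R₍ij₎ p([ij]→[jk])` and `τ` the mean step
   duration.  On a linear chain EPR_aff vanishes, so all irreversibility
   lives in the waiting-time asymmetry.  The mean dwell-time asymmetry
   factor, MDAF = mean of ⟨τ_kji⟩/⟨τ_ijk⟩, is the first-moment footprint
   of the same asymmetry (1 under time reversibility).

A six-state continuous-time Markov chain lumped to three observed states
provides a benchmark with an exactly computable total EPR (Schnakenberg
network formula), and a synthetic second-order semi-Markov generator with
Exponential/Gamma dwell laws provides closed-form ground truth for every
estimator.

## Worked example

```python
from wtdepr import FIG1_PRESET, SimConfig, simulate
from wtdepr.estimators import TrajectoryDiscretizer, SemiMarkovEPR
from wtdepr.thermo import total_epr

traj = simulate(FIG1_PRESET, SimConfig(dt=0.01, n_steps=2_000_000,
                                       burn_in_steps=100_000, seed=1))
tot = total_epr(traj)
chain = TrajectoryDiscretizer(n_states=7, scheme="equal").fit(traj).transform(traj)
est = SemiMarkovEPR(seed=1).fit(chain)
```

prints (via the obvious `print` statements):

```
EPR_tot  = 7.3231 +- 0.0735 kB/s
jumps    = 32198
EPR_aff  = 4.88e-05 kB/s
EPR_WTD  = 0.1009 +- 0.0000 kB/s
MDAF     = 1.0852 +- 0.0205
ratio    = 0.0138
```

The driven preset (`F_max = 70 pN`, `S = 1`, `T_eff/T = 1.5`) dissipates
about 7.3 k_B/s in total.  After discretizing the tip position into 7
equal bins, the affinity part is statistically zero (linear topology),
while the waiting-time part recovers ≈ 0.10 k_B/s — a genuine lower bound
on the total, about 1.4 % of it, with a mean dwell-time asymmetry of
≈ 1.09.  The same analysis from the shell:

```sh
wtdepr ctmc-demo --n-jumps 200000 --seed 0
```

```
macro jumps     = 147144
EPR_aff         = 3.86166e-17 kB/s
EPR_WTD         = 0.232992 +- 0 kB/s
MDAF            = 1.90789
Schnakenberg    = 12.9837 kB/s (exact total)
```

Here the lumped six-state benchmark shows the estimator at work where the
exact answer is known: the bound 0.233 k_B/s sits below the exact
Schnakenberg EPR of 12.98 k_B/s, and the dwell-time asymmetry (MDAF ≈ 1.9)
flags the hidden driving even though the observed three-state chain
carries no net current.

Other entry points: `wtdepr simulate-bundle`, `coarse-grain`, `estimate`,
`sweep` (full parameter-grid orchestration with a JSON/TSV report), and
`simulate-ctmc`.

## Documentation

`docs/methods.md` describes the model, the estimator numerics (KLD
estimation on lattice-valued dwell samples, exclusion rules, bootstrap
errors), the synthetic benchmark design, and known limitations.
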