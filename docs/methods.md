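# Methods

## The physical model

The active hair-bundle model couples an observed coordinate `X1` (bundle
tip position, nm) to a hidden coordinate `X2` (motor position, nm)
through the potential

    V(X1, X2) = k_gs ΔX²/2 + k_sp X1²/2 − N k_B T ln[exp(k_gs D ΔX / N k_B T) + A],

with `ΔX = X1 − X2` and `A = exp[(ΔG + k_gs D²/2N)/k_B T]`.  The last
term is the free energy of `N` independent two-state transduction
channels; its derivative produces the gating force `−k_gs D P₀` with open
probability `P₀ = 1/[1 + A exp(−k_gs D ΔX / N k_B T)]`.  The motors exert
the non-conservative force `F_act = F_max (1 − S P₀)` on `X2` and feel
thermal noise at `T_eff ≥ T`.  Driving enters through `F_max` and
`T_eff/T > 1`; with `F_max = 0` and `T_eff = T` the model is an
equilibrium system and every irreversibility estimate must vanish.

### Units

Lengths are nm, forces pN, energies pN nm, and the model time unit is the
second (frictions in pN s/nm).  With `k_B = 1`, entropy rates come out in
k_B per second with no conversion factor.  The default parameter preset
(`FIG1_PRESET`) is λ₁ = 2.8, λ₂ = 10 pN s/nm, k_gs = 0.75, k_sp = 0.6
pN/nm, D = 61 nm, k_B T = 4 pN nm, ΔG = 10 k_B T, F_max = 70 pN, S = 1,
T_eff/T = 1.5.

### Parameters chosen where the literature is silent

* `N_channels = 50`, the value used throughout the hair-bundle modelling
  literature.  With it, the driven preset dissipates 7.32–7.38 k_B/s
  (run-to-run), matching the reference value 7.3312 k_B/s to under 1 %.
  The waiting-time quantities depend more strongly on this choice than
  the total EPR does; it is configurable.
* Integration: Euler–Maruyama with `dt = 0.01 s`.  The fastest relaxation
  time is λ₁/k_gs ≈ 3.7 s, so the default step resolves it by ~370
  substeps.  A step-halving test checks that steady-state means are
  step-size independent within Monte-Carlo error.  Divergence (|x| >
  10⁴ nm) aborts with a step-size diagnostic.
* Run lengths: headline runs use 10⁷ steps after 10⁵ burn-in (about ten
  seconds of compute); the test suite uses 1.5–3 × 10⁶ steps.  All
  lengths are configuration fields.
* All logistic/log-sum-exp expressions use stable branch forms, so `P₀`
  and `V` are finite and monotone for any finite input.

## Total EPR from trajectories

The heat current ⟨Q̇₁⟩ = ⟨(∂V/∂X1) ∘ Ẋ₁⟩ and active-work rate
⟨Ẇ_act⟩ = −⟨F_act ∘ Ẋ₂⟩ are discretized with the Stratonovich midpoint
rule: integrands are evaluated at the midpoints of *both* coordinates and
multiplied by the corresponding coordinate increment.  The total EPR is

    EPR_tot = [ −⟨Q̇₁⟩ (1 − T/T_eff) + ⟨Ẇ_act⟩ T/T_eff ] / (k_B T),

exactly linear in the two currents (same increments, same midpoints), so
the identity is machine-precision testable.  Standard errors come from 20
non-overlapping contiguous blocks of increments (count configurable).
At equilibrium the prefactors make the estimate identically zero.

## Coarse-graining

The observed series is thresholded into `N ≥ 3` bins.  Two schemes:

* `equal` — widths 1:1:…:1;
* `unequal` — widths 1 : 1/(N−2) : … : 1/(N−2) : 1 (identical to equal
  for N = 3), concentrating resolution in the interior where irregular
  oscillations spend their time, so that boundary states keep enough
  statistics.

The reference span defaults to the empirical min/max of the series
(`mean ± 3 std`, clipped, is available); the choice is recorded in sweep
manifests.  Bins are half-open and lower-inclusive, the last bin closed;
out-of-span values land in the nearest boundary bin.  Runs of identical
labels merge into dwells (count × sampling interval), conserving total
time exactly.  There is no debouncing or milestoning of fast recrossings:
the plain-lumping convention is part of the method, and recrossing noise
is controlled only through the sampling-rate guidance below.

A linearity gate reports the fraction of jumps with |Δstate| > 1, which
can only arise from under-sampling a continuous path; estimation refuses
chains above a threshold (default 0.1 %).  A coverage check warns when
any passage type has fewer samples than the estimator minimum — the
practical failure mode of equal partitions on rugged trajectories.

## Second-order semi-Markov statistics and the bounds

Every internal position of a jump chain contributes a passage
`i → j → k` with its dwell at `j`.  From these: pair occupancies
`R[i,j]`, pair-conditioned transition probabilities `p([ij]→[jk])`,
conditional mean dwells `τ[i,j]`, the mean step duration
`τ = Σ R[i,j] τ[i,j]`, and per-triplet dwell samples.

* **EPR_aff** uses the transition probabilities only.  A forward
  transition with no observed reverse makes it formally unbounded; this
  is reported as `inf` with a warning, since on finite data it usually
  signals undersampling.
* **EPR_WTD** sums `p(ijk) D[Ψ(t|ijk) ‖ Ψ(t|kji)] / τ` over pass-through
  triplets (`i ≠ k`).  Reflection triplets compare a density with itself
  and contribute exactly zero, so they are skipped.  Triplets with fewer
  than `min_samples` (default 50) dwell samples in either direction are
  excluded and listed with reasons.
* **MDAF** averages ⟨τ_kji⟩/⟨τ_ijk⟩ over observed direction pairs, the
  upward passage (increasing state index) in the denominator.  The
  normalizer divides by the number of contributing pairs; dividing by the
  number of states `N` instead is available behind a flag
  (`normalizer="n_states"`).  The pair count is the natural normalizer
  because a linear N-state chain contributes a variable number of
  direction pairs depending on which passages are actually sampled.

## KLD estimation

Default: the k-nearest-neighbour divergence estimator (k = 5) on the raw
dwell samples,

    D̂ = (1/n) Σ ln(ν_k/ρ_k) + ln(m/(n−1)),

with ρ_k the k-th neighbour distance within the sample of `p` and ν_k the
k-th neighbour distance into the sample of `q`.  Dwells from a uniformly
sampled trajectory sit on a lattice (integer multiples of the sampling
interval); exact ties would produce zero neighbour distances, so tied
samples are dithered by a uniform jitter of half the smallest positive
spacing, seeded and deterministic.  Raw estimates below zero are clipped
to 0 for the EPR sum (the divergence is non-negative); raw values are
kept in diagnostics.  A shared-bin histogram estimator on the log-time
axis (0.5 pseudo-count smoothing) serves as a cross-check; on driven
hair-bundle chains the two agree to a few per cent.

The estimator is consistent but carries a small negative finite-sample
bias for smooth heavy-tailed laws (measured: about −0.03 nats at
n = 2 × 10⁴ for a Gamma pair with true divergence 0.61, shrinking roughly
as n^(−1/2)).  Because EPR_WTD is a *lower* bound on the total EPR, a
negative bias is conservative.  Bootstrap standard errors (resampling the
dwell samples; for the pipeline, circular block bootstrap over contiguous
jump blocks) cover this bias at the sample sizes the tests use.

## The CTMC benchmark

A six-state chain on two branches (1, 2, 3 and primed twins) forms a
driven cycle 1→2→3→3′→2′→1′→1 with forward rates u₁ = 10, u₂ = 3, reverse
rates l₁ = l₂ = 1 on the up-branch, rung rates r₁ = r₂ = 3 and down-branch
rates d₂ = 4, d₁ = 2.  Edges without a physical reverse get a small
reverse rate ε = 0.01 so the Schnakenberg EPR

    Σ_(i<j) (π_i w_ij − π_j w_ji) ln[(π_i w_ij)/(π_j w_ji)]

is finite (ε = 0 is supported for simulation only and reports `inf`).
The exact topology is a reconstruction — the six-state model is specified
in the literature only by its rates and its lumped behaviour — so it is
validated qualitatively: lumping {i, i′} → i produces a linear three-state
chain whose up/down waiting-time distributions differ under driving and
coincide under detailed balance.  The default spec's exact EPR,
12.9837 k_B per unit time, is frozen as a regression constant.  Gillespie
simulation is exact and seeded; the lumped chain merges consecutive equal
macrostates, conserving total time to machine precision.

## Synthetic benchmarks

`SemiMarkovSpec` realizes a second-order semi-Markov chain directly:
pair-conditioned transition probabilities and per-triplet dwell laws
restricted to Exponential and Gamma, for which every pairwise KLD has a
closed form (both reduce to Gamma(shape, rate)).  The stationary pair
occupancy is solved from the embedded pair chain, giving
`analytic_epr_wtd` (and `analytic_epr_aff`) exactly — the ground truth
for estimator-recovery tests at 10³–10⁵ jumps.  The time-reversible null
(symmetric random walk, direction-blind dwell laws) has EPR_aff =
EPR_WTD = 0 and MDAF = 1 by construction and calibrates the false-positive
rate: across 100 seeds, the estimate exceeds twice its bootstrap error in
far fewer than 10 % of runs.

What the generator does *not* emulate: multimodal waiting-time densities
(internal cycles), dwell laws outside the Exponential/Gamma menu, and the
lattice discreteness of dwells obtained by thresholding a sampled
continuous path.  Passing the recovery suite therefore shows estimator
correctness on smooth unimodal laws; the lattice case is exercised by the
Langevin and CTMC pipelines instead.

## Resolution dependence and desk-scale behaviour

EPR_tot is insensitive to the analysis resolution and reproduces the
reference dissipation of the driven preset to under 1 %.  The waiting-time
bound, by contrast, depends on the partition span, the number of states,
and the run length.  On desk-scale runs (1.5 × 10⁶ steps) the bound rises
steeply from N = 3 (~10⁻³ k_B/s) to N = 4 and then saturates around
0.09–0.12 k_B/s through N = 7 — between one and two orders of magnitude
below the total EPR — while the MDAF's deviation from unity grows with N.
Strict monotonicity of the bound in N is not resolved at this scale; the
orchestration layer (`run_sweep`) exposes all lengths so longer profiles
can be run where needed.

## Numerical choices and edge cases

* Seeds: every stochastic stage (integrator, Gillespie, generator,
  dithering, bootstraps) takes an explicit seed; identical configurations
  are bit-reproducible.
* Degenerate inputs: a series that never leaves one bin yields a flagged
  single-record chain that estimation refuses; chains shorter than three
  states cannot produce a triplet and are rejected; absorbing CTMC states
  abort Gillespie with a diagnostic; reducible chains are rejected by the
  stationary solve.
* Bootstrap defaults: 200 replicates for MDAF (cheap, mean-based), 0 for
  per-triplet KLD errors in the pipeline (enable via `n_boot_kld`), 200
  replicates over 50 blocks for the block bootstrap.
* The sweep continues past per-cell failures, flagging them in the
  `status` column, and its manifest records seeds, config, versions and
  output checksums.

## Known limitations

* EPR_WTD inherits the coarse-graining: it is a bound, not an estimate of
  EPR_tot, and its tightness here is 10⁻³–10⁻¹ of the total depending on
  resolution.
* The k-NN KLD bias noted above means very small true divergences are
  reported as 0 after clipping; the raw (possibly negative) values are
  retained for diagnosis.
* Plain lumping at a fine sampling interval produces many short
  recrossing dwells near bin edges; these carry genuine information about
  irreversibility but make the absolute EPR_WTD value
  resolution-dependent.  Comparisons should fix the sampling interval and
  span convention.
* The estimator assumes second-order statistics suffice; higher-order
  memory is not modelled.
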