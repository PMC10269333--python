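# Methods

## The reference Hamiltonian and the boost

The package combines N end-state Hamiltonians into the EDS reference
`E_R = -RT ln Σ_i exp(-(H_i - ΔF_i)/RT)` with `R = 0.0083145
kJ mol⁻¹ K⁻¹` and a default temperature of 300 K.  The log-sum-exp is
evaluated after factoring out `min_i (H_i - ΔF_i)`, so arbitrarily
large energy gaps cannot overflow; the exact bounds
`min_i(H_i-ΔF_i) - RT ln N ≤ E_R ≤ min_i(H_i-ΔF_i)` are enforced by
property tests.

The harmonic boost is parametrized by two thresholds.  Below `E_min`
the surface is untouched; between `E_min` and `E_max` the energy is
lowered by `(E_R-E_min)²/(2(E_max-E_min))`; above `E_max` the boosted
energy is the constant `(E_min+E_max)/2`.  This is the unique
once-differentiable map whose slope falls linearly from 1 at `E_min`
to 0 at `E_max` — the basins keep their exact shape, the barrier tops
are levelled.  The degenerate case `E_min = E_max` is treated as "no
acceleration" (identity map).  A consequence of the flat plateau is
that the boosted surface is bounded above: on an unbounded toy domain
the stationary distribution would not be normalizable, which is why
the sampler operates on a finite box (below).

Forces and the TI integrand follow by the chain rule:
`∇E_R* = s(E_R) Σ w_i ∇H_i` and
`∂H/∂λ = ∂H_S/∂λ + s(E_R) Σ w_i (∂H_i/∂λ - S_i)` with
`s = dE_R*/dE_R ∈ [0,1]`, `w_i` the reference-state weights and `S_i`
the slope of state i's linear offset schedule `ΔF_i(λ) = S_i λ + b_i`.
Both identities are pinned against central finite differences at 1e-5
tolerance.

## Toy systems and their oracles

All fixtures come from one separable potential family per coordinate:
a quadratic `k/2 (x-x₀)² + c` plus Gaussian wells/bumps
`a·exp(-(x-m)²/2s²)`, every parameter interpolating linearly between
its λ=0 and λ=1 values.  The family has closed-form gradients and
λ-derivatives and packs into plain arrays for the compiled sampler
kernel.  Exact references:

* displaced harmonic pair — `ΔF = ΔE + (RT/2) ln(k_b/k_a)` from
  Gaussian integrals;
* any 1-D potential — `F = -RT ln ∫ exp(-U/RT) dx` by composite
  trapezoidal quadrature with grid doubling until the change is below
  1e-9 kJ/mol;
* the pocket model — two-state occupancies and free-energy legs from
  the same quadrature, including the boosted ensemble (the boost enters
  the Boltzmann factor pointwise).

The pocket fixture emulates a buried hydration site: a confining well
(`k_conf = 100 kJ mol⁻¹ nm⁻²`, playing the role of the distance
restraint to the binding site) plus, in the coupled state, a Gaussian
site attraction of width 0.12 nm whose strength morphs `g_a → g_b`
with the ligand parameter.  The default cycle fixture uses
`g_a = -10 kJ/mol` (the A-ligand binds the water) and `g_b = +4 kJ/mol`
(the B-ligand expels it).  `g_b` is deliberately non-zero: with
`g_b = 0` the coupled and dummy states would be *identical* at λ=1 and
the state-crossing monitor would never fire.  A configuration-
independent ligand self-energy `h_s(λ) = 20·λ + 10·λ(1-λ)` kJ/mol makes
the TI profiles non-trivial; it cancels in all closure sums.  The
soft-core pair potential (α_LJ = 0.5, α_CRF = 0.5 nm²) scales the
interaction by (1-λ) and inflates the LJ/Coulomb denominators by
λ²-terms, so it is the full interaction at λ=0, zero at λ=1, and finite
at contact in between; it is provided as a standalone, analytically
differentiable building block and is not part of the sampled toy path.

## Sampling

The correctness path is Metropolis Monte Carlo with an isotropic
Gaussian proposal.  The proposal width is auto-tuned during burn-in
(default `min(n_steps/10, 5000)` steps, excluded from all records)
toward a 30–50% acceptance rate.  The chain lives on a finite box
(default ±1.5 nm; the pocket uses ±1.2 nm): proposals leaving the box
are rejected, which preserves detailed balance exactly and makes the
stationary density match quadrature oracles integrated over the same
interval — this mirrors a simulation box and is required because the
boosted surface is flat at large energy.  A fixed seed yields a
bit-identical trajectory.  An overdamped Euler–Maruyama Langevin
integrator (reflecting walls) is included for time-series realism
(state lifetimes); it carries the usual first-order discretization bias
and is not used for free energies.

Every run records, per saved frame (default every 10 steps, every step
during searches): all end-state energies, `E_R`, `E_R*`, the restraint
energy, per-state `∂H_i/∂λ` and the combined TI integrand.  Stored
`E_R` must be recomputable from the stored `H_i` and offsets to 1e-9,
which is asserted by the `self_check` of every series.  The "time"
column converts MC steps at 0.002 ps per step, the nominal MD-step
equivalent used for lifetime reporting.

## Parameter search

The search alternates 2000-step sampling stretches with updates.  The
currently visited state is `argmin_i (H_i - ΔF_i)` (ties to the lowest
index).  `E_max` is the largest `E_R` seen at a visited-state change.
For `E_min` the package uses the mean plus one standard deviation of
`E_R` within each visited basin, maximized over states with at least
10 frames — the boost then acts only above typical basin energies.
This specific fluctuation rule is this package's own calibration of
the qualitative prescription "from the fluctuations of the end-state
energies"; it is the one deliberately heuristic point of the search
and is validated end-to-end (searched parameters must produce ≥ 10%
sampling of every state in production).  Transient `E_min > E_max`
inversions before the offsets converge are clamped and counted in the
diagnostics.  Offsets are re-estimated each update by exponential
averaging over a trailing memory window that grows linearly from 500
steps at the start of the search to 500,000 steps at the end, and are
gauge-fixed to `min_i ΔF_i = 0` (only differences matter; every report
states this gauge).

## Analysis estimators

Occupancy defaults to the *weights* method (mean per-frame Boltzmann
weight of each state in the reference ensemble), with frame counting
by visited state (*argmin*) as the alternative; both sum to one
exactly.  Lifetimes are mean lengths of maximal constant runs of the
visited-state series with the first and last (censored) runs dropped.
One-step-perturbation estimates are flagged unreliable when the target
state carries less than 1% of the weight mass — below that the
exponential average is dominated by configurations the ensemble never
visits; flagged legs are excluded from closure sums unless forced.
Reweighting reports the Kish effective sample size `(Σw)²/Σw²` and the
per-window prediction is flagged when the ESS drops below 1% of the
frames; a flagged window withholds the integrated ΔG.  Statistical
errors come from block averaging (10 blocks by default), also applied
blockwise to the nonlinear OSP and reweighted estimators; cycle and
assembly errors combine leg errors in quadrature assuming independent
legs.

## TI–AEDS and the cycle study

TI uses composite trapezoidal integration over a sorted λ-grid
containing 0 and 1; the default protocol is 41 equally spaced windows
of 20,000 production steps after 2,000 equilibration steps, each window
starting from the previous window's final configuration, with optional
backward sweeps (started from the final λ=1 configuration) providing a
hysteresis diagnostic.  Desk-scale problem sizes throughout (10⁵–10⁶
MC steps, 41 windows, 4×10⁵-step searches) were chosen so that every
stochastic tolerance in the test suite sits several standard errors
away from its bound on one CPU core.

The cycle study names its six states by ligand (A at λ=0, B at λ=1)
and probed-water state (W coupled, D dummy, R the boosted reference).
`AR→BR` is the simulated TI–AEDS path; `AW→AR`, `AR→AD`, `BW→BR`,
`BR→BD` are one-step-perturbation endpoint legs; `AW→BW` and `AD→BD`
are reweighted fixed-state predictions.  Offsets interpolate linearly
between two endpoint searches so both water states stay sampled at
every window (the λ-derivative `-S_i` term in the integrand is the
price of that choice), and the acceleration range is the union of the
two endpoint searches.  Three closure sums are evaluated (upper
4-cycle, lower 4-cycle, outer 6-cycle; only two are linearly
independent, all three are reported).  On exact synthetic edges the
closure is identically zero; on the stochastic pipeline it is bounded
by the combined statistical error of the legs.

Sign conventions are fixed in one table in `cycles.py`: the restraint
correction is `-RT ln(V_restraint/V_site)` with
`V_restraint = (2πRT/K)^{3/2}` the configurational volume of a
zero-reference-distance harmonic distance restraint (checked against
the radial quadrature oracle to 1e-6 relative), and the bulk-transfer
term adds one bulk removal free energy (default 26.8 kJ/mol, the SPC
water value) per perturbed water in the removal direction.

## What the toys do and do not show

The toy systems exercise every estimator against exact references:
log-sum-exp bookkeeping, boost calculus, search convergence,
occupancies, OSP, reweighting, TI coupling and cycle assembly are all
validated end to end.  They do not contain explicit solvent, periodic
boundaries, long-range electrostatics, multi-dimensional water
orientations or protein flexibility, so passing tests demonstrate the
correctness of the method's machinery and estimators — not force-field
accuracy or protein-scale sampling behaviour.  An external MD engine
can be coupled by writing per-frame end-state energies in the
documented tabular format; the whole analysis layer operates on those
files alone.

## Known limitations

* The Metropolis kernel requires end states built from the bundled
  parametric potential family; arbitrary Python energy models are
  supported by the (slower, un-compiled) evaluation helpers used in
  forces and `dhdl_frame`.
* One probed coordinate per site and 1-D sites only in the required
  path; multi-site references are combinatorial products of
  independent 1-D sites.
* Lifetimes from Metropolis chains measure mixing of the chain, not
  physical kinetics; use the Langevin mode for kinetics-flavoured
  series.
* No multistate (Bennett-style) estimators and no autocorrelation
  models beyond block averaging, by design.
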