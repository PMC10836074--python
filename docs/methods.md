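# Methods

## The model

Two microbial populations, A and B, differ by a single gene allele,
compete for a shared resource and exchange the allele by horizontal
gene transfer (HGT).  The abundances follow generalised Lotka–Volterra
competition with an HGT conversion term,

    dn_A/dt = n_A (r_A − a₁₁ n_A − a₁₂ n_B) + γ n_A n_B,
    dn_B/dt = n_B (r_B − a₂₁ n_A − a₂₂ n_B) − γ n_A n_B,

where r_i > 0 are reproduction rates (1/time), a_ij > 0 competition
rates (1/(time·abundance)), and γ is the *HGT balance*: the net rate of
allele flow, positive when conversion B→A outweighs A→B.  In the
canonical variables p_A = n_A/(n_A+n_B) and N = n_A+n_B the system is
replicator dynamics with a density-dependent payoff and a dynamic total
abundance:

    dp_A/dt = p_A (f_A − f̄),    dN/dt = N f̄,
    f_A = r_A − a₁₁ p_A N − (a₁₂ − γ)(1 − p_A) N,
    f_B = r_B − (a₂₁ + γ) p_A N − a₂₂ (1 − p_A) N.

Both representations are implemented (`rhs_full` / `rhs_counts`) and
tested against each other; `(p_A, N)` is canonical for analysis.

### Fixed environment

Setting the right-hand sides to zero gives the trivial equilibrium
(always unstable), the two boundary states (1, r_A/a₁₁) and
(0, r_B/a₂₂), and possibly an interior state.  Boundary stability is
an invasion criterion:

    A-only stable ⇔ (a₂₁+γ)/a₁₁ · r_A/r_B > 1,
    B-only stable ⇔ (a₁₂−γ)/a₂₂ · r_B/r_A > 1.

Both violated plus positive community-matrix determinant
(a₁₁a₂₂ − (a₁₂−γ)(a₂₁+γ) > 0) gives stable coexistence; both satisfied
gives bistability with the interior point as the basin separator.  For
the single-allele scenario (a_ij = a) and balanced HGT (γ = 0) the
competitive exclusion principle holds: the faster grower wins and
N* = max(r_A, r_B)/a.  Unbalanced HGT restores coexistence exactly for
γ ∈ (a(1 − r_A/r_B), a(r_B/r_A − 1)); interval endpoints are treated as
non-coexisting and marginal cases (conditions equal to 1 within 1e−12)
are reported as `degenerate` rather than silently binned.  Interior
stability decided by these sign conditions is cross-checked against the
numerically evaluated Jacobian of the (p, N) system; a disagreement
raises an internal-consistency error.

### Fast-oscillating environment

The environment enters through zero-mean periodic oscillations of the
reproduction and HGT-balance rates, r_i(τ) = r_i + r̃_i(τ),
γ(τ) = γ + γ̃(τ), with τ = ωt and ω > 1 separating the environmental
from the demographic timescale.  Averaging over the fast time (the
standard two-timescale recipe: expand the oscillating parts in powers of
1/ω, separate timescales, average over a period) yields autonomous slow
dynamics in which each population gains an induced fitness term

    φ_A = N (1 − p_A) ξ,   φ_B = −N κ p_A,
    ξ = (1/ω) ⟨r̂_B γ̃⟩,    κ = (1/ω) ⟨r̂_A γ̃⟩,

with r̂ the zero-mean periodic primitive and ⟨·⟩ the period mean.  The
pairing is deliberately asymmetric — each payoff couples the
*competitor's* reproduction oscillation with the HGT-balance
oscillation — and a regression test pins the sign convention to the
reference values below.  The slow system is algebraically identical to
the fixed-environment system with effective between-population
competition rates a₁₂ − ξ and a₂₁ + κ (an exact identity, tested at
1e−12), so the entire fixed-environment analysis transfers.  An
effective rate may legitimately be negative (mutualism-side regime);
the `ModelParams.effective` flag relaxes the positivity invariant for
such derived parameter sets only.

Canonical oscillation representation is a finite Fourier series
(amplitude, integer harmonic ≥ 1, phase), for which primitives and the
payoff integrals are exact by orthogonality; tabulated periodic
functions are a secondary path using FFT primitives and spectral
(uniform-grid trapezoid, 4096 nodes) quadrature, with the zero-mean
requirement checked to 1e−10.

### Slow initial conditions

The observed state is slow part plus an O(1/ω) oscillation, so the slow
system must not be started from the raw initial condition.  The
leading-order oscillating corrections are obtained by the averaging
recipe as zero-mean τ-primitives of the oscillatory part of the full
right-hand side at frozen slow variables:

    π₁ = p̄(1−p̄) [r̂_A − r̂_B + N̄ γ̂],   𝒱₁ = N̄ [p̄ r̂_A + (1−p̄) r̂_B]

(the γ̃ contribution cancels from the mean fitness because it enters the
two fitnesses antisymmetrically).  The slow initial condition solves
p(0) = p̄ + π₁/ω, N(0) = N̄ + 𝒱₁/ω by damped Picard iteration (damping
0.5, tolerance 1e−10, ≤ 100 iterations) with a derivative-free root
finder as fallback.  These functional forms are a derivation internal to
this package; they are validated empirically — the corrected pairing
tracks the period-averaged full solution measurably better than the
naive pairing in the early transient (tested on the region-I reference
scenario), and the correction scales as 1/ω.

### Phase space, symbiosis and synergy

For a_ij = a, γ = 0, r_A > r_B, the (ξ, κ) plane splits into: I
(coexistence without synergy, ξ < 0), II (synergetic pure competition,
0 < ξ < a, κ > −a), III (synergetic parasitism or mutualism, ξ > a or
κ < −a), IV (A wins), V (bistability), VI (reversal: B wins), and N/A
(coexistence composition exists but the averaged abundance diverges,
a(ξ−κ) + ξκ ≤ 0).  Coexistence requires κ < a(r_B/r_A − 1),
ξ > a(1 − r_A/r_B) and a positive denominator; the coexistence
abundance is N*_c = (r_B ξ − r_A κ)/(a(ξ−κ) + ξκ) with composition from
the interior formula on effective rates.  Symbiosis is read off the
cross-derivatives of total fitness, ∂(f_A+φ_A)/∂p_B = −(a−γ−ξ)N and
∂(f_B+φ_B)/∂p_A = −(a+γ+κ)N: both negative is pure competition, mixed
signs parasitism, both positive mutualism.  Synergy (N*_c > N*_f with
N*_f the fixed-environment attractor abundance) is decided by direct
numerical comparison of the two abundances, which is unambiguous where
printed inequality chains are not.  Unbalanced average HGT shifts every
threshold by γ (γ+ξ, γ+κ) with determinant condition
a(ξ−κ) + (γ+ξ)(γ+κ) > 0; the classifier also reports when oscillations
destroy a fixed-environment coexistence.

Boundary handling: a point within 1e−12 of a line separating two
*distinct region labels* is labelled `region="boundary"`.  The lines
ξ = a and κ = −a continue into the interiors of regions I and III where
they separate only symbiosis sub-regions; there the region label is
kept and the `symbiosis` field carries the `boundary` marker.  This
keeps every region a connected set on classification grids while still
refusing to guess sub-region membership on the lines themselves.

## Stochastic engine

The continuum model is the large-size limit of a birth–death–transfer
process on counts N_i = V·n_i (V = system size): reproduction at
r_i N_i, pairwise competition deaths at (a_ij/V) N_i N_j (including
i = j), and conversions at (h_BA/V) N_A N_B and (h_AB/V) N_A N_B with
h_BA − h_AB = γ.  Only the balance is fixed by the deterministic model;
the split defaults to h_AB = max(0, −γ) + h₀, h_BA = max(0, γ) + h₀
with the baseline bidirectional rate h₀ (default 0) exposed explicitly,
since equal-and-opposite components cancel in the mean but add
demographic noise.  Simulation is exact (Gillespie) and compiled with
numba; time-dependent rates use thinning against constant upper bounds
built from the Fourier amplitude sums, with negative instantaneous
reproduction realised as a density-independent death channel.  Runs are
exactly reproducible from their integer seed.  The engine is validated
against the deterministic limit: ensemble means over 50 seeds at
V = 10⁴ agree with the ODE solution within three standard errors at ten
checkpoints, and the exclusion principle is realised path-wise at large
V.

## Numerical choices

- Integrator LSODA, rtol 1e−9, atol 1e−12.  Oscillating runs cap the
  step at one twentieth of the environmental period so no oscillation
  is skipped; output grids use ≥ 40 points per period.
- State clipping: p_A and N are clipped to their ranges only when the
  violation is below 1e−8.  The band must sit *above* the integrator's
  own error scale (rtol 1e−9): near fixation the dense output
  legitimately overshoots p = 1 by a few 1e−10, which is round-off for
  this purpose, while genuine failures violate by orders of magnitude
  more.  Larger violations raise an error.
- Divergence ceiling N_max = 10⁶·max(r_A, r_B)/min(a_ij); crossing it
  terminates the run with a `diverged` flag (the N/A regime exhibits
  unbounded growth of the averaged abundance).
- Time averages are trapezoidal over the largest whole number of
  environmental periods in the retained window; by default the first
  80% of the horizon is discarded as transient and at least 5 periods
  are required.  The averaging window is an engineering choice — the
  underlying comparison defines no canonical window — and attractor
  averages are insensitive to it (verified).
- Full-vs-averaged comparison: in coexistence regions the averaged
  comparator is the analytic equilibrium (the slow system is autonomous
  and converges to it), removing one discretisation from the metric; in
  exclusion/bistability regions it is the tail average of the slow
  trajectory from corrected initial conditions.  The "negligible"
  thresholds quoted in tests (fraction distance < 0.02 in regions
  IV–VI; interior fractions in (0.01, 0.99) for coexistence) are
  package choices, not claims from the comparison's source.

## Problem sizes used in tests

Acceptance-grade checks run at desk scale: ODE horizons of 40–200 time
units, a 121×121 classification grid at step 0.005, stochastic
ensembles of 50 seeds at V = 10⁴ (and 20 seeds at V = 500–5000 in unit
tests), and 5 random parameter draws per phase-space region.  These
sizes make every result statistically decidable while keeping the full
suite under a minute of compute.

## Known limitations

- The averaged description is first order in 1/ω.  At the reference
  frequency ω = 5 the time-averaged abundance of the full solution in
  the synergetic coexistence scenario sits ~11% below the analytic
  equilibrium (the gap shrinks to ~2% by ω = 20); the fractions agree
  to ~3.5%.  This is a property of the truncation, reproduced
  identically by independent integration routes, not a numerical error.
- Scope is two populations, one transferable allele, no mutation, no
  spatial structure, periodic (not stochastic) environments, and no
  resonance between environmental and demographic timescales.
- The stochastic engine's elementary competition events are pairwise
  encounters; its operative contract is agreement with the ODE limit,
  not any particular microscopic derivation.
- Demographic-noise phenomena (quasi-stationary distributions,
  extinction times) are outside scope beyond the law-of-large-numbers
  check.
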