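# Methods

## Model and assumptions

The package treats a polymer as `N` inextensible segments joined at bending
sites; site `i` carries the angle `θᵢ` between consecutive segment
directions (`θ = 0` straight, `θ ∈ [0, π]`) and the energy `E(θᵢ)` in units
of kT at 300 K. Profiles carry no temperature; the Monte-Carlo samplers
rescale acceptance by `300 K / T`. Analytic profiles satisfy `E(0) = 0`
(no intrinsic bend) and bending is isotropic — no sequence dependence,
twist, or groove-direction anisotropy. Entropic contributions are assumed
small on scales below the persistence length; the closed-form loop analysis
is pure energy minimisation, and the Monte-Carlo runs probe how far thermal
fluctuations move the system off the minimum.

The constrained minimum of `Σ E(θᵢ)` at fixed `Σθᵢ` is uniform bending for
convex `E`, and two-state bending at the double-tangent angles
`(θ_a, θ_b)` when the average angle falls inside a non-convex region. The
ECH chain model keeps only `Lp` and `θ_a`: harmonic below `θ_a`, linear
(the hull line) above, with value and slope continuous at the joint. The
extreme regime `θ̄ ≥ θ_b` (DNA loops below ~10 bp, where every site would
be kinked) is outside the model and raises an error rather than
extrapolating.

## Hull detection

`find_double_tangent` samples the profile on a uniform grid (default 4001
points), builds the discrete lower convex hull by a monotone-chain scan,
and looks for a hull edge that skips interior samples; that edge brackets
the non-convex region. The bracket is polished by a damped Newton iteration
on the tangency system `E′(a) = E′(b) = (E(b) − E(a))/(b − a)` with a
finite-difference 2×2 Jacobian, to a slope residual of 1e−10 kT/rad by
default. Convex profiles return `None`; an edge touching the domain
boundary raises (the hull is truncated — widen the domain); more than one
skipping edge raises (multi-well profiles are rejected explicitly rather
than silently mishandled). Because tangency only involves derivatives, a
uniform rescaling `E → λE` leaves the endpoints unchanged — asserted as a
property test.

Tabulated profiles interpolate with shape-preserving piecewise cubics
(PCHIP): hull detection needs a continuous derivative without spurious
oscillation between knots, which a plain cubic spline does not guarantee.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `Lp` | 150 bp | dsDNA persistence length, in bending-site units |
| `θ_a` | solved: 2.2° | hull onset; the only shape parameter ECH inherits |
| `θ_b` | solved: 35.8° | hull end; only bounds the validity range |
| `h` | 10 bp/turn | helical repeat for the torsional j-factor modulation |
| `b` | 3.3 Å | bead spacing (bp rise) in the samplers |
| bond k | 100 kT/Å² | "virtually inextensible" bonds |
| Bjerrum `l_B` | 7.1 Å | Coulomb constant of the confinement model (water, 300 K) |

Quartic profiles default to the domain [0, 1.2] rad: it covers the dsDNA
hull (ends at 0.62 rad) with margin while excluding the unphysical
large-angle tail. Samplers extend profiles linearly beyond their domain
(`E(hi) + E′(hi)(θ − hi)`) so moves to large angles are defined and
penalised, while the profile is preserved exactly inside its domain.

## Cyclization

The j-factor uses the Shimada–Yamakawa closed form with the geometry
prefactor `k` free; `k` cancels exactly in ratios, and `fit_k` calibrates
it against (L, j) data by least squares on log j, whose solution is the
geometric mean of observed/predicted ratios. Torsional alignment is
modelled by multiplying j with `(1 + cos(2πL/h))/2`, clamped to a
configurable floor (default 1e−3) so j stays positive at half-integer
turns; the unmodulated curve is the envelope, and ratios at phase-matched
lengths (equal fractional `L/h`) are independent of any multiplicative
modulation, so the headline ratio predictions use the unmodulated form.
The envelope minimum `L* = 5/(1/(4Lp) + Lp·θ_a²/2)` is cross-checked
against a numerical argmin on a 0.01-bp grid.

Two known tensions in the reference numbers, documented rather than hidden:
the quoted "~54 kT" WLC energy of a 50-bp loop is 59.22 kT from the formula
as written (the package follows the formula), and the reference ratio rows
at 80/101, 90/101 (both models) and the WLC 71/101 value are not
reproducible from the unmodulated closed form with `Lp = 150`
(the modulation treatment behind them is unspecified); `jfactor_ratio`
computes them, but no reference value is asserted.

## Loop Monte Carlo

`mc_sample` is a single-bead Metropolis sampler: Gaussian displacements,
step size auto-tuned toward 40% acceptance during a discarded burn-in
(default first 10% of sweeps), ring closure carried by the bonded topology
alone — no planarity constraint or excluded volume. Energies are tracked
incrementally with a full recomputation every 10³ sweeps; the worst
discrepancy is reported and tested below 1e−6 kT. Every sampled closed
conformation must satisfy the Fenchel bound `Σθᵢ ≥ 2π`, which the tests
assert frame by frame.

Bimodality is scored on fixed 0.5°-wide histogram bins over [0°, 60°],
smoothed with a 9-bin moving average; a mode must exceed 2% prominence and
1% height relative to the smoothed maximum. The thresholds sit well below
the kink peak (which holds only ~p of the angle mass spread over a wide
angular range) and far above bin noise at the sample sizes used.
Weak/strong occupancies are classified by the hull midpoint
`(θ_a + θ_b)/2`, which lies in the depleted valley between the two peaks;
the boundary is configurable since no canonical criterion exists.

`minimize_loop` relaxes bonds + angles with L-BFGS on analytic gradients,
then polishes with a Newton-CG step (finite-difference Hessian-vector
products) because quasi-Newton line searches stall on rounding-limited
energy decreases before reaching the exit criterion, a gradient max-norm
below 1e−6 kT/Å. Near `N = 2π/θ_a` the kinked minimum undercuts the
uniform ring by under 1%, so `minimize_from_ensemble` descends from the
last few thermal snapshots (which already contain kinks) and keeps the
lowest result — the annealing-style protocol that reliably finds the
two-state minimum.

## Confined chains

The protein–DNA toy model is an open charged chain (bead charge −1)
attracted to a core charge Q (sphere or cylinder of radius R, default
12 Å for the 20-bead model) between two confining walls (gap 50 Å). The
default radius puts the imposed curvature mid-hull, where the gap between
the hull line and `E(θ̄)` is several kT — large against thermal noise, so
the weak/strong-confinement crossover is resolvable at modest sweep
counts. Electrostatics are unscreened Coulomb with Bjerrum length 7.1 Å
(optionally Debye-screened); core and walls are steep `r⁻¹²` repulsions so
gradients stay smooth, with overlaps carrying infinite energy (never
accepted). Bead–bead non-bonded terms (soft-core + Coulomb) are off for
the 20-bead model and on for the 147-bead nucleosome-geometry variant,
whose core dimension is exposed explicitly as a *radius* because
nucleosome-scale geometry is often quoted as a ~100 Å diameter.

Reported observables are the mean bend angle and mean per-site bending
energy over *contact* sites (interior beads within `R + 1.5b` of the core
surface) — the part of the chain whose curvature the core dictates; if a
frame has no contact beads (released chain), all interior sites are used.
The mean per-site energy is bounded below by the hull line for any angle
distribution (the hull is a convex minorant of `E`, so Jensen's inequality
applies twice), and the upper bound `E(θ̄)` is approached from below in
the profile's concave region; finite-temperature tests allow a 0.5 kT
equipartition offset on both bounds, alongside the seed-to-seed CI.

Initial conditions: a wrapping arc at contact distance (bound states), or
a tangent straight line (`start="straight"`) for unbound checks — with
nothing binding, a wrapped start can only relax by sterically unwrapping
around the impenetrable core, which is physically slow. The free chain
equilibrates to the exact single-site law `p(θ) ∝ sinθ·e^{−E(θ)}` of a
freely rotating chain, which serves as an independent oracle.

`unwrap_energy` estimates the cost of detaching a terminal fragment as the
difference of mean potential energies between two restrained simulations
(tail decoupled from the core charge and held off the surface by a
flat-bottom restraint, restraint energy excluded from the means). It is a
mean-energy estimate, not a free-energy method; only orderings (zero at
zero detachment, monotone in confinement strength) are asserted, since the
absolute scale depends on the electrostatic constants, which the model
fixes by convention.

## Synthetic fixtures

The fixture generator emulates the package's reference inputs, not real
experiments: quartic profiles are drawn as scaled/width-modulated copies of
the dsDNA shape (guaranteeing a single non-convex well, with ground-truth
tangencies recorded by an independent dense-grid chord search); synthetic
cyclization datasets apply multiplicative lognormal noise (σ = 0.1, 50
points) to the closed-form j-factor with a known prefactor, the standard
noise model for quantities measured on a log scale. Passing tests on these
fixtures show the solvers are correct and the estimators calibrated; they
do not validate the quartic profile itself against reality, nor
sequence-dependent effects, which are outside scope.

## Problem sizes

Tests and the acceptance script run scaled-down simulations chosen so every
asserted feature is already stable: loops of 20–300 beads with 1.2–8×10³
sweeps (the bimodal histogram shape and occupancy lever rule converge well
before this), confinement runs of 1.2×10³ sweeps over 3 seeds, and oracle
comparisons on 20 random profiles plus DP grids up to N = 60. Production
exploration can raise sweep counts freely; all entry points are
seed-deterministic.

## Known limitations

No twist degrees of freedom or supercoiling (torsion enters only through
the phenomenological cosine modulation); no sequence dependence; no
excluded volume in plain loops (out-of-plane effects slightly shift the
largest-loop angle distributions); `unwrap_energy` is qualitative by
construction; absolute j-factors require an external calibration of `k` —
the package reports relative units otherwise.
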