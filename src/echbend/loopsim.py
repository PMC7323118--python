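"""Coarse-grained Metropolis Monte Carlo and minimisation of closed bead loops.

One bead per base pair (bond length 3.3 A), bonds kept virtually
inextensible by a stiff harmonic stretch term, and a bond-angle potential
given by any :class:`~echbend.profiles.BendingProfile`.  No other bead-bead
interactions or geometry constraints are imposed: ring closure is carried by
the bonded topology alone, which realises the closed-loop constraint
``sum_i theta_i >= 2*pi`` (Fenchel's theorem; equality for planar convex
rings).

The sampler exists to test the structural predictions of the convex-hull
analysis: loops whose average bend angle ``2*pi/N`` falls inside the hull
interval develop a *bimodal* bend-angle distribution (weak bends near
``theta_a`` coexisting with kinks near ``theta_b``), and minimised loop
energies per site track the hull line rather than the uniform-bending curve.

Angles beyond the profile's tabulated/analytic domain are assigned a linear
continuation ``E(hi) + E'(hi)*(theta - hi)`` so the sampler is defined on
the full [0, pi] range while preserving the profile exactly inside its
domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .profiles import (
    BendingProfile,
    HarmonicProfile,
    QuarticProfile,
)
from .hull import HullResult

__all__ = [
    "RingChain",
    "LoopEnsemble",
    "build_regular_loop",
    "bend_angles",
    "mc_sample",
    "minimize_loop",
    "minimize_from_ensemble",
    "angle_occupancy",
    "mode_locations",
    "angle_histogram",
    "count_modes",
    "bend_energy_and_gradient",
    "MinimizationError",
]

DEFAULT_BOND_LENGTH = 3.3  # A, base-pair rise of B-DNA
DEFAULT_BOND_K = 100.0  # kT/A^2, "virtually inextensible" bonds


class MinimizationError(RuntimeError):
    """Minimiser failed to reach the gradient tolerance; carries last state."""

    def __init__(self, message, coords=None):
        super().__init__(message)
        self.coords = coords


@dataclass(frozen=True, eq=False)
class RingChain:
    """Closed bead chain: N beads, bead i bonded to i+1 (mod N).

    coords : (N, 3) array, Angstrom.  b : rest bond length, Angstrom.
    """

    coords: np.ndarray
    b: float = DEFAULT_BOND_LENGTH

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 3:
            raise ValueError("coords must be an (N>=3, 3) array")
        object.__setattr__(self, "coords", coords)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def bond_lengths(self) -> np.ndarray:
        d = np.roll(self.coords, -1, axis=0) - self.coords
        return np.linalg.norm(d, axis=1)


@dataclass(frozen=True, eq=False)
class LoopEnsemble:
    """Monte-Carlo snapshots of a closed loop with per-frame observables.

    frames : (n_frames, N, 3) coordinates (A); angles : (n_frames, N) bend
    angles (rad); bend_energies : per-frame total bending energy (kT);
    acceptance_rate : post-burn-in fraction of accepted moves; step : final
    (tuned) Gaussian move size (A); bookkeeping_drift : worst discrepancy
    between the incrementally tracked and fully recomputed total energy (kT).
    """

    frames: np.ndarray
    angles: np.ndarray
    bend_energies: np.ndarray
    acceptance_rate: float
    seed: int
    temperature: float
    step: float
    bookkeeping_drift: float

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def all_angles(self) -> np.ndarray:
        return self.angles.ravel()


def build_regular_loop(n: int, b: float = DEFAULT_BOND_LENGTH) -> RingChain:
    """Planar regular n-gon with side b; every bend angle is 2*pi/n."""
    if n < 3:
        raise ValueError(f"a closed loop needs at least 3 beads, got {n}")
    radius = b / (2.0 * math.sin(math.pi / n))
    phi = 2.0 * math.pi * np.arange(n) / n
    coords = np.column_stack(
        [radius * np.cos(phi), radius * np.sin(phi), np.zeros(n)]
    )
    return RingChain(coords=coords, b=b)


def bend_angles(coords: np.ndarray, ring: bool = True) -> np.ndarray:
    """Bend angle at each site: angle between consecutive bond vectors.

    theta = 0 for collinear (straight) junctions, pi for a full back-fold.
    Ring chains have N sites (wraparound); open chains N-2 interior sites.
    """
    coords = np.asarray(coords, dtype=float)
    if ring:
        u = np.roll(coords, -1, axis=0) - coords  # bond i: bead i -> i+1
        uprev = np.roll(u, 1, axis=0)
        vnext = u
    else:
        u = coords[1:] - coords[:-1]
        uprev, vnext = u[:-1], u[1:]
    nu = np.linalg.norm(uprev, axis=1)
    nv = np.linalg.norm(vnext, axis=1)
    if np.any(nu < 1e-12) or np.any(nv < 1e-12):
        raise ValueError("degenerate geometry: zero-length bond")
    c = np.einsum("ij,ij->i", uprev, vnext) / (nu * nv)
    return np.arccos(np.clip(c, -1.0, 1.0))


# ---------------------------------------------------------------------------
# site-energy closures (python-scalar fast paths for the samplers)
# ---------------------------------------------------------------------------

def _site_energy_scalar(profile: BendingProfile):
    """Scalar E(theta) with linear continuation beyond the profile domain."""
    lo, hi = profile.domain
    e_hi = float(profile.energy(hi))
    d_hi = float(profile.derivative(hi))
    if isinstance(profile, QuarticProfile):
        c2, c3, c4 = profile.c2, profile.c3, profile.c4

        def v(t):
            if t > hi:
                return e_hi + d_hi * (t - hi)
            return t * t * (c2 + t * (c3 + t * c4))

    elif isinstance(profile, HarmonicProfile):
        half_lp = 0.5 * profile.lp

        def v(t):
            if t > hi:
                return e_hi + d_hi * (t - hi)
            return half_lp * t * t

    else:
        def v(t):
            if t > hi:
                return e_hi + d_hi * (t - hi)
            return float(profile.energy(t))

    return v


def _site_energy_vec(profile: BendingProfile):
    """Vectorised (E, dE/dtheta) with linear continuation beyond the domain."""
    lo, hi = profile.domain
    e_hi = float(profile.energy(hi))
    d_hi = float(profile.derivative(hi))

    def v(t):
        t = np.asarray(t, dtype=float)
        inner = np.minimum(t, hi)
        return np.where(t > hi, e_hi + d_hi * (t - hi), profile.energy(inner))

    def vp(t):
        t = np.asarray(t, dtype=float)
        inner = np.minimum(t, hi)
        return np.where(t > hi, d_hi, profile.derivative(inner))

    return v, vp


# ---------------------------------------------------------------------------
# total energy and analytic gradient (used by the minimiser and for checks)
# ---------------------------------------------------------------------------

def bend_energy_and_gradient(
    coords: np.ndarray,
    profile: BendingProfile,
    b: float = DEFAULT_BOND_LENGTH,
    bond_k: float = DEFAULT_BOND_K,
    ring: bool = True,
):
    """Total energy (bond stretch + bending, kT) and its coordinate gradient.

    Gradient is analytic: bond term ``k*(|u|-b)*u/|u|`` and the standard
    three-body bend-angle derivative via d(cos theta).  Returns
    ``(energy, gradient)`` with gradient shaped like coords (kT/A).
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    v, vp = _site_energy_vec(profile)
    grad = np.zeros_like(coords)

    if ring:
        u = np.roll(coords, -1, axis=0) - coords
    else:
        u = coords[1:] - coords[:-1]
    nu = np.linalg.norm(u, axis=1)
    e_bond = 0.5 * bond_k * np.sum((nu - b) ** 2)
    f_bond = (bond_k * (nu - b) / nu)[:, None] * u
    if ring:
        grad -= f_bond
        grad += np.roll(f_bond, 1, axis=0)
    else:
        grad[:-1] -= f_bond
        grad[1:] += f_bond

    if ring:
        up, vn = np.roll(u, 1, axis=0), u  # angle site i: bonds (i-1), (i)
        i_prev = np.arange(-1, n - 1)
        i_mid = np.arange(n)
        i_next = np.arange(1, n + 1) % n
    else:
        up, vn = u[:-1], u[1:]
        i_prev = np.arange(n - 2)
        i_mid = np.arange(1, n - 1)
        i_next = np.arange(2, n)
    nup = np.linalg.norm(up, axis=1)
    nvn = np.linalg.norm(vn, axis=1)
    c = np.einsum("ij,ij->i", up, vn) / (nup * nvn)
    c = np.clip(c, -1.0, 1.0)
    theta = np.arccos(c)
    e_bend = float(np.sum(v(theta)))
    s = np.sqrt(np.maximum(1.0 - c * c, 1e-24))
    coef = -vp(theta) / s  # d E_site/d cos(theta)
    dc_dup = vn / (nup * nvn)[:, None] - (c / nup**2)[:, None] * up
    dc_dvn = up / (nup * nvn)[:, None] - (c / nvn**2)[:, None] * vn
    g_up = coef[:, None] * dc_dup
    g_vn = coef[:, None] * dc_dvn
    np.add.at(grad, i_prev, -g_up)
    np.add.at(grad, i_mid, g_up - g_vn)
    np.add.at(grad, i_next, g_vn)

    return e_bond + e_bend, grad


# ---------------------------------------------------------------------------
# Metropolis sampler
# ---------------------------------------------------------------------------

def _local_energy(xs, ys, zs, n, m, v, half_k, b):
    """Energy of the bonds and angle sites touched by bead m (ring topology).

    Moving bead m changes bonds (m-1, m) and (m, m+1) and the bend angles
    centred at beads m-1, m, m+1.
    """
    e = 0.0
    # two bonds
    for i in (m - 1, m):
        j = (i + 1) % n
        i %= n
        dx = xs[j] - xs[i]
        dy = ys[j] - ys[i]
        dz = zs[j] - zs[i]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        d = r - b
        e += half_k * d * d
    # three angle sites
    for s in (m - 1, m, m + 1):
        i = (s - 1) % n
        j = s % n
        k = (s + 1) % n
        ux = xs[j] - xs[i]
        uy = ys[j] - ys[i]
        uz = zs[j] - zs[i]
        wx = xs[k] - xs[j]
        wy = ys[k] - ys[j]
        wz = zs[k] - zs[j]
        dot = ux * wx + uy * wy + uz * wz
        r2 = (ux * ux + uy * uy + uz * uz) * (wx * wx + wy * wy + wz * wz)
        c = dot / math.sqrt(r2)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        e += v(math.acos(c))
    return e


def mc_sample(
    chain: RingChain,
    profile: BendingProfile,
    sweeps: int,
    seed: int,
    temperature: float = 300.0,
    bond_k: float = DEFAULT_BOND_K,
    burn_in: float = 0.1,
    sample_every: int = 10,
    step: float | None = None,
    target_acceptance: float = 0.4,
    check_every: int = 1000,
) -> LoopEnsemble:
    """Metropolis sampling of a closed loop with single-bead Gaussian moves.

    One sweep = N attempted single-bead displacements.  The move size is
    auto-tuned toward ``target_acceptance`` during the burn-in fraction
    (discarded), then frozen.  The running total energy is tracked
    incrementally and compared against a full recomputation every
    ``check_every`` sweeps; the worst discrepancy is reported as
    ``bookkeeping_drift``.  Fully reproducible from ``seed``.
    """
    if sweeps <= 0:
        raise ValueError("sweeps must be positive")
    n = chain.n
    v = _site_energy_scalar(profile)
    half_k = 0.5 * bond_k
    beta = 300.0 / temperature  # energies are in kT at 300 K
    rng = np.random.default_rng(seed)

    xs = chain.coords[:, 0].tolist()
    ys = chain.coords[:, 1].tolist()
    zs = chain.coords[:, 2].tolist()

    def full_energy():
        arr = np.column_stack([xs, ys, zs])
        d = np.roll(arr, -1, axis=0) - arr
        nu = np.linalg.norm(d, axis=1)
        e_b = half_k * float(np.sum((nu - chain.b) ** 2))
        th = bend_angles(arr, ring=True)
        return e_b + float(sum(v(t) for t in th))

    e_tot = full_energy()
    burn_sweeps = int(round(burn_in * sweeps))
    sigma = step if step is not None else 0.3 * chain.b
    tune_block = max(20, n)  # moves per tuning update during burn-in

    frames, frame_angles, frame_energies = [], [], []
    accepted_prod = attempted_prod = 0
    drift = 0.0
    tune_acc = tune_att = 0

    for sweep in range(sweeps):
        beads = rng.integers(0, n, size=n)
        disp = rng.normal(0.0, 1.0, size=(n, 3))
        unif = rng.random(n)
        in_burn = sweep < burn_sweeps
        for t in range(n):
            m = int(beads[t])
            e_old = _local_energy(xs, ys, zs, n, m, v, half_k, chain.b)
            ox, oy, oz = xs[m], ys[m], zs[m]
            xs[m] = ox + sigma * disp[t, 0]
            ys[m] = oy + sigma * disp[t, 1]
            zs[m] = oz + sigma * disp[t, 2]
            e_new = _local_energy(xs, ys, zs, n, m, v, half_k, chain.b)
            de = e_new - e_old
            if de <= 0.0 or unif[t] < math.exp(-beta * de):
                e_tot += de
                if in_burn:
                    tune_acc += 1
                else:
                    accepted_prod += 1
            else:
                xs[m], ys[m], zs[m] = ox, oy, oz
            if in_burn:
                tune_att += 1
                if tune_att >= tune_block:
                    acc = tune_acc / tune_att
                    sigma *= 1.15 if acc > target_acceptance else 0.85
                    tune_acc = tune_att = 0
            else:
                attempted_prod += 1

        if (sweep + 1) % check_every == 0:
            e_full = full_energy()
            drift = max(drift, abs(e_full - e_tot))
            e_tot = e_full

        if not in_burn and (sweep - burn_sweeps) % sample_every == 0:
            arr = np.column_stack([xs, ys, zs])
            th = bend_angles(arr, ring=True)
            frames.append(arr)
            frame_angles.append(th)
            frame_energies.append(float(sum(v(t) for t in th)))

    return LoopEnsemble(
        frames=np.array(frames),
        angles=np.array(frame_angles),
        bend_energies=np.array(frame_energies),
        acceptance_rate=(accepted_prod / attempted_prod) if attempted_prod else 0.0,
        seed=seed,
        temperature=temperature,
        step=sigma,
        bookkeeping_drift=drift,
    )


# ---------------------------------------------------------------------------
# minimisation
# ---------------------------------------------------------------------------

def minimize_loop(
    chain: RingChain,
    profile: BendingProfile,
    bond_k: float = DEFAULT_BOND_K,
    gtol: float = 1e-6,
    max_iter: int = 20000,
) -> tuple[RingChain, float]:
    """Relax a loop to a local minimum of bond + bending energy.

    Quasi-Newton (L-BFGS) descent on the analytic gradient; declared
    converged when the gradient max-norm drops below ``gtol`` (kT/A).
    Returns the relaxed chain and its bending energy per site (kT); the
    residual bond-stretch energy at the minimum is negligible by
    construction (stiff bonds).
    """

    def fun(x):
        e, g = bend_energy_and_gradient(
            x.reshape(-1, 3), profile, b=chain.b, bond_k=bond_k, ring=True
        )
        return e, g.ravel()

    def hessp(x, v):
        # finite-difference Hessian-vector product from analytic gradients
        eps = 1e-6 / max(1e-12, float(np.linalg.norm(v)))
        return (fun(x + eps * v)[1] - fun(x)[1]) / eps

    x0 = chain.coords.ravel().copy()
    opts = {"maxiter": max_iter, "ftol": 0.0, "gtol": 0.2 * gtol}
    res = _scipy_minimize(fun, x0, jac=True, method="L-BFGS-B", options=opts)
    x = res.x
    _, g = fun(x)
    if np.max(np.abs(g)) > gtol:
        # Newton-CG polish: quadratic convergence where L-BFGS line
        # searches stall on rounding-limited energy decreases
        res = _scipy_minimize(
            fun, x, jac=True, hessp=hessp, method="trust-ncg",
            options={"gtol": 0.01 * gtol, "maxiter": 200},
        )
        x = res.x
        _, g = fun(x)
        if np.max(np.abs(g)) > gtol:
            raise MinimizationError(
                f"gradient max-norm {np.max(np.abs(g)):.3g} kT/A above "
                f"tolerance {gtol:g} after {max_iter} iterations",
                coords=x.reshape(-1, 3),
            )
    relaxed = RingChain(coords=x.reshape(-1, 3), b=chain.b)
    vfun, _ = _site_energy_vec(profile)
    per_site = float(np.mean(vfun(bend_angles(relaxed.coords, ring=True))))
    return relaxed, per_site


def minimize_from_ensemble(
    ensemble: LoopEnsemble,
    profile: BendingProfile,
    n_starts: int = 3,
    bond_k: float = DEFAULT_BOND_K,
    gtol: float = 1e-6,
) -> tuple[RingChain, float]:
    """Minimise from the last few MC snapshots and keep the lowest result.

    Thermal snapshots already contain the kinks of the two-state regime, so
    descending from several of them reliably reaches the non-uniform
    minimum even when it is only marginally below the uniform ring.
    """
    if ensemble.n_frames == 0:
        raise ValueError("ensemble has no frames")
    best: tuple[RingChain, float] | None = None
    for idx in range(max(0, ensemble.n_frames - n_starts), ensemble.n_frames):
        chain = RingChain(coords=ensemble.frames[idx].copy())
        try:
            cand = minimize_loop(chain, profile, bond_k=bond_k, gtol=gtol)
        except MinimizationError:
            continue
        if best is None or cand[1] < best[1]:
            best = cand
    if best is None:
        raise MinimizationError("no snapshot could be minimised to tolerance")
    return best


# ---------------------------------------------------------------------------
# ensemble analysis
# ---------------------------------------------------------------------------

def angle_occupancy(
    angles: np.ndarray,
    hull: HullResult | None = None,
    boundary: float | None = None,
) -> tuple[float, float]:
    """(weak, strong) state occupancies of a set of sampled bend angles.

    Angles are classified by a boundary angle, by default the hull midpoint
    ``(theta_a + theta_b)/2`` -- it sits in the depleted valley between the
    bimodal peaks.  Fractions sum to 1.
    """
    a = np.ravel(np.asarray(angles, dtype=float))
    if a.size == 0:
        raise ValueError("no angles supplied")
    if boundary is None:
        if hull is None:
            raise ValueError("supply either a HullResult or an explicit boundary")
        boundary = 0.5 * (hull.theta_a + hull.theta_b)
    strong = float(np.mean(a >= boundary))
    return 1.0 - strong, strong


def angle_histogram(
    angles: np.ndarray,
    bin_width_deg: float = 0.5,
    range_deg: tuple[float, float] = (0.0, 60.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Normalised bend-angle histogram on fixed-width bins.

    Returns (bin centres in radians, probability density per radian).
    """
    a = np.degrees(np.ravel(np.asarray(angles, dtype=float)))
    edges = np.arange(range_deg[0], range_deg[1] + bin_width_deg, bin_width_deg)
    density, edges = np.histogram(a, bins=edges, density=True)
    centers = np.radians(0.5 * (edges[:-1] + edges[1:]))
    # histogram density is per degree (degree-valued bins); report per radian
    return centers, density * (180.0 / math.pi)


def count_modes(
    density: np.ndarray,
    smooth_bins: int = 9,
    min_prominence: float = 0.02,
    min_height: float = 0.01,
) -> int:
    """Number of local maxima of a histogram after fixed moving-average smoothing.

    A mode must have prominence above ``min_prominence`` and height above
    ``min_height``, both as fractions of the smoothed global maximum.  The
    strong-state (kink) peak holds only ~p of the angle mass spread over a
    wide angular range, so its height is a small fraction of the weak-state
    peak; the thresholds are set well below that while staying far above
    the bin-noise level of smoothed multi-thousand-sample histograms.
    """
    from scipy.signal import find_peaks

    d = np.asarray(density, dtype=float)
    kernel = np.ones(smooth_bins) / smooth_bins
    smooth = np.convolve(d, kernel, mode="same")
    peaks, _ = find_peaks(
        smooth,
        prominence=min_prominence * np.max(smooth),
        height=min_height * np.max(smooth),
    )
    # a peak in the first bin (monotone-decreasing histogram) is not found
    # by find_peaks; count it when the histogram starts at its maximum
    if smooth[0] >= np.max(smooth) * 0.999:
        return int(len(peaks)) + 1
    return int(len(peaks))


def mode_locations(
    centers: np.ndarray,
    density: np.ndarray,
    smooth_bins: int = 9,
    min_prominence: float = 0.02,
    min_height: float = 0.01,
) -> np.ndarray:
    """Angles (rad) of the smoothed histogram modes, in increasing order."""
    from scipy.signal import find_peaks

    d = np.asarray(density, dtype=float)
    kernel = np.ones(smooth_bins) / smooth_bins
    smooth = np.convolve(d, kernel, mode="same")
    peaks, _ = find_peaks(
        smooth,
        prominence=min_prominence * np.max(smooth),
        height=min_height * np.max(smooth),
    )
    locs = list(centers[peaks])
    if smooth[0] >= np.max(smooth) * 0.999:
        locs.insert(0, centers[0])
    return np.asarray(locs)
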