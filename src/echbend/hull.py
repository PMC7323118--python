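"""Convex-hull (double-tangent) analysis of bending-energy profiles.

If the per-site bending energy ``E(theta)`` has a non-convex region, a
chain constrained only in its *total* bend (e.g. a closed loop, where the
bend angles must sum to 2*pi) can lower its energy below uniform bending by
splitting its sites between two coexisting states: weak bends at ``theta_a``
and strong bends ("kinks") at ``theta_b``.  The two angles are the tangency
points of the common tangent line lying below ``E`` -- the lower convex
hull.  Lagrange minimisation of ``sum_i E(theta_i)`` under
``sum_i theta_i = N*theta_bar`` gives equal slopes at every occupied angle,
``E'(theta_a) = E'(theta_b) = lambda``, with ``lambda`` also equal to the
chord slope ``(E_b - E_a)/(theta_b - theta_a)``.

In the hull interval the minimum energy per site is linear in the average
bend angle ``theta_bar``:

    Ebar(theta_bar) = E_a + lambda * (theta_bar - theta_a)

and the fraction of strongly bent sites grows linearly,
``p = (theta_bar - theta_a)/(theta_b - theta_a)``.

The energy-convex-hull (ECH) chain model keeps only ``Lp`` and ``theta_a``:
harmonic (WLC) below ``theta_a``, linear above, joined with continuous value
and slope:

    Ebar(theta_bar) = Lp/2 * theta_bar^2                 for theta_bar <= theta_a
                    = Lp * theta_a * (theta_bar - theta_a/2)   otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .profiles import BendingProfile, DomainError

__all__ = [
    "HullResult",
    "EchModel",
    "find_double_tangent",
    "hull_energy",
    "strong_fraction",
    "constrained_minimum",
    "HullTruncatedError",
    "UnsupportedProfileError",
]


class HullTruncatedError(ValueError):
    """The double-tangent segment touches the search domain boundary."""


class UnsupportedProfileError(ValueError):
    """Profile has more than one non-convex region (multi-well)."""


@dataclass(frozen=True)
class HullResult:
    """Double-tangent descriptor of a non-convex bending profile.

    Attributes
    ----------
    theta_a, theta_b : float
        Lower/upper tangency angles (rad); the ends of the hull segment.
    slope : float
        Common tangent slope lambda (kT/rad) -- the Lagrange multiplier of
        the constrained minimisation.
    e_a, e_b : float
        Profile energies (kT) at the tangency points.
    """

    theta_a: float
    theta_b: float
    slope: float
    e_a: float
    e_b: float

    @property
    def theta_a_deg(self) -> float:
        return math.degrees(self.theta_a)

    @property
    def theta_b_deg(self) -> float:
        return math.degrees(self.theta_b)


def _lower_hull_indices(theta: np.ndarray, energy: np.ndarray) -> list[int]:
    """Indices of the lower convex hull of sampled (theta, E) points.

    Monotone-chain scan; theta must be sorted increasing.  Cross-product
    test keeps only counter-clockwise (convex-down) turns.
    """
    hull: list[int] = []
    for i in range(theta.size):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            # turn of (j -> k -> i); pop k if it lies on/above chord j -> i
            cross = (theta[k] - theta[j]) * (energy[i] - energy[j]) - (
                energy[k] - energy[j]
            ) * (theta[i] - theta[j])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return hull


def find_double_tangent(
    profile: BendingProfile,
    domain: tuple[float, float] | None = None,
    tol: float = 1e-10,
    grid: int = 4001,
    max_iter: int = 100,
) -> HullResult | None:
    """Locate the double tangent (convex-hull segment) of a profile.

    Strategy: sample the profile on a uniform grid, build the discrete
    lower convex hull by a monotone-chain scan, and look for a hull edge
    that skips interior samples -- that edge brackets the non-convex
    region.  The bracket is then polished by a damped Newton iteration on
    the two-point tangency system

        E'(a) = E'(b) = (E(b) - E(a)) / (b - a)

    until both slope residuals fall below ``tol`` (kT/rad).

    Returns ``None`` for profiles convex on the whole domain.  Raises
    :class:`HullTruncatedError` when the hull edge touches a domain
    boundary (the user must widen the domain) and
    :class:`UnsupportedProfileError` for profiles with more than one
    non-convex region.
    """
    lo, hi = domain if domain is not None else profile.domain
    if not (hi > lo):
        raise ValueError(f"empty angle domain ({lo}, {hi})")
    theta = np.linspace(lo, hi, grid)
    energy = np.asarray(profile.energy(theta), dtype=float)

    hull_idx = _lower_hull_indices(theta, energy)
    gaps = [
        (hull_idx[m], hull_idx[m + 1])
        for m in range(len(hull_idx) - 1)
        if hull_idx[m + 1] - hull_idx[m] > 1
    ]
    if not gaps:
        return None
    if len(gaps) > 1:
        raise UnsupportedProfileError(
            f"profile has {len(gaps)} disjoint non-convex regions; "
            "only single-well hulls are supported"
        )
    ia, ib = gaps[0]
    if ia == 0 or ib == grid - 1:
        raise HullTruncatedError(
            "double-tangent segment touches the domain boundary "
            f"[{lo:g}, {hi:g}] rad; widen the domain"
        )

    # Damped Newton on F(a,b) = (E'(a) - s, E'(b) - s), s = chord slope.
    a, b = float(theta[ia]), float(theta[ib])
    h = (hi - lo) * 1e-7

    def _deriv(x):
        return float(profile.derivative(x))

    def _e(x):
        return float(profile.energy(x))

    def _resid(a, b):
        s = (_e(b) - _e(a)) / (b - a)
        return np.array([_deriv(a) - s, _deriv(b) - s]), s

    f, s = _resid(a, b)
    for _ in range(max_iter):
        if max(abs(f[0]), abs(f[1])) < tol:
            break
        # finite-difference Jacobian of the 2x2 tangency system
        fa1, _ = _resid(a + h, b)
        fb1, _ = _resid(a, b + h)
        jac = np.column_stack([(fa1 - f) / h, (fb1 - f) / h])
        try:
            step = np.linalg.solve(jac, -f)
        except np.linalg.LinAlgError:
            break
        lam = 1.0
        while lam > 1e-6:
            a1, b1 = a + lam * step[0], b + lam * step[1]
            if lo < a1 < b1 < hi:
                f1, s1 = _resid(a1, b1)
                if np.max(np.abs(f1)) < np.max(np.abs(f)):
                    a, b, f, s = a1, b1, f1, s1
                    break
            lam *= 0.5
        else:
            break
    if max(abs(f[0]), abs(f[1])) > max(tol, 1e-8):
        raise RuntimeError(
            f"tangency iteration stalled at residual {np.max(np.abs(f)):.3g} kT/rad"
        )
    return HullResult(theta_a=a, theta_b=b, slope=s, e_a=_e(a), e_b=_e(b))


def hull_energy(profile: BendingProfile, hull: HullResult, theta_bar) -> np.ndarray | float:
    """Minimum energy per site (kT) on the hull segment: linear in theta_bar.

    Valid for ``theta_a <= theta_bar <= theta_b``; outside the segment the
    chain bends uniformly and the profile itself applies (use
    ``profile.energy``).
    """
    t = np.asarray(theta_bar, dtype=float)
    if np.any(t < hull.theta_a) or np.any(t > hull.theta_b):
        raise ValueError(
            "theta_bar outside the hull segment "
            f"[{hull.theta_a:g}, {hull.theta_b:g}] rad; "
            "uniform bending applies there -- evaluate the profile directly"
        )
    out = hull.e_a + hull.slope * (t - hull.theta_a)
    return float(out) if np.isscalar(theta_bar) else out


def strong_fraction(theta_bar, theta_a: float, theta_b: float):
    """Fraction p of sites in the strongly bent state at average angle theta_bar.

    Two-state lever rule: ``p = (theta_bar - theta_a)/(theta_b - theta_a)``,
    0 at the hull onset and 1 at the hull end.
    """
    t = np.asarray(theta_bar, dtype=float)
    if np.any(t < theta_a) or np.any(t > theta_b):
        raise ValueError(
            f"theta_bar outside [{theta_a:g}, {theta_b:g}] rad"
        )
    p = (t - theta_a) / (theta_b - theta_a)
    return float(p) if np.isscalar(theta_bar) else p


@dataclass(frozen=True)
class EchModel:
    """Energy-convex-hull chain model: WLC below theta_a, linear above.

    Parameters
    ----------
    lp : float
        Persistence length in bending-site units (bp for DNA; ~150).
    theta_a : float
        Hull onset angle (rad); the only parameter the model inherits from
        the shape of the underlying bending-energy profile.
    theta_b : float, optional
        Hull end angle (rad), the upper validity bound.  The extreme regime
        ``theta_bar >= theta_b`` (re-entrant uniform bending; DNA loops
        shorter than ~10 bp) is outside the model.
    """

    lp: float
    theta_a: float
    theta_b: float | None = None

    def __post_init__(self):
        if not (self.lp > 0 and math.isfinite(self.lp)):
            raise ValueError(f"lp must be positive, got {self.lp!r}")
        if not (self.theta_a > 0 and math.isfinite(self.theta_a)):
            raise ValueError(f"theta_a must be positive, got {self.theta_a!r}")
        if self.theta_b is not None and self.theta_b <= self.theta_a:
            raise ValueError("theta_b must exceed theta_a")

    def energy(self, theta_bar):
        """Per-site energy (kT) at average bend angle theta_bar (rad).

        Piecewise with continuous value and slope at theta_a:
        ``Lp/2 * t^2`` below, ``Lp * theta_a * (t - theta_a/2)`` above.
        """
        t = np.asarray(theta_bar, dtype=float)
        if np.any(t < 0):
            raise ValueError("theta_bar must be non-negative")
        if self.theta_b is not None and np.any(t >= self.theta_b):
            raise ValueError(
                f"theta_bar >= theta_b ({self.theta_b:g} rad): the extreme "
                "strong-bending regime is outside the model"
            )
        out = np.where(
            t <= self.theta_a,
            0.5 * self.lp * t * t,
            self.lp * self.theta_a * (t - 0.5 * self.theta_a),
        )
        return float(out) if np.isscalar(theta_bar) else out

    def __call__(self, theta_bar):
        return self.energy(theta_bar)


def constrained_minimum(
    profile: BendingProfile, n: int, alpha: float
) -> tuple[float, np.ndarray]:
    """Minimise the total bending energy of an n-site chain at fixed total bend.

    Solves ``min sum_i E(theta_i)`` subject to ``sum_i theta_i = alpha``.
    For convex profiles the optimum is uniform (``theta_i = alpha/n``).  If
    the profile has a hull and ``alpha/n`` falls inside it, the optimum is
    two-state: ``m`` sites strongly bent, the rest weakly bent.  The integer
    ``m`` is taken as floor or ceil of ``p*n`` (both completions evaluated,
    lower total kept), and for each ``m`` the two angle values are optimised
    continuously under the exact sum constraint, so the returned assignment
    honours ``sum theta_i = alpha`` to machine precision.

    Returns ``(per-site energy kT, angle assignment array)``.
    """
    if n < 2:
        raise ValueError("need at least 2 sites")
    lo, hi = profile.domain
    tbar = alpha / n
    if not (lo <= tbar <= hi):
        raise DomainError(
            f"alpha/n = {tbar:g} rad outside profile domain [{lo:g}, {hi:g}]"
        )

    try:
        hull = find_double_tangent(profile)
    except HullTruncatedError:
        hull = None
    uniform = np.full(n, tbar)
    e_uniform = float(np.mean(profile.energy(uniform)))
    if hull is None or not (hull.theta_a < tbar < hull.theta_b):
        return e_uniform, uniform

    p = strong_fraction(tbar, hull.theta_a, hull.theta_b)
    best = (e_uniform, uniform)
    for m in {math.floor(p * n), math.ceil(p * n)}:
        if not (0 < m < n):
            continue

        def total(x, m=m):
            # m strong sites at angle x, remainder shares the rest of alpha
            y = (alpha - m * x) / (n - m)
            if not (lo <= y <= hi):
                return np.inf
            return m * float(profile.energy(x)) + (n - m) * float(profile.energy(y))

        xlo = max(lo, hull.theta_a)
        xhi = min(hi, hull.theta_b + 0.25 * (hull.theta_b - hull.theta_a))
        res = minimize_scalar(total, bounds=(xlo, xhi), method="bounded",
                              options={"xatol": 1e-12})
        if res.fun / n < best[0]:
            x = float(res.x)
            y = (alpha - m * x) / (n - m)
            assignment = np.concatenate([np.full(m, x), np.full(n - m, y)])
            best = (res.fun / n, assignment)
    return best
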