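"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.spatial import ConvexHull

import echbend as eb


@pytest.fixture(scope="session")
def dna_profile():
    return eb.dna_quartic_profile()


@pytest.fixture(scope="session")
def dna_hull(dna_profile):
    return eb.find_double_tangent(dna_profile)


# ---------------------------------------------------------------------------
# independent oracles (never share code with the implementation they check)
# ---------------------------------------------------------------------------

def grid_hull_oracle(profile, n=100001):
    """Hull endpoints by brute force: dense sampling + scipy ConvexHull.

    Builds the full 2-D convex hull of the sampled (theta, E) points with
    qhull, keeps the lower chain, and returns the endpoints of the edge
    that skips interior samples.  Returns None if every sample lies on the
    lower hull (convex profile).
    """
    lo, hi = profile.domain
    theta = np.linspace(lo, hi, n)
    energy = np.asarray(profile.energy(theta), dtype=float)
    # close the point set from above so qhull's hull has a trivial upper chain
    top = max(energy.max(), 0.0) + 1.0
    pts = np.concatenate(
        [np.column_stack([theta, energy]),
         [[theta[0], top], [theta[-1], top]]]
    )
    hull = ConvexHull(pts)
    verts = sorted(v for v in hull.vertices if v < n)
    for a, b in zip(verts[:-1], verts[1:]):
        if b - a > 1:
            return float(theta[a]), float(theta[b])
    return None


def dp_constrained_minimum(profile, n_sites, alpha, grid=1200):
    """Dynamic-programming minimisation of sum E(theta_i) with fixed sum.

    Discretises the per-site angle on a uniform grid and the running total
    on the matching grid, then performs a min-plus recursion over sites.
    Returns the per-site energy of the best discrete assignment.
    """
    lo, hi = profile.domain
    step = (hi - lo) / (grid - 1)
    angles = lo + step * np.arange(grid)
    evals = np.asarray(profile.energy(angles), dtype=float)
    n_tot = int(round((alpha - n_sites * lo) / step)) + grid
    best = np.full(n_tot, np.inf)
    best[0] = 0.0  # total (above n*lo) of zero extra steps
    for _ in range(n_sites):
        new = np.full(n_tot, np.inf)
        for j in range(grid):
            shifted = np.concatenate(
                [np.full(j, np.inf), best[: n_tot - j]]
            ) + evals[j]
            np.minimum(new, shifted, out=new)
        best = new
    target = int(round((alpha - n_sites * lo) / step))
    window = best[max(0, target - 1): target + 2]
    return float(np.min(window)) / n_sites


def boltzmann_angle_moments(site_energy, beta=1.0):
    """<theta> and <E> of one bend site of a free freely-rotating chain.

    For an open chain of inextensible bonds the joint angle measure
    factorises, with solid-angle weight: p(theta) ~ sin(theta) exp(-beta E).
    """
    from scipy.integrate import quad

    z = quad(lambda t: math.sin(t) * math.exp(-beta * site_energy(t)),
             0, math.pi, limit=200)[0]
    tmean = quad(lambda t: t * math.sin(t) * math.exp(-beta * site_energy(t)),
                 0, math.pi, limit=200)[0] / z
    emean = quad(lambda t: site_energy(t) * math.sin(t)
                 * math.exp(-beta * site_energy(t)),
                 0, math.pi, limit=200)[0] / z
    return tmean, emean
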