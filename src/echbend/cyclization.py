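"""Loop energies, cyclization j-factors, ratios and prefactor calibration.

For a closed loop of ``L`` bending sites the bend angles sum to 2*pi, so the
average bend per site is ``theta_bar = 2*pi/L`` and the total bending energy
is ``L * Ebar(2*pi/L)``.  With the ECH per-site energy this gives the
piecewise loop energy (kT):

    E_loop(L) = 2*pi^2 * Lp / L                     for L > 2*pi/theta_a   (WLC)
              = Lp * theta_a * (2*pi - L*theta_a/2) for 2*pi/theta_b < L < 2*pi/theta_a

The WLC branch diverges as ~1/L for small loops; the ECH branch approaches a
constant, which is what reconciles theory with the measured cyclization of
short DNA fragments.

The cyclization probability (Jacobson-Stockmayer j-factor) uses the
Shimada-Yamakawa closed-loop form

    j(L) ~= k * Lp^-3 * (Lp/L)^5 * exp(-E_loop/kT + L/(4*Lp))

where the power-law/exponential entropy factor counts looping geometries and
``k`` subsumes the loop-closure geometry details; ``k`` cancels in ratios
``j(L1)/j(L2)``.  Torsional alignment of the cohesive ends modulates j with
the helical phase cos(2*pi*L/h) (helical repeat ``h`` = 10 bp/turn by
default); the unmodulated curve is the envelope.  The ECH envelope has a
minimum at

    L* = 5 / (1/(4*Lp) + Lp*theta_a^2/2)

(~45 bp for Lp = 150 bp, theta_a = 2.2 deg): below L* the flat ECH bending
cost lets the shrinking entropy penalty win and the cyclization probability
counter-intuitively rises again as loops get shorter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LoopSpec",
    "JFactorCurve",
    "loop_energy",
    "jfactor",
    "jfactor_ratio",
    "jfactor_curve",
    "envelope_minimum",
    "envelope_argmin_numeric",
    "fit_k",
    "OutOfRegimeError",
]

TWO_PI = 2.0 * math.pi


class OutOfRegimeError(ValueError):
    """Loop length outside the validity range of the requested model branch."""


@dataclass(frozen=True)
class LoopSpec:
    """Parameters of a closed-loop energy model.

    model : "wlc" or "ech"; lp : persistence length (bp); theta_a/theta_b :
    hull angles (rad, ECH only); h : helical repeat (bp/turn).
    """

    model: str = "ech"
    lp: float = 150.0
    theta_a: float | None = None
    theta_b: float | None = None
    h: float = 10.0

    def __post_init__(self):
        if self.model not in ("wlc", "ech"):
            raise ValueError(f"model must be 'wlc' or 'ech', got {self.model!r}")
        if not self.lp > 0:
            raise ValueError("lp must be positive")
        if self.model == "ech":
            if self.theta_a is None or not self.theta_a > 0:
                raise ValueError("ECH model requires theta_a > 0 (rad)")
            if self.theta_b is not None and self.theta_b <= self.theta_a:
                raise ValueError("theta_b must exceed theta_a")


def loop_energy(spec: LoopSpec, L) -> np.ndarray | float:
    """Total bending energy (kT) of a closed loop of L sites.

    WLC: ``2*pi^2*Lp/L`` for all L > 0.  ECH: same for ``L > 2*pi/theta_a``
    (weak bending), ``Lp*theta_a*(2*pi - L*theta_a/2)`` inside the hull
    regime; the two branches agree at ``L = 2*pi/theta_a``.  Lengths at or
    below ``2*pi/theta_b`` (all sites fully kinked) are out of regime.
    """
    Lv = np.asarray(L, dtype=float)
    if np.any(Lv <= 0):
        raise ValueError("loop length must be positive")
    if spec.model == "wlc":
        out = 2.0 * math.pi**2 * spec.lp / Lv
    else:
        l_onset = TWO_PI / spec.theta_a
        if spec.theta_b is not None:
            l_min = TWO_PI / spec.theta_b
            if np.any(Lv <= l_min):
                raise OutOfRegimeError(
                    f"L <= 2*pi/theta_b = {l_min:.3g} bp: extreme strong-bending "
                    "regime (fully kinked loop) is outside the ECH model"
                )
        out = np.where(
            Lv > l_onset,
            2.0 * math.pi**2 * spec.lp / Lv,
            spec.lp * spec.theta_a * (TWO_PI - 0.5 * Lv * spec.theta_a),
        )
    return float(out) if np.isscalar(L) else out


def _modulation_factor(L, h: float, floor: float) -> np.ndarray:
    """Torsional phase factor (1 + cos(2*pi*L/h))/2, clamped to a positive floor.

    Equals 1 at integer numbers of helical turns (curve touches the
    envelope) and is clamped away from 0 so log-scale plots and fits remain
    defined at half-integer turns.
    """
    f = 0.5 * (1.0 + np.cos(TWO_PI * np.asarray(L, dtype=float) / h))
    return np.maximum(f, floor)


def jfactor(
    spec: LoopSpec,
    L,
    k: float = 1.0,
    modulation: str = "none",
    floor: float = 1e-3,
) -> np.ndarray | float:
    """Shimada-Yamakawa j-factor (relative units unless k is calibrated).

    ``j = k * Lp^-3 * (Lp/L)^5 * exp(-E_loop + L/(4*Lp))``, optionally
    multiplied by the torsional modulation factor (``modulation="cosine"``).
    """
    if not k > 0:
        raise ValueError("prefactor k must be positive")
    if modulation not in ("none", "cosine"):
        raise ValueError(f"modulation must be 'none' or 'cosine', got {modulation!r}")
    Lv = np.asarray(L, dtype=float)
    e = loop_energy(spec, Lv)
    j = k * spec.lp**-3 * (spec.lp / Lv) ** 5 * np.exp(-e + Lv / (4.0 * spec.lp))
    if modulation == "cosine":
        j = j * _modulation_factor(Lv, spec.h, floor)
    return float(j) if np.isscalar(L) else j


def jfactor_ratio(
    spec: LoopSpec, l1: float, l2: float, modulation: str = "none"
) -> float:
    """Ratio j(L1)/j(L2); the geometry prefactor k cancels by construction."""
    return float(jfactor(spec, l1, modulation=modulation)
                 / jfactor(spec, l2, modulation=modulation))


def envelope_minimum(lp: float, theta_a: float) -> float:
    """Loop length (bp, real-valued) minimising the ECH j-factor envelope.

    Stationary point of ``ln j`` with the linear-branch loop energy:
    ``d/dL [-5 ln L - Lp*theta_a*(2*pi - L*theta_a/2) + L/(4*Lp)] = 0``
    gives ``L* = 5 / (1/(4*Lp) + Lp*theta_a^2/2)``.
    """
    if not (lp > 0 and theta_a >= 0):
        raise ValueError("need lp > 0 and theta_a >= 0")
    return 5.0 / (1.0 / (4.0 * lp) + 0.5 * lp * theta_a**2)


def envelope_argmin_numeric(
    spec: LoopSpec, l_lo: float | None = None, l_hi: float | None = None,
    step: float = 0.01,
) -> float:
    """Numerical argmin of the unmodulated j-factor envelope on a length grid.

    Cross-check for :func:`envelope_minimum`; scans ``[l_lo, l_hi]``
    (default: just above 2*pi/theta_b up to the hull-onset length) at
    ``step`` bp resolution.
    """
    if spec.model != "ech":
        raise ValueError("the WLC envelope has no interior minimum to locate")
    if l_lo is None:
        l_lo = TWO_PI / spec.theta_b + step if spec.theta_b else 10.0
    if l_hi is None:
        l_hi = TWO_PI / spec.theta_a
    grid = np.arange(l_lo, l_hi, step)
    logj = (-5.0 * np.log(grid)
            - loop_energy(spec, grid)
            + grid / (4.0 * spec.lp))
    return float(grid[np.argmin(logj)])


def fit_k(spec: LoopSpec, lengths, j_obs, modulation: str = "none") -> float:
    """Calibrate the geometry prefactor k against measured (L, j) points.

    Least squares on ``log j`` with k the only free parameter has the closed
    form: k is the geometric mean of observed/predicted (k=1) ratios.
    """
    Lv = np.atleast_1d(np.asarray(lengths, dtype=float))
    jv = np.atleast_1d(np.asarray(j_obs, dtype=float))
    if Lv.size == 0:
        raise ValueError("need at least one (L, j) calibration point")
    if Lv.shape != jv.shape:
        raise ValueError("lengths and j values differ in length")
    if np.any(jv <= 0):
        raise ValueError("j-factor values must be positive")
    pred = jfactor(spec, Lv, k=1.0, modulation=modulation)
    return float(np.exp(np.mean(np.log(jv) - np.log(pred))))


@dataclass(frozen=True, eq=False)
class JFactorCurve:
    """j-factor curve over a loop-length grid, with its unmodulated envelope."""

    lengths: np.ndarray
    j: np.ndarray
    envelope: np.ndarray
    k: float
    modulation: str
    h: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"L_bp": self.lengths, "j": self.j, "envelope": self.envelope}
        )


def jfactor_curve(
    spec: LoopSpec,
    lengths,
    k: float = 1.0,
    modulation: str = "none",
    floor: float = 1e-3,
) -> JFactorCurve:
    """Evaluate j(L) and its envelope on a grid of loop lengths."""
    Lv = np.asarray(lengths, dtype=float)
    env = jfactor(spec, Lv, k=k, modulation="none")
    j = (jfactor(spec, Lv, k=k, modulation="cosine", floor=floor)
         if modulation == "cosine" else env.copy())
    return JFactorCurve(lengths=Lv, j=j, envelope=env, k=k,
                        modulation=modulation, h=spec.h)
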