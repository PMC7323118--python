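"""File formats, run configuration and synthetic fixture generation.

Plain-text formats only: two-column angle/energy tables for bending
profiles, multi-frame XYZ for trajectories, TSV for tidy tables, YAML for
run configuration.  The fixture generator produces deterministic synthetic
inputs (profiles with known hulls, noisy j-factor datasets with a known
prefactor, toy ring geometries) so every part of the package is testable
without external data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .profiles import BendingProfile, QuarticProfile, TabulatedProfile
from .cyclization import LoopSpec, jfactor
from .loopsim import build_regular_loop

__all__ = [
    "RunConfig",
    "read_profile_table",
    "write_profile_table",
    "read_xyz",
    "write_xyz",
    "make_fixtures",
    "ProfileFormatError",
]


class ProfileFormatError(ValueError):
    """Malformed profile table file."""


@dataclass
class RunConfig:
    """Serializable bag of run parameters (YAML round-trip is identity)."""

    command: str = ""
    seed: int = 0
    params: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            yaml.safe_dump(
                {"command": self.command, "seed": self.seed, "params": self.params},
                sort_keys=True,
            )
        )
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            command=data.get("command", ""),
            seed=int(data.get("seed", 0)),
            params=data.get("params", {}),
        )


def read_profile_table(path: str | Path, degrees: bool = False) -> TabulatedProfile:
    """Read a two-column (angle, energy kT) text table into a profile.

    Whitespace- or comma-separated; lines starting with ``#`` and an
    optional non-numeric header row are skipped.  Angles are radians unless
    ``degrees=True``.  At least 4 knots are required and angles must be
    strictly increasing (error messages carry the offending row number).
    """
    path = Path(path)
    rows: list[tuple[float, float]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise ProfileFormatError(f"{path}:{lineno}: expected two columns")
        try:
            theta, energy = float(parts[0]), float(parts[1])
        except ValueError:
            if lineno == 1 or not rows:
                continue  # header row
            raise ProfileFormatError(
                f"{path}:{lineno}: non-numeric cell in {parts[:2]!r}"
            ) from None
        rows.append((theta, energy))
    if len(rows) < 4:
        raise ProfileFormatError(
            f"{path}: need at least 4 data rows, found {len(rows)}"
        )
    theta = np.array([r[0] for r in rows])
    energy = np.array([r[1] for r in rows])
    if degrees:
        theta = np.radians(theta)
    d = np.diff(theta)
    if np.any(d <= 0):
        row = int(np.argmax(d <= 0)) + 2  # 1-based, offending (second) row
        raise ProfileFormatError(
            f"{path}: angles not strictly increasing at data row {row}"
        )
    return TabulatedProfile(theta=theta, values=energy)


def write_profile_table(
    profile: BendingProfile, path: str | Path, n: int = 101, degrees: bool = False
) -> Path:
    """Write a profile sampled on n uniform knots as a two-column table."""
    path = Path(path)
    theta = np.linspace(profile.domain[0], profile.domain[1], n)
    energy = np.asarray(profile.energy(theta), dtype=float)
    col = np.degrees(theta) if degrees else theta
    unit = "deg" if degrees else "rad"
    lines = [f"# angle_{unit}\tenergy_kT"]
    lines += [f"{a:.12g}\t{e:.12g}" for a, e in zip(col, energy)]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_xyz(
    frames,
    path: str | Path,
    element: str = "C",
    comments: list[str] | None = None,
) -> Path:
    """Write coordinate frames as standard multi-frame XYZ (Angstrom).

    Each block: atom count, comment line (frame index, plus any
    user-supplied annotation such as the frame energy), then
    ``element x y z`` rows.
    """
    arr = np.asarray(frames, dtype=float)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3 or arr.shape[0] == 0 or arr.shape[2] != 3:
        raise ValueError("frames must be a non-empty (n_frames, N, 3) stack")
    frames = list(arr)
    path = Path(path)
    out = []
    for i, fr in enumerate(frames):
        note = comments[i] if comments is not None else ""
        out.append(str(fr.shape[0]))
        out.append(f"frame {i} {note}".rstrip())
        for x, y, z in fr:
            out.append(f"{element} {x:.6f} {y:.6f} {z:.6f}")
    path.write_text("\n".join(out) + "\n")
    return path


def read_xyz(path: str | Path) -> list[np.ndarray]:
    """Read a multi-frame XYZ file back into a list of (N, 3) arrays."""
    lines = Path(path).read_text().splitlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        natoms = int(lines[i].strip())
        block = lines[i + 2 : i + 2 + natoms]
        coords = np.array(
            [[float(v) for v in ln.split()[1:4]] for ln in block]
        )
        frames.append(coords)
        i += 2 + natoms
    return frames


FIXTURE_KINDS = ("convex-profile", "nonconvex-profile", "noisy-jfactor", "toy-loop")


def make_fixtures(kind: str, seed: int, outdir: str | Path) -> dict:
    """Generate deterministic synthetic fixture files.

    * ``convex-profile``: a harmonic-like quartic with no hull.
    * ``nonconvex-profile``: a random single-well non-convex quartic; the
      ground-truth tangency points (found by a dense-grid chord search,
      independent of the package's hull solver) are recorded alongside.
    * ``noisy-jfactor``: (L, j) pairs from the closed-form j-factor with a
      known prefactor k and multiplicative lognormal noise.
    * ``toy-loop``: a regular ring polygon as an XYZ file.

    Returns a manifest dict (also written as JSON) describing the files and
    any recorded ground truth.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest: dict = {"kind": kind, "seed": seed}

    if kind == "convex-profile":
        c2 = float(rng.uniform(50, 300))
        profile = QuarticProfile(c2=c2, c3=0.0, c4=float(rng.uniform(0, 100)))
        f = write_profile_table(profile, outdir / "convex_profile.tsv", n=201)
        manifest.update(files=[str(f)], c2=profile.c2, c3=0.0, c4=profile.c4)

    elif kind == "nonconvex-profile":
        # scaled copies of a reference single-well shape stay single-well
        scale = float(rng.uniform(0.5, 5.0))
        width = float(rng.uniform(0.8, 1.2))
        c2, c3, c4 = 203.1 * scale, -552.7 * scale / width, 416.8 * scale / width**2
        profile = QuarticProfile(c2=c2, c3=c3, c4=c4)
        f = write_profile_table(profile, outdir / "nonconvex_profile.tsv", n=801)
        theta_a, theta_b = _chord_search_hull(profile)
        manifest.update(
            files=[str(f)], c2=c2, c3=c3, c4=c4,
            theta_a_true=theta_a, theta_b_true=theta_b,
        )

    elif kind == "noisy-jfactor":
        k_true = 0.07
        spec = LoopSpec(model="ech", lp=150.0, theta_a=math.radians(2.2))
        lengths = np.array(sorted(rng.choice(np.arange(40, 180), size=50, replace=False)), dtype=float)
        j = jfactor(spec, lengths, k=k_true) * np.exp(rng.normal(0.0, 0.1, lengths.size))
        f = outdir / "jfactor_points.tsv"
        lines = ["# L_bp\tj"]
        lines += [f"{L:g}\t{val:.8e}" for L, val in zip(lengths, j)]
        f.write_text("\n".join(lines) + "\n")
        manifest.update(files=[str(f)], k_true=k_true, lp=150.0, theta_a_deg=2.2)

    elif kind == "toy-loop":
        n = int(rng.integers(12, 120))
        chain = build_regular_loop(n)
        f = write_xyz([chain.coords], outdir / "toy_loop.xyz")
        manifest.update(files=[str(f)], n=n, b=chain.b)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _chord_search_hull(profile: QuarticProfile, n: int = 100001) -> tuple[float, float]:
    """Brute-force hull endpoints: densely sample and find the chord of the
    discrete lower convex hull that skips interior samples.

    Independent of the package's tangency solver (pure chord geometry on a
    dense grid); used only to record fixture ground truth.
    """
    lo, hi = profile.domain
    theta = np.linspace(lo, hi, n)
    energy = np.asarray(profile.energy(theta), dtype=float)
    hull = [0]
    for i in range(1, n):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            if (theta[k] - theta[j]) * (energy[i] - energy[j]) <= (
                energy[k] - energy[j]
            ) * (theta[i] - theta[j]):
                hull.pop()
            else:
                break
        hull.append(i)
    for m in range(len(hull) - 1):
        if hull[m + 1] - hull[m] > 1:
            return float(theta[hull[m]]), float(theta[hull[m + 1]])
    raise ValueError("profile is convex: no hull chord found")
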