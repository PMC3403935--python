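"""Synthetic structure ensembles with known ground truth.

Real decoy sets and fragment libraries are large downloads; the generator
here emulates their geometry at any scale: k center conformations built
from a common base trace (helix-like, extended, or a random walk) plus
center-specific smooth deformations of a chosen RMSD scale, then n
structures drawn as a center plus per-atom Gaussian noise.  Every
structure is finally given its own random rigid rototranslation so that
optimal superposition is always exercised non-trivially.

The generator returns the true center label of every structure, which is
what makes clustering-recovery tests possible without external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import AtomSelection, CoordinateSet
from .search import Ensemble

__all__ = ["SyntheticSpec", "make_ensemble", "make_toy_pair"]

_GEOMETRIES = ("helix", "extended", "random-walk")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a labelled synthetic ensemble.

    separation is the approximate center-to-center RMSD (Å); sigma the
    per-atom, per-coordinate Gaussian noise within a center (Å), so two
    members of one center sit at roughly sigma*sqrt(6) RMSD of each other.
    """

    n: int = 100
    geometry: str = "helix"
    n_residues: int = 30
    k: int = 1
    separation: float = 5.0
    sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("need n >= 1 structures")
        if self.k < 1:
            raise ValueError("need k >= 1 centers")
        if self.k > self.n:
            raise ValueError(f"k={self.k} centers cannot exceed n={self.n} structures")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.n_residues < 1:
            raise ValueError("need at least one residue")
        if self.geometry not in _GEOMETRIES:
            raise ValueError(f"geometry must be one of {_GEOMETRIES}")


def _base_trace(geometry: str, n_res: int, rng: np.random.Generator) -> np.ndarray:
    """CA trace of the requested base geometry, ~3.8 Å between neighbours."""
    i = np.arange(n_res)
    if geometry == "helix":
        # Ideal alpha-helix CA parameters: 2.3 Å radius, 1.5 Å rise,
        # 100 degrees per residue.
        theta = np.deg2rad(100.0) * i
        return np.column_stack(
            [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i]
        )
    if geometry == "extended":
        # Flat zigzag with ~3.8 Å CA-CA spacing.
        return np.column_stack(
            [3.63 * i, 1.1 * (i % 2), np.zeros(n_res)]
        )
    # random-walk: fixed 3.8 Å steps in random directions.
    steps = rng.normal(size=(n_res - 1, 3)) if n_res > 1 else np.empty((0, 3))
    norms = np.linalg.norm(steps, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    steps = 3.8 * steps / norms
    return np.vstack([[0.0, 0.0, 0.0], np.cumsum(steps, axis=0)])


def make_ensemble(spec: SyntheticSpec) -> tuple[Ensemble, np.ndarray]:
    """Generate a labelled ensemble from a single seeded random stream.

    Returns the ensemble (CA-only CoordinateSets) and an integer array of
    ground-truth center labels, one per structure.
    """
    rng = np.random.default_rng(spec.seed)
    base = _base_trace(spec.geometry, spec.n_residues, rng)

    # Center construction: base plus a center-specific Gaussian deformation
    # scaled so two centers sit at ~`separation` RMSD of each other
    # (per-coordinate std sep/sqrt(6) gives E[pairwise raw RMSD] ~ sep).
    if spec.k == 1:
        centers = [base.copy()]
    else:
        center_sigma = spec.separation / np.sqrt(6.0)
        centers = [
            base + rng.normal(scale=center_sigma, size=base.shape)
            for _ in range(spec.k)
        ]

    labels = rng.integers(spec.k, size=spec.n)
    # Guarantee every center is represented at least once.
    labels[: spec.k] = np.arange(spec.k)

    members = []
    for idx in range(spec.n):
        coords = centers[labels[idx]].copy()
        if spec.sigma > 0:
            coords = coords + rng.normal(scale=spec.sigma, size=coords.shape)
        # Random rigid motion so raw and optimal RMSD differ.
        R = Rotation.random(rng=rng).as_matrix()
        T = rng.uniform(-20.0, 20.0, size=3)
        coords = coords @ R.T + T
        atoms = [("A", r + 1, "CA") for r in range(spec.n_residues)]
        members.append(CoordinateSet(f"synth_{idx:05d}", atoms, coords))
    return Ensemble(members, AtomSelection("CA")), labels


def make_toy_pair(kind: str, delta: float = 1.0) -> tuple[CoordinateSet, CoordinateSet]:
    """Small deterministic coordinate pairs with known RMSD behaviour.

    kinds: ``translated`` (b = a shifted by (delta,0,0): raw RMSD = delta,
    optimal 0), ``rotated`` (b = a turned 90° about z and shifted: optimal
    RMSD 0), ``single-atom-shift`` (one atom of a 4-atom set moved by
    delta along x; optimal RMSD known only numerically).
    """
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [3.8, 0.0, 0.0],
            [5.0, 3.0, 1.0],
            [2.0, 4.0, -2.0],
        ]
    )
    atoms = [("A", r + 1, "CA") for r in range(4)]
    a = CoordinateSet("toy_a", atoms, coords)
    if kind == "translated":
        b = CoordinateSet("toy_b", atoms, coords + np.array([delta, 0.0, 0.0]))
    elif kind == "rotated":
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        b = CoordinateSet("toy_b", atoms, coords @ Rz.T + np.array([10.0, -3.0, 7.0]))
    elif kind == "single-atom-shift":
        shifted = coords.copy()
        shifted[2, 0] += delta
        b = CoordinateSet("toy_b", atoms, shifted)
    else:
        raise ValueError(f"unknown toy pair kind {kind!r}")
    return a, b
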