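"""Coordinate handling, optimal superposition and RMSD computation.

The distance used throughout the package is RMSD after optimal rigid
superposition (Kabsch), which is a metric on rototranslation-equivalence
classes of structures.  Both the triangle inequality and the inverse
triangle inequality therefore hold for it; the latter is what the pruned
pair search in :mod:`rmsdprune.search` exploits.

Mirror images are deliberately *not* superposable: the rotation returned
is always proper (det = +1), the standard convention for protein
comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AtomSelection",
    "CoordinateSet",
    "Superposition",
    "center",
    "superpose",
    "optimal_rmsd",
    "raw_rmsd",
    "rmsd100",
    "RMSD100_DEFAULT_CAP",
]

#: Distance reported by :func:`rmsd100` when fewer than 14 residues align.
#: Any value larger than every working threshold serves; pairs that short
#: are treated as maximally dissimilar.
RMSD100_DEFAULT_CAP = 999.9

#: Below this many aligned residues the RMSD100 denominator
#: 1 + 0.5*ln(N/100) is zero or negative (it crosses zero near N ~ 13.5).
RMSD100_MIN_RESIDUES = 14

# Canonical backbone atom order used for the "backbone" selection.
BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class AtomSelection:
    """Which atoms of each residue participate in superposition.

    mode
        ``"CA"`` (alpha carbons only), ``"backbone"`` (N, CA, C, O) or
        ``"custom"`` with explicit atom ``names``.
    """

    mode: str = "CA"
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("CA", "backbone", "custom"):
            raise ValueError(f"unknown selection mode {self.mode!r}")
        if self.mode == "custom" and not self.names:
            raise ValueError("custom selection requires a non-empty name list")

    @property
    def atom_names(self) -> tuple[str, ...]:
        if self.mode == "CA":
            return ("CA",)
        if self.mode == "backbone":
            return BACKBONE_ATOMS
        return tuple(self.names)

    @classmethod
    def from_string(cls, text: str, names: Sequence[str] = ()) -> "AtomSelection":
        key = text.strip().lower()
        if key == "ca":
            return cls("CA")
        if key == "backbone":
            return cls("backbone")
        if key == "custom":
            return cls("custom", tuple(names))
        raise ValueError(f"unknown selection {text!r}")


@dataclass
class CoordinateSet:
    """One structure's selected atoms: identity labels plus coordinates (Å).

    ``atoms[k]`` is a ``(chain_id, residue_id, atom_name)`` triple labelling
    row ``k`` of ``coords``; labels must be unique and coordinates finite.
    """

    name: str
    atoms: list[tuple]
    coords: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        if len(self.atoms) != self.coords.shape[0]:
            raise ValueError(
                f"{len(self.atoms)} atom labels but {self.coords.shape[0]} coordinates"
            )
        if self.coords.shape[0] < 1:
            raise ValueError("a CoordinateSet needs at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates in {self.name!r}")
        if len(set(map(tuple, self.atoms))) != len(self.atoms):
            raise ValueError(f"duplicate atom labels in {self.name!r}")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class Superposition:
    """A proper rigid motion (rotation then translation) and its RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=np.float64)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ np.asarray(self.rotation).T + np.asarray(self.translation)


def center(cs: CoordinateSet) -> tuple[CoordinateSet, np.ndarray]:
    """Translate a structure so its centroid sits at the origin.

    Returns the centered copy and the original centroid.
    """
    centroid = cs.coords.mean(axis=0)
    return CoordinateSet(cs.name, list(cs.atoms), cs.coords - centroid), centroid


def _check_pairable(a: CoordinateSet, b: CoordinateSet) -> None:
    if a.n_atoms != b.n_atoms:
        raise ValueError(
            f"atom-count mismatch: {a.name!r} has {a.n_atoms} atoms, "
            f"{b.name!r} has {b.n_atoms}"
        )


def _kabsch_rotation(H: np.ndarray) -> np.ndarray:
    """Best proper rotation from a 3×3 cross-covariance H = QᵀP.

    With H = U S Vᵀ the optimum is R = V D Uᵀ, D = diag(1, 1, d) and the
    sign d chosen so det(R) = +1 (mirror images are never superposed).
    """
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
    D = np.diag([1.0, 1.0, d])
    return (U @ D @ Vt).T


def kabsch_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Minimum RMSD between two *centered* (N, 3) coordinate arrays.

    The RMSD is evaluated from the actual rotated residuals rather than
    the singular-value trace identity: the latter loses ~half the digits
    to cancellation for near-identical structures, and searches at tight
    thresholds care precisely about that regime.
    """
    n = P.shape[0]
    R = _kabsch_rotation(Q.T @ P)
    diff = P - Q @ R.T
    return math.sqrt(np.einsum("ij,ij->", diff, diff) / n)


def kabsch_rmsd_many(P: np.ndarray, Qs: np.ndarray) -> np.ndarray:
    """Minimum RMSD of one centered structure against a stack of centered ones.

    ``P`` is (N, 3); ``Qs`` is (M, N, 3).  The 3×3 SVDs are batched, which
    is what makes the one-vs-many reference passes of the pair search
    cheap.  Residual-based evaluation as in :func:`kabsch_rmsd`.
    """
    n = P.shape[0]
    H = np.einsum("mki,kj->mij", Qs, P)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
    D = np.zeros_like(H)
    D[:, 0, 0] = 1.0
    D[:, 1, 1] = 1.0
    D[:, 2, 2] = d
    R = np.transpose(U @ D @ Vt, (0, 2, 1))
    diff = P[None, :, :] - np.einsum("mnj,mij->mni", Qs, R)
    msd = np.einsum("mni,mni->m", diff, diff) / n
    return np.sqrt(msd)


def superpose(a: CoordinateSet, b: CoordinateSet) -> Superposition:
    """Optimal proper rigid motion mapping ``b`` onto ``a``.

    Minimizes ``sqrt(Σ‖a_k − (R b_k + T)‖²/N)`` over rotations R with
    det(R) = +1 and translations T.
    """
    _check_pairable(a, b)
    ca = a.coords.mean(axis=0)
    cb = b.coords.mean(axis=0)
    P = a.coords - ca
    Q = b.coords - cb
    R = _kabsch_rotation(Q.T @ P)
    diff = P - Q @ R.T
    rmsd = math.sqrt(np.einsum("ij,ij->", diff, diff) / a.n_atoms)
    T = ca - R @ cb
    return Superposition(rotation=R, translation=T, rmsd=rmsd)


def optimal_rmsd(a: CoordinateSet, b: CoordinateSet) -> float:
    """RMSD after optimal superposition — the metric used for searching."""
    _check_pairable(a, b)
    P = a.coords - a.coords.mean(axis=0)
    Q = b.coords - b.coords.mean(axis=0)
    return kabsch_rmsd(P, Q)


def raw_rmsd(a: CoordinateSet, b: CoordinateSet) -> float:
    """Coordinate RMSD with no superposition; never below :func:`optimal_rmsd`."""
    _check_pairable(a, b)
    diff = a.coords - b.coords
    return math.sqrt(np.einsum("ij,ij->", diff, diff) / a.n_atoms)


def rmsd100(rmsd: float, n_aligned: int, cap: float = RMSD100_DEFAULT_CAP) -> float:
    """Length-normalized RMSD (Carugo–Pongor scaling).

    Estimates the RMSD expected if 100 residues were aligned:
    ``rmsd / (1 + 0.5·ln(N/100))``.  For fewer than 14 aligned residues the
    denominator is non-positive, so the pair is reported as ``cap``
    (maximally dissimilar).
    """
    if rmsd < 0:
        raise ValueError("rmsd must be non-negative")
    if n_aligned < 0:
        raise ValueError("n_aligned must be non-negative")
    if cap <= 0:
        raise ValueError("cap must be positive")
    if n_aligned < RMSD100_MIN_RESIDUES:
        return cap
    return rmsd / (1.0 + 0.5 * math.log(n_aligned / 100.0))
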