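"""Pruned all-pairs RMSD similarity search.

Finding every pair of structures with optimal-superposition RMSD below a
threshold t normally costs N(N-1)/2 RMSD evaluations.  Because the optimal
RMSD is a metric, the inverse triangle inequality

    RMSD(i, j) >= |RMSD(ref, i) - RMSD(ref, j)|

lets a single one-vs-all reference pass certify many pairs as above
threshold without ever computing their RMSD.  The search iterates:

1. take the lowest-index structure not yet resolved as reference, compare
   it to every unresolved structure (the reference pass);
2. sort those RMSDs ascending; walk the sorted list retiring structure j
   after comparing it only against structures k whose reference RMSD lies
   within t of j's — all other pairs are excluded by the bound;
3. stop the walk adaptively when the ratio (structures retired) /
   (comparisons spent) stops improving, and start a new reference pass.

The output is exact: the hit list equals the brute-force hit list for any
ensemble and threshold, only the number of RMSD evaluations changes.
Memory stays O(N): only the current reference's RMSD list is kept.

`predicted_cost` evaluates the closed-form cost model for one such
iteration given the ensemble's pairwise-RMSD density f(x): with s the
reference RMSD at which the walk stops,

    N_cmp  = (N-1) + (N-1)(N-2) ∫₀ˢ f(x) ∫ₓ^{x+t} f(x') dx' dx
    N_done = 1 + (N-1) ∫₀ˢ f(x) dx
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np

from .geometry import AtomSelection, CoordinateSet, kabsch_rmsd_many

__all__ = [
    "Ensemble",
    "PairHit",
    "IterationRecord",
    "SearchStats",
    "RmsdHistogram",
    "lower_bound",
    "search_pairs",
    "brute_force_pairs",
    "predicted_cost",
]

#: Default slack added to the exclusion window; the bound is mathematically
#: exact but floating point can lose the last bits at the boundary.
DEFAULT_SLACK = 1e-6


class PairHit(NamedTuple):
    """An unordered structure pair (canonicalized i < j) within threshold."""

    i: int
    j: int
    rmsd: float


class IterationRecord(NamedTuple):
    """Accounting for one reference pass plus its pruning walk.

    ``retired`` counts structures fully resolved in the iteration,
    including the reference itself; ``stop_rmsd`` is the reference RMSD of
    the last structure retired by the walk (the effective stop value s).
    """

    reference: int
    n_cmp: int
    retired: int
    stop_rmsd: float


@dataclass
class SearchStats:
    """Comparison counts of a search and the ratio vs exhaustive all-vs-all."""

    n_structures: int
    n_cmp: int
    per_iteration: list[IterationRecord] = field(default_factory=list)

    @property
    def all_vs_all(self) -> int:
        return self.n_structures * (self.n_structures - 1) // 2

    @property
    def ratio(self) -> float:
        if self.all_vs_all == 0:
            return 0.0
        return self.n_cmp / self.all_vs_all

    def summary_line(self) -> str:
        return f"{self.n_structures}\t{self.n_cmp}\t{self.all_vs_all}\t{self.ratio:.4f}"


class Ensemble:
    """An ordered set of structures sharing one atom selection.

    All members must expose the same number of atoms so that RMSDs are
    comparable; coordinates are centered once at construction so the
    Kabsch kernel can run batched during searches.
    """

    def __init__(self, members: Sequence[CoordinateSet], selection: AtomSelection | None = None):
        members = list(members)
        if not members:
            raise ValueError("an ensemble needs at least one member")
        n_atoms = members[0].n_atoms
        for m in members[1:]:
            if m.n_atoms != n_atoms:
                raise ValueError(
                    f"atom-count mismatch in ensemble: {members[0].name!r} has "
                    f"{n_atoms} atoms, {m.name!r} has {m.n_atoms}"
                )
        self.members = members
        self.selection = selection if selection is not None else AtomSelection("CA")
        stacked = np.stack([m.coords for m in members])
        self._centered = stacked - stacked.mean(axis=1, keepdims=True)

    def __len__(self) -> int:
        return len(self.members)

    @property
    def n_atoms(self) -> int:
        return self.members[0].n_atoms

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.members]

    def rmsd_one_to_many(self, i: int, others: np.ndarray) -> np.ndarray:
        """Optimal RMSD of member ``i`` against members ``others`` (batched)."""
        if others.size == 0:
            return np.empty(0)
        return kabsch_rmsd_many(self._centered[i], self._centered[others])

    def subset(self, indices: Sequence[int]) -> "Ensemble":
        return Ensemble([self.members[i] for i in indices], self.selection)


def lower_bound(d1i: float, d1j: float) -> float:
    """Guaranteed lower bound on RMSD(i, j) from two reference distances."""
    if d1i < 0 or d1j < 0:
        raise ValueError("distances must be non-negative")
    return abs(d1i - d1j)


DistanceFn = Callable[[int, np.ndarray], np.ndarray]


def pruned_pair_search(
    n: int,
    dist: DistanceFn,
    t: float,
    slack: float = DEFAULT_SLACK,
) -> tuple[list[PairHit], SearchStats]:
    """Generic pruned search over any metric given as a one-vs-many callable.

    ``dist(i, others)`` must return the distances from item ``i`` to each
    item in ``others``.  Used directly by :func:`search_pairs` (batched
    Kabsch RMSD) and by the redundancy filter (normalized common-residue
    RMSD).  Pairs excluded by the inverse triangle bound are never passed
    to ``dist``; every reported hit was computed directly.
    """
    if t <= 0:
        raise ValueError("threshold must be positive")
    if n < 1:
        raise ValueError("need at least one item")
    done = np.zeros(n, dtype=bool)
    hits: list[PairHit] = []
    records: list[IterationRecord] = []
    window = t + slack

    while not done.all():
        ref = int(np.flatnonzero(~done)[0])
        done[ref] = True
        cand = np.flatnonzero(~done)  # all have index > ref
        if cand.size == 0:
            records.append(IterationRecord(ref, 0, 1, 0.0))
            break

        # Reference pass: one-vs-all over unresolved structures.
        d = np.asarray(dist(ref, cand), dtype=np.float64)
        n_cmp = int(cand.size)
        for k in np.flatnonzero(d <= t):
            hits.append(PairHit(ref, int(cand[k]), float(d[k])))

        # Stable ascending sort: ties keep original (index) order.
        order = np.argsort(d, kind="stable")
        sorted_idx = cand[order]
        sorted_d = d[order]

        # Pruning walk with the adaptive stop rule: retire the structure
        # with the j-th smallest reference RMSD while the retired-per-
        # comparison ratio is still improving.
        ratio = 0.0
        retired = 0
        stop_rmsd = 0.0
        m = sorted_idx.size
        for j in range(m):
            new_ratio = (j + 1) / n_cmp
            if not new_ratio > ratio:
                break
            ratio = new_ratio
            within = np.flatnonzero(sorted_d[j + 1:] - sorted_d[j] <= window)
            if within.size:
                ks = sorted_idx[j + 1:][within]
                dj = np.asarray(dist(int(sorted_idx[j]), ks), dtype=np.float64)
                n_cmp += int(ks.size)
                for h in np.flatnonzero(dj <= t):
                    a, b = int(sorted_idx[j]), int(ks[h])
                    hits.append(PairHit(min(a, b), max(a, b), float(dj[h])))
            done[sorted_idx[j]] = True
            retired += 1
            stop_rmsd = float(sorted_d[j])

        records.append(IterationRecord(ref, n_cmp, retired + 1, stop_rmsd))

    hits.sort(key=lambda h: (h.i, h.j))
    stats = SearchStats(n, sum(r.n_cmp for r in records), records)
    return hits, stats


def search_pairs(
    ens: Ensemble, t: float, slack: float = DEFAULT_SLACK
) -> tuple[list[PairHit], SearchStats]:
    """All pairs with optimal RMSD ≤ t, found with inverse-triangle pruning.

    Returns exactly the brute-force hit set (pairs canonicalized i < j,
    sorted) while typically evaluating far fewer than N(N-1)/2 RMSDs when
    t is well below the ensemble's typical pairwise RMSD.
    """
    return pruned_pair_search(len(ens), ens.rmsd_one_to_many, t, slack)


def brute_force_pairs(ens: Ensemble, t: float) -> tuple[list[PairHit], SearchStats]:
    """Exhaustive all-vs-all reference: every one of N(N-1)/2 RMSDs computed."""
    if t <= 0:
        raise ValueError("threshold must be positive")
    n = len(ens)
    hits: list[PairHit] = []
    for i in range(n - 1):
        others = np.arange(i + 1, n)
        d = ens.rmsd_one_to_many(i, others)
        for k in np.flatnonzero(d <= t):
            hits.append(PairHit(i, int(others[k]), float(d[k])))
    stats = SearchStats(n, n * (n - 1) // 2)
    return hits, stats


@dataclass
class RmsdHistogram:
    """A normalized pairwise-RMSD density f(x) on histogram bins."""

    edges: np.ndarray
    densities: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.float64)
        self.densities = np.asarray(self.densities, dtype=np.float64)
        if self.edges.ndim != 1 or self.edges.size < 2:
            raise ValueError("need at least two bin edges")
        if self.densities.size != self.edges.size - 1:
            raise ValueError("densities must have one entry per bin")
        if np.any(self.densities < 0):
            raise ValueError("densities must be non-negative")
        total = float(np.sum(self.densities * np.diff(self.edges)))
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"histogram not normalized (integral {total:.6g})")

    @classmethod
    def from_samples(cls, samples: np.ndarray, bins: int = 200) -> "RmsdHistogram":
        densities, edges = np.histogram(np.asarray(samples), bins=bins, density=True)
        return cls(edges, densities)

    @property
    def support_max(self) -> float:
        return float(self.edges[-1])

    def density_at(self, x: np.ndarray) -> np.ndarray:
        """Piecewise-constant density, zero outside the support."""
        x = np.asarray(x, dtype=np.float64)
        idx = np.clip(np.searchsorted(self.edges, x, side="right") - 1, 0, None)
        inside = (x >= self.edges[0]) & (x <= self.edges[-1])
        idx = np.minimum(idx, self.densities.size - 1)
        return np.where(inside, self.densities[idx], 0.0)


def predicted_cost(
    f: RmsdHistogram, n: int, t: float, s: float, grid_points: int = 4000
) -> tuple[float, float]:
    """Evaluate the iteration cost model (N_cmp, N_done) numerically.

    Trapezoidal quadrature of the nested integrals over the histogram
    density.  ``s`` is the reference-RMSD stop value of the pruning walk,
    ``t`` the search threshold.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if not 0.0 <= s <= f.support_max + 1e-12:
        raise ValueError(f"s={s} outside histogram support [0, {f.support_max}]")
    lo = float(f.edges[0])
    hi = f.support_max

    grid = np.linspace(min(lo, 0.0), hi, grid_points)
    fx = f.density_at(grid)
    # CDF on the grid for the inner integral F(x+t) - F(x).
    from scipy.integrate import cumulative_trapezoid

    F = np.concatenate([[0.0], cumulative_trapezoid(fx, grid)])
    Fq = lambda x: np.interp(np.clip(x, grid[0], grid[-1]), grid, F)

    xs = np.linspace(min(lo, 0.0), s, grid_points)
    inner = Fq(xs + t) - Fq(xs)
    outer = np.trapezoid(f.density_at(xs) * inner, xs)
    n_cmp = (n - 1) + (n - 1) * (n - 2) * outer
    n_done = 1 + (n - 1) * float(Fq(s))
    return float(n_cmp), float(n_done)
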