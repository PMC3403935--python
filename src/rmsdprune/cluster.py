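"""Weighted greedy clustering and near-duplicate filtering.

Fragments (or models) found similar by the pair search are grouped by a
leader algorithm: every item gets a proximity weight

    w_i = Σ_j  w_j⁰ · cos(π · RMSD_ij / (2t))      over j with RMSD_ij ≤ t,

the sum including j = i (an isolated item keeps its prior weight w_i⁰,
which is 1 at the first level and the accumulated cluster weight at later
levels).  Items are then taken in decreasing weight order; each unassigned
item of largest weight becomes a representative and absorbs every
unassigned item within the threshold.  Repeating with a doubled threshold
on the surviving representatives — whose priors carry their clusters'
accumulated weight — condenses a large fragment set into a small library
of representatives.

`filter_redundant` applies the same machinery to models of possibly
different residue content: the pairwise dissimilarity is the
length-normalized RMSD100 over the residues common to both models, and a
model is dropped when an earlier kept model lies strictly within the
normalized threshold.  Because the common-residue set varies by pair this
dissimilarity is not guaranteed to be a strict metric; the pruned search
only ever *excludes* candidate pairs by the bound, so every removal rests
on a directly computed distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import (
    RMSD100_DEFAULT_CAP,
    CoordinateSet,
    kabsch_rmsd,
    rmsd100,
)
from .search import (
    DEFAULT_SLACK,
    Ensemble,
    PairHit,
    SearchStats,
    pruned_pair_search,
    search_pairs,
)

__all__ = [
    "Cluster",
    "Schedule",
    "LevelResult",
    "neighbor_weights",
    "cluster_once",
    "cluster_iterative",
    "filter_redundant",
]


@dataclass
class Cluster:
    """A representative and the members it stands for (with their RMSDs)."""

    representative: int
    members: list[tuple[int, float]]

    @property
    def size(self) -> int:
        return len(self.members)

    def member_ids(self) -> list[int]:
        return [m for m, _ in self.members]


@dataclass(frozen=True)
class Schedule:
    """Strictly increasing RMSD thresholds for iterative clustering."""

    thresholds: tuple[float, ...]
    stop: str = "single_cluster"  # or "fixed_levels"

    def __post_init__(self) -> None:
        if not self.thresholds:
            raise ValueError("schedule needs at least one threshold")
        if any(t <= 0 for t in self.thresholds):
            raise ValueError("thresholds must be positive")
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if self.stop not in ("single_cluster", "fixed_levels"):
            raise ValueError(f"unknown stop rule {self.stop!r}")

    @classmethod
    def doubling(
        cls, initial: float = 0.05, levels: int = 7, stop: str = "single_cluster"
    ) -> "Schedule":
        return cls(tuple(initial * 2**i for i in range(levels)), stop)


@dataclass
class LevelResult:
    """Outcome of one clustering level, with search accounting."""

    threshold: float
    n_input: int
    clusters: list[Cluster]
    stats: SearchStats
    representatives: list[int]  # ids in the original ensemble
    weights: dict[int, float] = field(default_factory=dict)
    #: prior weight each representative carries to the next level
    #: (its cluster's accumulated prior mass; sums to the original N)
    carried_priors: dict[int, float] = field(default_factory=dict)

    @property
    def n_representatives(self) -> int:
        return len(self.representatives)


def neighbor_weights(
    hits: Sequence[PairHit],
    n: int,
    t: float,
    priors: np.ndarray | None = None,
) -> np.ndarray:
    """Proximity weight of each item from its sub-threshold neighbours."""
    if t <= 0:
        raise ValueError("threshold must be positive")
    if priors is None:
        priors = np.ones(n)
    priors = np.asarray(priors, dtype=np.float64)
    if priors.size != n:
        raise ValueError(f"{priors.size} priors for {n} items")
    weights = priors.copy()  # self term: cos(0) * w_i0
    for i, j, r in hits:
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"hit ({i},{j}) outside 0..{n - 1}")
        if r > t:
            raise ValueError(f"hit ({i},{j}) has rmsd {r} above threshold {t}")
        c = math.cos(math.pi * r / (2.0 * t))
        weights[i] += priors[j] * c
        weights[j] += priors[i] * c
    return weights


def cluster_once(
    hits: Sequence[PairHit], weights: np.ndarray, t: float
) -> list[Cluster]:
    """Greedy leader clustering at one threshold.

    The unassigned item of largest weight (ties: lower index) becomes a
    representative and absorbs every unassigned neighbour within t.  The
    hit list must be complete for the threshold (as returned by
    ``search_pairs``) or membership would be missed.
    """
    weights = np.asarray(weights, dtype=np.float64)
    n = weights.size
    neighbours: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for i, j, r in hits:
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"hit ({i},{j}) does not match {n} weights")
        if r <= t:
            neighbours[i].append((j, r))
            neighbours[j].append((i, r))

    # Sort once by (-weight, index); ties deterministically to lower index.
    order = sorted(range(n), key=lambda i: (-weights[i], i))
    assigned = np.zeros(n, dtype=bool)
    clusters: list[Cluster] = []
    for rep in order:
        if assigned[rep]:
            continue
        assigned[rep] = True
        members = [(rep, 0.0)]
        for j, r in neighbours[rep]:
            if not assigned[j]:
                assigned[j] = True
                members.append((j, r))
        clusters.append(Cluster(representative=rep, members=members))
    return clusters


def cluster_iterative(
    ens: Ensemble,
    schedule: Schedule,
    slack: float = DEFAULT_SLACK,
) -> list[LevelResult]:
    """Multi-level clustering with increasing thresholds.

    At each level the pair search runs on the current representatives
    only; weights use the priors accumulated so far, and each surviving
    representative carries the summed prior weight of its cluster to the
    next level.  Stops early when a single cluster remains (default) or
    runs every scheduled level.
    """
    current_ids = list(range(len(ens)))  # ids into the original ensemble
    priors = np.ones(len(ens))
    results: list[LevelResult] = []

    for threshold in schedule.thresholds:
        sub = ens.subset(current_ids)
        hits, stats = search_pairs(sub, threshold, slack)
        weights = neighbor_weights(hits, len(sub), threshold, priors)
        clusters = cluster_once(hits, weights, threshold)

        # Map local indices back to original ensemble ids.
        mapped = [
            Cluster(
                representative=current_ids[c.representative],
                members=[(current_ids[m], r) for m, r in c.members],
            )
            for c in clusters
        ]
        new_ids = [c.representative for c in mapped]
        # Carried prior: the cluster's accumulated weight (sum of member
        # priors), so total weight is conserved across levels.
        local_of = {mid: k for k, mid in enumerate(current_ids)}
        new_priors = np.array(
            [sum(priors[local_of[m]] for m, _ in c.members) for c in mapped]
        )
        results.append(
            LevelResult(
                threshold=threshold,
                n_input=len(sub),
                clusters=mapped,
                stats=stats,
                representatives=new_ids,
                weights={current_ids[i]: float(weights[i]) for i in range(len(sub))},
                carried_priors={
                    rid: float(p) for rid, p in zip(new_ids, new_priors)
                },
            )
        )
        current_ids = new_ids
        priors = new_priors
        if schedule.stop == "single_cluster" and len(current_ids) == 1:
            break
    return results


def _common_residue_distance(
    a: CoordinateSet, b: CoordinateSet, cap: float
) -> float:
    """RMSD100 over the residues common to both models.

    Residues are matched by (chain, residue id); within a residue only
    atom names present in both models are used.  Fewer than 14 common
    residues yields ``cap`` (maximally dissimilar).
    """
    index_b = {atom: k for k, atom in enumerate(b.atoms)}
    ia, ib = [], []
    residues = set()
    for k, atom in enumerate(a.atoms):
        kb = index_b.get(tuple(atom))
        if kb is not None:
            ia.append(k)
            ib.append(kb)
            residues.add((atom[0], atom[1]))
    n_res = len(residues)
    if n_res < 14 or not ia:
        return cap
    P = a.coords[ia]
    Q = b.coords[ib]
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    return rmsd100(kabsch_rmsd(P, Q), n_res, cap)


def filter_redundant(
    models: Sequence[CoordinateSet],
    t_norm: float = 1.0,
    cap: float = RMSD100_DEFAULT_CAP,
    slack: float = DEFAULT_SLACK,
) -> tuple[list[int], list[tuple[int, int, float]], SearchStats]:
    """Drop models nearly identical (RMSD100 < t_norm) to an earlier kept one.

    Models are scanned in input order; a model is removed when its
    normalized distance to some earlier *kept* model is strictly below
    ``t_norm``.  Returns (kept ids, removals as (removed, kept_as, rmsd100),
    search stats).  The pruned search supplies candidate pairs; each
    removal distance was computed directly, never inferred from the bound.
    """
    if t_norm <= 0:
        raise ValueError("t_norm must be positive")
    models = list(models)
    for m in models:
        if m.n_atoms == 0:
            raise ValueError(f"model {m.name!r} has no selected atoms")

    def dist(i: int, others: np.ndarray) -> np.ndarray:
        return np.array(
            [_common_residue_distance(models[i], models[int(j)], cap) for j in others]
        )

    hits, stats = pruned_pair_search(len(models), dist, t_norm, slack)
    below: dict[int, list[tuple[int, float]]] = {}
    for i, j, r in hits:
        if r < t_norm:  # strict: a pair exactly at t_norm keeps both
            below.setdefault(j, []).append((i, r))
            below.setdefault(i, []).append((j, r))

    kept: list[int] = []
    kept_set: set[int] = set()
    removed: list[tuple[int, int, float]] = []
    for i in range(len(models)):
        match = None
        for j, r in sorted(below.get(i, [])):
            if j < i and j in kept_set:
                match = (j, r)
                break
        if match is None:
            kept.append(i)
            kept_set.add(i)
        else:
            removed.append((i, match[0], match[1]))
    return kept, removed, stats
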