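import math

import numpy as np
import pytest

from rmsdprune import (
    CoordinateSet,
    PairHit,
    Schedule,
    SyntheticSpec,
    cluster_iterative,
    cluster_once,
    filter_redundant,
    make_ensemble,
    neighbor_weights,
    optimal_rmsd,
    rmsd100,
    search_pairs,
)


class TestNeighborWeights:
    def test_isolated_item_keeps_prior(self):
        w = neighbor_weights([], n=3, t=1.0)
        np.testing.assert_allclose(w, [1.0, 1.0, 1.0])

    def test_coincident_neighbor_doubles_weight(self):
        w = neighbor_weights([PairHit(0, 1, 0.0)], n=2, t=1.0)
        np.testing.assert_allclose(w, [2.0, 2.0])

    def test_half_threshold_neighbor(self):
        w = neighbor_weights([PairHit(0, 1, 0.5)], n=2, t=1.0)
        assert w[0] == pytest.approx(1 + math.cos(math.pi / 4))

    def test_neighbor_at_threshold_contributes_nothing(self):
        w = neighbor_weights([PairHit(0, 1, 1.0)], n=2, t=1.0)
        np.testing.assert_allclose(w, [1.0, 1.0], atol=1e-12)

    def test_priors_scale_contributions(self):
        w = neighbor_weights([PairHit(0, 1, 0.0)], n=2, t=1.0, priors=[2.0, 3.0])
        np.testing.assert_allclose(w, [2 + 3, 3 + 2])

    def test_errors(self):
        with pytest.raises(ValueError):
            neighbor_weights([], n=2, t=0.0)
        with pytest.raises(ValueError, match="above threshold"):
            neighbor_weights([PairHit(0, 1, 2.0)], n=2, t=1.0)
        with pytest.raises(ValueError):
            neighbor_weights([PairHit(0, 5, 0.1)], n=2, t=1.0)

    def test_level_one_total_weight_at_least_n(self, clustered_ensemble):
        ens, _ = clustered_ensemble
        hits, _ = search_pairs(ens, 1.0)
        w = neighbor_weights(hits, len(ens), 1.0)
        assert w.sum() >= len(ens)


class TestClusterOnce:
    def test_everything_within_threshold_single_cluster(self):
        hits = [PairHit(i, j, 0.1) for i in range(4) for j in range(i + 1, 4)]
        w = neighbor_weights(hits, 4, 1.0)
        clusters = cluster_once(hits, w, 1.0)
        assert len(clusters) == 1
        assert clusters[0].representative == 0  # equal weights: lowest index
        assert sorted(clusters[0].member_ids()) == [0, 1, 2, 3]

    def test_no_hits_all_singletons(self):
        clusters = cluster_once([], np.ones(5), 1.0)
        assert len(clusters) == 5
        assert all(c.size == 1 for c in clusters)

    def test_highest_weight_becomes_representative(self):
        hits = [PairHit(0, 1, 0.2), PairHit(1, 2, 0.2)]
        w = neighbor_weights(hits, 3, 1.0)
        clusters = cluster_once(hits, w, 1.0)
        # Item 1 touches both neighbours, so it leads the first cluster.
        assert clusters[0].representative == 1
        assert sorted(clusters[0].member_ids()) == [0, 1, 2]

    def test_recovers_ground_truth_centers(self, clustered_ensemble):
        ens, labels = clustered_ensemble
        t = 2.0  # between intra-center spread and inter-center separation
        hits, _ = search_pairs(ens, t)
        w = neighbor_weights(hits, len(ens), t)
        clusters = cluster_once(hits, w, t)
        assert len(clusters) == len(set(labels))
        for c in clusters:
            assert len({labels[m] for m in c.member_ids()}) == 1

    def test_partition_and_radius_invariants(self, decoy_ensemble):
        t = 2.5
        hits, _ = search_pairs(decoy_ensemble, t)
        w = neighbor_weights(hits, len(decoy_ensemble), t)
        clusters = cluster_once(hits, w, t)
        seen = [m for c in clusters for m in c.member_ids()]
        assert sorted(seen) == list(range(len(decoy_ensemble)))
        for c in clusters:
            for m, r in c.members:
                assert r <= t
        reps_w = [w[c.representative] for c in clusters]
        assert all(a >= b - 1e-12 for a, b in zip(reps_w, reps_w[1:]))

    def test_mismatched_weights_rejected(self):
        with pytest.raises(ValueError):
            cluster_once([PairHit(0, 7, 0.1)], np.ones(3), 1.0)


class TestClusterIterative:
    def test_single_level_equals_cluster_once(self, clustered_ensemble):
        ens, _ = clustered_ensemble
        t = 2.0
        results = cluster_iterative(ens, Schedule((t,)))
        hits, _ = search_pairs(ens, t)
        w = neighbor_weights(hits, len(ens), t)
        direct = cluster_once(hits, w, t)
        assert [c.representative for c in results[0].clusters] == [
            c.representative for c in direct
        ]

    def test_centers_merge_only_at_coarse_level(self, clustered_ensemble):
        ens, labels = clustered_ensemble
        # Level 1 below the separation resolves the k centers; the coarse
        # level above it collapses everything into one cluster.
        results = cluster_iterative(ens, Schedule((2.0, 20.0)))
        assert results[0].n_representatives == len(set(labels))
        assert results[1].n_representatives == 1

    def test_priors_conserved_across_levels(self, clustered_ensemble):
        ens, _ = clustered_ensemble
        results = cluster_iterative(
            ens, Schedule.doubling(0.5, 8, stop="fixed_levels")
        )
        for level in results:
            # Every level's carried prior mass equals the original count.
            assert sum(level.carried_priors.values()) == pytest.approx(len(ens))
        # Representative count never increases level to level.
        reps = [r.n_representatives for r in results]
        assert all(a >= b for a, b in zip(reps, reps[1:]))

    def test_doubling_schedule_stops_at_single_cluster(self, clustered_ensemble):
        ens, _ = clustered_ensemble
        results = cluster_iterative(ens, Schedule.doubling(0.5, 12))
        assert results[-1].n_representatives == 1
        assert len(results) < 12

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            Schedule(())
        with pytest.raises(ValueError):
            Schedule((1.0, 0.5))
        with pytest.raises(ValueError):
            Schedule((0.5,), stop="whenever")


def _model(name, coords, start_res=1):
    coords = np.asarray(coords, dtype=float)
    atoms = [("A", start_res + i, "CA") for i in range(coords.shape[0])]
    return CoordinateSet(name, atoms, coords)


def _chain(n, seed=0, scale=1.0):
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(n - 1, 3))
    steps = 3.8 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
    return np.vstack([[0, 0, 0], np.cumsum(steps, axis=0)]) * scale


class TestFilterRedundant:
    def test_exact_duplicate_removed(self):
        coords = _chain(30)
        models = [_model("m0", coords), _model("m1", coords)]
        kept, removed, _ = filter_redundant(models, t_norm=1.0)
        assert kept == [0]
        assert removed[0][:2] == (1, 0)

    def test_transitive_removal_to_first_kept(self):
        coords = _chain(30)
        rng = np.random.default_rng(1)
        models = [
            _model(f"m{i}", coords + rng.normal(scale=0.01, size=coords.shape))
            for i in range(3)
        ]
        kept, removed, _ = filter_redundant(models, t_norm=1.0)
        assert kept == [0]
        assert [r[1] for r in removed] == [0, 0]

    def test_strictly_below_threshold_required(self):
        # t_norm set to the pair's own normalized distance: strict '<'
        # keeps both models.
        coords = _chain(100, seed=3)
        rng = np.random.default_rng(4)
        other = coords + rng.normal(scale=0.8, size=coords.shape)
        a, b = _model("a", coords), _model("b", other)
        d = rmsd100(optimal_rmsd(a, b), 100)
        kept, removed, _ = filter_redundant([a, b], t_norm=d)
        assert kept == [0, 1]
        assert removed == []
        kept2, removed2, _ = filter_redundant([a, b], t_norm=d + 1e-6)
        assert kept2 == [0]

    def test_partial_overlap_uses_common_residues(self):
        # Models share residues 11..40; identical there, so one is removed
        # even though total lengths differ.
        coords = _chain(50, seed=5)
        full = _model("full", coords, start_res=1)
        tail = _model("tail", coords[10:], start_res=11)
        kept, removed, _ = filter_redundant([full, tail], t_norm=1.0)
        assert kept == [0]
        assert removed[0][:2] == (1, 0)

    def test_short_overlap_never_removes(self):
        # Only 10 common residues: distance is the cap, far above t_norm.
        coords = _chain(10, seed=6)
        a = _model("a", coords, start_res=1)
        b = _model("b", coords, start_res=1)
        kept, removed, _ = filter_redundant([a, b], t_norm=1.0)
        assert kept == [0, 1]

    def test_disjoint_residue_ranges_both_kept(self):
        a = _model("a", _chain(20, seed=7), start_res=1)
        b = _model("b", _chain(20, seed=8), start_res=100)
        kept, _, _ = filter_redundant([a, b], t_norm=1.0)
        assert kept == [0, 1]

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            filter_redundant([_model("a", _chain(20))], t_norm=0.0)
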