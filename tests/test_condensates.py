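"""Cluster identification, unwrapping, exchange counting and shape metrics."""

import numpy as np
import pytest

from condensaxs import condensates, synth
from condensaxs.cgsim import Trajectory
from condensaxs.condensates import (ClusterTimeline, chain_shape,
                                    cluster_growth_series, find_clusters,
                                    hull_jaccard, migration_events,
                                    unwrap_clusters)


def _frame(chain_positions, beads_per_chain=1):
    """Positions array + chain ids from a list of per-chain bead arrays."""
    pos = np.vstack(chain_positions)
    ids = np.repeat(np.arange(len(chain_positions)),
                    [len(c) for c in chain_positions])
    return pos, ids


class TestFindClusters:
    def test_isolated_chains(self):
        pos, ids = _frame([[[0, 0, 0]], [[20, 0, 0]], [[40, 0, 0]]])
        labels = find_clusters(pos, ids, box=100.0, cutoff=7.5)
        assert len(set(labels)) == 3

    def test_threshold_behaviour(self):
        for d, n_expected in [(7.0, 1), (8.0, 2)]:
            pos, ids = _frame([[[0, 0, 0]], [[d, 0, 0]]])
            labels = find_clusters(pos, ids, box=100.0, cutoff=7.5)
            assert len(set(labels)) == n_expected

    def test_minimum_image_linking(self):
        # chains near opposite faces are neighbours through the boundary
        pos, ids = _frame([[[1.0, 50, 50]], [[97.0, 50, 50]]])
        labels = find_clusters(pos, ids, box=100.0, cutoff=7.5)
        assert labels[0] == labels[1]

    def test_matches_union_find_oracle(self, rng):
        n_chains, beads = 30, 3
        pos = rng.uniform(0, 60, size=(n_chains * beads, 3))
        ids = np.repeat(np.arange(n_chains), beads)
        box, cutoff = 60.0, 7.5
        labels = find_clusters(pos, ids, box, cutoff)

        parent = list(range(n_chains))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(n_chains * beads):
            for j in range(i + 1, n_chains * beads):
                if ids[i] == ids[j]:
                    continue
                d = pos[i] - pos[j]
                d -= box * np.round(d / box)
                if np.linalg.norm(d) <= cutoff:
                    parent[find(ids[i])] = find(ids[j])
        brute = [find(c) for c in range(n_chains)]
        for a in range(n_chains):
            for b in range(n_chains):
                assert (labels[a] == labels[b]) == (brute[a] == brute[b])

    def test_rna_only_mode_ignores_peptide(self):
        # RNA chains bridged only by a peptide chain: separate in RNA-only mode
        rna1 = np.array([[0.0, 0, 0]])
        pep = np.array([[6.0, 0, 0]])
        rna2 = np.array([[12.0, 0, 0]])
        pos = np.vstack([rna1, pep, rna2])
        ids = np.array([0, 1, 2])
        include = np.array([True, False, True])
        labels = find_clusters(pos, ids, box=100.0, cutoff=7.5, include=include)
        assert labels[1] == -1
        assert labels[0] != labels[2]
        labels_all = find_clusters(pos, ids, box=100.0, cutoff=7.5)
        assert labels_all[0] == labels_all[2]


class TestUnwrap:
    def _traj(self, frames, ids, box):
        return Trajectory(frames=np.asarray(frames, dtype=float),
                          chain_ids=np.asarray(ids), box_edge=box,
                          times=np.arange(len(frames), dtype=float))

    def test_chain_straddling_one_face(self):
        box = 50.0
        chain = np.array([[46, 10, 10], [49, 10, 10], [2, 10, 10], [5, 10, 10]])
        traj = self._traj([chain], np.zeros(4, dtype=int), box)
        tl = ClusterTimeline(labels=np.array([[0]]))
        out = unwrap_clusters(traj, tl, 0)[0]
        bonds = np.linalg.norm(np.diff(out, axis=0), axis=1)
        assert bonds.max() < 6.0

    def test_interior_cluster_unchanged(self):
        box = 50.0
        chain = np.array([[20.0, 20, 20], [24, 20, 20], [28, 20, 20]])
        traj = self._traj([chain], np.zeros(3, dtype=int), box)
        tl = ClusterTimeline(labels=np.array([[0]]))
        out = unwrap_clusters(traj, tl, 0)[0]
        assert np.allclose(out, chain)

    def test_wrapped_fixture_recovers_reference(self):
        """Wrap a known contiguous 2-chain cluster, unwrap, compare exactly."""
        box = 40.0
        ref_a = np.array([[35.0, 20, 20], [39.0, 20, 20], [43.0, 20, 20]])
        ref_b = ref_a + np.array([5.0, 3.0, 0.0])
        wrapped = np.vstack([ref_a, ref_b]) % box
        traj = self._traj([wrapped], np.array([0, 0, 0, 1, 1, 1]), box)
        tl = ClusterTimeline(labels=np.array([[0, 0]]))
        out = unwrap_clusters(traj, tl, 0)[0]
        ref = np.vstack([ref_a, ref_b])
        # unwrapped coordinates agree up to one global box translation
        shift = out[0] - ref[0]
        assert np.allclose(shift, box * np.round(shift / box))
        assert np.allclose(out - out[0], ref - ref[0], atol=1e-9)


class TestMigrationEvents:
    def test_static_partition(self):
        labels = np.tile([0, 0, 1, 1, 2], (6, 1))
        ev = migration_events(ClusterTimeline(labels=labels))
        assert ev.total_arrivals == 0 and ev.total_departures == 0

    def test_single_move(self):
        labels = np.array([[0, 0, 0, 1, 1], [1, 0, 0, 1, 1]])
        ev = migration_events(ClusterTimeline(labels=labels))
        assert (ev.total_arrivals, ev.total_departures) == (1, 1)

    def test_departure_to_solo(self):
        # chain 0 leaves a 3-chain cluster and becomes its own cluster
        labels = np.array([[0, 0, 0], [1, 0, 0]])
        ev = migration_events(ClusterTimeline(labels=labels))
        assert (ev.total_arrivals, ev.total_departures) == (0, 1)

    def test_scripted_totals(self):
        script = synth.TrajectoryScript.random(
            n_chains=16, n_frames=70, n_events=50, n_clusters=3,
            box_edge=800.0, seed=21)
        traj = synth.gen_scripted_trajectory(script)
        tl = condensates.build_timeline(traj)
        ev = migration_events(tl)
        assert (ev.total_arrivals, ev.total_departures) == script.count_events()

    def test_needs_two_frames(self):
        with pytest.raises(ValueError):
            migration_events(ClusterTimeline(labels=np.array([[0, 0]])))


class TestChainShape:
    def test_rod_limit(self):
        coords = np.column_stack([np.arange(10) * 3.0, np.zeros(10), np.zeros(10)])
        s = chain_shape(coords)
        assert s.kappa2 == pytest.approx(1.0)
        assert s.REE == pytest.approx(27.0)

    def test_octahedron_isotropic(self):
        coords = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                           [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float)
        assert chain_shape(coords).kappa2 == pytest.approx(0.0, abs=1e-12)

    def test_dimer(self):
        s = chain_shape(np.array([[0.0, 0, 0], [6.0, 0, 0]]))
        assert s.REE == pytest.approx(6.0)
        assert s.Rg == pytest.approx(3.0)

    def test_kappa2_bounds_random(self, rng):
        for _ in range(2000):
            coords = rng.normal(size=(5, 3))
            k2 = chain_shape(coords).kappa2
            assert 0.0 <= k2 <= 1.0


class TestHullJaccard:
    def _cube(self, edge, center=0.0):
        g = np.array(np.meshgrid([0, 1], [0, 1], [0, 1])).T.reshape(-1, 3)
        return g * edge - edge / 2 + center

    def test_identical_sets(self):
        pts = self._cube(10.0)
        assert hull_jaccard(pts, pts, n_samples=20_000, seed=0) == pytest.approx(1.0)

    def test_disjoint_sets(self):
        assert hull_jaccard(self._cube(5.0), self._cube(5.0, center=50.0),
                            n_samples=20_000, seed=0) == 0.0

    def test_nested_cubes(self):
        """Concentric cubes with 2x volume ratio overlap at exactly 1/2."""
        inner = self._cube(10.0)
        outer = self._cube(10.0 * 2 ** (1 / 3))
        j = hull_jaccard(inner, outer, n_samples=100_000, seed=1)
        assert j == pytest.approx(0.5, abs=0.02)

    def test_estimator_error_scales_with_samples(self):
        inner = self._cube(10.0)
        outer = self._cube(10.0 * 2 ** (1 / 3))
        reps = {n: np.std([hull_jaccard(inner, outer, n_samples=n, seed=s)
                           for s in range(8)]) for n in (1000, 16000)}
        ratio = reps[1000] / max(reps[16000], 1e-12)
        assert 2.0 <= ratio <= 8.0  # expect ~4 = sqrt(16)

    def test_degenerate_hull_rejected(self):
        flat = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
        with pytest.raises(ValueError):
            hull_jaccard(flat, flat)


class TestGrowthSeries:
    def test_merge_only_script_sizes_nondecreasing(self):
        script = synth.TrajectoryScript(
            n_chains=9, n_frames=20, box_edge=600.0,
            initial={0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1,
                     6: "solution", 7: "solution", 8: "solution"},
            events=[synth.ScriptEvent(5, 6, "solution", 0),
                    synth.ScriptEvent(10, 7, "solution", 1),
                    synth.ScriptEvent(15, 8, "solution", 0)])
        tl = condensates.build_timeline(synth.gen_scripted_trajectory(script))
        tracks, n_per_frame = cluster_growth_series(tl)
        grown = [t for t, series in tracks.items() if len(series) > 3]
        for t in grown:
            sizes = [tracks[t][f] for f in sorted(tracks[t])]
            assert all(b >= a for a, b in zip(sizes, sizes[1:]))

    def test_split_increases_cluster_count(self):
        labels = np.array([[0, 0, 0, 0], [0, 0, 1, 1]])
        tl = ClusterTimeline(labels=labels)
        _, n_per_frame = cluster_growth_series(tl)
        assert n_per_frame[1] == n_per_frame[0] + 1

    def test_partition_conservation(self):
        script = synth.TrajectoryScript.random(
            n_chains=14, n_frames=40, n_events=25, n_clusters=3,
            box_edge=800.0, seed=5)
        tl = condensates.build_timeline(synth.gen_scripted_trajectory(script))
        for f in range(tl.n_frames):
            assert sum(tl.cluster_sizes(f).values()) == 14
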