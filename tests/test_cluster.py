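"""RMSD computation and trajectory clustering."""
import numpy as np
import pytest

from alloscreen import cluster as C
from alloscreen import synthetic
from alloscreen.superpose import kabsch, rmsd

from conftest import random_rotation


def _traj_from_coords(coords):
    coords = np.asarray(coords, dtype=float)
    n_atoms = coords.shape[1]
    return C.Trajectory(
        coords=coords,
        names=np.array(["CA"] * n_atoms, dtype=object),
        resids=np.arange(1, n_atoms + 1),
        resnames=np.array(["GLY"] * n_atoms, dtype=object),
        elements=np.array(["C"] * n_atoms, dtype=object),
    )


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def _oracle_gromos(values, cutoff):
    """Naive re-statement of the peeling algorithm, written independently."""
    n = values.shape[0]
    pool = set(range(n))
    clusters = []
    while pool:
        best_center, best_nb = None, None
        for i in sorted(pool):
            nb = {j for j in pool if j != i and values[i, j] < cutoff}
            if best_nb is None or len(nb) > len(best_nb):
                best_center, best_nb = i, nb
        members = {best_center} | best_nb
        clusters.append(sorted(members))
        pool -= members
    return sorted(clusters, key=lambda c: c[0])


def _oracle_single_linkage(values, cutoff):
    import networkx as nx
    n = values.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if values[i, j] < cutoff:
                g.add_edge(i, j)
    comps = [sorted(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: c[0])


def _random_matrix(rng, n):
    v = rng.uniform(0.1, 4.0, size=(n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return C.RmsdMatrix(v)


# --------------------------------------------------------------------------
# pairwise RMSD
# --------------------------------------------------------------------------

class TestPairwiseRmsd:
    def test_identical_frames_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(5, 3))
        m = C.pairwise_rmsd(_traj_from_coords([x, x.copy()]))
        assert m.values[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(8, 3))
        R = random_rotation(rng)
        y = x @ R.T + np.array([3.0, -1.0, 2.0])
        m = C.pairwise_rmsd(_traj_from_coords([x, y]), superpose=True)
        assert m.values[0, 1] == pytest.approx(0.0, abs=1e-6)

    def test_single_atom_move_without_superposition(self):
        x = np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0], [0, 0, 2]], float)
        y = x.copy()
        y[0, 0] += 1.0
        m = C.pairwise_rmsd(_traj_from_coords([x, y]), superpose=False)
        assert m.values[0, 1] == pytest.approx(0.5)  # sqrt(1/4)

    def test_selection_and_errors(self):
        x = np.zeros((3, 3))
        traj = _traj_from_coords([x, x + 1.0])
        with pytest.raises(ValueError, match="matches no atoms"):
            C.pairwise_rmsd(traj, selection="name XX")
        with pytest.raises(ValueError, match="two frames"):
            C.pairwise_rmsd(_traj_from_coords([x]))


# --------------------------------------------------------------------------
# clustering
# --------------------------------------------------------------------------

class TestClusterFrames:
    @pytest.mark.parametrize("method", C.METHODS)
    def test_two_near_one_far(self, method):
        vals = np.array([[0, 0.1, 5], [0.1, 0, 5], [5, 5, 0]], float)
        c = C.cluster_frames(C.RmsdMatrix(vals), 0.5, method)
        assert sorted(map(sorted, c.clusters)) == [[0, 1], [2]]

    @pytest.mark.parametrize("method", C.METHODS)
    def test_large_cutoff_single_cluster(self, method):
        rng = np.random.default_rng(2)
        m = _random_matrix(rng, 6)
        c = C.cluster_frames(m, m.max() + 1.0, method)
        assert c.n_clusters == 1

    def test_chain_distinguishes_methods(self):
        # A-B and B-C within cutoff, A-C outside: single linkage chains all
        # three; gromos peels B (two neighbours) with both
        vals = np.array([[0, 0.4, 0.9], [0.4, 0, 0.4], [0.9, 0.4, 0]], float)
        m = C.RmsdMatrix(vals)
        assert C.cluster_frames(m, 0.5, "single_linkage").n_clusters == 1
        g = C.cluster_frames(m, 0.5, "gromos")
        assert g.n_clusters == 1 and sorted(g.clusters[0]) == [0, 1, 2]

    @pytest.mark.parametrize("method", C.METHODS)
    def test_partition_property(self, method):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m = _random_matrix(rng, int(rng.integers(2, 10)))
            c = C.cluster_frames(m, float(rng.uniform(0.2, 4.0)), method)
            members = sorted(i for cl in c.clusters for i in cl)
            assert members == list(range(m.n))

    def test_gromos_members_within_cutoff_of_center(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            m = _random_matrix(rng, 8)
            cutoff = float(rng.uniform(0.5, 3.0))
            c = C.cluster_frames(m, cutoff, "gromos")
            for cl in c.clusters:
                # the founding center has all members within the cutoff
                assert any(all(m.values[i, j] < cutoff for j in cl if j != i)
                           for i in cl)

    @pytest.mark.parametrize("method", C.METHODS)
    def test_oracle_equivalence(self, method):
        rng = np.random.default_rng(5)
        oracle = _oracle_gromos if method == "gromos" else _oracle_single_linkage
        for _ in range(500):
            n = int(rng.integers(2, 9))
            m = _random_matrix(rng, n)
            cutoff = float(rng.uniform(0.2, 4.2))
            got = sorted(map(sorted, C.cluster_frames(m, cutoff, method).clusters))
            assert got == oracle(m.values, cutoff)

    def test_single_linkage_count_nonincreasing_in_cutoff(self):
        rng = np.random.default_rng(6)
        m = _random_matrix(rng, 10)
        counts = [C.cluster_frames(m, c, "single_linkage").n_clusters
                  for c in np.linspace(0.05, m.max() + 0.1, 40)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestRepresentative:
    def test_smallest_average_distance(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = 1.0
        vals[0, 2] = vals[2, 0] = 1.0
        vals[1, 2] = vals[2, 1] = 2.0
        m = C.RmsdMatrix(vals)
        c = C.cluster_frames(m, 3.0, "gromos")
        assert c.representatives == [0]  # mean 1.0 beats 1.5

    def test_singleton_and_tie(self):
        vals = np.array([[0, 1, 1, 9], [1, 0, 1, 9], [1, 1, 0, 9], [9, 9, 9, 0]],
                        float)
        m = C.RmsdMatrix(vals)
        c = C.cluster_frames(m, 2.0, "gromos")
        reps = dict(zip(map(tuple, map(sorted, c.clusters)), c.representatives))
        assert reps[(0, 1, 2)] == 0  # symmetric triangle: lowest index
        assert reps[(3,)] == 3


class TestFindCutoff:
    @pytest.mark.parametrize("method", C.METHODS)
    def test_two_state_trajectory(self, method):
        traj, gt = synthetic.gen_two_state_trajectory(
            n_frames=60, inter_state_rmsd=3.0, jitter_sd=0.1, seed=0)
        m = C.pairwise_rmsd(traj)
        c = C.find_cutoff_for_k(m, 2, method)
        assert c.exact and c.n_clusters == 2
        labs = c.labels()
        agreement = max(np.mean(labs == gt.cluster_labels),
                        np.mean(labs == 1 - gt.cluster_labels))
        assert agreement == 1.0

    def test_extreme_k(self):
        rng = np.random.default_rng(7)
        m = _random_matrix(rng, 6)
        assert C.find_cutoff_for_k(m, 6, "gromos").n_clusters == 6
        assert C.find_cutoff_for_k(m, 1, "gromos").n_clusters == 1

    def test_unachievable_k_flagged_inexact(self):
        # two coincident frames and one far: 3 singletons unreachable below
        # the zero distance
        vals = np.array([[0, 0, 5], [0, 0, 5], [5, 5, 0]], float)
        c = C.find_cutoff_for_k(C.RmsdMatrix(vals), 3, "single_linkage")
        assert not c.exact
        assert c.n_clusters == 2
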