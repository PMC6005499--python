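"""RMSD-based clustering of conformational ensembles.

Implements the two flavours used when post-processing MD trajectories:

* ``gromos`` — iteratively pick the conformation with the largest number of
  neighbours within the RMSD cut-off, peel it off together with its
  neighbours as one cluster, and repeat on the remainder (the g_cluster
  algorithm).
* ``single_linkage`` — connected components of the graph whose edges join
  conformations closer than the cut-off.

A per-cluster representative is the member with the smallest average RMSD
to the other members.  ``find_cutoff_for_k`` searches the cut-off by
bisection for a requested cluster count (the "try different cut-offs until
ten clusters" step of trajectory post-processing).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .superpose import rmsd as _rmsd

METHODS = ("gromos", "single_linkage")


@dataclass
class Trajectory:
    """An ordered stack of superposable coordinate frames with atom metadata."""

    coords: np.ndarray            # (n_frames, n_atoms, 3) Å
    names: np.ndarray             # (n_atoms,) PDB atom names
    resids: np.ndarray            # (n_atoms,) 1-based residue numbers
    resnames: np.ndarray          # (n_atoms,)
    elements: Optional[np.ndarray] = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @classmethod
    def from_pdb(cls, path) -> "Trajectory":
        """Read a multi-model PDB via MDAnalysis (one frame per MODEL)."""
        import MDAnalysis as mda
        u = mda.Universe(str(path))
        frames = [u.atoms.positions.copy() for _ in u.trajectory]
        elements = None
        if hasattr(u.atoms, "elements"):
            elements = np.array(u.atoms.elements)
        return cls(
            coords=np.array(frames, dtype=float),
            names=np.array(u.atoms.names),
            resids=np.array(u.atoms.resids, dtype=int),
            resnames=np.array(u.atoms.resnames),
            elements=elements,
        )

    def select(self, expression: Optional[str]) -> np.ndarray:
        """Resolve an MDAnalysis selection expression to atom indices."""
        if expression is None or expression == "all":
            return np.arange(self.n_atoms)
        import MDAnalysis as mda
        u = mda.Universe.empty(self.n_atoms, n_residues=len(np.unique(self.resids)),
                               atom_resindex=np.unique(self.resids, return_inverse=True)[1],
                               trajectory=True)
        u.add_TopologyAttr("names", self.names)
        u.add_TopologyAttr("resids", np.unique(self.resids))
        resnames = [self.resnames[self.resids == r][0] for r in np.unique(self.resids)]
        u.add_TopologyAttr("resnames", resnames)
        if self.elements is not None:
            u.add_TopologyAttr("elements", self.elements)
        u.atoms.positions = self.coords[0]
        idx = u.select_atoms(expression).indices
        if len(idx) == 0:
            raise ValueError(f"selection {expression!r} matches no atoms")
        return np.asarray(idx, dtype=int)


@dataclass
class RmsdMatrix:
    values: np.ndarray          # (n, n) Å, symmetric, zero diagonal
    selection: str = "all"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RMSD matrix must be square")
        if (v < 0).any():
            raise ValueError("RMSD values must be >= 0")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("RMSD matrix must be symmetric")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def max(self) -> float:
        return float(self.values.max())


@dataclass
class Clustering:
    clusters: List[List[int]]
    representatives: List[int]
    cutoff: float
    method: str
    exact: bool = True          # find_cutoff_for_k: achieved the target count

    def __post_init__(self):
        members = sorted(i for c in self.clusters for i in c)
        n = len(members)
        if members != list(range(n)):
            raise ValueError("clusters must partition frame indices 0..n-1")
        for rep, c in zip(self.representatives, self.clusters):
            if rep not in c:
                raise ValueError("representative must belong to its cluster")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def labels(self) -> np.ndarray:
        n = sum(len(c) for c in self.clusters)
        lab = np.empty(n, dtype=int)
        for k, c in enumerate(self.clusters):
            lab[list(c)] = k
        return lab


def pairwise_rmsd(traj: Trajectory, selection: Optional[str] = None,
                  superpose: bool = True) -> RmsdMatrix:
    """All-against-all RMSD over the selected atoms.

    With ``superpose`` on, each pair is optimally least-squares superposed
    before the deviation is measured (rigid motions contribute nothing).
    """
    if traj.n_frames < 2:
        raise ValueError("need at least two frames")
    idx = traj.select(selection)
    X = traj.coords[:, idx, :]
    n = traj.n_frames
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = _rmsd(X[i], X[j], superpose=superpose)
    return RmsdMatrix(values=m, selection=selection or "all")


def _gromos_partition(values: np.ndarray, cutoff: float) -> List[List[int]]:
    n = values.shape[0]
    remaining = list(range(n))
    adj = values < cutoff
    np.fill_diagonal(adj, False)
    clusters = []
    while remaining:
        rem = np.array(remaining)
        counts = adj[np.ix_(rem, rem)].sum(axis=1)
        center = rem[int(np.argmax(counts))]  # argmax ties -> lowest index
        members = [center] + [j for j in remaining if j != center and adj[center, j]]
        clusters.append(sorted(members))
        remaining = [j for j in remaining if j not in set(members)]
    return clusters


def _single_linkage_partition(values: np.ndarray, cutoff: float) -> List[List[int]]:
    adj = (values < cutoff).astype(np.int8)
    np.fill_diagonal(adj, 0)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    clusters = [[] for _ in range(n_comp)]
    for i, l in enumerate(labels):
        clusters[l].append(i)
    # deterministic order: by lowest member index
    return sorted((sorted(c) for c in clusters), key=lambda c: c[0])


def cluster_frames(m: RmsdMatrix, cutoff: float,
                   method: str = "gromos") -> Clustering:
    """Partition frames at the given RMSD cut-off (strictly-less neighbour rule)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if method == "gromos":
        clusters = _gromos_partition(m.values, cutoff)
    else:
        clusters = _single_linkage_partition(m.values, cutoff)
    clusters = [[int(i) for i in cl] for cl in clusters]
    reps = [int(r) for r in _representatives(clusters, m)]
    return Clustering(clusters=clusters, representatives=reps,
                      cutoff=float(cutoff), method=method)


def _representatives(clusters: Sequence[Sequence[int]], m: RmsdMatrix) -> List[int]:
    reps = []
    for c in clusters:
        if len(c) == 1:
            reps.append(c[0])
            continue
        sub = m.values[np.ix_(c, c)]
        means = sub.sum(axis=1) / (len(c) - 1)
        reps.append(c[int(np.argmin(means))])  # argmin ties -> lowest index
    return reps


def representative(clustering: Clustering, m: RmsdMatrix) -> List[int]:
    """Per-cluster member with the smallest average RMSD to the others."""
    return _representatives(clustering.clusters, m)


def find_cutoff_for_k(m: RmsdMatrix, k: int, method: str = "gromos",
                      tol: float = 1e-4) -> Clustering:
    """Bisect the cut-off to reach exactly ``k`` clusters.

    Returns the clustering at the found cut-off; if no cut-off within the
    bisection tolerance yields exactly k clusters, the nearest achievable
    count is returned with ``exact=False``.
    """
    if not 1 <= k <= m.n:
        raise ValueError("k must be in [1, n]")
    lo, hi = 0.0, m.max() * (1 + 1e-9) + tol
    best = None
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        c = cluster_frames(m, mid, method)
        if c.n_clusters == k:
            return c
        if best is None or abs(c.n_clusters - k) < abs(best.n_clusters - k):
            best = c
        if c.n_clusters > k:
            lo = mid   # cutoff too small -> too many clusters
        else:
            hi = mid
    for edge in (lo if lo > 0 else tol, hi):
        c = cluster_frames(m, edge, method)
        if c.n_clusters == k:
            return c
        if best is None or abs(c.n_clusters - k) < abs(best.n_clusters - k):
            best = c
    best.exact = False
    return best
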