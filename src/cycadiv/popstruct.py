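"""Distance-based population structure: Nei distance, PCoA, connection
networks, Monmonier barrier search, pairwise Fst and bootstrap NJ trees.

Sampling localities are treated as planar after an equirectangular
projection about the mean latitude; at island scale the projection error
is far below the differences between edge lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from scipy.spatial import Delaunay, cKDTree

from cycadiv.genodata import GenotypeMatrix, allele_freq
from cycadiv import sumstats

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "nei_distance",
    "pcoa",
    "ConnectionNetwork",
    "build_network",
    "BarrierResult",
    "monmonier_barriers",
    "pairwise_fst_matrix",
    "nj_tree",
    "project_coordinates",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if np.nanmax(np.abs(v - v.T)) > 1e-12:
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


# ---------------------------------------------------------------------------
# Nei's (1972) standard genetic distance
# ---------------------------------------------------------------------------

def nei_distance(freqs: pd.DataFrame) -> DistanceMatrix:
    """Nei's standard distance D = -ln( J_xy / sqrt(J_x J_y) ).

    ``freqs``: group x locus table of alt-allele frequencies (NaN =
    undefined; loci undefined in either group of a pair are excluded
    pairwise).  J terms are means over loci of sum of squared (or
    cross-multiplied) allele frequencies over the two alleles.
    """
    groups = list(freqs.index)
    P = freqs.to_numpy(float)
    n = len(groups)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~np.isnan(P[i]) & ~np.isnan(P[j])
            if not ok.any():
                raise ValueError(f"no shared loci between {groups[i]} and {groups[j]}")
            pi, pj = P[i, ok], P[j, ok]
            jx = np.mean(pi**2 + (1 - pi) ** 2)
            jy = np.mean(pj**2 + (1 - pj) ** 2)
            jxy = np.mean(pi * pj + (1 - pi) * (1 - pj))
            if jxy <= 0:
                logger.warning("J_xy = 0 between %s and %s; D set to inf",
                               groups[i], groups[j])
                d = np.inf
            else:
                d = -np.log(jxy / np.sqrt(jx * jy))
            D[i, j] = D[j, i] = max(d, 0.0) if np.isfinite(d) else d
    return DistanceMatrix(labels=groups, values=D)


# ---------------------------------------------------------------------------
# PCoA (classical metric scaling)
# ---------------------------------------------------------------------------

def pcoa(d: DistanceMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal coordinates of a distance matrix.

    Double-centers ``-D^2/2``, eigendecomposes, and returns coordinates
    for the positive axes (ordered by eigenvalue) together with all
    eigenvalues (negative ones reported, no coordinates for them).
    """
    D2 = d.values**2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-10 * max(abs(evals[0]), 1.0), 0)
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=d.labels, columns=cols), evals


# ---------------------------------------------------------------------------
# Connection networks
# ---------------------------------------------------------------------------

@dataclass
class ConnectionNetwork:
    nodes: list[str]
    coords: np.ndarray               # planar (n, 2)
    edges: list[tuple[int, int]]     # undirected, i < j
    kind: str

    def edge_set(self) -> set[tuple[int, int]]:
        return set(self.edges)

    def adjacency(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {i: set() for i in range(len(self.nodes))}
        for i, j in self.edges:
            adj[i].add(j)
            adj[j].add(i)
        return adj


def project_coordinates(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Equirectangular projection (km) about the mean latitude."""
    lat = np.asarray(lat, float)
    lon = np.asarray(lon, float)
    lat0 = np.deg2rad(lat.mean())
    R = 6371.0
    x = R * np.deg2rad(lon) * np.cos(lat0)
    y = R * np.deg2rad(lat)
    return np.column_stack([x, y])


def build_network(coords: np.ndarray, kind: str, labels: list[str] | None = None,
                  k: int = 7) -> ConnectionNetwork:
    """Build a connection network among planar points.

    ``kind``: 'delaunay' (triangulation), 'knn' (union of directed
    K-nearest neighborhoods, default K=7, made undirected) or 'mst'
    (minimum spanning tree on Euclidean distances).
    """
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    labels = labels if labels is not None else [f"node{i}" for i in range(n)]
    if len(np.unique(coords, axis=0)) != n:
        raise ValueError("duplicate coordinates; jitter the points and retry")
    edges: set[tuple[int, int]] = set()
    if kind == "delaunay":
        if n < 3:
            raise ValueError("delaunay needs >= 3 points")
        tri = Delaunay(coords)
        for simplex in tri.simplices:
            for a in range(3):
                for b in range(a + 1, 3):
                    i, j = sorted((int(simplex[a]), int(simplex[b])))
                    edges.add((i, j))
    elif kind == "knn":
        kk = min(k, n - 1)
        tree = cKDTree(coords)
        _, idx = tree.query(coords, k=kk + 1)
        for i in range(n):
            for j in idx[i, 1:]:
                edges.add(tuple(sorted((i, int(j)))))
    elif kind == "mst":
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
        mst = minimum_spanning_tree(scipy.sparse.csr_matrix(dist))
        ii, jj = mst.nonzero()
        for i, j in zip(ii, jj):
            edges.add(tuple(sorted((int(i), int(j)))))
    else:
        raise ValueError(f"unknown network kind {kind!r}")
    return ConnectionNetwork(nodes=list(labels), coords=coords,
                             edges=sorted(edges), kind=kind)


# ---------------------------------------------------------------------------
# Monmonier maximum-difference barriers
# ---------------------------------------------------------------------------

@dataclass
class Barrier:
    edges: list[tuple[int, int]]     # crossed edges in crossing order
    values: list[float]              # local difference (distance) per edge

    @property
    def total(self) -> float:
        return float(sum(self.values))


@dataclass
class BarrierResult:
    barriers: list[Barrier]          # one per run, best first
    best_run: int


def _triangles(net: ConnectionNetwork) -> list[tuple[int, int, int]]:
    """All 3-cliques of the network (the faces Monmonier barriers walk
    through; for a Delaunay network these are the triangulation)."""
    adj = net.adjacency()
    tris = []
    for (i, j) in net.edges:
        for c in sorted(adj[i] & adj[j]):
            if c > j:
                tris.append((i, j, c))
    return tris


def monmonier_barriers(
    net: ConnectionNetwork,
    d: DistanceMatrix,
    n_runs: int = 20,
    threshold: float = 0.0,
) -> BarrierResult:
    """Monmonier's maximum-difference barrier search on a connection
    network.

    A barrier crosses network edges, moving through the triangles
    (3-cliques) of the network: each run starts at a high-distance edge
    (run r starts at the edge with the r-th largest associated distance;
    ties broken by lowest edge index) and extends in both directions;
    inside a triangle the barrier exits across whichever of the other
    two uncrossed edges has the larger distance, provided it exceeds
    ``threshold`` (ties again by lowest edge index).  A direction ends at
    the network boundary (no adjacent triangle), on re-entering a
    visited triangle (loop) or when no candidate clears the threshold.
    On triangle-free networks (paths, spanning trees) every edge is a
    bridge and a barrier is a single crossed edge.  The best run
    maximizes the cumulative crossed distance.
    """
    if d.labels != net.nodes:
        raise ValueError("distance labels must match network nodes")
    n_comp, _ = connected_components(_as_csr(net), directed=False)
    if n_comp != 1:
        raise ValueError("network must be connected")
    edge_d = {e: d.values[e[0], e[1]] for e in net.edges}
    eindex = {e: i for i, e in enumerate(net.edges)}
    tris = _triangles(net)
    tri_edges = []
    edge_tris: dict[tuple[int, int], list[int]] = {e: [] for e in net.edges}
    for ti, (i, j, c) in enumerate(tris):
        es = [(i, j), (i, c), (j, c)]
        tri_edges.append(es)
        for e in es:
            edge_tris[e].append(ti)

    # deterministic start edges: r-th largest distance, ties by edge index
    ranked = sorted(range(len(net.edges)),
                    key=lambda ei: (-edge_d[net.edges[ei]], ei))
    starts = [net.edges[ranked[r % len(ranked)]] for r in range(min(n_runs, len(ranked)))]

    barriers: list[Barrier] = []
    for start in starts:
        crossed = [start]
        values = [edge_d[start]]
        used = {start}
        visited_tris: set[int] = set()
        for side, tri0 in enumerate(edge_tris[start][:2]):
            tri = tri0
            while tri is not None and tri not in visited_tris:
                visited_tris.add(tri)
                cands = [e for e in tri_edges[tri]
                         if e not in used and edge_d[e] > threshold]
                if not cands:
                    break
                nxt = min(cands, key=lambda e: (-edge_d[e], eindex[e]))
                if side == 0:
                    crossed.append(nxt)
                    values.append(edge_d[nxt])
                else:
                    crossed.insert(0, nxt)
                    values.insert(0, edge_d[nxt])
                used.add(nxt)
                onward = [t for t in edge_tris[nxt] if t != tri]
                tri = onward[0] if onward else None
        barriers.append(Barrier(edges=crossed, values=values))

    order = sorted(range(len(barriers)), key=lambda i: (-barriers[i].total, i))
    return BarrierResult(barriers=[barriers[i] for i in order], best_run=order[0])


def _as_csr(net: ConnectionNetwork) -> scipy.sparse.csr_matrix:
    n = len(net.nodes)
    m = scipy.sparse.lil_matrix((n, n))
    for i, j in net.edges:
        m[i, j] = 1
        m[j, i] = 1
    return m.tocsr()


def barrier_separates(net: ConnectionNetwork, barrier: Barrier) -> list[set[int]]:
    """Connected components of the network after removing the barrier's
    crossed edges (used to score planted-partition recovery)."""
    n = len(net.nodes)
    keep = [e for e in net.edges if e not in set(barrier.edges)]
    m = scipy.sparse.lil_matrix((n, n))
    for i, j in keep:
        m[i, j] = 1
        m[j, i] = 1
    ncomp, lab = connected_components(m.tocsr(), directed=False)
    return [set(np.flatnonzero(lab == c)) for c in range(ncomp)]


# ---------------------------------------------------------------------------
# Pairwise Fst and NJ trees
# ---------------------------------------------------------------------------

def pairwise_fst_matrix(gm: GenotypeMatrix, grouping: str = "population") -> pd.DataFrame:
    """Multilocus W&C Fst for every pair of groups (negative estimates
    reported as computed; diagonal 0)."""
    labels = gm.labels(grouping)
    groups = sorted(set(labels))
    out = pd.DataFrame(0.0, index=groups, columns=groups)
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            mask = (labels == a) | (labels == b)
            sub = gm.take_individuals(np.flatnonzero(mask))
            val = sumstats.fst(sub, grouping, "multilocus")
            out.loc[a, b] = out.loc[b, a] = val
    return out


def _nj_newick(d: DistanceMatrix) -> str:
    from io import StringIO

    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj

    sk = SkDM(d.values, ids=d.labels)
    tree = nj(sk)
    buf = StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def _bipartitions(newick: str, labels: list[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, canonicalized as the
    smaller side (ties by sorted labels)."""
    from skbio import TreeNode
    from io import StringIO

    tree = TreeNode.read(StringIO(newick))
    all_tips = frozenset(labels)
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = all_tips - side
        if 1 < len(side) < len(all_tips) - 1:
            canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
            parts.add(frozenset(canon))
    return parts


def nj_tree(
    d: DistanceMatrix,
    gm: GenotypeMatrix | None = None,
    grouping: str = "population",
    bootstrap: int = 0,
    seed: int = 0,
) -> tuple[str, dict[frozenset, float]]:
    """Saitou-Nei neighbor joining with optional locus-resampling
    bootstrap.

    When ``bootstrap > 0`` a GenotypeMatrix must be supplied: loci are
    resampled with replacement, Nei distances recomputed, NJ rebuilt and
    bipartition frequencies of the full-data tree reported (0-100).
    Returns (newick, support-by-bipartition).
    """
    if len(d.labels) < 3:
        raise ValueError("need >= 3 groups for a tree")
    newick = _nj_newick(d)
    support: dict[frozenset, float] = {}
    if bootstrap > 0:
        if gm is None:
            raise ValueError("bootstrap requires the genotype matrix")
        if bootstrap < 1:
            raise ValueError("reps must be >= 1")
        ref_parts = _bipartitions(newick, d.labels)
        counts = {p: 0 for p in ref_parts}
        rng = np.random.default_rng(seed)
        full_freqs, _ = allele_freq(gm, grouping)
        full_freqs = full_freqs.loc[d.labels]
        locus_ids = gm.loci["locus_id"].to_numpy()
        uniq = np.unique(locus_ids)
        sites_of = {l: np.flatnonzero(locus_ids == l) for l in uniq}
        for _ in range(bootstrap):
            chosen = rng.choice(uniq, size=len(uniq), replace=True)
            site_idx = np.concatenate([sites_of[l] for l in chosen])
            f = full_freqs.iloc[:, site_idx]
            f.columns = range(f.shape[1])
            boot_parts = _bipartitions(_nj_newick(nei_distance(f)), d.labels)
            for p in ref_parts & boot_parts:
                counts[p] += 1
        support = {p: 100.0 * c / bootstrap for p, c in counts.items()}
    return newick, support
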