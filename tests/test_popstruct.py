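"""Nei distance, PCoA, connection networks, barriers, Fst matrix, NJ."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cycadiv import popstruct, synthdata
from cycadiv.popstruct import (
    ConnectionNetwork,
    DistanceMatrix,
    barrier_separates,
    build_network,
    monmonier_barriers,
    nei_distance,
    nj_tree,
    pairwise_fst_matrix,
    pcoa,
)
from conftest import make_gm


class TestNeiDistance:
    def test_identical_frequencies_zero(self):
        f = pd.DataFrame([[0.3, 0.7, 0.1], [0.3, 0.7, 0.1]], index=["A", "B"])
        d = nei_distance(f)
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_hand_value_single_locus(self):
        f = pd.DataFrame([[0.8], [0.2]], index=["A", "B"])
        d = nei_distance(f)
        assert d.values[0, 1] == pytest.approx(-np.log(0.32 / 0.68), abs=1e-4)

    def test_shared_monomorphic_locus_dilutes_toward_zero(self):
        base = pd.DataFrame([[0.8], [0.2]], index=["A", "B"])
        extended = pd.DataFrame([[0.8, 1.0], [0.2, 1.0]], index=["A", "B"])
        d0 = nei_distance(base).values[0, 1]
        d1 = nei_distance(extended).values[0, 1]
        # brute-force evaluation of the definition
        jx = np.mean([0.8**2 + 0.2**2, 1.0])
        jy = np.mean([0.2**2 + 0.8**2, 1.0])
        jxy = np.mean([0.32, 1.0])
        assert d1 == pytest.approx(-np.log(jxy / np.sqrt(jx * jy)))
        assert d1 < d0

    def test_nan_loci_excluded_pairwise(self):
        f = pd.DataFrame([[0.8, np.nan], [0.2, 0.5]], index=["A", "B"])
        d = nei_distance(f)
        assert d.values[0, 1] == pytest.approx(-np.log(0.32 / 0.68), abs=1e-4)


class TestPcoa:
    def test_collinear_points_give_one_axis(self):
        d = DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0.0]]))
        coords, evals = pcoa(d)
        assert coords.shape[1] == 1
        got = abs(coords.iloc[0, 0] - coords.iloc[2, 0])
        assert got == pytest.approx(2.0, abs=1e-9)

    def test_planar_configuration_recovered(self, rng):
        pts = rng.normal(size=(6, 2))
        diff = pts[:, None] - pts[None, :]
        D = np.sqrt((diff**2).sum(-1))
        coords, evals = pcoa(DistanceMatrix([f"p{i}" for i in range(6)], D))
        emb = coords.to_numpy()[:, :2]
        diff2 = emb[:, None] - emb[None, :]
        D2 = np.sqrt((diff2**2).sum(-1))
        np.testing.assert_allclose(D2, D, atol=1e-9)

    def test_label_permutation_permutes_coordinates(self, rng):
        pts = rng.normal(size=(5, 2))
        diff = pts[:, None] - pts[None, :]
        D = np.sqrt((diff**2).sum(-1))
        labels = [f"p{i}" for i in range(5)]
        perm = [3, 1, 4, 0, 2]
        c1, _ = pcoa(DistanceMatrix(labels, D))
        c2, _ = pcoa(DistanceMatrix([labels[i] for i in perm],
                                    D[np.ix_(perm, perm)]))
        d1 = c1.loc["p3"].to_numpy() - c1.loc["p0"].to_numpy()
        d2 = c2.loc["p3"].to_numpy() - c2.loc["p0"].to_numpy()
        assert np.linalg.norm(d1) == pytest.approx(np.linalg.norm(d2), abs=1e-9)

    def test_zero_matrix_gives_zero_coordinates(self):
        coords, evals = pcoa(DistanceMatrix(["A", "B"], np.zeros((2, 2))))
        assert coords.shape[1] == 0


class TestBuildNetwork:
    def test_knn_one_links_nearest_neighbor(self):
        pts = np.array([[0, 0], [1, 0], [5, 0], [6, 0.0]])
        net = build_network(pts, "knn", k=1)
        assert set(net.edges) == {(0, 1), (2, 3)}

    def test_square_mst_is_minimal_spanning_tree(self):
        pts = np.array([[0, 0], [1, 0], [1, 1.1], [0, 1.3]])
        net = build_network(pts, "mst")
        assert len(net.edges) == 3
        total = sum(np.linalg.norm(pts[i] - pts[j]) for i, j in net.edges)
        # brute force over all 16 labelled spanning trees of K4
        best = np.inf
        all_edges = list(itertools.combinations(range(4), 2))
        for tree in itertools.combinations(all_edges, 3):
            nodes = set()
            for e in tree:
                nodes.update(e)
            if len(nodes) < 4:
                continue
            m = np.zeros((4, 4))
            for i, j in tree:
                m[i, j] = m[j, i] = 1
            from scipy.sparse.csgraph import connected_components
            if connected_components(m, directed=False)[0] == 1:
                best = min(best, sum(np.linalg.norm(pts[i] - pts[j])
                                     for i, j in tree))
        assert total == pytest.approx(best)

    def test_mst_subset_of_delaunay(self, rng):
        pts = rng.normal(size=(15, 2))
        mst = build_network(pts, "mst")
        dt = build_network(pts, "delaunay")
        assert set(mst.edges) <= set(dt.edges)

    def test_duplicate_coordinates_rejected(self):
        with pytest.raises(ValueError, match="jitter"):
            build_network(np.array([[0, 0], [0, 0], [1, 1.0]]), "mst")


class TestMonmonier:
    def test_path_graph_barrier_crosses_largest_gap(self):
        net = ConnectionNetwork(nodes=list("ABCD"),
                                coords=np.arange(8.0).reshape(4, 2),
                                edges=[(0, 1), (1, 2), (2, 3)], kind="path")
        D = np.array([[0, .1, 5, 5.1], [.1, 0, 5, 5.1],
                      [5, 5, 0, .1], [5.1, 5.1, .1, 0]])
        res = monmonier_barriers(net, DistanceMatrix(list("ABCD"), D))
        assert res.barriers[0].edges == [(1, 2)]

    def test_equal_distances_deterministic_single_edge(self):
        # triangle-free network + all-equal distances: each run crosses one
        # bridge; the best run starts at the lowest-index edge
        pts = np.array([[0, 0], [1, 0], [2, 0.2], [3, 0.0]])
        net = build_network(pts, "mst")
        D = np.ones((4, 4)) - np.eye(4)
        a = monmonier_barriers(net, DistanceMatrix([f"node{i}" for i in range(4)], D))
        b = monmonier_barriers(net, DistanceMatrix([f"node{i}" for i in range(4)], D))
        assert a.barriers[0].edges == b.barriers[0].edges == [net.edges[0]]
        assert len({tuple(x.values) for x in a.barriers}) == 1  # all totals tie

    def test_two_cluster_lattice_matches_min_cut(self, rng):
        pts = np.array([[x, y] for x in range(4) for y in range(2)], float)
        pts += rng.normal(0, 1e-3, pts.shape)
        labels = [f"n{i}" for i in range(8)]
        cluster = [0 if i // 2 < 2 else 1 for i in range(8)]
        D = np.zeros((8, 8))
        for i in range(8):
            for j in range(8):
                if i != j:
                    D[i, j] = 3.0 if cluster[i] != cluster[j] else 0.05
        net = build_network(pts, "delaunay", labels)
        res = monmonier_barriers(net, DistanceMatrix(labels, D))
        comps = barrier_separates(net, res.barriers[0])
        assert sorted(map(sorted, comps)) == [[0, 1, 2, 3], [4, 5, 6, 7]]

    def test_relabeling_invariance(self):
        coords, freqs, dmat = synthdata.generate_island_fixture(8, 4, seed=3)
        net = build_network(coords.to_numpy(), "delaunay", list(coords.index))
        res = monmonier_barriers(net, dmat)
        # reverse node order
        perm = list(range(7, -1, -1))
        inv = {old: new for new, old in enumerate(perm)}
        net2 = ConnectionNetwork(
            nodes=[net.nodes[i] for i in perm],
            coords=net.coords[perm],
            edges=sorted(tuple(sorted((inv[i], inv[j]))) for i, j in net.edges),
            kind="delaunay")
        d2 = DistanceMatrix([dmat.labels[i] for i in perm],
                            dmat.values[np.ix_(perm, perm)])
        res2 = monmonier_barriers(net2, d2)
        names = lambda net_, bar: {frozenset((net_.nodes[i], net_.nodes[j]))
                                   for i, j in bar.edges}
        assert names(net, res.barriers[0]) == names(net2, res2.barriers[0])

    def test_disconnected_network_rejected(self):
        net = ConnectionNetwork(nodes=list("ABCD"),
                                coords=np.arange(8.0).reshape(4, 2),
                                edges=[(0, 1), (2, 3)], kind="x")
        with pytest.raises(ValueError, match="connected"):
            monmonier_barriers(net, DistanceMatrix(list("ABCD"),
                                                   np.ones((4, 4)) - np.eye(4)))

    def test_coalescent_two_deme_clusters_recovered(self):
        """SNP data simulated under deep isolation, individuals spread over
        8 pseudo-localities (4 per deme): the top barrier should separate
        the demes in at least 18 of 20 seeded replicates."""
        from cycadiv.coalsim import DemographicParams, SimConfig, simulate_dataset
        from cycadiv.genodata import allele_freq

        p = DemographicParams(N_CR2=1000, N_CT2=1000, N_anc_REL=1, N_CR_REL=1,
                              N_CT_REL=1, t1=100, t2=15000, t3=20000, mu=1e-6)
        hits = 0
        for seed in range(20):
            gm = simulate_dataset(p, "CI", SimConfig(n_CR=16, n_CT=16,
                                                     n_loci=200, seed=3000 + seed))
            # 4 localities per species, 4 diploids each
            pops = {ind: f"{ind[:2]}{i % 4}" for i, ind in enumerate(gm.individuals)}
            gm.pop_of = pops
            f, _ = allele_freq(gm, "population")
            dmat = nei_distance(f)
            rng = np.random.default_rng(seed)
            # two 2x2 blobs of localities separated along x
            coords = []
            for lab in dmat.labels:
                k = int(lab[2])
                x0 = 0.0 if lab.startswith("CR") else 6.0
                coords.append([x0 + 2 * (k % 2), 2 * (k // 2)])
            coords = np.asarray(coords) + rng.normal(0, 0.1, (8, 2))
            net = build_network(coords, "delaunay", dmat.labels)
            res = monmonier_barriers(net, dmat)
            comps = barrier_separates(net, res.barriers[0])
            # the demes are separated when no remaining component mixes
            # species (a threshold-0 barrier may fragment further)
            mixed = any(
                {dmat.labels[i][:2] for i in comp} == {"CR", "CT"}
                for comp in comps
            )
            if len(comps) >= 2 and not mixed:
                hits += 1
        assert hits >= 18


class TestPairwiseFst:
    def test_identical_groups_nonpositive_and_symmetric(self, rng):
        block = rng.choice([0, 1, 2], size=(6, 15))
        gm = make_gm(np.vstack([block, block]), species=["CR"] * 12,
                     pops=["P1"] * 6 + ["P2"] * 6)
        out = pairwise_fst_matrix(gm)
        assert out.loc["P1", "P2"] <= 0
        assert out.loc["P1", "P2"] == out.loc["P2", "P1"]

    def test_fixed_difference_pair_high(self):
        gm = make_gm([[0]] * 8 + [[2]] * 8, species=["CR"] * 16,
                     pops=["P1"] * 8 + ["P2"] * 8)
        assert pairwise_fst_matrix(gm).loc["P1", "P2"] >= 0.95


class TestNjTree:
    def additive_matrix(self):
        # tree ((A:1,B:2):3,(C:4,D:5)) gives these additive distances
        labels = list("ABCD")
        D = np.array([
            [0, 3, 8, 9],
            [3, 0, 9, 10],
            [8, 9, 0, 9],
            [9, 10, 9, 0.0],
        ])
        return DistanceMatrix(labels, D)

    def test_nj_reproduces_additive_distances(self):
        from io import StringIO
        from skbio import TreeNode

        newick, _ = nj_tree(self.additive_matrix())
        tree = TreeNode.read(StringIO(newick))
        for a, b in itertools.combinations("ABCD", 2):
            got = tree.find(a).distance(tree.find(b))
            assert got == pytest.approx(self.additive_matrix().loc(a, b), abs=1e-9)

    def test_three_taxa_and_bootstrap_reproducibility(self, rng):
        calls = rng.choice([0, 1, 2], size=(12, 30))
        gm = make_gm(calls, species=["CR"] * 12,
                     pops=["P1"] * 4 + ["P2"] * 4 + ["P3"] * 4,
                     locus_ids=[f"L{j}" for j in range(30)])
        from cycadiv.genodata import allele_freq
        f, _ = allele_freq(gm, "population")
        d = nei_distance(f)
        n1, s1 = nj_tree(d, gm, bootstrap=1, seed=4)
        n2, s2 = nj_tree(d, gm, bootstrap=1, seed=4)
        assert n1 == n2 and s1 == s2
        assert s1 == {}  # 3 taxa: no non-trivial bipartitions

    def test_bootstrap_supports_resolved_clusters(self):
        # two tight clusters of populations -> the split should get
        # near-full support
        rng = np.random.default_rng(8)
        base1 = rng.choice([0, 2], size=40)
        base2 = 2 - base1
        rows = []
        pops = []
        for pi, base in enumerate([base1, base1, base2, base2]):
            for i in range(4):
                noisy = base.copy()
                flip = rng.random(40) < 0.05
                noisy[flip] = 1
                rows.append(noisy)
                pops.append(f"P{pi}")
        gm = make_gm(np.array(rows), species=["CR"] * 16, pops=pops,
                     locus_ids=[f"L{j}" for j in range(40)])
        from cycadiv.genodata import allele_freq
        f, _ = allele_freq(gm, "population")
        d = nei_distance(f)
        newick, support = nj_tree(d, gm, bootstrap=50, seed=1)
        assert support[frozenset({"P0", "P1"})] >= 90.0

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            nj_tree(DistanceMatrix(["A", "B"], np.zeros((2, 2))))
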