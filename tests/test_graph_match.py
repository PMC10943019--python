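"""Pseudo-atom vectors, association graphs, clique search and superposition."""

import itertools

import networkx as nx
import numpy as np
import pytest

from pocketome.graph_match import (
    ALL_COMPONENTS,
    AssociationGraph,
    MatchParams,
    NodeConstructionError,
    association_graph,
    build_graph,
    find_cliques,
    match_sites,
    node_vectors,
    superpose,
    superpose_transform,
)
from pocketome.structure_io import Atom, Residue
from pocketome.synthetic import (FixtureSpec, _rotation, make_decoy_db,
                                 place_residue)


def _residue_from_atoms(resname, pairs):
    atoms = [Atom(i + 1, n, n[0], "", 1.0, np.array(p, float))
             for i, (n, p) in enumerate(pairs)]
    return Residue("A", 1, "", resname, atoms)


class TestNodeVectors:
    def test_lysine_vector(self):
        res = _residue_from_atoms("LYS", [
            ("CA", (0, 0, -1.5)), ("CB", (0, 0, 0)), ("NZ", (0, 0, 4.0)),
        ])
        v = node_vectors(res)
        np.testing.assert_allclose(v.S, [0, 0, 0])
        np.testing.assert_allclose(v.E, [0, 0, 4.0])
        np.testing.assert_allclose(v.M, [0, 0, 2.0])

    def test_glycine_degenerate(self):
        res = _residue_from_atoms("GLY", [("CA", (1.0, 2.0, 3.0))])
        v = node_vectors(res)
        np.testing.assert_allclose(v.S, v.E)
        np.testing.assert_allclose(v.M, [1.0, 2.0, 3.0])

    def test_aspartate_centroid(self):
        res = _residue_from_atoms("ASP", [
            ("CB", (0, 0, -2)), ("OD1", (1, 0, 0)), ("OD2", (-1, 0, 0)),
        ])
        v = node_vectors(res)
        np.testing.assert_allclose(v.E, [0, 0, 0])

    def test_missing_atom_names_residue(self):
        res = _residue_from_atoms("LYS", [("CB", (0, 0, 0))])
        with pytest.raises(NodeConstructionError, match="LYS"):
            node_vectors(res)

    def test_nonstandard_residue_rejected(self):
        res = _residue_from_atoms("LIG", [("C1", (0, 0, 0))])
        with pytest.raises(NodeConstructionError):
            node_vectors(res)


class TestBuildGraph:
    def test_counting(self, fx_motif):
        g = build_graph(fx_motif.residues[:3])
        assert g.n_nodes == 3
        pairs = list(itertools.combinations(range(3), 2))
        assert len(pairs) == 3
        # five stored distances per unordered pair
        assert all(len(g.edge(i, j)) == 5 for i, j in pairs)

    def test_degenerate_vectors_all_distances_equal(self):
        r1 = _residue_from_atoms("GLY", [("CA", (0, 0, 0))])
        r2 = _residue_from_atoms("GLY", [("CA", (0, 0, 5.0))])
        g = build_graph([r1, r2])
        assert g.edge(0, 1) == pytest.approx((5.0,) * 5)

    def test_rigid_invariance(self, fx_motif):
        g = build_graph(fx_motif.residues)
        R = _rotation([1.0, 0.3, 0.8], 2.0)
        t = np.array([3.0, -7.0, 1.0])
        moved = []
        for r in fx_motif.residues:
            atoms = [Atom(a.serial, a.name, a.element, "", 1.0, R @ a.coords + t)
                     for a in r.atoms]
            moved.append(Residue(r.chain, r.resseq, r.icode, r.resname, atoms))
        g2 = build_graph(moved)
        for i in range(g.n_nodes):
            for j in range(i + 1, g.n_nodes):
                assert g.edge(i, j) == pytest.approx(g2.edge(i, j), abs=1e-9)

    def test_se_es_symmetry(self, fx_motif):
        g = build_graph(fx_motif.residues)
        for i in range(g.n_nodes):
            for j in range(g.n_nodes):
                if i != j:
                    assert g.distance("SE", i, j) == pytest.approx(
                        g.distance("ES", j, i))


def _random_site(rng, types, spread=12.0):
    residues = []
    for i, t in enumerate(types):
        target = rng.uniform(-spread, spread, size=3)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        residues.append(place_residue(t, "A", i + 1, target, d,
                                      roll=float(rng.uniform(0, 2 * np.pi))))
    return residues


class TestAssociationGraph:
    def test_exact_copy_contains_full_clique(self, fx_motif):
        Q = build_graph(fx_motif.residues)
        ag = association_graph(Q, Q, tol=1.5)
        cliques = find_cliques(ag, min_size=Q.n_nodes)
        identity = tuple(sorted(ag.vertices.index((i, i))
                                for i in range(Q.n_nodes)))
        assert identity in cliques

    def test_wrong_types_empty(self, fx_motif):
        rng = np.random.default_rng(0)
        T = build_graph(_random_site(rng, ["ALA", "GLY", "LYS", "ASN"]))
        Q = build_graph(fx_motif.residues)
        ag = association_graph(Q, T, tol=1.5)
        assert ag.n_vertices == 0

    def test_edges_match_bruteforce(self):
        rng = np.random.default_rng(3)
        types_q = ["SER", "LYS", "ASP", "VAL", "SER", "LYS"]
        types_t = types_q * 2
        Q = build_graph(_random_site(rng, types_q))
        T = build_graph(_random_site(rng, types_t, spread=16.0))
        tol = 1.5
        ag = association_graph(Q, T, tol=tol)
        edges = {(min(i, j), max(i, j))
                 for i in range(ag.n_vertices) for j in ag.adjacency[i]}
        expected = set()
        for i, (q1, t1) in enumerate(ag.vertices):
            for j in range(i + 1, ag.n_vertices):
                q2, t2 = ag.vertices[j]
                if q1 == q2 or t1 == t2:
                    continue
                if all(abs(Q.distance(c, q1, q2) - T.distance(c, t1, t2)) <= tol
                       for c in ALL_COMPONENTS):
                    expected.add((i, j))
        assert edges == expected


def _assoc_from_nx(g):
    n = g.number_of_nodes()
    return AssociationGraph(
        vertices=[(i, i) for i in range(n)],
        adjacency=[set(g.neighbors(i)) for i in range(n)],
    )


def _exhaustive_max_cliques(g, min_size):
    nodes = list(g.nodes)
    cliques = []
    for r in range(min_size, len(nodes) + 1):
        for comb in itertools.combinations(nodes, r):
            if all(g.has_edge(a, b) for a, b in itertools.combinations(comb, 2)):
                cliques.append(frozenset(comb))
    return {c for c in cliques if not any(c < d for d in cliques)}


class TestFindCliques:
    def test_embedded_four_clique(self):
        g = nx.Graph()
        g.add_nodes_from(range(7))
        for a, b in itertools.combinations(range(4), 2):
            g.add_edge(a, b)
        g.add_edges_from([(4, 5), (5, 6)])
        out = find_cliques(_assoc_from_nx(g), min_size=4)
        assert out == [(0, 1, 2, 3)]

    def test_triangle_free_graph_empty(self):
        g = nx.cycle_graph(8)  # even cycle has no triangles
        assert find_cliques(_assoc_from_nx(g), min_size=3) == []

    def test_two_disjoint_triangles_sorted(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        assert find_cliques(_assoc_from_nx(g), min_size=3) == [(0, 1, 2), (3, 4, 5)]

    def test_matches_exhaustive_and_networkx(self):
        rng = np.random.default_rng(12)
        for trial in range(100):
            n = int(rng.integers(4, 16))
            p = float(rng.uniform(0.2, 0.8))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2 ** 31)))
            ours = {frozenset(c) for c in find_cliques(_assoc_from_nx(g), 3)}
            brute = {c for c in _exhaustive_max_cliques(g, 3)}
            assert ours == brute
            nx_cliques = {frozenset(c) for c in nx.find_cliques(g) if len(c) >= 3}
            assert ours == nx_cliques


class TestSuperpose:
    def test_rotated_copy_zero_rmsd(self):
        rng = np.random.default_rng(0)
        P = rng.normal(size=(6, 3))
        R = _rotation([0.2, 1.0, 0.4], 1.3)
        Q = P @ R.T + np.array([4.0, 5.0, 6.0])
        rmsd, reflected = superpose(P, Q)
        assert rmsd <= 1e-6 and not reflected

    def test_mirror_detection(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(5, 3))  # generic point set is chiral
        Q = P.copy()
        Q[:, 0] *= -1
        rmsd_no, _ = superpose(P, Q, allow_reflection=False)
        assert rmsd_no > 0.1
        rmsd_yes, reflected = superpose(P, Q, allow_reflection=True)
        assert rmsd_yes <= 1e-9 and reflected

    def test_matches_rotation_sampling_oracle(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(2)
        P = rng.normal(size=(5, 3))
        Q = rng.normal(size=(5, 3))
        rmsd, _ = superpose(P, Q)
        P0 = P - P.mean(axis=0)
        Q0 = Q - Q.mean(axis=0)
        Rs = Rotation.random(20000, random_state=3).as_matrix()
        sampled = np.sqrt(
            ((np.einsum("nij,kj->nki", Rs, P0) - Q0) ** 2)
            .sum(axis=(1, 2)) / len(P)
        )
        best = float(sampled.min())
        assert rmsd <= best + 1e-12
        assert best - rmsd < 0.05

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_transform_maps_points(self):
        rng = np.random.default_rng(4)
        P = rng.normal(size=(6, 3))
        R_true = _rotation([1.0, 1.0, 0.0], 0.7)
        Q = P @ R_true.T + 2.5
        rmsd, reflected, R, t = superpose_transform(P, Q)
        np.testing.assert_allclose(P @ R + t, Q, atol=1e-8)
        assert rmsd <= 1e-8 and not reflected


class TestMatchSites:
    def test_planted_exact_copy_single_hit(self, fx_motif):
        db = make_decoy_db(FixtureSpec(seed=1, n_decoys=6, planted_fraction=0.5,
                                       jitter_sigma=0.0), fx_motif)
        params = MatchParams(tol=1.5)
        for s, (_, row) in zip(db.structures, db.truth.iterrows()):
            hits = match_sites([fx_motif], s, params)
            if row.planted:
                assert len(hits) == 1
                assert hits[0].rmsd <= 1e-6
                assert hits[0].correspondence == db.correspondences[s.id]
            else:
                assert hits == []

    def test_jittered_copy_rmsd_bound(self, fx_motif):
        db = make_decoy_db(FixtureSpec(seed=2, n_decoys=8, planted_fraction=1.0,
                                       jitter_sigma=0.3), fx_motif)
        for s in db.structures:
            hits = match_sites([fx_motif], s, MatchParams(tol=1.5))
            assert len(hits) == 1 and hits[0].rmsd <= 1.0

    def test_mirrored_plant_needs_reflection(self, fx_motif):
        db = make_decoy_db(FixtureSpec(seed=3, n_decoys=4, planted_fraction=1.0,
                                       jitter_sigma=0.0, mirror_fraction=1.0),
                           fx_motif)
        for s in db.structures:
            strict = match_sites([fx_motif], s,
                                 MatchParams(tol=1.5, allow_reflection=False))
            assert all(h.rmsd > 0.1 for h in strict)
            mirrored = match_sites([fx_motif], s,
                                   MatchParams(tol=1.5, allow_reflection=True))
            assert len(mirrored) == 1
            assert mirrored[0].rmsd <= 1e-6 and mirrored[0].reflected

    def test_pruning_equals_unpruned(self, fx_motif):
        db = make_decoy_db(FixtureSpec(seed=4, n_decoys=10, planted_fraction=0.5,
                                       jitter_sigma=0.2), fx_motif)
        for s in db.structures:
            pruned = match_sites([fx_motif], s, MatchParams(prune=True))
            full = match_sites([fx_motif], s, MatchParams(prune=False))
            assert [(h.correspondence, h.rmsd) for h in pruned] == \
                [(h.correspondence, h.rmsd) for h in full]

    def test_rigid_transform_invariance(self, fx_motif):
        db = make_decoy_db(FixtureSpec(seed=5, n_decoys=2, planted_fraction=1.0,
                                       jitter_sigma=0.1), fx_motif)
        s = db.structures[0]
        hits = match_sites([fx_motif], s, MatchParams())
        moved = s.copy()
        R = _rotation([0.1, 0.9, 0.4], 2.2)
        moved.set_coords(moved.coords() @ R.T + np.array([8.0, 1.0, -3.0]))
        hits2 = match_sites([fx_motif], moved, MatchParams())
        assert len(hits) == len(hits2) == 1
        assert hits[0].rmsd == pytest.approx(hits2[0].rmsd, abs=1e-6)
        assert hits[0].correspondence == hits2[0].correspondence
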