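import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from alchemnet.graphs import (ATOM_FEATURE_DIM, DEFAULT_NONCOVALENT_CUTOFF,
                              ELEMENTS, GraphPair, build_complex_graph,
                              build_ligand_graph, featurize_atom, graph_to_json)
from alchemnet.structio import ComplexStructure, read_ligand

from conftest import make_ligand, make_pocket


class TestFeaturizeAtom:
    def test_aromatic_carbon(self):
        v = featurize_atom("C", 0, 3, True, origin=0)
        assert v.shape == (ATOM_FEATURE_DIM,)
        assert v[ELEMENTS.index("C")] == 1.0
        assert v[len(ELEMENTS) + 1 + 3] == 1.0          # degree-3 slot
        assert v[len(ELEMENTS) + 1 + 7 + 2] == 1.0       # charge-0 slot
        assert v[len(ELEMENTS) + 1 + 7 + 5] == 1.0       # aromatic flag

    def test_unsupported_element_goes_to_other_bucket(self):
        v = featurize_atom("Se", 0, 2, False)
        assert v[len(ELEMENTS)] == 1.0
        assert v[: len(ELEMENTS)].sum() == 0.0

    def test_deterministic(self):
        a = featurize_atom("N", -1, 2, False, origin=1)
        b = featurize_atom("N", -1, 2, False, origin=1)
        np.testing.assert_array_equal(a, b)

    def test_origin_flag_distinguishes(self):
        assert not np.array_equal(featurize_atom("C", 0, 2, False, 0),
                                  featurize_atom("C", 0, 2, False, 1))


class TestLigandGraph:
    def test_three_atom_chain_excludes_13_pair(self):
        # all pairwise distances < cutoff, but 1-2 and 1-3 pairs are excluded
        lig = make_ligand([[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0]],
                          bonds=[(0, 1, 1.0), (1, 2, 1.0)])
        g = build_ligand_graph(lig)
        assert g.covalent_pairs == {(0, 1), (1, 2)}
        assert g.noncovalent_pairs == set()

    def test_single_atom_no_edges(self):
        g = build_ligand_graph(make_ligand([[0, 0, 0]]))
        assert len(g.cov_src) == 0 and len(g.ncov_src) == 0

    def test_benzene_matches_bruteforce(self, benzene_sdf):
        lig = read_ligand(benzene_sdf)
        g = build_ligand_graph(lig)
        ring = {(i, (i + 1) % 6) for i in range(6)}
        ring = {tuple(sorted(p)) for p in ring}
        assert ring <= g.covalent_pairs
        assert len(g.covalent_pairs) == 12  # 6 ring + 6 C-H

        # brute-force oracle over all 66 unordered pairs
        adj = {i: set() for i in range(12)}
        for i, j, _ in lig.bonds:
            adj[i].add(j)
            adj[j].add(i)
        excl = {tuple(sorted((i, j))) for i in adj for j in adj[i]}
        for k in adj:
            for a in adj[k]:
                for b in adj[k]:
                    if a < b:
                        excl.add((a, b))
        d = cdist(lig.coords, lig.coords)
        expected = {(i, j) for i in range(12) for j in range(i + 1, 12)
                    if d[i, j] <= DEFAULT_NONCOVALENT_CUTOFF and (i, j) not in excl}
        assert g.noncovalent_pairs == expected
        assert len(expected) > 0

    def test_edge_sets_disjoint_and_symmetric(self, benzene_sdf):
        g = build_ligand_graph(read_ligand(benzene_sdf))
        assert not (g.covalent_pairs & g.noncovalent_pairs)
        # symmetric storage: both directions present
        pairs = set(zip(g.ncov_src.tolist(), g.ncov_dst.tolist()))
        assert all((j, i) in pairs for i, j in pairs)

    def test_noncovalent_distances_within_cutoff(self, benzene_sdf):
        g = build_ligand_graph(read_ligand(benzene_sdf))
        assert np.all(g.ncov_dist <= DEFAULT_NONCOVALENT_CUTOFF)


class TestComplexGraph:
    def test_single_cross_pair_within_cutoff(self):
        lig = make_ligand([[0, 0, 0]])
        pocket = make_pocket([[3.0, 0, 0]])
        g = build_complex_graph(ComplexStructure(lig, pocket), cutoff=4.5)
        assert g.is_complex
        assert g.noncovalent_pairs == {(0, 1)}

    def test_no_cross_pair_below_small_cutoff(self):
        lig = make_ligand([[0, 0, 0]])
        pocket = make_pocket([[3.0, 0, 0]])
        g = build_complex_graph(ComplexStructure(lig, pocket), cutoff=2.0)
        assert g.noncovalent_pairs == set()

    def test_cross_edges_match_bruteforce(self):
        rng = np.random.default_rng(2)
        lig = make_ligand(rng.uniform(-2, 2, (5, 3)))
        pk_coords = rng.uniform(-4, 4, (6, 3))
        pocket = make_pocket(pk_coords, residue_of=[1, 1, 1, 2, 2, 2])
        g = build_complex_graph(ComplexStructure(lig, pocket), cutoff=4.5)
        d = cdist(lig.coords, pk_coords)
        expected_cross = {(i, 5 + j) for i in range(5) for j in range(6)
                          if d[i, j] <= 4.5}
        cross = {p for p in g.noncovalent_pairs if p[0] < 5 <= p[1]}
        assert cross == expected_cross
        # intra-ligand pairs follow the ligand-graph rule (no bonds here)
        dl = cdist(lig.coords, lig.coords)
        expected_intra = {(i, j) for i in range(5) for j in range(i + 1, 5)
                          if dl[i, j] <= 4.5}
        intra = {p for p in g.noncovalent_pairs if p[1] < 5}
        assert intra == expected_intra

    def test_pocket_internal_noncovalent_excluded(self):
        # two pocket atoms 3 Å apart, ligand far from one of them
        lig = make_ligand([[0, 0, 0]])
        pocket = make_pocket([[3.0, 0, 0], [3.0, 3.0, 0]], residue_of=[1, 2])
        g = build_complex_graph(ComplexStructure(lig, pocket), cutoff=4.4)
        assert (1, 2) not in g.noncovalent_pairs  # no pocket-pocket edge

    def test_empty_pocket_rejected(self):
        lig = make_ligand([[0, 0, 0]])
        with pytest.raises(ValueError):
            build_complex_graph(ComplexStructure(lig, make_pocket(np.zeros((0, 3)))))


def test_rigid_motion_preserves_features_and_distances(benzene_sdf):
    lig = read_ligand(benzene_sdf)
    g0 = build_ligand_graph(lig)
    rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
    moved = make_ligand(lig.coords @ rot.T + np.array([5.0, -3.0, 1.0]),
                        elements=lig.elements, bonds=lig.bonds,
                        charges=lig.formal_charges)
    moved = type(lig)(moved.elements, moved.coords, moved.formal_charges,
                      moved.bonds, lig.aromatic_flags)
    g1 = build_ligand_graph(moved)
    np.testing.assert_array_equal(g0.node_features, g1.node_features)
    np.testing.assert_allclose(np.sort(g0.ncov_dist), np.sort(g1.ncov_dist), atol=1e-9)


def test_graph_pair_kind_validation():
    lig = make_ligand([[0, 0, 0]])
    pocket = make_pocket([[3.0, 0, 0]])
    cg = build_complex_graph(ComplexStructure(lig, pocket))
    lg = build_ligand_graph(lig)
    GraphPair(cg, cg, kind="complex-pair")
    GraphPair(cg, lg, kind="complex-ligand-pair")
    with pytest.raises(ValueError):
        GraphPair(cg, lg, kind="complex-pair")
    with pytest.raises(ValueError):
        GraphPair(cg, cg, kind="complex-ligand-pair")
    with pytest.raises(ValueError):
        GraphPair(cg, cg, kind="nonsense")


def test_graph_json_writer(benzene_sdf):
    g = build_ligand_graph(read_ligand(benzene_sdf))
    blob = graph_to_json(g)
    assert blob["n_nodes"] == 12
    assert len(blob["node_features"][0]) == ATOM_FEATURE_DIM
    assert all(len(e) == 3 for e in blob["noncovalent_edges"])
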