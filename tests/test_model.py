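import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from alchemnet.graphs import GraphPair, build_complex_graph, build_ligand_graph
from alchemnet.model import (BatchedGraphs, LambdaWindow, ModelConfig,
                             WindowPrediction, embed_lambda_basis, encode_graphs,
                             init_params, load_checkpoint, predict_profile,
                             predict_window, save_checkpoint)
from alchemnet.structio import ComplexStructure, LigandStructure

from conftest import make_ligand, make_pocket


class TestLambdaEmbedding:
    def test_basis_at_zero_peaks_first_center(self):
        v = embed_lambda_basis(0.0)[0]
        assert v[0] == pytest.approx(1.0)
        assert np.all(v[1:] < 1.0)

    def test_deterministic(self):
        np.testing.assert_array_equal(embed_lambda_basis(0.37), embed_lambda_basis(0.37))

    def test_mirror_symmetry(self):
        # centers are symmetric on [0,1], so basis(λ) reversed equals basis(1−λ)
        lam = 0.23
        np.testing.assert_allclose(embed_lambda_basis(lam)[0],
                                   embed_lambda_basis(1 - lam)[0][::-1], atol=1e-12)

    @pytest.mark.parametrize("bad", [-0.1, 1.0001, 2.0])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            embed_lambda_basis(bad)


class TestLambdaWindow:
    def test_validation(self):
        with pytest.raises(ValueError):
            LambdaWindow(3, 0.5)
        with pytest.raises(ValueError):
            LambdaWindow(1, 1.5)


def test_anchoring_zero_lambda(tiny_dataset, small_params):
    """F(leg, 0) = 0 exactly for every pair, leg and parameter draw."""
    for pair in tiny_dataset.pairs:
        for leg in (1, 2):
            pred = predict_window(pair, LambdaWindow(leg, 0.0), small_params)
            assert pred.cumulative_dG == 0.0


def test_profile_matches_pointwise_calls(tiny_dataset, small_params):
    pair = tiny_dataset.pairs[0]
    grid = [0.0, 0.25, 0.5, 0.75, 1.0]
    profile = predict_profile(pair, 1, grid, small_params)
    for wp, lam in zip(profile, grid):
        single = predict_window(pair, LambdaWindow(1, lam), small_params)
        assert wp.cumulative_dG == pytest.approx(single.cumulative_dG, abs=1e-6)
    assert profile[0].cumulative_dG == 0.0


def test_profile_rejects_unsorted_grid(tiny_dataset, small_params):
    with pytest.raises(ValueError):
        predict_profile(tiny_dataset.pairs[0], 1, [0.5, 0.2], small_params)


def test_dense_profile_finite(tiny_dataset, small_params):
    grid = np.linspace(0, 1, 1001)
    profile = predict_profile(tiny_dataset.pairs[0], 1, grid, small_params)
    assert len(profile) == 1001
    assert np.all(np.isfinite([w.cumulative_dG for w in profile]))


def test_permutation_invariance(tiny_dataset, small_params):
    """Re-ordering ligand atoms leaves predictions unchanged (≤1e-6)."""
    ds = tiny_dataset
    lig = ds.ligands[0]
    rng = np.random.default_rng(0)
    perm = rng.permutation(lig.n_atoms)
    inv = np.argsort(perm)
    permuted = LigandStructure(
        tuple(lig.elements[i] for i in perm), lig.coords[perm],
        tuple(lig.formal_charges[i] for i in perm),
        tuple((int(inv[i]), int(inv[j]), o) for i, j, o in lig.bonds),
        tuple(lig.aromatic_flags[i] for i in perm), name=lig.name)
    ga = build_complex_graph(ComplexStructure(lig, ds.pocket))
    gp = build_complex_graph(ComplexStructure(permuted, ds.pocket))
    gb = ds.pairs[0].graph_b
    for lam in (0.3, 0.9):
        p0 = predict_window(GraphPair(ga, gb, "complex-pair"),
                            LambdaWindow(1, lam), small_params)
        p1 = predict_window(GraphPair(gp, gb, "complex-pair"),
                            LambdaWindow(1, lam), small_params)
        assert p0.cumulative_dG == pytest.approx(p1.cumulative_dG, abs=1e-6)


def test_se3_invariance(tiny_dataset, small_params):
    """Rigid rotation+translation drifts predictions by < 1e-5 kcal/mol."""
    ds = tiny_dataset
    rng = np.random.default_rng(5)
    lig = ds.ligands[0]
    base_pair = ds.pairs[0]
    for _ in range(3):
        rot = Rotation.random(random_state=rng).as_matrix()
        shift = rng.uniform(-20, 20, 3)
        moved_lig = LigandStructure(lig.elements, lig.coords @ rot.T + shift,
                                    lig.formal_charges, lig.bonds, lig.aromatic_flags)
        moved_pocket = make_pocket(ds.pocket.coords @ rot.T + shift,
                                   elements=list(ds.pocket.elements),
                                   residue_of=[a.residue_id[1] for a in ds.pocket.atoms])
        ga = build_complex_graph(ComplexStructure(moved_lig, moved_pocket))
        pair = GraphPair(ga, base_pair.graph_b, "complex-pair")
        for lam in (0.4, 1.0):
            p_ref = predict_window(base_pair, LambdaWindow(1, lam), small_params)
            p_mov = predict_window(pair, LambdaWindow(1, lam), small_params)
            assert abs(p_ref.cumulative_dG - p_mov.cumulative_dG) < 1e-5


def test_heterogeneous_block_only_for_complex_graphs(tiny_dataset, small_params):
    """Relabelling pocket nodes as a plain ligand graph changes the output."""
    ds = tiny_dataset
    g = ds.pairs[0].graph_a
    import copy

    g_flat = copy.deepcopy(g)
    g_flat.is_complex = False  # heterogeneous block disabled
    za = encode_graphs(BatchedGraphs.from_graphs([g]), small_params)
    zb = encode_graphs(BatchedGraphs.from_graphs([g_flat]), small_params)
    assert not np.allclose(za.data, zb.data)


def test_leg_encoding_exchange(tiny_dataset, small_params):
    """Swapping endpoint order exchanges the two legs' outputs exactly."""
    pair = tiny_dataset.pairs[1]
    swapped = GraphPair(pair.graph_b, pair.graph_a, "complex-pair")
    for lam in (0.5, 1.0):
        f1 = predict_window(pair, LambdaWindow(1, lam), small_params).cumulative_dG
        f2 = predict_window(pair, LambdaWindow(2, lam), small_params).cumulative_dG
        g1 = predict_window(swapped, LambdaWindow(1, lam), small_params).cumulative_dG
        g2 = predict_window(swapped, LambdaWindow(2, lam), small_params).cumulative_dG
        assert f1 == g2 and f2 == g1


def test_identical_endpoints_make_legs_identical(tiny_dataset, small_params):
    g = tiny_dataset.pairs[0].graph_a
    sym = GraphPair(g, g, "complex-pair")
    for lam in (0.2, 0.8, 1.0):
        f1 = predict_window(sym, LambdaWindow(1, lam), small_params).cumulative_dG
        f2 = predict_window(sym, LambdaWindow(2, lam), small_params).cumulative_dG
        assert f1 == f2  # exact equality by construction


def test_checkpoint_roundtrip(tmp_path, tiny_dataset, small_params):
    path = tmp_path / "ckpt.json"
    save_checkpoint(small_params, path)
    loaded = load_checkpoint(path)
    assert loaded.config == small_params.config
    pair = tiny_dataset.pairs[0]
    a = predict_window(pair, LambdaWindow(1, 0.7), small_params).cumulative_dG
    b = predict_window(pair, LambdaWindow(1, 0.7), loaded).cumulative_dG
    assert a == pytest.approx(b, abs=1e-12)


def test_init_params_deterministic():
    p1 = init_params(ModelConfig(d_hidden=16, seed=3))
    p2 = init_params(ModelConfig(d_hidden=16, seed=3))
    for k in p1:
        np.testing.assert_array_equal(p1[k].data, p2[k].data)
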