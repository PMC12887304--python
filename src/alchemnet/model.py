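"""The alchemical-path-aware network.

Architecture (per forward pass):

1. atom encoder: linear + SiLU on the fixed atom features;
2. L message-passing rounds with *separate* message functions for covalent
   and non-covalent edges (edge features concatenated to the source node
   state), residual SiLU updates, and — for complex-type graphs only — a
   heterogeneous block applying distinct transforms to ligand-origin and
   pocket-origin nodes;
3. readout: sum pooling over ligand nodes and pocket nodes separately,
   concatenated and projected to the hidden width (one embedding per graph);
4. λ embedding: Gaussian radial basis of the alchemical coordinate λ on
   [0, 1] followed by a learned linear map;
5. multiplicative fusion: elementwise product of graph embedding and λ
   embedding, then linear + SiLU;
6. leg encoding by concatenation order — leg 1 is (endpoint A ‖ endpoint B),
   leg 2 is (endpoint B ‖ endpoint A) — with all downstream weights shared
   across legs;
7. an MLP head mapping the fused leg representation to a scalar. The
   window-level cumulative free energy is ``head(λ) − head(0)``, which
   anchors F(leg, 0) = 0 for every pair and parameter setting by
   construction, and makes symmetric perturbations (identical endpoints)
   yield ΔΔG = 0 exactly: both legs then carry identical representations.

All geometry enters through inter-atomic distances, so predictions are
invariant under rigid motions and atom re-orderings of the input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .graphs import (ATOM_FEATURE_DIM, N_BOND_CLASSES, N_DISTANCE_BASIS,
                     GraphPair, MolecularGraph)

__all__ = ["ModelConfig", "ModelParams", "LambdaWindow", "WindowPrediction",
           "BatchedGraphs", "embed_lambda_basis", "init_params", "encode_graphs",
           "predict_window", "predict_profile", "predict_windows_batch",
           "save_checkpoint", "load_checkpoint"]

D_LAMBDA_BASIS = 16


@dataclass(frozen=True)
class ModelConfig:
    d_hidden: int = 128
    n_layers: int = 3
    d_lambda_basis: int = D_LAMBDA_BASIS
    activation: str = "silu"   # fixed; recorded for checkpoint provenance
    pooling: str = "sum"
    seed: int = 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("d_hidden", "n_layers", "d_lambda_basis", "activation", "pooling", "seed")}


@dataclass(frozen=True)
class LambdaWindow:
    """One (leg, λ) point on an alchemical path."""
    leg_id: int       # 1 or 2
    lam: float        # alchemical coordinate in [0, 1]

    def __post_init__(self):
        if self.leg_id not in (1, 2):
            raise ValueError(f"leg_id must be 1 or 2, got {self.leg_id}")
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError(f"lambda must lie in [0, 1], got {self.lam}")


@dataclass(frozen=True)
class WindowPrediction:
    window: LambdaWindow
    cumulative_dG: float  # kcal/mol, accumulated from λ=0 of the leg


class ModelParams(dict):
    """name → Tensor mapping of all learnable weights."""

    config: ModelConfig

    def detached_copy(self) -> "ModelParams":
        out = ModelParams({k: ad.parameter(v.data.copy()) for k, v in self.items()})
        out.config = self.config
        return out


def _glorot(rng, fan_in, fan_out):
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=(fan_in, fan_out))


def init_params(config: ModelConfig = ModelConfig()) -> ModelParams:
    """Seeded Glorot-uniform initialization of every layer."""
    rng = np.random.default_rng(config.seed)
    d = config.d_hidden
    p = ModelParams()
    p.config = config

    def lin(name, fi, fo):
        p[f"{name}.w"] = ad.parameter(_glorot(rng, fi, fo))
        p[f"{name}.b"] = ad.parameter(np.zeros(fo))

    lin("enc", ATOM_FEATURE_DIM, d)
    for layer in range(config.n_layers):
        lin(f"mp{layer}.cov", d + N_BOND_CLASSES, d)
        lin(f"mp{layer}.ncov", d + N_DISTANCE_BASIS, d)
        lin(f"mp{layer}.upd", 3 * d, d)
        lin(f"mp{layer}.het_lig", d, d)
        lin(f"mp{layer}.het_pkt", d, d)
    lin("readout", 2 * d, d)
    lin("lam", config.d_lambda_basis, d)
    lin("fuse", d, d)
    lin("head1", 2 * d, d)
    lin("head2", d, 1)
    return p


def embed_lambda_basis(lam, n_basis: int = D_LAMBDA_BASIS) -> np.ndarray:
    """Raw Gaussian radial basis of λ: centers evenly spaced on [0, 1],
    width equal to the center spacing. Returns [m, n_basis]."""
    lam = np.atleast_1d(np.asarray(lam, dtype=np.float64))
    if np.any((lam < 0) | (lam > 1)):
        raise ValueError("lambda values must lie in [0, 1]")
    centers = np.linspace(0.0, 1.0, n_basis)
    width = centers[1] - centers[0]
    return np.exp(-(((lam[:, None] - centers[None, :]) / width) ** 2))


@dataclass
class BatchedGraphs:
    """Disjoint union of graphs with scatter indices for vectorized forward."""

    x: np.ndarray             # [N, d_atom]
    cov_src: np.ndarray
    cov_dst: np.ndarray
    cov_feat: np.ndarray
    ncov_src: np.ndarray
    ncov_dst: np.ndarray
    ncov_feat: np.ndarray
    graph_id: np.ndarray      # [N] node → graph index
    lig_mask: np.ndarray      # [N, 1] float
    pkt_mask: np.ndarray      # [N, 1]
    het_mask: np.ndarray      # [N, 1] node belongs to a complex-type graph
    n_graphs: int

    @classmethod
    def from_graphs(cls, graphs: list[MolecularGraph]) -> "BatchedGraphs":
        xs, gids, ligm, pktm, hetm = [], [], [], [], []
        cs, cd, cf, ns, nd, nf = [], [], [], [], [], []
        offset = 0
        for g_idx, g in enumerate(graphs):
            n = g.n_nodes
            xs.append(g.node_features)
            gids.append(np.full(n, g_idx, dtype=int))
            lig = (g.node_origin == 0).astype(float)
            ligm.append(lig)
            pktm.append(1.0 - lig)
            hetm.append(np.full(n, 1.0 if g.is_complex else 0.0))
            cs.append(g.cov_src + offset)
            cd.append(g.cov_dst + offset)
            cf.append(g.cov_feat.reshape(-1, N_BOND_CLASSES))
            ns.append(g.ncov_src + offset)
            nd.append(g.ncov_dst + offset)
            nf.append(g.ncov_feat.reshape(-1, N_DISTANCE_BASIS))
            offset += n
        return cls(
            x=np.concatenate(xs),
            cov_src=np.concatenate(cs).astype(int), cov_dst=np.concatenate(cd).astype(int),
            cov_feat=np.concatenate(cf),
            ncov_src=np.concatenate(ns).astype(int), ncov_dst=np.concatenate(nd).astype(int),
            ncov_feat=np.concatenate(nf),
            graph_id=np.concatenate(gids),
            lig_mask=np.concatenate(ligm)[:, None],
            pkt_mask=np.concatenate(pktm)[:, None],
            het_mask=np.concatenate(hetm)[:, None],
            n_graphs=len(graphs),
        )


def _affine(p: ModelParams, name: str, x: Tensor) -> Tensor:
    return ad.affine(x, p[f"{name}.w"], p[f"{name}.b"])


def encode_graphs(batch: BatchedGraphs, p: ModelParams) -> Tensor:
    """Run message passing + readout; returns graph embeddings [n_graphs, d]."""
    cfg = p.config
    n = batch.x.shape[0]
    cov_e = ad.constant(batch.cov_feat)
    ncov_e = ad.constant(batch.ncov_feat)
    lig_mask = ad.constant(batch.lig_mask)
    pkt_mask = ad.constant(batch.pkt_mask)
    het_lig = ad.constant(batch.lig_mask * batch.het_mask)
    het_pkt = ad.constant(batch.pkt_mask * batch.het_mask)

    h = ad.silu(_affine(p, "enc", ad.constant(batch.x)))
    for layer in range(cfg.n_layers):
        if len(batch.cov_src):
            msg_in = ad.concat([ad.gather_rows(h, batch.cov_src), cov_e])
            m_cov = ad.segment_sum(ad.silu(_affine(p, f"mp{layer}.cov", msg_in)),
                                   batch.cov_dst, n)
        else:
            m_cov = ad.constant(np.zeros((n, cfg.d_hidden)))
        if len(batch.ncov_src):
            msg_in = ad.concat([ad.gather_rows(h, batch.ncov_src), ncov_e])
            m_ncov = ad.segment_sum(ad.silu(_affine(p, f"mp{layer}.ncov", msg_in)),
                                    batch.ncov_dst, n)
        else:
            m_ncov = ad.constant(np.zeros((n, cfg.d_hidden)))
        h = ad.add(h, ad.silu(_affine(p, f"mp{layer}.upd",
                                      ad.concat([h, m_cov, m_ncov]))))
        # heterogeneous block: complex-type graphs only
        h = ad.add(h, ad.add(
            ad.mul(het_lig, ad.silu(_affine(p, f"mp{layer}.het_lig", h))),
            ad.mul(het_pkt, ad.silu(_affine(p, f"mp{layer}.het_pkt", h))),
        ))

    z_lig = ad.segment_sum(ad.mul(h, lig_mask), batch.graph_id, batch.n_graphs)
    z_pkt = ad.segment_sum(ad.mul(h, pkt_mask), batch.graph_id, batch.n_graphs)
    return ad.silu(_affine(p, "readout", ad.concat([z_lig, z_pkt])))


def _fuse(z: Tensor, lam_emb: Tensor, p: ModelParams) -> Tensor:
    """Multiplicative fusion: elementwise product, then linear + SiLU."""
    return ad.silu(_affine(p, "fuse", ad.mul(z, lam_emb)))


def _head(leg_rep: Tensor, p: ModelParams) -> Tensor:
    return _affine(p, "head2", ad.silu(_affine(p, "head1", leg_rep)))


def _window_outputs(z_a: Tensor, z_b: Tensor, leg_ids: np.ndarray,
                    lams: np.ndarray, p: ModelParams) -> Tensor:
    """Cumulative free energies [m, 1] for rows of (z_a, z_b, leg, λ)."""
    lam_emb = _affine(p, "lam", ad.constant(embed_lambda_basis(lams, p.config.d_lambda_basis)))
    zero_emb = _affine(p, "lam", ad.constant(
        embed_lambda_basis(np.zeros_like(lams), p.config.d_lambda_basis)))

    def through_head(emb: Tensor) -> Tensor:
        fa, fb = _fuse(z_a, emb, p), _fuse(z_b, emb, p)
        # leg 1 = (A ‖ B), leg 2 = (B ‖ A); shared downstream weights
        leg1 = np.asarray(leg_ids) == 1
        m1 = ad.constant(leg1.astype(float)[:, None])
        m2 = ad.constant((~leg1).astype(float)[:, None])
        first = ad.add(ad.mul(m1, fa), ad.mul(m2, fb))
        second = ad.add(ad.mul(m1, fb), ad.mul(m2, fa))
        return _head(ad.concat([first, second]), p)

    return ad.sub(through_head(lam_emb), through_head(zero_emb))


def predict_windows_batch(z_pairs: Tensor, pair_index: np.ndarray,
                          leg_ids: np.ndarray, lams: np.ndarray,
                          p: ModelParams) -> Tensor:
    """Vectorized window predictions.

    ``z_pairs`` holds graph embeddings with endpoint A of pair k at row 2k and
    endpoint B at row 2k+1; ``pair_index[i]`` names the pair of sample i.
    """
    pair_index = np.asarray(pair_index, dtype=int)
    z_a = ad.gather_rows(z_pairs, 2 * pair_index)
    z_b = ad.gather_rows(z_pairs, 2 * pair_index + 1)
    return _window_outputs(z_a, z_b, np.asarray(leg_ids), np.asarray(lams), p)


def predict_window(pair: GraphPair, window: LambdaWindow,
                   p: ModelParams) -> WindowPrediction:
    """Cumulative free energy (kcal/mol) at one (leg, λ) window."""
    batch = BatchedGraphs.from_graphs([pair.graph_a, pair.graph_b])
    z = encode_graphs(batch, p)
    out = predict_windows_batch(z, np.array([0]), np.array([window.leg_id]),
                                np.array([window.lam]), p)
    return WindowPrediction(window=window, cumulative_dG=float(out.data[0, 0]))


def predict_profile(pair: GraphPair, leg_id: int, lam_grid, p: ModelParams
                    ) -> list[WindowPrediction]:
    """Batched predictions over a sorted λ grid (one leg)."""
    lam_grid = np.asarray(lam_grid, dtype=np.float64)
    if np.any(np.diff(lam_grid) < 0):
        raise ValueError("lambda grid must be sorted ascending")
    batch = BatchedGraphs.from_graphs([pair.graph_a, pair.graph_b])
    z = encode_graphs(batch, p)
    out = predict_windows_batch(z, np.zeros(len(lam_grid), dtype=int),
                                np.full(len(lam_grid), leg_id), lam_grid, p)
    return [WindowPrediction(LambdaWindow(leg_id, float(l)), float(v))
            for l, v in zip(lam_grid, out.data[:, 0])]


def save_checkpoint(p: ModelParams, path: str) -> None:
    """Serialize weights + config (JSON, plain text)."""
    blob = {"config": p.config.to_dict(),
            "weights": {k: v.data.tolist() for k, v in p.items()}}
    with open(path, "w") as fh:
        json.dump(blob, fh)


def load_checkpoint(path: str) -> ModelParams:
    with open(path) as fh:
        blob = json.load(fh)
    cfg = ModelConfig(**blob["config"])
    p = ModelParams({k: ad.parameter(np.array(v)) for k, v in blob["weights"].items()})
    p.config = cfg
    return p
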