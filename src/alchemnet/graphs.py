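"""Molecular graph construction with distinct covalent / non-covalent edges.

Nodes are atoms with fixed-length numeric features; covalent edges come from
bonds (order one-hot), non-covalent edges from inter-atomic distances under a
cutoff, expanded in Gaussian radial basis functions. All geometric
information enters as distances only, which makes every downstream quantity
invariant under rigid motions of the input coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .structio import ComplexStructure, LigandStructure

__all__ = ["MolecularGraph", "GraphPair", "featurize_atom", "build_ligand_graph",
           "build_complex_graph", "graph_to_json", "ATOM_FEATURE_DIM",
           "DEFAULT_NONCOVALENT_CUTOFF", "N_DISTANCE_BASIS"]

ELEMENTS = ("H", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I")  # + "other"
DEGREES = 7          # one-hot 0..6
CHARGES = (-2, -1, 0, 1, 2)
N_BOND_CLASSES = 4   # single, double, triple, aromatic
N_DISTANCE_BASIS = 16
DEFAULT_NONCOVALENT_CUTOFF = 4.5  # Å

# element 11 + degree 7 + charge 5 + aromatic 1 + origin 2
# + hybridization-bucket 2 + in-ring 1
ATOM_FEATURE_DIM = len(ELEMENTS) + 1 + DEGREES + len(CHARGES) + 1 + 2 + 2 + 1

ORIGIN_LIGAND, ORIGIN_POCKET = 0, 1


def featurize_atom(element: str, formal_charge: int = 0, degree: int = 0,
                   aromatic: bool = False, origin: int = ORIGIN_LIGAND,
                   in_ring: bool = False) -> np.ndarray:
    """Fixed-length atom feature vector (one-hot blocks; unknown element →
    'other' slot; degree clipped to 6, charge clipped to ±2)."""
    v = np.zeros(ATOM_FEATURE_DIM)
    off = 0
    try:
        v[off + ELEMENTS.index(element)] = 1.0
    except ValueError:
        v[off + len(ELEMENTS)] = 1.0  # "other" bucket
    off += len(ELEMENTS) + 1
    v[off + min(max(int(degree), 0), DEGREES - 1)] = 1.0
    off += DEGREES
    v[off + CHARGES.index(min(max(int(formal_charge), -2), 2))] = 1.0
    off += len(CHARGES)
    v[off] = 1.0 if aromatic else 0.0
    off += 1
    v[off + (1 if origin == ORIGIN_POCKET else 0)] = 1.0
    off += 2
    # coarse hybridization bucket: aromatic/sp2-like vs saturated
    v[off + (1 if aromatic else 0)] = 1.0
    off += 2
    v[off] = 1.0 if in_ring else 0.0
    return v


def _rbf(d: np.ndarray, cutoff: float, n: int = N_DISTANCE_BASIS) -> np.ndarray:
    centers = np.linspace(0.0, cutoff, n)
    width = centers[1] - centers[0]
    return np.exp(-(((d[:, None] - centers[None, :]) / width) ** 2))


def _bond_onehot(order: float) -> np.ndarray:
    v = np.zeros(N_BOND_CLASSES)
    v[{1.0: 0, 2.0: 1, 3.0: 2, 1.5: 3}[float(order)]] = 1.0
    return v


@dataclass
class MolecularGraph:
    """Atoms + two disjoint symmetric edge sets (covalent / non-covalent)."""

    node_features: np.ndarray      # [n, ATOM_FEATURE_DIM]
    coords: np.ndarray             # [n, 3] Å
    cov_src: np.ndarray            # int, both directions stored
    cov_dst: np.ndarray
    cov_feat: np.ndarray           # [m_cov, N_BOND_CLASSES]
    ncov_src: np.ndarray
    ncov_dst: np.ndarray
    ncov_dist: np.ndarray          # [m_ncov] Å
    ncov_feat: np.ndarray          # [m_ncov, N_DISTANCE_BASIS]
    node_origin: np.ndarray        # [n] int, 0=ligand 1=pocket
    is_complex: bool               # heterogeneous block active downstream

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def covalent_pairs(self) -> set[tuple[int, int]]:
        return {tuple(sorted((int(i), int(j)))) for i, j in zip(self.cov_src, self.cov_dst)}

    @property
    def noncovalent_pairs(self) -> set[tuple[int, int]]:
        return {tuple(sorted((int(i), int(j)))) for i, j in zip(self.ncov_src, self.ncov_dst)}


@dataclass
class GraphPair:
    """The two endpoint graphs of an alchemical transformation."""

    graph_a: MolecularGraph
    graph_b: MolecularGraph
    kind: str  # "complex-pair" (relative) or "complex-ligand-pair" (absolute)

    def __post_init__(self):
        if self.kind == "complex-pair":
            if not (self.graph_a.is_complex and self.graph_b.is_complex):
                raise ValueError("complex-pair requires pocket nodes in both graphs")
        elif self.kind == "complex-ligand-pair":
            if self.graph_a.is_complex == self.graph_b.is_complex:
                raise ValueError("complex-ligand-pair requires exactly one complex graph")
        else:
            raise ValueError(f"unknown pair kind {self.kind!r}")


def _ligand_degrees(ligand: LigandStructure) -> np.ndarray:
    deg = np.zeros(ligand.n_atoms, dtype=int)
    for i, j, _ in ligand.bonds:
        deg[i] += 1
        deg[j] += 1
    return deg


def _ring_membership(ligand: LigandStructure) -> np.ndarray:
    """True for atoms lying on any cycle (endpoints of non-bridge bonds)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(ligand.n_atoms))
    g.add_edges_from((i, j) for i, j, _ in ligand.bonds)
    bridges = set(frozenset(e) for e in nx.bridges(g))
    in_ring = np.zeros(ligand.n_atoms, dtype=bool)
    for i, j, _ in ligand.bonds:
        if frozenset((i, j)) not in bridges:
            in_ring[i] = in_ring[j] = True
    return in_ring


def _excluded_pairs(ligand: LigandStructure) -> set[tuple[int, int]]:
    """1-2 and 1-3 covalent neighbor pairs (excluded from non-covalent edges)."""
    adj: dict[int, set[int]] = {i: set() for i in range(ligand.n_atoms)}
    excl: set[tuple[int, int]] = set()
    for i, j, _ in ligand.bonds:
        adj[i].add(j)
        adj[j].add(i)
        excl.add(tuple(sorted((i, j))))
    for k, nbrs in adj.items():
        for a in nbrs:
            for b in nbrs:
                if a < b:
                    excl.add((a, b))
    return excl


def _symmetrize(pairs: list[tuple[int, int]], feats: list[np.ndarray],
                dists: list[float] | None = None):
    src = [p[0] for p in pairs] + [p[1] for p in pairs]
    dst = [p[1] for p in pairs] + [p[0] for p in pairs]
    ff = feats + feats
    out = (np.array(src, dtype=int), np.array(dst, dtype=int),
           np.array(ff).reshape(len(ff), -1) if ff else np.zeros((0, 1)))
    if dists is not None:
        dd = np.array(dists + dists)
        return out + (dd,)
    return out


def build_ligand_graph(ligand: LigandStructure,
                       cutoff: float = DEFAULT_NONCOVALENT_CUTOFF) -> MolecularGraph:
    """Ligand-only graph: covalent edges from bonds; intramolecular
    non-covalent edges between pairs within ``cutoff`` that are neither
    bonded nor 1-3 neighbors."""
    deg = _ligand_degrees(ligand)
    ring = _ring_membership(ligand)
    feats = np.stack([
        featurize_atom(e, q, d, a, ORIGIN_LIGAND, in_ring=r)
        for e, q, d, a, r in zip(ligand.elements, ligand.formal_charges, deg,
                                 ligand.aromatic_flags, ring)
    ]) if ligand.n_atoms else np.zeros((0, ATOM_FEATURE_DIM))

    cov_pairs = [(i, j) for i, j, _ in ligand.bonds]
    cov_feats = [_bond_onehot(o) for _, _, o in ligand.bonds]
    excl = _excluded_pairs(ligand)
    d = cdist(ligand.coords, ligand.coords)
    ncov_pairs, ncov_d = [], []
    n = ligand.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] <= cutoff and (i, j) not in excl:
                ncov_pairs.append((i, j))
                ncov_d.append(d[i, j])

    cs, cd, cf = _symmetrize(cov_pairs, cov_feats)
    if cf.shape[1] != N_BOND_CLASSES:
        cf = np.zeros((0, N_BOND_CLASSES))
    ns, nd, _, ndist = _symmetrize(ncov_pairs, [np.zeros(1)] * len(ncov_pairs), ncov_d)
    nfeat = _rbf(ndist, cutoff) if len(ndist) else np.zeros((0, N_DISTANCE_BASIS))
    return MolecularGraph(
        node_features=feats, coords=ligand.coords.copy(),
        cov_src=cs, cov_dst=cd, cov_feat=cf,
        ncov_src=ns, ncov_dst=nd, ncov_dist=ndist, ncov_feat=nfeat,
        node_origin=np.zeros(n, dtype=int), is_complex=False,
    )


# intra-residue covalent bond inference thresholds (Å)
_POCKET_BOND_HEAVY = 1.9
_POCKET_BOND_H = 1.3


def build_complex_graph(complex_structure: ComplexStructure,
                        cutoff: float = DEFAULT_NONCOVALENT_CUTOFF) -> MolecularGraph:
    """Ligand + pocket graph.

    Ligand-internal edges as in :func:`build_ligand_graph`; ligand–pocket
    non-covalent edges for every cross pair within ``cutoff``;
    pocket-internal edges covalent only, inferred from intra-residue
    inter-atomic distances (cross-pocket non-covalent edges excluded).
    """
    ligand, pocket = complex_structure.ligand, complex_structure.pocket
    if pocket.n_atoms == 0:
        raise ValueError("complex graph requires a non-empty pocket")
    lig_graph = build_ligand_graph(ligand, cutoff)
    n_lig = ligand.n_atoms
    pcoords = pocket.coords

    # pocket covalent edges: intra-residue distance-based
    pk_pairs, pk_feats = [], []
    for i in range(pocket.n_atoms):
        for j in range(i + 1, pocket.n_atoms):
            if pocket.atoms[i].residue_id != pocket.atoms[j].residue_id:
                continue
            dij = float(np.linalg.norm(pcoords[i] - pcoords[j]))
            is_h = "H" in (pocket.atoms[i].element, pocket.atoms[j].element)
            if dij <= (_POCKET_BOND_H if is_h else _POCKET_BOND_HEAVY):
                pk_pairs.append((n_lig + i, n_lig + j))
                pk_feats.append(_bond_onehot(1.0))

    pk_deg = np.zeros(pocket.n_atoms, dtype=int)
    for i, j in pk_pairs:
        pk_deg[i - n_lig] += 1
        pk_deg[j - n_lig] += 1
    pk_featmat = np.stack([
        featurize_atom(a.element, 0, pk_deg[k], False, ORIGIN_POCKET)
        for k, a in enumerate(pocket.atoms)
    ])

    # cross ligand-pocket non-covalent edges
    d_cross = cdist(ligand.coords, pcoords)
    li, pj = np.nonzero(d_cross <= cutoff)
    cross_pairs = [(int(i), n_lig + int(j)) for i, j in zip(li, pj)]
    cross_d = [float(d_cross[i, j]) for i, j in zip(li, pj)]

    cov_src = np.concatenate([lig_graph.cov_src,
                              [p[0] for p in pk_pairs] + [p[1] for p in pk_pairs]]).astype(int)
    cov_dst = np.concatenate([lig_graph.cov_dst,
                              [p[1] for p in pk_pairs] + [p[0] for p in pk_pairs]]).astype(int)
    cov_feat = np.concatenate([lig_graph.cov_feat.reshape(-1, N_BOND_CLASSES),
                               np.array(pk_feats + pk_feats).reshape(-1, N_BOND_CLASSES)])

    ncov_src = np.concatenate([lig_graph.ncov_src,
                               [p[0] for p in cross_pairs] + [p[1] for p in cross_pairs]]).astype(int)
    ncov_dst = np.concatenate([lig_graph.ncov_dst,
                               [p[1] for p in cross_pairs] + [p[0] for p in cross_pairs]]).astype(int)
    ncov_dist = np.concatenate([lig_graph.ncov_dist, cross_d + cross_d])
    ncov_feat = _rbf(ncov_dist, cutoff) if len(ncov_dist) else np.zeros((0, N_DISTANCE_BASIS))

    return MolecularGraph(
        node_features=np.concatenate([lig_graph.node_features, pk_featmat]),
        coords=np.concatenate([ligand.coords, pcoords]),
        cov_src=cov_src, cov_dst=cov_dst, cov_feat=cov_feat,
        ncov_src=ncov_src, ncov_dst=ncov_dst, ncov_dist=ncov_dist, ncov_feat=ncov_feat,
        node_origin=np.concatenate([np.zeros(n_lig, dtype=int),
                                    np.ones(pocket.n_atoms, dtype=int)]),
        is_complex=True,
    )


def graph_to_json(graph: MolecularGraph) -> dict:
    """Debug representation of a graph as plain JSON-compatible structures."""
    return {
        "n_nodes": graph.n_nodes,
        "is_complex": graph.is_complex,
        "node_origin": graph.node_origin.tolist(),
        "node_features": graph.node_features.tolist(),
        "covalent_edges": [[int(i), int(j)] for i, j in zip(graph.cov_src, graph.cov_dst)],
        "noncovalent_edges": [
            [int(i), int(j), float(d)]
            for i, j, d in zip(graph.ncov_src, graph.ncov_dst, graph.ncov_dist)
        ],
    }
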