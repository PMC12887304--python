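"""Synthetic alchemical-path datasets for training and validation.

The generator emulates the *statistical structure* of window-level labels
produced by an alchemical transfer simulation post-processed with a
multistate estimator: per (pair, leg) a smooth cumulative profile F(λ) with
F(0) = 0, two correlated legs whose terminal difference is a known per-pair
ΔΔG, heteroscedastic Gaussian label noise, and a per-sample uncertainty σ
stored alongside each label. Molecules are random small organics (6–20
heavy atoms, valence-legal, 3D-embedded by distance geometry) docked at the
center of a fixed 30-atom spherical toy pocket.

The profile family is deliberately simple — linear ramp blended with a
smoothstep plus optional interior bumps that vanish at both endpoints — so
the implied ΔΔG is available in closed form:

    F_leg1(λ) = G1·S1(λ),  F_leg2(λ) = G2·S2(λ),  S(0)=0, S(1)=1
    ΔΔG = G1 − G2 = 0.45·(n_heavy_A − n_heavy_B) + 1.1·(n_rings_A − n_rings_B)

Terminal amplitudes G are deterministic functions of simple graph
descriptors (heavy-atom and ring counts), so held-out pairs have learnable
targets; the interior shape parameters are seeded per pair/leg and carry no
ΔΔG information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .graphs import GraphPair, build_complex_graph
from .model import LambdaWindow
from .structio import (ComplexStructure, LigandStructure, ProteinAtom,
                       ProteinPocket)
from .training import TrainingSample

__all__ = ["SyntheticSpec", "SyntheticDataset", "gen_molecules", "gen_profile",
           "gen_dataset", "TOY_POCKET_N_ATOMS", "TOY_POCKET_RADIUS"]

TOY_POCKET_N_ATOMS = 30
TOY_POCKET_RADIUS = 6.0  # Å; close enough that ligand atoms form cross edges

# ΔΔG descriptor weights (kcal/mol per unit descriptor difference)
DDG_PER_HEAVY_ATOM = 0.45
DDG_PER_RING = 1.1


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset (seed fixes everything)."""

    n_pairs: int = 40
    windows_per_leg: int = 11
    amplitude_range: tuple[float, float] = (3.0, 15.0)   # terminal |F|, kcal/mol
    smoothness: float = 0.15          # smoothstep half-width in λ
    barrier_prob: float = 0.35        # chance of an interior bump per leg
    barrier_amplitude: float = 2.0    # kcal/mol scale of interior bumps
    sigma_range: tuple[float, float] = (0.1, 0.5)        # label noise, kcal/mol
    heteroscedastic: bool = True
    outlier_fraction: float = 0.0     # fraction of samples with outlier noise
    outlier_sigma: float = 5.0        # kcal/mol
    sigma_cap: float | None = None    # quality screen: drop samples with σ > cap
    seed: int = 0

    def __post_init__(self):
        if self.n_pairs < 1 or self.windows_per_leg < 2:
            raise ValueError("need n_pairs >= 1 and windows_per_leg >= 2")
        if self.amplitude_range[0] > self.amplitude_range[1] or self.sigma_range[0] > self.sigma_range[1]:
            raise ValueError("ranges must be (lo, hi) with lo <= hi")
        if not (0.0 <= self.outlier_fraction <= 1.0):
            raise ValueError("outlier_fraction must lie in [0, 1]")


def _toy_pocket() -> ProteinPocket:
    """Fixed 30-atom shell on a Fibonacci sphere, grouped into 10 residues."""
    n = TOY_POCKET_N_ATOMS
    golden = np.pi * (3.0 - np.sqrt(5.0))
    atoms = []
    elements = ("C", "C", "N", "O", "C", "C")
    for k in range(n):
        y = 1.0 - 2.0 * (k + 0.5) / n
        r = np.sqrt(1.0 - y * y)
        th = golden * k
        x, z = np.cos(th) * r, np.sin(th) * r
        atoms.append(ProteinAtom(
            element=elements[k % len(elements)],
            coord=(TOY_POCKET_RADIUS * x, TOY_POCKET_RADIUS * y, TOY_POCKET_RADIUS * z),
            residue_id=("P", k // 3 + 1),
            residue_name="PKT",
            atom_name=f"X{k}",
        ))
    return ProteinPocket(atoms=tuple(atoms))


_VALENCE = {"C": 4, "N": 3, "O": 2}


def _random_rdkit_molecule(rng: np.random.Generator):
    from rdkit import Chem, RDLogger
    from rdkit.Chem import AllChem

    RDLogger.DisableLog("rdApp.*")

    n_heavy = int(rng.integers(6, 21))
    symbols = rng.choice(["C", "N", "O"], size=n_heavy, p=[0.7, 0.15, 0.15])
    symbols[0] = "C"
    rw = Chem.RWMol()
    used = np.zeros(n_heavy, dtype=int)
    rw.AddAtom(Chem.Atom(str(symbols[0])))
    for i in range(1, n_heavy):
        free = [j for j in range(i) if used[j] < _VALENCE[str(symbols[j])]]
        parent = int(free[rng.integers(len(free))]) if free else 0
        rw.AddAtom(Chem.Atom(str(symbols[i])))
        rw.AddBond(parent, i, Chem.BondType.SINGLE)
        used[parent] += 1
        used[i] += 1
    # optional single ring closure between distant atoms with spare valence
    if n_heavy >= 6 and rng.random() < 0.6:
        mol0 = rw.GetMol()
        dmat = Chem.GetDistanceMatrix(mol0)
        cands = [(i, j) for i in range(n_heavy) for j in range(i + 1, n_heavy)
                 if dmat[i, j] >= 3
                 and used[i] < _VALENCE[str(symbols[i])]
                 and used[j] < _VALENCE[str(symbols[j])]]
        if cands:
            i, j = cands[int(rng.integers(len(cands)))]
            rw.AddBond(int(i), int(j), Chem.BondType.SINGLE)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    ps = AllChem.ETKDGv3()
    ps.randomSeed = int(rng.integers(1, 2**31 - 1))
    if AllChem.EmbedMolecule(mol, ps) != 0:
        return None
    return mol


def gen_molecules(spec: SyntheticSpec) -> tuple[list[LigandStructure], ProteinPocket]:
    """2·n_pairs random ligands (centered at the pocket origin) + shared pocket."""
    from .structio import _from_rdkit

    rng = np.random.default_rng(spec.seed)
    pocket = _toy_pocket()
    ligands: list[LigandStructure] = []
    while len(ligands) < 2 * spec.n_pairs:
        mol = _random_rdkit_molecule(rng)
        if mol is None:
            continue
        lig = _from_rdkit(mol, name=f"SYN{len(ligands):03d}")
        coords = lig.coords - lig.coords.mean(axis=0)
        ligands.append(LigandStructure(lig.elements, coords, lig.formal_charges,
                                       lig.bonds, lig.aromatic_flags, name=lig.name))
    return ligands, pocket


def _descriptors(lig: LigandStructure) -> tuple[int, int]:
    n_heavy = lig.n_heavy_atoms
    n_rings = len(lig.bonds) - lig.n_atoms + 1  # connected molecule
    return n_heavy, n_rings


def _smoothstep(lam, c, w):
    t = np.clip((np.asarray(lam, dtype=float) - (c - w)) / (2 * w), 0.0, 1.0)
    return 3 * t**2 - 2 * t**3


def true_ddg(lig_a: LigandStructure, lig_b: LigandStructure) -> float:
    """Closed-form ground-truth ΔΔG implied by the profile family."""
    na, ra = _descriptors(lig_a)
    nb, rb = _descriptors(lig_b)
    return DDG_PER_HEAVY_ATOM * (na - nb) + DDG_PER_RING * (ra - rb)


def _terminal_amplitude(desc_a, desc_b, spec: SyntheticSpec) -> float:
    """Leg-1 terminal G1, deterministic in the descriptors of both endpoints."""
    lo, hi = spec.amplitude_range
    mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
    s = ((desc_a[0] + desc_b[0] - 26) / 14.0 + 0.4 * (desc_a[1] + desc_b[1] - 1))
    return mid + half * float(np.tanh(s))


def gen_profile(lig_a: LigandStructure, lig_b: LigandStructure, leg_id: int,
                spec: SyntheticSpec, pair_index: int = 0):
    """Ground-truth cumulative profile F*(λ) for one leg of one pair.

    Returns a vectorized callable with F*(0)=0; leg 2's terminal value is
    tied to leg 1's so that F1*(1) − F2*(1) equals :func:`true_ddg` exactly.
    """
    if leg_id not in (1, 2):
        raise ValueError("leg_id must be 1 or 2")
    desc_a, desc_b = _descriptors(lig_a), _descriptors(lig_b)
    g1 = _terminal_amplitude(desc_a, desc_b, spec)
    g = g1 if leg_id == 1 else g1 - true_ddg(lig_a, lig_b)

    shape_rng = np.random.default_rng((spec.seed, pair_index, leg_id, 7919))
    m = shape_rng.uniform(0.2, 0.7)
    c = shape_rng.uniform(0.25, 0.75)
    w = max(spec.smoothness, 1e-3)
    w = min(w, c, 1.0 - c)  # keep S(0)=0 and S(1)=1 exact
    has_bump = shape_rng.random() < spec.barrier_prob
    beta = shape_rng.uniform(-1.0, 1.0) * spec.barrier_amplitude
    cb = shape_rng.uniform(0.2, 0.8)

    def profile(lam):
        lam = np.asarray(lam, dtype=float)
        s = (1.0 - m) * lam + m * _smoothstep(lam, c, w)
        f = g * s
        if has_bump:
            bump = np.exp(-(((lam - cb) / 0.15) ** 2))
            b0 = np.exp(-((cb / 0.15) ** 2))
            b1 = np.exp(-(((1 - cb) / 0.15) ** 2))
            f = f + beta * (bump - (1 - lam) * b0 - lam * b1)  # vanishes at 0 and 1
        return f

    return profile


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    ligands: list[LigandStructure]
    pocket: ProteinPocket
    pairs: list[GraphPair]                 # one complex-pair per molecular pair
    samples: list[TrainingSample]
    pair_of_sample: np.ndarray             # sample → pair index
    truth: dict                            # per-pair ground-truth table

    def samples_of_pairs(self, pair_indices) -> list[TrainingSample]:
        wanted = set(int(i) for i in pair_indices)
        return [s for s, p in zip(self.samples, self.pair_of_sample) if int(p) in wanted]


def gen_dataset(spec: SyntheticSpec = SyntheticSpec()) -> SyntheticDataset:
    """Full synthetic dataset: molecules, graphs, noisy window labels, truth."""
    rng = np.random.default_rng((spec.seed, 104729))
    ligands, pocket = gen_molecules(spec)
    grid = np.linspace(0.0, 1.0, spec.windows_per_leg)

    pairs, samples, pair_of_sample = [], [], []
    truth = {}
    for p_i in range(spec.n_pairs):
        lig_a, lig_b = ligands[2 * p_i], ligands[2 * p_i + 1]
        graph_a = build_complex_graph(ComplexStructure(lig_a, pocket))
        graph_b = build_complex_graph(ComplexStructure(lig_b, pocket))
        pair = GraphPair(graph_a, graph_b, kind="complex-pair")
        pairs.append(pair)
        profiles = {leg: gen_profile(lig_a, lig_b, leg, spec, pair_index=p_i)
                    for leg in (1, 2)}
        truth[p_i] = {
            "ligand_a": lig_a.name, "ligand_b": lig_b.name,
            "ddg_true": true_ddg(lig_a, lig_b),
            "terminal_leg1": float(profiles[1](1.0)),
            "terminal_leg2": float(profiles[2](1.0)),
        }
        for leg in (1, 2):
            f_true = profiles[leg](grid)
            for k, lam in enumerate(grid):
                if spec.outlier_fraction and rng.random() < spec.outlier_fraction:
                    sigma = spec.outlier_sigma
                elif spec.heteroscedastic:
                    sigma = float(rng.uniform(*spec.sigma_range))
                else:
                    sigma = 0.5 * (spec.sigma_range[0] + spec.sigma_range[1])
                if lam == 0.0:
                    # the leg anchor is exact by definition of a cumulative profile
                    target, sigma = 0.0, spec.sigma_range[0]
                else:
                    target = float(f_true[k] + rng.normal(0.0, sigma) if sigma else f_true[k])
                samples.append(TrainingSample(
                    pair=pair, window=LambdaWindow(leg, float(lam)),
                    target_cumulative_dG=target, sigma=sigma))
                pair_of_sample.append(p_i)

    if spec.sigma_cap is not None:
        kept = [(s, p) for s, p in zip(samples, pair_of_sample) if s.sigma <= spec.sigma_cap]
        if not kept:
            warnings.warn("quality cap removed every sample; dataset is empty")
            samples, pair_of_sample = [], []
        else:
            samples, pair_of_sample = map(list, zip(*kept))

    return SyntheticDataset(spec=spec, ligands=ligands, pocket=pocket, pairs=pairs,
                            samples=samples,
                            pair_of_sample=np.array(pair_of_sample, dtype=int),
                            truth=truth)
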