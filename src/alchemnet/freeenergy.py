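"""Assembly of relative and absolute binding free energies from leg profiles.

A thermodynamic cycle is described by a :class:`PathwaySpec`: each leg
carries a sorted λ grid starting at 0 and a combination sign. The network
predicts the cumulative free energy of each leg at its terminal λ; signed
summation over legs then yields ΔΔG (relative, two legs with signs +1/−1 so
shared-environment contributions cancel) or ΔG (absolute decoupling).

Star-network utilities map a ligand series onto hub perturbations against a
single reference ligand (chosen by maximum-common-substructure overlap) and
place the resulting ΔΔG values on an absolute scale by mean-matching against
available experimental ΔG values — an offset choice that leaves all rank and
correlation metrics untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graphs import GraphPair
from .model import ModelParams, predict_profile
from .structio import LigandStructure, to_rdkit

__all__ = ["PathwaySpec", "FreeEnergyResult", "default_rbfe_pathway", "rbfe",
           "abfe", "star_map", "ddg_to_dg"]

DEFAULT_WINDOWS_PER_LEG = 11


@dataclass(frozen=True)
class PathwaySpec:
    """Ordered legs of a thermodynamic cycle: (leg_id, λ values, sign)."""

    legs: tuple[tuple[int, tuple[float, ...], int], ...]

    def __post_init__(self):
        for leg_id, lams, sign in self.legs:
            if sign not in (+1, -1):
                raise ValueError(f"leg {leg_id}: sign must be ±1")
            if not lams or lams[0] != 0.0:
                raise ValueError(f"leg {leg_id}: λ values must start at 0")
            if any(b <= a for a, b in zip(lams, lams[1:])):
                raise ValueError(f"leg {leg_id}: λ values must be strictly increasing")
            if any(not (0.0 <= l <= 1.0) for l in lams):
                raise ValueError(f"leg {leg_id}: λ values must lie in [0, 1]")


def default_rbfe_pathway(windows_per_leg: int = DEFAULT_WINDOWS_PER_LEG,
                         leg_signs: tuple[int, int] = (+1, -1)) -> PathwaySpec:
    """Two legs with uniform λ grids on [0, 1] and signs (+1, −1), the
    convention under which a symmetric perturbation vanishes identically."""
    grid = tuple(np.linspace(0.0, 1.0, windows_per_leg).tolist())
    return PathwaySpec(legs=((1, grid, leg_signs[0]), (2, grid, leg_signs[1])))


@dataclass(frozen=True)
class FreeEnergyResult:
    value: float                       # ΔΔG or ΔG, kcal/mol
    per_leg_terminal: dict             # leg_id → terminal cumulative F, kcal/mol
    pathway: PathwaySpec
    kind: str                          # "rbfe" or "abfe"


def _assemble(pair: GraphPair, pathway: PathwaySpec, params: ModelParams,
              kind: str) -> FreeEnergyResult:
    terminals = {}
    total = 0.0
    for leg_id, lams, sign in pathway.legs:
        profile = predict_profile(pair, leg_id, np.asarray(lams), params)
        terminals[leg_id] = profile[-1].cumulative_dG
        total += sign * terminals[leg_id]
    return FreeEnergyResult(value=total, per_leg_terminal=terminals,
                            pathway=pathway, kind=kind)


def rbfe(pair: GraphPair, pathway: PathwaySpec | None = None,
         params: ModelParams | None = None) -> FreeEnergyResult:
    """Relative binding free energy ΔΔG = Σ signₗ·Fₗ(λ_end) over two legs."""
    if params is None:
        raise ValueError("model parameters required")
    if pair.kind != "complex-pair":
        raise ValueError("rbfe requires a complex-pair (both endpoints in the pocket)")
    pathway = pathway or default_rbfe_pathway()
    if len(pathway.legs) != 2:
        raise ValueError("rbfe pathway must have exactly two legs")
    return _assemble(pair, pathway, params, "rbfe")


def abfe(pair: GraphPair, pathway: PathwaySpec | None = None,
         params: ModelParams | None = None) -> FreeEnergyResult:
    """Absolute binding free energy from a complex/ligand decoupling pathway."""
    if params is None:
        raise ValueError("model parameters required")
    if pair.kind != "complex-ligand-pair":
        raise ValueError("abfe requires a complex-ligand-pair")
    pathway = pathway or default_rbfe_pathway(leg_signs=(+1, +1))
    return _assemble(pair, pathway, params, "abfe")


def _mcs_heavy_atoms(mol_a, mol_b) -> int:
    from rdkit.Chem import rdFMCS

    res = rdFMCS.FindMCS([mol_a, mol_b], timeout=10, ringMatchesRingOnly=True)
    return 0 if res.canceled and res.numAtoms < 0 else res.numAtoms


def star_map(ligands: list[LigandStructure], reference_selector: str = "mcs"
             ) -> tuple[int, list[tuple[int, int]]]:
    """Star perturbation network over a ligand series.

    Returns ``(reference_index, [(reference_index, other_index), ...])`` with
    N−1 edges all sharing the hub. The reference is the ligand with the
    largest mean maximum-common-substructure overlap with the others (i.e.
    the smallest perturbed structure on average); ties break by fewest heavy
    atoms, then input order.
    """
    if len(ligands) < 2:
        raise ValueError("star mapping needs at least two ligands")
    if reference_selector == "first":
        ref = 0
    elif reference_selector == "mcs":
        mols = [to_rdkit(l) for l in ligands]
        n = len(mols)
        mean_mcs = np.zeros(n)
        for i in range(n):
            sizes = [_mcs_heavy_atoms(mols[i], mols[j]) for j in range(n) if j != i]
            mean_mcs[i] = float(np.mean(sizes))
        best = max(range(n), key=lambda i: (mean_mcs[i], -ligands[i].n_heavy_atoms, -i))
        ref = best
    else:
        raise ValueError(f"unknown reference selector {reference_selector!r}")
    edges = [(ref, j) for j in range(len(ligands)) if j != ref]
    return ref, edges


def ddg_to_dg(ddg_map: dict, experimental_dg: dict) -> dict:
    """Place star-network ΔΔG values on an absolute ΔG scale.

    ΔGᵢ = ΔΔGᵢ + c with one offset c chosen so the mean predicted ΔG over
    ligands with experimental values matches the experimental mean. The
    reference ligand should appear in ``ddg_map`` with ΔΔG = 0.
    """
    if not experimental_dg:
        raise ValueError("need at least one experimental ΔG to anchor the scale")
    common = [k for k in ddg_map if k in experimental_dg]
    if not common:
        raise ValueError("no overlap between predicted and experimental ligands")
    c = (float(np.mean([experimental_dg[k] for k in common]))
         - float(np.mean([ddg_map[k] for k in common])))
    return {k: ddg_map[k] + c for k in ddg_map}
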