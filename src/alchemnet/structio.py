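"""Structure I/O: ligands from SDF/MOL2, proteins from PDB, pocket extraction.

Ligand parsing goes through RDKit (sanitization doubles as valence
validation, so chemically impossible records are rejected rather than
silently featurized). Protein parsing uses Biopython's permissive PDB parser
with explicit altloc resolution. All coordinates are Ångström throughout; no
unit conversion happens anywhere in the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyPocketError, StructureParseError, StructureValidationError

__all__ = [
    "LigandStructure", "ProteinAtom", "ProteinPocket", "ComplexStructure",
    "read_ligand", "write_ligand", "read_protein", "extract_pocket",
    "write_pocket_pdb",
]

#: residue names treated as solvent and dropped by default
WATER_RESNAMES = {"HOH", "WAT", "H2O", "DOD", "TIP", "TIP3", "SOL"}
ION_RESNAMES = {"NA", "CL", "K", "MG", "CA", "ZN", "MN", "FE", "BR", "IOD", "CS", "LI"}

DEFAULT_POCKET_CUTOFF = 5.0  # Å, with whole-residue completion


@dataclass(frozen=True)
class LigandStructure:
    """A small molecule: elements, 3D coordinates (Å), formal charges, bonds.

    ``bonds`` holds ``(i, j, order)`` with 0-based atom indices and order in
    {1.0, 1.5, 2.0, 3.0} (1.5 encodes aromatic).
    """

    elements: tuple[str, ...]
    coords: np.ndarray  # [n, 3] float64, Å
    formal_charges: tuple[int, ...]
    bonds: tuple[tuple[int, int, float], ...]
    aromatic_flags: tuple[bool, ...] = ()
    name: str = ""

    def __post_init__(self):
        n = len(self.elements)
        coords = np.asarray(self.coords, dtype=np.float64)
        if coords.shape != (n, 3):
            raise StructureValidationError(f"coords shape {coords.shape} != ({n}, 3)")
        if not np.all(np.isfinite(coords)):
            raise StructureValidationError("non-finite ligand coordinates")
        object.__setattr__(self, "coords", coords)
        for i, j, _ in self.bonds:
            if i == j or not (0 <= i < n and 0 <= j < n):
                raise StructureValidationError(f"bond ({i},{j}) out of range for {n} atoms")
        if not self.aromatic_flags:
            object.__setattr__(self, "aromatic_flags", tuple([False] * n))

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_heavy_atoms(self) -> int:
        return sum(1 for e in self.elements if e != "H")


@dataclass(frozen=True)
class ProteinAtom:
    element: str
    coord: tuple[float, float, float]
    residue_id: tuple[str, int]  # (chain, residue number)
    residue_name: str
    atom_name: str = ""


@dataclass(frozen=True)
class ProteinPocket:
    """Protein atoms lining the binding site, with residue metadata."""

    atoms: tuple[ProteinAtom, ...]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=np.float64)

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(a.element for a in self.atoms)


@dataclass(frozen=True)
class ComplexStructure:
    ligand: LigandStructure
    pocket: ProteinPocket


_BOND_ORDER = {"SINGLE": 1.0, "DOUBLE": 2.0, "TRIPLE": 3.0, "AROMATIC": 1.5}


def _from_rdkit(mol, name: str) -> LigandStructure:
    from rdkit import Chem

    conf = mol.GetConformer()
    elements, charges, arom = [], [], []
    for atom in mol.GetAtoms():
        elements.append(atom.GetSymbol())
        charges.append(atom.GetFormalCharge())
        arom.append(atom.GetIsAromatic())
    coords = np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])
    bonds = tuple(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _BOND_ORDER.get(str(b.GetBondType()), 1.0))
        for b in mol.GetBonds()
    )
    return LigandStructure(tuple(elements), coords, tuple(charges), bonds,
                           tuple(arom), name=name)


def read_ligand(path: str, fmt: str | None = None) -> LigandStructure:
    """Read one ligand record from an SDF or MOL2 file.

    Hydrogens are retained if present and never added. Sanitization failures
    (impossible valence, malformed records) raise
    :class:`StructureValidationError` / :class:`StructureParseError`.
    """
    from rdkit import Chem, RDLogger

    RDLogger.DisableLog("rdApp.*")
    fmt = (fmt or str(path).rsplit(".", 1)[-1]).lower()
    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
        records = [m for m in supplier]
        if not records or records[0] is None:
            raise StructureParseError(f"{path}: no parsable SDF record (record 1)")
        mol = records[0]
    elif fmt == "mol2":
        mol = Chem.MolFromMol2File(str(path), removeHs=False, sanitize=False)
        if mol is None:
            raise StructureParseError(f"{path}: unparsable MOL2 record")
    else:
        raise StructureParseError(f"unsupported ligand format {fmt!r} (use sdf or mol2)")
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # rdkit raises several sanitize error classes
        raise StructureValidationError(f"{path}: invalid molecule ({exc})") from exc
    if mol.GetNumConformers() == 0:
        raise StructureParseError(f"{path}: record carries no 3D coordinates")
    return _from_rdkit(mol, name=mol.GetProp("_Name") if mol.HasProp("_Name") else "")


def to_rdkit(ligand: LigandStructure):
    """Rebuild an RDKit molecule (with conformer) from a LigandStructure."""
    from rdkit import Chem
    from rdkit.Chem import AllChem  # noqa: F401  (registers geometry code)
    from rdkit.Geometry import Point3D

    order_map = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
                 3.0: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}
    rw = Chem.RWMol()
    for el, q in zip(ligand.elements, ligand.formal_charges):
        a = Chem.Atom(el)
        a.SetFormalCharge(int(q))
        a.SetNoImplicit(True)
        rw.AddAtom(a)
    for i, j, order in ligand.bonds:
        rw.AddBond(int(i), int(j), order_map[float(order)])
    mol = rw.GetMol()
    Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, (x, y, z) in enumerate(ligand.coords):
        conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
    mol.AddConformer(conf)
    if ligand.name:
        mol.SetProp("_Name", ligand.name)
    return mol


def write_ligand(ligand: LigandStructure, path: str) -> None:
    """Write a ligand as a single-record SDF (round-trips through read_ligand)."""
    from rdkit import Chem

    mol = to_rdkit(ligand)
    with Chem.SDWriter(str(path)) as w:
        w.write(mol)


_ELEMENT_FROM_NAME_2 = {"CL", "BR", "FE", "ZN", "MG", "MN", "NA", "SE"}


def _infer_element(atom_name: str) -> str:
    name = atom_name.strip().lstrip("0123456789")
    if name[:2].upper() in _ELEMENT_FROM_NAME_2:
        return name[:2].capitalize()
    return name[:1].upper()


def read_protein(path: str, exclude_waters: bool = True,
                 exclude_ions: bool = True) -> list[ProteinAtom]:
    """Read protein atoms from a PDB file.

    Waters (and monoatomic ions) are dropped by default. For altloc
    duplicates the highest-occupancy conformer is kept, ties broken by
    altloc letter order. Missing element columns are inferred from the atom
    name.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True, PERMISSIVE=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure("prot", str(path))
    except Exception as exc:
        raise StructureParseError(f"{path}: PDB parse failure ({exc})") from exc

    atoms: list[ProteinAtom] = []
    for model in structure:
        for chain in model:
            for residue in chain:
                resname = residue.get_resname().strip()
                if exclude_waters and resname in WATER_RESNAMES:
                    continue
                if exclude_ions and resname in ION_RESNAMES:
                    continue
                for atom in residue:
                    if atom.is_disordered():
                        variants = atom.disordered_get_list()
                        variants.sort(key=lambda a: (-(a.get_occupancy() or 0.0),
                                                     a.get_altloc()))
                        atom = variants[0]
                    element = (atom.element or "").strip()
                    if not element:
                        element = _infer_element(atom.get_name())
                    x, y, z = atom.get_coord()
                    if not np.all(np.isfinite([x, y, z])):
                        raise StructureParseError(f"{path}: non-finite coordinate "
                                                  f"on atom {atom.get_name()}")
                    atoms.append(ProteinAtom(
                        element=element.capitalize(),
                        coord=(float(x), float(y), float(z)),
                        residue_id=(chain.id, residue.get_id()[1]),
                        residue_name=resname,
                        atom_name=atom.get_name(),
                    ))
        break  # first model only
    if not atoms:
        raise StructureParseError(f"{path}: no protein atoms found")
    return atoms


def extract_pocket(protein_atoms: list[ProteinAtom], ligand: LigandStructure,
                   cutoff: float = DEFAULT_POCKET_CUTOFF) -> ProteinPocket:
    """Protein atoms within ``cutoff`` Å of any ligand atom, completed to
    whole residues (one atom in range keeps the full residue)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not protein_atoms:
        raise EmptyPocketError("no protein atoms supplied")
    pcoords = np.array([a.coord for a in protein_atoms])
    tree = cKDTree(ligand.coords)
    dmin, _ = tree.query(pcoords, k=1)
    in_range = dmin <= cutoff
    if not np.any(in_range):
        raise EmptyPocketError(
            f"no protein atom within {cutoff:.2f} Å of the ligand "
            f"(closest is {dmin.min():.2f} Å)")
    keep_residues = {protein_atoms[i].residue_id for i in np.nonzero(in_range)[0]}
    kept = tuple(a for a in protein_atoms if a.residue_id in keep_residues)
    return ProteinPocket(atoms=kept)


def write_pocket_pdb(pocket: ProteinPocket, path: str) -> None:
    """Write pocket atoms as PDB ATOM records (round-trips via read_protein)."""
    lines = []
    for k, a in enumerate(pocket.atoms, start=1):
        chain, resnum = a.residue_id
        name = (a.atom_name or a.element)[:4]
        x, y, z = a.coord
        lines.append(
            f"ATOM  {k:>5d} {name:<4s} {a.residue_name:<3s} {str(chain)[:1]}"
            f"{resnum:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {a.element.upper():>2s}"
        )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
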