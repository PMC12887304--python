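import numpy as np
import pytest

from alchemnet.structio import LigandStructure, ProteinAtom, ProteinPocket

METHANE_SDF = """methane
  hand built

  5  4  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.6300    0.6300    0.6300 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6300   -0.6300    0.6300 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6300    0.6300   -0.6300 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.6300   -0.6300   -0.6300 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  1  3  1  0
  1  4  1  0
  1  5  1  0
M  END
$$$$
"""

# texas carbon: five single bonds on one carbon
INVALID_SDF = """texas-carbon
  hand built

  6  5  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    1.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000   -1.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    1.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  1  3  1  0
  1  4  1  0
  1  5  1  0
  1  6  1  0
M  END
$$$$
"""


def _benzene_sdf() -> str:
    rc, rh = 1.39, 2.49
    lines = ["benzene", "  hand built", "",
             " 12 12  0  0  0  0  0  0  0  0999 V2000"]
    for r in (rc, rh):
        for k in range(6):
            a = np.pi / 3 * k
            el = "C" if r == rc else "H"
            lines.append(f"{r*np.cos(a):10.4f}{r*np.sin(a):10.4f}{0.0:10.4f} {el:<3s}"
                         " 0  0  0  0  0  0  0  0  0  0  0  0")
    for k in range(6):  # alternating kekulé ring + C-H bonds
        lines.append(f"{k+1:3d}{(k+1) % 6 + 1:3d}{1 + (k % 2):3d}  0")
    for k in range(6):
        lines.append(f"{k+1:3d}{k+7:3d}  1  0")
    lines += ["M  END", "$$$$", ""]
    return "\n".join(lines)


BENZENE_SDF = _benzene_sdf()

TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       3.988   2.839   0.000  1.00  0.00           C
ATOM      6  C   GLY A   2       5.504   2.693   0.000  1.00  0.00           C
ATOM      7  N   SER A   3       6.191   3.832   0.000  1.00  0.00           N
ATOM      8  CA  SER A   3       7.648   3.841   0.000  1.00  0.00           C
ATOM      9  OG  SER A   3       8.171   5.170   0.000  1.00  0.00           O
HETATM   10  O   HOH A  90      20.000  20.000  20.000  1.00  0.00           O
HETATM   11  O   HOH A  91      21.000  21.000  21.000  1.00  0.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AALA A   1       1.458   0.000   0.000  0.40  0.00           C
ATOM      3  CA BALA A   1       1.500   0.100   0.000  0.60  0.00           C
ATOM      4  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def methane_sdf(tmp_path):
    p = tmp_path / "methane.sdf"
    p.write_text(METHANE_SDF)
    return p


@pytest.fixture
def benzene_sdf(tmp_path):
    p = tmp_path / "benzene.sdf"
    p.write_text(BENZENE_SDF)
    return p


@pytest.fixture
def invalid_sdf(tmp_path):
    p = tmp_path / "texas.sdf"
    p.write_text(INVALID_SDF)
    return p


@pytest.fixture
def toy_pdb(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(TOY_PDB)
    return p


@pytest.fixture
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p


def make_ligand(coords, elements=None, bonds=(), charges=None) -> LigandStructure:
    """Hand-built ligand for geometric tests."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    elements = tuple(elements) if elements else tuple(["C"] * n)
    charges = tuple(charges) if charges else tuple([0] * n)
    return LigandStructure(elements, coords, charges, tuple(bonds))


def make_pocket(coords, elements=None, residue_of=None) -> ProteinPocket:
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    elements = elements or ["C"] * n
    residue_of = residue_of or list(range(n))
    atoms = tuple(
        ProteinAtom(element=elements[i], coord=tuple(coords[i]),
                    residue_id=("A", int(residue_of[i])), residue_name="RES",
                    atom_name=f"X{i}")
        for i in range(n)
    )
    return ProteinPocket(atoms=atoms)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small synthetic dataset shared by model-level tests (no training)."""
    from alchemnet.synthetic import SyntheticSpec, gen_dataset

    return gen_dataset(SyntheticSpec(n_pairs=3, windows_per_leg=5, seed=11))


@pytest.fixture(scope="session")
def small_params():
    from alchemnet.model import ModelConfig, init_params

    return init_params(ModelConfig(d_hidden=24, n_layers=2, seed=7))


@pytest.fixture(scope="session")
def recovery_run():
    """Parameter-recovery experiment on the default synthetic conditions:
    40 pairs, 11 windows/leg, σ ∈ [0.1, 0.5] kcal/mol, seed 0; 8 pairs held
    out; reduced width d_hidden=64. Shared across acceptance-level tests."""
    from alchemnet.model import ModelConfig
    from alchemnet.synthetic import SyntheticSpec, gen_dataset
    from alchemnet.training import TrainConfig, train

    ds = gen_dataset(SyntheticSpec())
    rng = np.random.default_rng(0)
    held = sorted(int(i) for i in rng.choice(ds.spec.n_pairs, size=8, replace=False))
    train_samples = ds.samples_of_pairs(
        [i for i in range(ds.spec.n_pairs) if i not in held])
    params, log = train(train_samples, TrainConfig(seed=0),
                        model_config=ModelConfig(d_hidden=64, seed=0))
    return ds, held, params, log
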