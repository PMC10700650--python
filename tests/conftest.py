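import pytest

from prostab.energy import EnergyModel, default_rotamer_library
from prostab.structures import truncate_n_terminus
from prostab.synthetic import demo_wt_sequence, make_ideal_helix


@pytest.fixture(scope="session")
def energy_model():
    return EnergyModel()


@pytest.fixture(scope="session")
def rotlib():
    return default_rotamer_library()


@pytest.fixture(scope="session")
def demo_helix():
    """The 71-residue demo helix (polar, glycine-rich at planted positions)."""
    return make_ideal_helix(71, demo_wt_sequence(71))


@pytest.fixture(scope="session")
def design_region(demo_helix):
    """Demo helix after removing the 11 flexible N-terminal residues."""
    return truncate_n_terminus(demo_helix, 11)


ONE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       2.000  -0.750   1.200  1.00  0.00           C
END
"""


@pytest.fixture
def one_residue_pdb(tmp_path):
    p = tmp_path / "ala.pdb"
    p.write_text(ONE_RESIDUE_PDB)
    return p
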