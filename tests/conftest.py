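import numpy as np
import pytest

from igtandem import synthetic


@pytest.fixture(scope="session")
def tandem():
    """Default synthetic two-domain tandem (seed 0)."""
    return synthetic.gen_ig_tandem(seed=0)


@pytest.fixture(scope="session")
def tandem_split(tandem):
    return tandem.metadata["split"]


@pytest.fixture(scope="session")
def turn_library():
    """100-turn type-II library with 78% Gly planted at i+2 (seed 0)."""
    return synthetic.gen_turn_library(
        composition={"i+2": {"GLY": 0.78}}, n_turns=100, turn_type="II",
        seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00 10.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00 10.00           O
ATOM      5  N   THR A   2       3.332   1.536   0.000  1.00 10.00           N
ATOM      6  CA  THR A   2       4.012   2.823   0.062  1.00 10.00           C
ATOM      7  C   THR A   2       5.503   2.631   0.189  1.00 10.00           C
ATOM      8  O   THR A   2       6.021   1.520   0.102  1.00 10.00           O
ATOM      9  CB  THR A   2       3.704   3.704   1.266  1.00 10.00           C
ATOM     10  OG1 THR A   2       2.301   3.920   1.332  1.00 10.00           O
END
"""


@pytest.fixture()
def toy_pdb(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(TOY_PDB)
    return p
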