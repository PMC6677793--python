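import numpy as np
import pytest

from tpmkit.modeler import CrickParameters, build_ideal_coiled_coil


@pytest.fixture
def dimer_params():
    return CrickParameters()


@pytest.fixture
def dimer(dimer_params):
    """60-residue ideal parallel dimer, chains A/B."""
    return build_ideal_coiled_coil(dimer_params, 60)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def tiny_pdb(tmp_path):
    """Minimal hand-written single-atom PDB file."""
    text = (
        "ATOM      1  CA  ALA A  12       1.234   2.345   3.456  1.00 20.00           C  \n"
        "END\n"
    )
    p = tmp_path / "tiny.pdb"
    p.write_text(text)
    return p
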