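import numpy as np
import pytest

from ffval.synthetic import build_ideal_peptide


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def helix_peptide():
    """Ideal alpha-helical 6-mer with reconstructed amide hydrogens."""
    return build_ideal_peptide(6)


@pytest.fixture(scope="session")
def sheet_peptide():
    """Ideal extended (beta-like) 6-mer."""
    return build_ideal_peptide(6, phi_deg=-120.0, psi_deg=130.0)
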