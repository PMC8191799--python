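import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

# the 19-mer RAGATH-18 crystallization oligonucleotide; self-hybridizes into
# a duplex containing two k-turns related by two-fold symmetry
RAGATH18_19MER = "GUCUAUGAAGGCUGGAGAC"


@pytest.fixture(scope="session")
def ragath18():
    return RAGATH18_19MER


@pytest.fixture(scope="session")
def standard_grid():
    """20 log-spaced Mg2+ concentrations, 1 uM to 10 mM (molar)."""
    return np.geomspace(1e-6, 10e-3, 20)


@pytest.fixture
def ragath18_fasta(tmp_path, ragath18):
    path = tmp_path / "ragath18.fa"
    path.write_text(f">RAGATH-18\n{ragath18}\n")
    return path
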