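import numpy as np
import pytest

from mirsort.io_formats import SequenceSet
from mirsort.synthetic_data import SimulationConfig, fixture_motifs, simulate

# printed in the source study's worked example (Fig of miR-2137)
MIR2137 = "GCCGGCGGGAGCCCCAGGGAG"


@pytest.fixture(scope="session")
def motif_set():
    return fixture_motifs()


@pytest.fixture(scope="session")
def nono_motif(motif_set):
    return next(m for m in motif_set if m.rbp_name == "NONO")


@pytest.fixture(scope="session")
def hnrnpa2b1_motif(motif_set):
    return next(m for m in motif_set if m.rbp_name == "HNRNPA2B1")


@pytest.fixture
def mir2137_seqs():
    return SequenceSet({"mmu-miR-2137": MIR2137})


@pytest.fixture(scope="session")
def default_sim():
    """Default-scale synthetic dataset (527 miRNAs, 129 sEV-detected)."""
    return simulate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_sim():
    """Fully detected small dataset for fast classification tests."""
    cfg = SimulationConfig(n_mirna=120, n_sev_detected=120, seed=7)
    return simulate(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
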