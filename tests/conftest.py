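import numpy as np
import pytest

from naptrap.library import ReporterLibrary, ReporterRecord
from naptrap.simulate import SimConfig, simulate_experiment


def make_random_library(rng, n_reporters=8, n_spikeins=2, length=40):
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = set()
    while len(seqs) < n_reporters + n_spikeins:
        seqs.add(bases[rng.integers(0, 4, size=length)].tobytes().decode())
    seqs = sorted(seqs)
    records = [
        ReporterRecord(f"rep{i:03d}#reporter", seqs[i], "reporter")
        for i in range(n_reporters)
    ]
    records += [
        ReporterRecord(f"sp{j + 1}#spikein", seqs[n_reporters + j], "spikein")
        for j in range(n_spikeins)
    ]
    return ReporterLibrary(records)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_library(rng):
    return make_random_library(rng)


@pytest.fixture(scope="session")
def sim_small(tmp_path_factory):
    """A small, noisy simulated experiment shared by integration tests."""
    cfg = SimConfig(
        seed=11,
        n_reporters=60,
        n_replicates=2,
        reads_per_sample=4000,
        error_rate=0.001,
        pcr_duplicate_rate=0.2,
    )
    out = tmp_path_factory.mktemp("sim_small")
    return simulate_experiment(cfg, out)


@pytest.fixture(scope="session")
def sim_clean(tmp_path_factory):
    """Error-free, duplication-free experiment: every stage should be exact."""
    cfg = SimConfig(
        seed=7,
        n_reporters=40,
        n_replicates=2,
        reads_per_sample=3000,
        error_rate=0.0,
        pcr_duplicate_rate=0.0,
    )
    out = tmp_path_factory.mktemp("sim_clean")
    return simulate_experiment(cfg, out)
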