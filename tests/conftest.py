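import numpy as np
import pytest

from tagref.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def clean_dataset():
    """Error-free library with duplicates: exact oracles apply everywhere."""
    cfg = SimConfig(n_loci=30, n_reads=6000, dup_rate=0.8, error_rate=0.0, seed=11)
    transcriptome, reads, truth = simulate_dataset(cfg)
    return cfg, transcriptome, reads, truth


@pytest.fixture(scope="session")
def noisy_dataset():
    """Small library with sequencing error and duplication."""
    cfg = SimConfig(n_loci=40, n_reads=8000, dup_rate=1.0, error_rate=0.005, seed=23)
    transcriptome, reads, truth = simulate_dataset(cfg)
    return cfg, transcriptome, reads, truth


def make_read(bases: str, read_id: str = "r1", qual: int = 40):
    from tagref.iolib import SequencingRead

    return SequencingRead(read_id, bases, np.full(len(bases), qual, dtype=np.uint8))
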