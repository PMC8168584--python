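import numpy as np
import pytest

from ascav.motifs import PWM
from ascav.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def toy_pwm():
    """Length-4 PWM with consensus ACGT and exact +1/-1 log2-odds.

    p(consensus) = 4/7, p(other) = 1/7 against background 2/7 gives
    log2(2) = +1 at the consensus base and log2(1/2) = -1 elsewhere, so
    a perfect 4-bp site scores exactly 4 and a 1-bp disruption 2.
    """
    m = np.full((4, 4), 1 / 7)
    for i, b in enumerate("ACGT"):
        m[i, "ACGT".index(b)] = 4 / 7
    return PWM("toy_acgt", m, background=np.full(4, 2 / 7), pseudocount=0.0)


@pytest.fixture(scope="session")
def toy_pwm_aacg():
    """Non-palindromic variant (consensus AACG) for reverse-strand checks."""
    m = np.full((4, 4), 1 / 7)
    for i, b in enumerate("AACG"):
        m[i, "ACGT".index(b)] = 4 / 7
    return PWM("toy_aacg", m, background=np.full(4, 2 / 7), pseudocount=0.0)


@pytest.fixture(scope="session")
def small_bundle():
    """A miniature diploid dataset shared across tests (seeded)."""
    cfg = SimConfig(seed=3, n_chroms=2, chrom_length=60_000, n_peaks=40)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def snv_only_bundle():
    """Indel-free dataset: read origins are decided purely by het SNVs."""
    cfg = SimConfig(seed=5, n_chroms=1, chrom_length=50_000, n_peaks=30, indel_rate=0.0)
    return simulate_dataset(cfg)
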