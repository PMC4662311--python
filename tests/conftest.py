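import numpy as np
import pytest

from scatcap.dtypes import GenotypeTable
from scatcap.simulate import SimulationConfig


@pytest.fixture(scope="session")
def fixture_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def fixture_freqs(fixture_config):
    return fixture_config.freqs()


@pytest.fixture
def biallelic_pair_table() -> GenotypeTable:
    """Two individuals, both heterozygous A/B at one locus."""
    return GenotypeTable(
        ["i1", "i2"], ["L1"], {("i1", "L1"): (100, 102), ("i2", "L1"): (100, 102)}
    )


def hwe_genotype_probs(p: dict) -> dict:
    """Unordered genotype -> HWE probability, for enumeration oracles."""
    alleles = sorted(p)
    out = {}
    for i, a in enumerate(alleles):
        for b in alleles[i:]:
            out[(a, b)] = p[a] ** 2 if a == b else 2 * p[a] * p[b]
    return out
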