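import numpy as np
import pytest

from coocnet.datatypes import AbundanceTable, SampleMetadata, TaxonRecord
from coocnet.simulate import SimulationConfig, plant_network, simulate_counts


@pytest.fixture(scope="session")
def small_sim():
    """One modest synthetic dataset shared across read-only tests."""
    cfg = SimulationConfig(
        p_bacteria=25, p_phototroph=10, p_fungus=5, n_samples=120, seed=5
    )
    net = plant_network(cfg)
    return cfg, net, simulate_counts(net, cfg)


def make_table(counts, marker="16S", domain="bacteria", prefix="T"):
    counts = np.asarray(counts)
    taxa = [
        TaxonRecord(f"{prefix}{i}", domain) for i in range(counts.shape[0])
    ]
    samples = [f"S{j}" for j in range(counts.shape[1])]
    return AbundanceTable(counts, taxa, samples, marker)


@pytest.fixture
def tiny_16s():
    return make_table([[5, 0, 2], [1, 1, 0], [3, 4, 9]])


@pytest.fixture
def tiny_meta():
    return [
        SampleMetadata(f"S{j}", "Otemma", "GFS", "pre2000", {"ph": 7.0 + j})
        for j in range(3)
    ]
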