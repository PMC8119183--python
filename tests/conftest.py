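import numpy as np
import pytest

from cytobarcode import (
    SimulationConfig,
    generate_complete_scheme,
    simulate_barcoded_events,
)


@pytest.fixture(scope="session")
def scheme10():
    """The complete 5-choose-3 10-plex scheme."""
    return generate_complete_scheme()


@pytest.fixture(scope="session")
def clean_batch(scheme10):
    """Default-noise 10-plex batch, no doublets or dead cells, fixed seed."""
    cfg = SimulationConfig(events_per_sample=300, seed=42)
    return simulate_barcoded_events(scheme10, cfg)


@pytest.fixture(scope="session")
def doublet_batch(scheme10):
    """Default-noise 10-plex batch with 5% doublets and 2% dead cells."""
    cfg = SimulationConfig(
        events_per_sample=300, doublet_rate=0.05, dead_rate=0.02, seed=7
    )
    return simulate_barcoded_events(scheme10, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
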