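import numpy as np
import pytest

from igem.config import SimConfig


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Down-scaled study for fast unit tests (3 fields, small rasters,
    fewer probes/sites); effect structure identical to the defaults."""
    return SimConfig(
        seed=11,
        n_fields_per_well=3,
        image_size=(192, 192),
        n_nuclei_per_field=8,
        n_probes=6000,
        n_rrbs_sites=15000,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
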