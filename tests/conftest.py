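import numpy as np
import pytest

from nucleoscape.synthetic_microscopy import GenerationConfig, generate_nuclei_dataset


def fast_config(**overrides) -> GenerationConfig:
    """A small, quick-to-render configuration for unit tests."""
    kwargs = dict(
        n_nuclei=6,
        chromocenter_count_law=("poisson", 5.0),
        chromocenter_volume_law=("lognormal", 6.0, 1.8),
        locus_spots_per_nucleus=2,
        seed=123,
    )
    kwargs.update(overrides)
    return GenerationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_dataset():
    """Six rendered nuclei with ground truth, shared across tests."""
    return generate_nuclei_dataset(fast_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
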