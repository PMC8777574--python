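import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from woodvar.simulate import SimulationConfig, generate_dataset


def small_config(**overrides) -> SimulationConfig:
    """A quick-to-generate study-like configuration for unit tests."""
    base = dict(
        n_lots=4,
        n_subsamples_per_lot=4,
        n_replicates_per_subsample=2,
        n_scans_per_replicate=12,
        wavenumber_start=3880.0,
        wavenumber_end=9000.0,
        wavenumber_step=16.0,
        seed=11,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def zero_variance_config(**overrides) -> SimulationConfig:
    """All random effects, scatter, noise and BWC spread switched off."""
    base = dict(
        variance_components={"lot": 0.0, "subsample": 0.0, "replicate": 0.0, "scan": 0.0},
        scatter_slope_sd=0.0,
        scatter_offset_sd=0.0,
        additive_noise_sd=0.0,
        bwc_sd_lot=0.0,
        bwc_sd_subsample=0.0,
        bwc_dup_sd=0.0,
    )
    base.update(overrides)
    return small_config(**base)


@pytest.fixture(scope="session")
def small_bundle():
    """(dataset, bwc, truth) for a small default-variability simulation."""
    return generate_dataset(small_config())


@pytest.fixture(scope="session")
def flat_bundle():
    """(dataset, bwc, truth) for the zero-variance degenerate case."""
    return generate_dataset(zero_variance_config())
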