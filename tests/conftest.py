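import numpy as np
import pytest

from optpal import PhantomSpec, RunConfig


@pytest.fixture
def small_spec() -> PhantomSpec:
    """Fast default phantom: uniform moderately stiff tissue."""
    return PhantomSpec(
        nx=24,
        ny=24,
        nz=224,
        tissue_modulus_map=49.0,
        tissue_thickness_map=800.0,
        dead_zone_increments=1,
        n_increments=6,
        rng_seed=7,
    )


@pytest.fixture
def noiseless_spec(small_spec) -> PhantomSpec:
    return small_spec.with_(speckle_contrast=0.0, noise_sd=0.0)


@pytest.fixture
def pipeline_config() -> RunConfig:
    """Config with no lateral edge crop (phantoms have no sample edge)."""
    return RunConfig(edge_margin_um=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
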