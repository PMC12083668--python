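import numpy as np
import pytest

from wmbold import SyntheticConfig, make_parcellation, make_streamlines


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(seed=0)


@pytest.fixture(scope="session")
def small_geometry():
    """A small parcellation + streamline set with known ground truth."""
    cfg = SyntheticConfig(
        seed=3,
        grid_shape=(20, 20, 20),
        n_gm_parcels=3,
        n_pseudo_gm_parcels=1,
        n_assoc_bundles=3,
        n_proj_bundles=2,
        streamlines_per_bundle=10,
    )
    parc = make_parcellation(cfg)
    sls = make_streamlines(cfg, parc)
    return cfg, parc, sls


@pytest.fixture
def quiet_config():
    """Noise-free forward model: no fluctuations, no bump, no thermal noise."""
    return SyntheticConfig(
        seed=0,
        oef_fluct_sd=0.0,
        cbv_fluct_sd=0.0,
        bump_amp=0.0,
        noise_sd=0.0,
    )


def rcbv_truth():
    """Printed moderation coefficients for the relative-CBV predictor."""
    return (0.0, 0.57, -0.18, -0.32)
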