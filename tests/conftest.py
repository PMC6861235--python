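import numpy as np
import pytest

import fireadjust as fa


@pytest.fixture
def grid():
    """Small 4x4 grid at 0.25 deg."""
    return fa.GridSpec(resolution=0.25, lat_min=-10.0, lat_max=-9.0,
                       lon_min=-60.0, lon_max=-59.0)


@pytest.fixture
def calendar():
    return fa.AnalysisCalendar()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def coupled_bundle():
    """Seeded coupled-preset fields with known truth on a 10x10 grid."""
    cfg = fa.make_config("coupled", seed=11)
    rngs = cfg.rngs()
    P = fa.generate_precipitation(cfg, rngs)
    F, truth = fa.generate_fire_parameter(cfg, P, rngs)
    mask = fa.synthetic_region_mask(cfg.grid)
    return cfg, P, F, truth, mask
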