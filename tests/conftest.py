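"""Shared fixtures: small simulated measurements reused across test modules."""

import numpy as np
import pytest

from paintbench.model import DyePerformanceModel
from paintbench.sim import SimConfig, SiteLayout


@pytest.fixture(scope="session")
def cy3b_config():
    """A bright green-dye measurement: 600 isolated sites, 500 s at 100 ms frames."""
    layout = SiteLayout.single_sites(600, fov=(140, 140))
    return SimConfig(
        tau_b=0.35,
        tau_d=5.0,
        photon_rate=23195.0,
        bg_rate=237.0,
        n_frames=5000,
        width=140,
        height=140,
        layout=layout,
        seed=3,
    )


@pytest.fixture(scope="session")
def cy3b_results(cy3b_config):
    """Fitted dye-performance results on the bright-dye measurement."""
    model = DyePerformanceModel.from_simulation(
        cy3b_config, min_sites=100, nena_bin_width=None
    )
    return model.fit()


@pytest.fixture(scope="session")
def small_table():
    """A quick, low-traffic localization table (25 sites, 1000 frames)."""
    from paintbench.sim import emit_localizations

    cfg = SimConfig(n_frames=1000, seed=7)
    table, truth = emit_localizations(cfg)
    return table, truth, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
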