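import numpy as np
import pytest

from glycosim import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def valid_config():
    """A small, fully valid 2D configuration."""
    return SimulationConfig(
        global_name="test",
        fov_x=2.0,
        fov_y=2.0,
        prot_dens=25.0,
        lip_dens=25.0,
        prob_n_glycans_prot=[0.5, 0.5],
        prob_n_glycans_lip=[0.9, 0.1],
        prob_n_sias_prot_glycan=[0.2, 0.5, 0.3],
        prob_n_sias_lip_glycan=[0.3, 0.7],
        mu_sias_glycoprot=0.012,
        sigma_sias_glycoprot=0.002,
        mu_sias=0.0025,
        sigma_sias=0.0005,
        forbidden_angle_glycans=0.3,
        cutoff_gaussians=2.0,
        seed=7,
    )
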