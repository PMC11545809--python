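import numpy as np
import pytest

from burstquant import SimConfig


@pytest.fixture
def sim_config_factory():
    """SimConfig builder with fast, noise-free, bleach-free test defaults."""
    def make(**overrides):
        base = dict(
            n_nuclei_side=3,
            field_size_px=128,
            n_z_planes=1,
            n_frames_per_stage=50,
            stage_labels=("nc14",),
            noise_sd=0.0,
            bleach_halflife_s=float("inf"),
            dot_diffusion_px=0.0,
            amp_per_transcript=60.0,
            background_level=10.0,
            seed=0,
        )
        base.update(overrides)
        return SimConfig(**base)
    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
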