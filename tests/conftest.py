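import numpy as np
import pytest

from ptnfall.network import ModelConfig, PatchTransformer
from ptnfall.preprocessing import WindowConfig, build_patch_sequences
from ptnfall.simulate import SimConfig, gen_dataset


@pytest.fixture(scope="session")
def sim_config():
    """Smartphone-scale simulator settings: 3 s @ 50 Hz, 3-axis accelerometer."""
    return SimConfig(seed=7, confounder_fraction=0.2)


@pytest.fixture(scope="session")
def small_manifest(sim_config):
    """20 falls + 20 ADLs, enough to exercise every pipeline stage."""
    return gen_dataset(20, 20, sim_config)


@pytest.fixture(scope="session")
def window_config(sim_config):
    return WindowConfig(window_seconds=2.0, stride_seconds=1.0, fs=sim_config.fs)


@pytest.fixture(scope="session")
def small_sequences(small_manifest, window_config, sim_config):
    return build_patch_sequences(small_manifest, window_config,
                                 sim_config.duration)


@pytest.fixture()
def tiny_model():
    """C=3 network small enough for exhaustive numeric checks."""
    cfg = ModelConfig(channels=3, patch_side=10, seq_len=2, heads=3,
                      layers=2, seed=11)
    return PatchTransformer(cfg)
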