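import numpy as np
import pytest

import fedsense as fs


@pytest.fixture(scope="session")
def delta_batch():
    """One simulated Delta-pool batch with default noise."""
    cfg = fs.SimConfig(**fs.POOL_PRESETS["Delta"])
    return fs.simulate_batch(cfg, seed=11)


@pytest.fixture(scope="session")
def noise_free_batch():
    """Noise-free simulated batch (offline and online noise off)."""
    cfg = fs.SimConfig(**fs.POOL_PRESETS["Delta"])
    cfg.noise_rsd = {k: 0.0 for k in cfg.noise_rsd}
    cfg.online_noise = {k: 0.0 for k in cfg.online_noise}
    return fs.simulate_batch(cfg, seed=7)


@pytest.fixture(scope="session")
def small_campaign():
    """Six-batch campaign (2 per pool) for fast training tests."""
    return fs.generate_dataset(
        {"Delta": 2, "Beta": 2, "WuTL": 2}, base_seed=5, truncate_one=False
    )
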