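import numpy as np
import pytest
from hypothesis import settings as hyp_settings

import idealobs as io

hyp_settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
hyp_settings.load_profile("ci")


@pytest.fixture(scope="session")
def bke_cfg() -> io.TaskConfig:
    """The Gaussian SKS/BKE task with its printed parameters."""
    return io.get_preset("sks_bke_gaussian")


@pytest.fixture(scope="session")
def bke_model(bke_cfg) -> io.AnalyticIOModel:
    return io.AnalyticIOModel.from_task(bke_cfg)


@pytest.fixture(scope="session")
def bke_batch_small(bke_cfg) -> io.ImageBatch:
    """A small evaluation batch reused by quick tests."""
    return io.simulate_batch(bke_cfg, 60, 60, seed=123)


@pytest.fixture(scope="session")
def bks_cfg() -> io.TaskConfig:
    return io.get_preset("sks_bks_lumpy")
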