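import numpy as np
import pytest

from hearaid import (
    DEFAULT_AUDIOGRAM,
    DEFAULT_COMPRESSION,
    EngineConfig,
    map_bands,
)
from hearaid.filter_bank import build_filter_bank


@pytest.fixture(scope="session")
def cfg():
    return EngineConfig()


@pytest.fixture(scope="session")
def cal_cfg():
    """Config calibrated so a full-scale sine reads ~97 dB (field-like)."""
    return EngineConfig(calibration_offset_db=100.0)


@pytest.fixture(scope="session")
def params():
    return DEFAULT_COMPRESSION


@pytest.fixture(scope="session")
def audiogram():
    return DEFAULT_AUDIOGRAM


@pytest.fixture(scope="session")
def band_plan(audiogram):
    plan, _ = map_bands(audiogram)
    return plan


@pytest.fixture(scope="session")
def filter_bank(params, band_plan, cfg):
    return build_filter_bank(params, band_plan, cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251001)
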