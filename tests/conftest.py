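import numpy as np
import pytest

from pulsefeat import PipelineConfig, SimConfig, measure_record, simulate_record


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def sim_record():
    """One clean 12-s dual-channel record with known ground truth."""
    cfg = SimConfig(duration=12.0, target_inv_fwhm=8.0, channel_delay=0.012,
                    seed=42)
    return simulate_record(cfg)


@pytest.fixture(scope="session")
def sim_result(sim_record):
    record, _ = sim_record
    return measure_record(record)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
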