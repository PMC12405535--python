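import numpy as np
import pytest

from sensorscreen import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_experiment():
    """A small noiseless experiment shared by quantification tests."""
    on = {f"S{i:03d}": f for i, f in zip(range(5, 11), [0.0, 0.01, 0.1, 0.5, 1.0, 0.3])}
    config = synthetic.SimConfig(
        n_sensors=10,
        abundance_sigma=0.3,
        true_on_fraction={"cond": on},
        seed=11,
    )
    truth, samples = synthetic.simulate_experiment(config, noiseless=True)
    return config, truth, samples["cond"]
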