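import pytest

from barrelsim import ModelParams, StimulusSpec, build_wiring, run_condition


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def wiring(params):
    return build_wiring(params, seed=1)


@pytest.fixture(scope="session")
def fast_trials(wiring, params):
    """A small pre-adaptation trial set at the preferred direction, sigma 1."""
    spec = StimulusSpec(direction_deg=0, sigma_ms=1.0)
    return run_condition(wiring, params, spec, n_trials=30, base_seed=123)
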