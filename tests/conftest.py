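import numpy as np
import pytest

import apakit as ak


@pytest.fixture(scope="session")
def schedule():
    return ak.build_schedule(ak.ParadigmConfig(seed=3))


@pytest.fixture(scope="session")
def supine_run(schedule):
    """10 unsupported supine trials with ground truth (default noise)."""
    return ak.simulate_run("supine", ak.SupineTrialParams(seed=11), schedule,
                           n_trials=10)


@pytest.fixture(scope="session")
def step_run(schedule):
    """5 unsupported step trials with ground truth (default noise)."""
    return ak.simulate_run("step", ak.StepTrialParams(seed=11), schedule,
                           n_trials=5)


@pytest.fixture
def noiseless_supine(schedule):
    def make(condition="unsupported", trial=0, **kw):
        params = ak.SupineTrialParams(noise_sd=0.0, condition=condition,
                                      seed=7, **kw)
        return ak.simulate_supine_trial(params,
                                        schedule.events.for_trial(trial))
    return make


@pytest.fixture
def noiseless_step(schedule):
    def make(condition="unsupported", trial=0, **kw):
        params = ak.StepTrialParams(noise_sd_force=0.0, noise_sd_marker=0.0,
                                    condition=condition, seed=7, **kw)
        return ak.simulate_step_trial(params,
                                      schedule.events.for_trial(trial))
    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
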