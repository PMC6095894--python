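import numpy as np
import pytest

from cellsizer import MechanisticMode, ModelParams, simulate_lineages

MEAN_BIRTH = float(np.exp(ModelParams().mean_log_birth_volume))


def _archetype_table(mode: str, mode_sd: float, seed: int, **param_kw):
    params = ModelParams.stationary_defaults(**param_kw)
    # ~16k cycles (n >= 5000): keeps Monte-Carlo error on binned slopes small
    return simulate_lineages(
        params,
        MechanisticMode(mode=mode, mode_sd=mode_sd),
        n_founders=8,
        n_generations=11,
        seed=seed,
    )


@pytest.fixture(scope="session")
def sizer_table():
    # fixed target mitotic volume (twice the mean birth volume), CV 5%
    return _archetype_table("sizer", 0.05 * 2 * MEAN_BIRTH, seed=101)


@pytest.fixture(scope="session")
def adder_table():
    # added volume = mean birth volume, CV 15%, symmetric division
    return _archetype_table("adder", 0.15 * MEAN_BIRTH, seed=106)


@pytest.fixture(scope="session")
def timer_table():
    # size-independent duration, CV 10%, constant growth rate
    return _archetype_table("timer", 0.10 * 15.0, seed=103)


@pytest.fixture(scope="session")
def mech_adder_table():
    # nearly constant total added volume, random split over phases
    return _archetype_table("mechanistic_adder", 0.03 * MEAN_BIRTH, seed=104)
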