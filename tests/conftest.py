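import numpy as np
import pytest

from clincrowd import generator, pipeline
from clincrowd.core import CONTROL, NETWORK, TrialConfig


@pytest.fixture(scope="session")
def default_config():
    return pipeline.StudyConfig(master_seed=11)


@pytest.fixture(scope="session")
def small_config():
    """Two vignettes x (2 network + 1 control): fast end-to-end fixture."""
    return pipeline.StudyConfig(
        vignettes=pipeline.DEFAULT_VIGNETTES[:2],
        n_network=2,
        n_control=1,
        master_seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generator.simulate_study(
        small_config.vignettes,
        small_config.generator,
        n_network=small_config.n_network,
        n_control=small_config.n_control,
        master_seed=small_config.master_seed,
    )


@pytest.fixture(scope="session")
def default_study(default_config):
    return generator.simulate_study(
        default_config.vignettes,
        default_config.generator,
        n_network=default_config.n_network,
        n_control=default_config.n_control,
        master_seed=default_config.master_seed,
    )


def make_trial_config(condition=CONTROL, truth=30.0, n_clinicians=4, n_rounds=3):
    return TrialConfig(
        vignette_id="vx",
        condition=condition,
        truth=truth,
        options=("discharge", "observation_unit", "admit"),
        correct_option="observation_unit",
        n_clinicians=n_clinicians,
        n_rounds=n_rounds,
    )
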