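import dataclasses

import pytest
from hypothesis import HealthCheck, settings

import couchcorr as cc

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def presets():
    return cc.scenario_presets()


def _noise_free(config):
    return dataclasses.replace(config, noise_rms=0.0)


@pytest.fixture(scope="session")
def dibh_sim(presets):
    """Noise-free worst-case helical DIBH simulation."""
    return cc.simulate(_noise_free(presets["phantom_dibh_104kg"]))


@pytest.fixture(scope="session")
def fourd_sim(presets):
    """Noise-free worst-case axial 4DCT simulation."""
    return cc.simulate(_noise_free(presets["phantom_4dct_104kg"]))


@pytest.fixture(scope="session")
def dibh_corrected(dibh_sim):
    return cc.correct_streams(
        dibh_sim.patient, dibh_sim.table, xray_events=dibh_sim.truth.events
    )


@pytest.fixture(scope="session")
def fourd_corrected(fourd_sim):
    return cc.correct_streams(
        fourd_sim.patient, fourd_sim.table, xray_events=fourd_sim.truth.events
    )
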