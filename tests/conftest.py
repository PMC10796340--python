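import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import spastigen as sg

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort():
    return sg.load_reference_cohort()


@pytest.fixture(scope="session")
def patient1(cohort):
    return cohort[0]


@pytest.fixture(scope="session")
def skeleton1(patient1):
    return sg.build_skeleton(patient1.anthropometry)


@pytest.fixture(scope="session")
def marker_map():
    return sg.default_marker_map()


@pytest.fixture(scope="session")
def elbow_movement():
    return sg.get_movement("elbow_flexion_extension")


@pytest.fixture(scope="session")
def elbow_trajectory(elbow_movement):
    return sg.synthesize_trajectory(elbow_movement)


@pytest.fixture(scope="session")
def elbow_markers(skeleton1, elbow_trajectory):
    return sg.forward_kinematics(skeleton1, elbow_trajectory)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240918)
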