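from dataclasses import replace

import pytest

from mlklswitch.synthetic import CONSTRUCT_PRESETS, TrajectoryGenParams, generate_trajectory_ensemble
from mlklswitch.trajectory_io import DomainAnnotation


@pytest.fixture(scope="session")
def annotation() -> DomainAnnotation:
    return DomainAnnotation()


@pytest.fixture(scope="session")
def small_params() -> TrajectoryGenParams:
    """Three short wild-type-like replicates — fast unit-test scale."""
    return replace(CONSTRUCT_PRESETS["WT"], n_replicates=3, n_frames=50, seed=11)


@pytest.fixture(scope="session")
def small_ensemble(small_params):
    return generate_trajectory_ensemble(small_params)


@pytest.fixture(scope="session")
def recovery_params() -> TrajectoryGenParams:
    """The full study-design scale: 10 replicates x 1000 frames, WT scenario
    (loop helix 65 ± 5 degrees, H-bond probability 0.14)."""
    return replace(CONSTRUCT_PRESETS["WT"], seed=202)


@pytest.fixture(scope="session")
def recovery_ensemble(recovery_params):
    return generate_trajectory_ensemble(recovery_params)
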