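import numpy as np
import pytest

from dyskrep import AccelSession, SyntheticParams, generate_cohort


def make_sine_session(
    freq: float = 2.0,
    duration: float = 12.0,
    sample_rate: float = 50.0,
    amplitude: float = 1.0,
    axis: int = 0,
    gravity: float = 1.0,
    label: int = 0,
    session_id: str = "sine",
) -> AccelSession:
    """Pure-sine oscillation on one axis with gravity on z."""
    t = np.arange(int(round(duration * sample_rate)) + 1) / sample_rate
    acc = np.zeros((len(t), 3))
    acc[:, axis] = amplitude * np.sin(2 * np.pi * freq * t)
    acc[:, 2] += gravity
    return AccelSession(
        session_id=session_id, subject_id="subj", dataset_tag="test",
        task_tag="UPDRS_3_6", sample_rate=sample_rate, timestamps=t,
        acc=acc, label=label,
    )


@pytest.fixture
def sine_session() -> AccelSession:
    return make_sine_session()


@pytest.fixture(scope="session")
def small_cohort():
    """A ~40-session synthetic cohort with strong dyskinesia effect."""
    params = SyntheticParams(n_subjects=10, seed=21)
    manifest, sessions = generate_cohort(params, dataset_tag="test")
    return manifest, sessions


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random proper rotation matrix."""
    M = np.linalg.qr(rng.standard_normal((3, 3)))[0]
    if np.linalg.det(M) < 0:
        M[:, 0] *= -1
    return M
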