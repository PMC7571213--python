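import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gaitconcord.core import SkeletonSequence

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def make_sequence(rng):
    """Factory for random, optionally gappy, sequences."""

    def _make(n_frames=50, joints=("pelvis", "ankle_left"), rate=100.0, missing_frac=0.0,
              irregular=False):
        if irregular:
            dt = rng.uniform(0.5, 1.5, size=n_frames - 1) / rate
            t = np.concatenate([[0.0], np.cumsum(dt)])
        else:
            t = np.arange(n_frames) / rate
        pos = rng.normal(0.0, 100.0, size=(n_frames, len(joints), 3))
        if missing_frac > 0:
            mask = rng.random((n_frames, len(joints))) < missing_frac
            pos[mask] = np.nan
        return SkeletonSequence(
            system_id="test",
            joint_names=list(joints),
            timestamps=t,
            positions=pos,
            nominal_rate=None if irregular else rate,
        )

    return _make
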