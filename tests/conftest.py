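import numpy as np
import pytest

import steadywalk as sw


@pytest.fixture
def spec() -> sw.ExerciseSpec:
    return sw.ExerciseSpec()


@pytest.fixture
def template() -> sw.PostureTemplate:
    return sw.upright_template()


@pytest.fixture
def config() -> sw.ThresholdConfig:
    return sw.ThresholdConfig()


@pytest.fixture(scope="session")
def clean_stream() -> sw.SkeletonStream:
    """Noiseless, impairment-free walk over the default 5 m course."""
    return sw.walking_stream(
        sw.WalkerParams(noise_sd=0.0, seed=1), sw.ExerciseSpec()
    )


@pytest.fixture
def upright_frame() -> sw.SkeletonFrame:
    """One ideal upright frame at the default start line."""
    return sw.standing_frames(
        sw.WalkerParams(noise_sd=0.0, seed=0), duration=0.1
    ).frames[0]


@pytest.fixture
def make_random_frame():
    """Factory for frames with arbitrary (finite) joint positions."""

    def _make(rng: np.random.Generator, t: float = 0.0) -> sw.SkeletonFrame:
        return sw.SkeletonFrame(
            t=t,
            joints={
                name: sw.Joint(name, *rng.uniform(-1.5, 3.0, size=3))
                for name in sw.JOINT_ORDER
            },
        )

    return _make
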