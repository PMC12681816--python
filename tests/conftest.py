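import numpy as np
import pytest

from meaburst.core import Recording, SpikeTrain


def random_train(rng: np.random.Generator, n_max: int = 50, duration: float = 10.0,
                 unit_id: int = 0) -> SpikeTrain:
    n = int(rng.integers(1, n_max + 1))
    return SpikeTrain(unit_id, np.sort(rng.uniform(0, duration, n)), duration)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    duration = 30.0
    trains = {
        uid: SpikeTrain(uid, np.sort(rng.uniform(0, duration, 40)), duration,
                        position=(float(uid) * 10, 5.0))
        for uid in range(4)
    }
    return Recording(trains, duration, 20000.0)
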