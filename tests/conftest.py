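import numpy as np
import pytest

from swallow_ersp.containers import EpochedRecording
from swallow_ersp.synthgen import GroupProfile, _generate_trials_batch
from swallow_ersp.tfr import make_wavelet_plan


@pytest.fixture(scope="session")
def plan512():
    return make_wavelet_plan(rate=512.0)


def make_epochs(profile: GroupProfile, channel: str = "C3", n_trials: int = 50,
                rate: float = 512.0, seed: int = 1234,
                duration_ms: float = 6000.0, tmin_ms: float = -1000.0
                ) -> EpochedRecording:
    """Single-channel trial ensemble straight from the signal model."""
    rng = np.random.Generator(np.random.Philox(key=[seed, 0]))
    n = int(round(duration_ms * rate / 1000.0))
    trials = _generate_trials_batch(profile, channel, n_trials, n, rate,
                                    tmin_ms, rng)
    return EpochedRecording(data=trials[:, None, :], rate=rate,
                            channel_labels=[channel], tmin_ms=tmin_ms)


@pytest.fixture(scope="session")
def healthy_alpha_epochs():
    """200-trial healthy-preset ensemble used by the plateau-recovery tests."""
    from swallow_ersp.synthgen import group_preset
    return make_epochs(group_preset("healthy"), n_trials=200, seed=77)
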