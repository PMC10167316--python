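import numpy as np
import pytest

from eegvuln.containers import EpochSet, Recording
from eegvuln.montage import build_montage


@pytest.fixture(scope="session")
def montage():
    return build_montage(neighbor_k=4)


def make_recording(data, fs=512.0, roles=None, group="high", subject_id="S01"):
    n_ch = data.shape[0]
    names = tuple(f"ch{i}" for i in range(n_ch))
    roles = roles or ("scalp",) * n_ch
    return Recording(data=data, fs=fs, channel_names=names, channel_roles=roles,
                     subject_id=subject_id, group=group)


def make_epochs(data, fs=512.0, tmin=-0.5, roles=None, names=None, group="high", subject_id="S01"):
    """EpochSet from a (trials, channels, time) array with generic channel names."""
    n_ch = data.shape[1]
    names = names or tuple(f"ch{i}" for i in range(n_ch))
    roles = roles or ("scalp",) * n_ch
    return EpochSet(data=data, tmin_s=tmin, fs=fs, channel_names=names,
                    channel_roles=roles, subject_id=subject_id, group=group)


def sine_epochs(freq_hz, fs=512.0, n_trials=3, n_ch=2, dur_s=2.0, amp=1.0, phase=0.0):
    t = np.arange(int(dur_s * fs)) / fs
    x = amp * np.sin(2 * np.pi * freq_hz * t + phase)
    data = np.tile(x, (n_trials, n_ch, 1))
    return make_epochs(data, fs=fs, tmin=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
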