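import numpy as np
import pytest

from mmndecode.containers import Event, Recording
from mmndecode.montage import Montage, make_standard_montage


@pytest.fixture(scope="session")
def montage():
    return make_standard_montage()


@pytest.fixture(scope="session")
def small_montage():
    """Eight scalp channels + 2 mastoids + 1 EOG on the unit sphere."""
    rng = np.random.default_rng(7)
    n = 11
    z = np.linspace(0.95, 0.1, n)
    r = np.sqrt(1 - z**2)
    theta = rng.uniform(0, 2 * np.pi, n)
    pos = np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)
    labels = tuple(f"E{i}" for i in range(8)) + ("M1", "M2", "EOG")
    roles = ("eeg",) * 8 + ("mastoid", "mastoid", "eog")
    return Montage(labels, pos, roles)


def _make_recording(montage, n_events=6, fs=256.0, seed=0, isi_ms=500.0):
    rng = np.random.default_rng(seed)
    n_samples = int((n_events + 2) * isi_ms / 1000.0 * fs)
    signal = rng.normal(0, 5.0, size=(len(montage), n_samples))
    events = []
    for i in range(n_events):
        sample = int((i + 1) * isi_ms / 1000.0 * fs)
        label = "deviant" if i % 3 == 2 else "standard"
        events.append(Event(sample, label))
    return Recording(fs, signal, montage, events, meta={"subject": 0})


@pytest.fixture()
def recording(small_montage):
    return _make_recording(small_montage)


@pytest.fixture()
def make_recording():
    return _make_recording
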