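import numpy as np
import pandas as pd
import pytest

from eegdecode.preprocess import EpochSet
from eegdecode.synthetic import SimConfig, make_class_patterns, simulate_labelled_epochs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_epochs(
    n_chunks=6,
    n_channels=8,
    snr=0.0,
    seed=0,
    fs_hz=250.0,
    window_ms=(-100.0, 500.0),
    onset_ms=100.0,
    duration_ms=300.0,
    patterns=None,
):
    """Small labelled epoch set: one epoch per target stimulus per chunk."""
    cfg = SimConfig(
        n_channels=n_channels,
        evoked_snr=snr,
        evoked_onset_ms=onset_ms,
        evoked_duration_ms=duration_ms,
        seed=seed,
    )
    gen = np.random.default_rng(seed)
    return simulate_labelled_epochs(
        n_chunks, cfg, gen, fs_hz=fs_hz, window_ms=window_ms, patterns=patterns
    )


@pytest.fixture
def null_epochs():
    return make_epochs(n_chunks=6, snr=0.0, seed=11)


@pytest.fixture
def signal_epochs():
    return make_epochs(n_chunks=6, snr=4.0, seed=12)


def constant_pattern_epochs(
    n_per_class=8, n_channels=4, n_times=40, amp=5.0, seed=0, n_chunks=4
):
    """Epochs whose two categories differ by a fixed spatial pattern at all
    times — a fully deterministic, separable toy."""
    gen = np.random.default_rng(seed)
    pat = np.zeros(n_channels)
    pat[0] = 1.0
    data, rows = [], []
    for i in range(2 * n_per_class):
        cls = i % 2
        x = gen.standard_normal((n_channels, n_times)) * 0.1
        x += (amp if cls else -amp) * pat[:, None]
        data.append(x)
        rows.append(
            dict(
                epoch_role="vision",
                stimulus_id=f"{'place' if cls else 'face'}1",
                category="place" if cls else "face",
                exemplar=0,
                chunk=f"c{i % n_chunks}",
                subject="sub-01",
            )
        )
    times = np.arange(n_times) * 4.0
    return EpochSet(data=np.stack(data), times_ms=times, labels=pd.DataFrame(rows))
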