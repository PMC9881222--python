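import numpy as np
import pytest

from somnophot.simulate import SimConfig, simulate_recording

# test-suite acquisition rates: 200 Hz EEG/EMG, 50 Hz photometry keep the
# suite fast; all analysis windows are in seconds so nothing depends on them
TEST_EEG_RATE = 200.0
TEST_PHOT_RATE = 50.0


def make_config(**overrides) -> SimConfig:
    base = dict(
        seed=0,
        duration=2700.0,
        eeg_rate=TEST_EEG_RATE,
        emg_rate=TEST_EEG_RATE,
        photometry_rate=TEST_PHOT_RATE,
    )
    base.update(overrides)
    return SimConfig(**base)


def majority_epoch_labels(second_labels: np.ndarray, epoch_len: int, n_epochs: int) -> np.ndarray:
    """Ground-truth epoch label = majority state of the epoch's seconds."""
    out = np.empty(n_epochs, dtype="<U4")
    for i in range(n_epochs):
        seg = second_labels[i * epoch_len : (i + 1) * epoch_len]
        states, counts = np.unique(seg, return_counts=True)
        out[i] = states[np.argmax(counts)]
    return out


@pytest.fixture(scope="session")
def two_hour_recording():
    """A 2-h default synthetic session (no injected EMG bursts)."""
    cfg = make_config(seed=11, duration=7200.0)
    rec, truth = simulate_recording(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def burst_recording(two_hour_recording):
    """Same session with EMG bursts injected mid-bout in NREM and wake."""
    cfg, _, truth = two_hour_recording
    lab = truth.second_labels
    burst_times = []
    for state in ("nrem", "wake"):
        placed = 0
        for s, start, dur in truth.bouts:
            if s == state and dur >= 80 and placed < 2 and start > 120:
                burst_times.append((float(start + dur // 2), 10.0, 2.0))
                placed += 1
    assert len(burst_times) >= 3
    cfg_b = make_config(seed=11, duration=7200.0, emg_bursts=tuple(burst_times))
    rec_b, truth_b = simulate_recording(cfg_b)
    # the hypnogram stream is independent of burst config
    assert np.array_equal(truth_b.second_labels, lab)
    return cfg_b, rec_b, truth_b
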