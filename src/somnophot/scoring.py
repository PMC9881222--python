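"""Vigilance-state scoring and transition/sub-state detection.

Scoring follows the conventional rodent decision tree in 4-s epochs:
epochs with supra-threshold EMG are wake; among the rest, a high
theta/delta power ratio marks REM and the remainder is NREM.  Epoch
labels are then expanded to 1-s resolution (with an optional
EMG-driven refinement of wake onsets), transitions between states are
detected with a minimum-following-bout rule (30 s for spontaneous
NREM-to-wake awakenings), and within-state EMG threshold crossings
(threshold = within-state mean + k·SD of the 1-s EMG metric, k = 10)
mark active-awake onsets in wake and micro-awakenings in NREM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as spsig

from .io import Recording

__all__ = [
    "Hypnogram",
    "TransitionEvent",
    "SubstateOnset",
    "ScoringThresholds",
    "epoch_features",
    "calibrate_thresholds",
    "classify_epochs",
    "refine_to_seconds",
    "detect_transitions",
    "detect_substate_onsets",
    "emg_metric_1s",
    "score_recording",
]

logger = logging.getLogger(__name__)

DELTA_BAND = (0.5, 4.0)
THETA_BAND = (6.0, 9.0)
EMG_BAND = (10.0, 100.0)

UNSCORABLE = "unsc"


@dataclass
class Hypnogram:
    """Epoch-level and per-second vigilance-state labels with features."""

    epoch_labels: np.ndarray
    epoch_len: float = 4.0
    features: pd.DataFrame | None = None
    second_labels: np.ndarray | None = None
    provenance: str = "scored"

    @property
    def n_epochs(self) -> int:
        return len(self.epoch_labels)


@dataclass
class TransitionEvent:
    time: float
    from_state: str
    to_state: str
    bout_duration_after: float
    evoked: bool = False


@dataclass
class SubstateOnset:
    time: float
    kind: str  # active_awake_onset | micro_awakening
    parent_state: str
    threshold_used: float


@dataclass
class ScoringThresholds:
    """Decision-tree thresholds; ``emg_rms`` in the EMG metric's units,
    ``theta_delta_ratio`` dimensionless."""

    emg_rms: float
    theta_delta_ratio: float = 2.0
    smooth: bool = True


def _bandpower(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    sel = (freqs >= lo) & (freqs <= hi)
    if not sel.any():
        return np.zeros(psd.shape[0])
    return np.trapezoid(psd[:, sel], freqs[sel], axis=1)


def _bandpass_emg(emg: np.ndarray, rate: float) -> np.ndarray:
    hi = min(EMG_BAND[1], 0.45 * rate)
    sos = spsig.butter(4, [EMG_BAND[0], hi], btype="bandpass", fs=rate, output="sos")
    return spsig.sosfiltfilt(sos, emg)


def epoch_features(
    eeg: np.ndarray,
    emg: np.ndarray,
    eeg_rate: float,
    emg_rate: float | None = None,
    epoch_len: float = 4.0,
) -> pd.DataFrame:
    """Per-epoch spectral and EMG features.

    Delta (0.5-4 Hz) and theta (6-9 Hz) band powers come from a Welch
    periodogram (Hann window, one segment per epoch); total power spans
    0.5 Hz to Nyquist.  ``emg_rms`` is the RMS of 10-100 Hz band-passed
    EMG per epoch.  A trailing partial epoch is dropped with a log
    message.
    """
    if epoch_len < 2.0 / DELTA_BAND[0]:
        raise ValueError(
            f"epoch_len {epoch_len} shorter than two cycles of the "
            f"{DELTA_BAND[0]}-Hz delta lower edge"
        )
    emg_rate = emg_rate or eeg_rate
    spe = int(round(epoch_len * eeg_rate))
    spm = int(round(epoch_len * emg_rate))
    n_ep = min(len(eeg) // spe, len(emg) // spm)
    if n_ep == 0:
        raise ValueError("signals shorter than one epoch")
    if len(eeg) % spe or len(emg) % spm:
        logger.warning("trailing partial epoch dropped (%d full epochs kept)", n_ep)

    eeg_ep = np.asarray(eeg[: n_ep * spe], dtype=float).reshape(n_ep, spe)
    freqs, psd = spsig.welch(eeg_ep, fs=eeg_rate, window="hann", nperseg=spe, axis=1)
    delta = _bandpower(freqs, psd, DELTA_BAND)
    theta = _bandpower(freqs, psd, THETA_BAND)
    total = _bandpower(freqs, psd, (DELTA_BAND[0], eeg_rate / 2.0))

    emg_f = _bandpass_emg(np.asarray(emg[: n_ep * spm], dtype=float), emg_rate)
    emg_rms = np.sqrt(np.mean(emg_f.reshape(n_ep, spm) ** 2, axis=1))

    return pd.DataFrame(
        {
            "epoch": np.arange(n_ep),
            "t_start": np.arange(n_ep) * epoch_len,
            "delta_power": delta,
            "theta_power": theta,
            "total_power": total,
            "emg_rms": emg_rms,
        }
    )


def _otsu_threshold(values: np.ndarray) -> float:
    """Otsu's between-class variance split on log-scaled values."""
    x = np.log(np.maximum(values, 1e-12))
    hist, edges = np.histogram(x, bins=128)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(float)
    total = w.sum()
    best, best_t = -1.0, centers[len(centers) // 2]
    c_w = np.cumsum(w)
    c_m = np.cumsum(w * centers)
    m_tot = c_m[-1]
    for i in range(1, len(centers)):
        w0, w1 = c_w[i - 1], total - c_w[i - 1]
        if w0 == 0 or w1 == 0:
            continue
        m0, m1 = c_m[i - 1] / w0, (m_tot - c_m[i - 1]) / w1
        v = w0 * w1 * (m0 - m1) ** 2
        if v > best:
            best, best_t = v, 0.5 * (centers[i - 1] + centers[i])
    return float(np.exp(best_t))


def calibrate_thresholds(features: pd.DataFrame) -> ScoringThresholds:
    """Data-driven thresholds: Otsu split of the bimodal log EMG-RMS
    distribution; the theta/delta ratio threshold stays at its default."""
    return ScoringThresholds(emg_rms=_otsu_threshold(features["emg_rms"].to_numpy()))


def classify_epochs(
    features: pd.DataFrame, thresholds: ScoringThresholds | None = None, epoch_len: float = 4.0
) -> Hypnogram:
    """Rule-based epoch scoring.

    High EMG ⇒ wake; otherwise theta/delta above threshold ⇒ REM, else
    NREM.  Epochs with non-finite features are flagged unscorable.
    With ``thresholds.smooth``, an isolated single REM epoch flanked by
    wake is relabeled wake.  Deterministic given thresholds.
    """
    thr = thresholds or calibrate_thresholds(features)
    emg = features["emg_rms"].to_numpy()
    delta = features["delta_power"].to_numpy()
    theta = features["theta_power"].to_numpy()
    n = len(features)
    labels = np.empty(n, dtype="<U4")
    finite = np.isfinite(emg) & np.isfinite(delta) & np.isfinite(theta)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(delta > 0, theta / delta, np.inf)
    labels[:] = UNSCORABLE
    wake = finite & (emg > thr.emg_rms)
    rem = finite & ~wake & (ratio > thr.theta_delta_ratio)
    nrem = finite & ~wake & ~rem
    labels[wake], labels[rem], labels[nrem] = "wake", "rem", "nrem"
    if thr.smooth:
        for i in range(1, n - 1):
            if labels[i] == "rem" and labels[i - 1] == "wake" and labels[i + 1] == "wake":
                labels[i] = "wake"
    return Hypnogram(epoch_labels=labels, epoch_len=epoch_len, features=features)


def refine_to_seconds(
    hypnogram: Hypnogram,
    emg_metric: np.ndarray | None = None,
    emg_threshold: float | None = None,
    boundary_refinement: bool = False,
) -> np.ndarray:
    """Expand epoch labels to 1-s labels (each 4-s epoch → 4 seconds).

    With ``boundary_refinement`` and a per-second EMG metric, a wake
    onset moves earlier within the preceding epoch to the first second
    whose metric crosses the wake threshold — boundaries shift by at
    most one epoch and the set of states present never changes.
    Unscorable epochs inherit the previous epoch's label.
    """
    ep = int(round(hypnogram.epoch_len))
    labels = hypnogram.epoch_labels.copy()
    for i in range(len(labels)):
        if labels[i] == UNSCORABLE:
            labels[i] = labels[i - 1] if i > 0 else "wake"
    sec = np.repeat(labels, ep)
    if boundary_refinement and emg_metric is not None and emg_threshold is not None:
        for i in range(1, len(labels)):
            if labels[i] == "wake" and labels[i - 1] != "wake":
                start = (i - 1) * ep
                seg = emg_metric[start : start + ep]
                above = np.flatnonzero(seg >= emg_threshold)
                if above.size:
                    sec[start + above[0] : i * ep] = "wake"
    hypnogram.second_labels = sec
    return sec


def detect_transitions(
    second_labels: np.ndarray,
    from_state: str,
    to_state: str,
    min_bout_after: float = 0.0,
    stim_onsets: np.ndarray | None = None,
    evoked_window: float = 35.0,
) -> list[TransitionEvent]:
    """Transitions at 1-s resolution with a minimum following bout.

    A transition occurs at t where label(t-1) = from_state and
    label(t) = to_state and the new state persists for at least
    ``min_bout_after`` seconds (30 s for spontaneous NREM-to-wake
    awakenings).  Transitions with a stimulation onset within
    ``[t - evoked_window, t]`` are flagged evoked, the rest spontaneous.
    """
    lab = np.asarray(second_labels)
    out: list[TransitionEvent] = []
    stims = np.asarray(stim_onsets, dtype=float) if stim_onsets is not None else np.empty(0)
    n = len(lab)
    for t in range(1, n):
        if lab[t - 1] != from_state or lab[t] != to_state:
            continue
        run = 1
        while t + run < n and lab[t + run] == to_state:
            run += 1
        if run < min_bout_after:
            continue
        evoked = bool(np.any((stims >= t - evoked_window) & (stims <= t)))
        out.append(TransitionEvent(float(t), from_state, to_state, float(run), evoked))
    return out


def emg_metric_1s(emg: np.ndarray, rate: float, bandpass: bool = True) -> np.ndarray:
    """Per-second RMS of (band-passed) EMG — the sub-state EMG metric."""
    x = np.asarray(emg, dtype=float)
    if bandpass:
        x = _bandpass_emg(x, rate)
    sps_ = int(round(rate))
    n_sec = len(x) // sps_
    return np.sqrt(np.mean(x[: n_sec * sps_].reshape(n_sec, sps_) ** 2, axis=1))


def detect_substate_onsets(
    emg_metric: np.ndarray,
    second_labels: np.ndarray,
    parent_state: str,
    k: float = 10.0,
    threshold_rule: str = "mean_plus_k_sd",
    refractory_s: float = 8.0,
) -> list[SubstateOnset]:
    """Within-state EMG threshold crossings.

    The threshold is mean + k·SD of the 1-s EMG metric over all seconds
    of the parent state (``threshold_rule="k_sd"`` gives the alternative
    k·SD-only reading).  An onset is the first second of each
    supra-threshold run, with runs closer than ``refractory_s`` merged.
    Active-awake onsets inside wake, micro-awakenings inside NREM.
    Requires at least 60 s of the parent state.
    """
    lab = np.asarray(second_labels)
    m = np.asarray(emg_metric, dtype=float)
    n = min(len(lab), len(m))
    lab, m = lab[:n], m[:n]
    in_state = lab == parent_state
    if in_state.sum() < 60:
        raise ValueError(
            f"need >= 60 s of {parent_state!r} for threshold estimation, "
            f"got {int(in_state.sum())} s"
        )
    vals = m[in_state]
    if threshold_rule == "mean_plus_k_sd":
        threshold = float(vals.mean() + k * vals.std(ddof=0))
    elif threshold_rule == "k_sd":
        threshold = float(k * vals.std(ddof=0))
    else:
        raise ValueError(f"unknown threshold_rule {threshold_rule!r}")

    kind = "active_awake_onset" if parent_state == "wake" else "micro_awakening"
    above = in_state & (m > threshold)
    onsets: list[SubstateOnset] = []
    last_end = -np.inf
    t = 0
    while t < n:
        if above[t]:
            start = t
            while t < n and above[t]:
                t += 1
            if start - last_end >= refractory_s:
                onsets.append(SubstateOnset(float(start), kind, parent_state, threshold))
            last_end = t
        else:
            t += 1
    return onsets


def score_recording(
    recording: Recording,
    thresholds: ScoringThresholds | None = None,
    epoch_len: float = 4.0,
    boundary_refinement: bool = False,
) -> Hypnogram:
    """Full scoring chain on a recording with EEG and EMG channels."""
    eeg = recording.channels["EEG"]
    emg = recording.channels["EMG"]
    feats = epoch_features(eeg.samples, emg.samples, eeg.rate, emg.rate, epoch_len)
    thr = thresholds or calibrate_thresholds(feats)
    hyp = classify_epochs(feats, thr, epoch_len)
    metric = emg_metric_1s(emg.samples, emg.rate)
    refine_to_seconds(hyp, metric, thr.emg_rms, boundary_refinement)
    return hyp


def hypnogram_to_csv(hypnogram: Hypnogram, path) -> None:
    """Epoch-level CSV (epoch_index, t_start, state)."""
    pd.DataFrame(
        {
            "epoch_index": np.arange(hypnogram.n_epochs),
            "t_start": np.arange(hypnogram.n_epochs) * hypnogram.epoch_len,
            "state": hypnogram.epoch_labels,
        }
    ).to_csv(path, index=False)
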