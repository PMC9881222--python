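"""Ground-truth-annotated synthetic recordings.

Emulates the statistical structure of state-dependent fiber-photometry
experiments in head-fixed mice: a semi-Markov wake/NREM/REM hypnogram,
EEG as state-weighted band-limited noise (delta 0.5-4 Hz, theta
6-9 Hz), EMG as rectifiable noise with state-dependent amplitude and
optional injected bursts, an optogenetic stimulation protocol (1-s blue
light, 1-s yellow light 30 s later; 3-7 stimulations per session at
>= 5-min intervals, >= 7 min for lactate protocols, gated on a target
vigilance state), and sensor channels in which each stimulation adds a
state-conditioned difference-of-exponentials response on top of
photobleaching, slow drift, and Gaussian noise.

Everything injected (labels, events, kernel parameters, EMG bursts) is
returned in a :class:`GroundTruth` record so downstream stages can be
tested by parameter recovery.  All randomness derives from one seed via
deterministic sub-streams per component.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as spsig

from .io import Channel, Event, EventSet, Recording

__all__ = [
    "SimConfig",
    "StimConfig",
    "ResponseParams",
    "GroundTruth",
    "STATES",
    "diffexp_kernel",
    "diffexp_peak_time",
    "laconic_kernel",
    "lactate_kernel",
    "simulate_hypnogram",
    "simulate_eeg_emg",
    "simulate_stim_protocol",
    "simulate_sensor",
    "simulate_recording",
]

STATES = ("wake", "nrem", "rem")

DELTA_BAND = (0.5, 4.0)
THETA_BAND = (6.0, 9.0)


@dataclass
class StimConfig:
    """Stimulation-protocol parameters (blue opens the step-function
    opsin, yellow closes it 30 s later; yellow replaces blue in control
    sessions)."""

    n_per_session: int | None = None  # drawn uniformly from [3, 7] when None
    min_interval_s: float = 300.0  # >= 420 for lactate protocols
    target_state: str = "nrem"
    blue_dur: float = 1.0
    yellow_offset: float = 30.0
    yellow_dur: float = 1.0
    control: bool = False
    min_state_run_s: float = 20.0  # state must be established before a stim
    gating_error_prob: float = 0.0


@dataclass
class ResponseParams:
    """State-conditioned response kernel: peak amplitude (ΔR/R or %),
    onset latency, and rise/decay time constants in seconds."""

    amplitude: float
    latency: float = 1.0
    rise_tau: float = 1.5
    decay_tau: float = 20.0


def _default_response_params() -> dict:
    # stimulation-locked ATP-sensor responses are largest in REM,
    # intermediate in NREM, smallest in wake
    return {
        "wake": ResponseParams(amplitude=0.005),
        "nrem": ResponseParams(amplitude=0.010),
        "rem": ResponseParams(amplitude=0.015),
    }


@dataclass
class SimConfig:
    """Full parameterization of one synthetic session.

    Dwell means, spectral weights, EMG levels and response kernels are
    per-state; rates are Hz.  ``noise_sd_ratio`` is the standard
    deviation of the resulting ratio/intensity trace on the ΔR/R scale
    (split between FRET channels); ``lactate_noise_pct`` is in percent
    of baseline.
    """

    seed: int = 0
    duration: float = 7200.0
    state_dwell_means: dict = field(
        default_factory=lambda: {"wake": 150.0, "nrem": 180.0, "rem": 75.0}
    )
    min_dwell_s: float = 20.0
    p_nrem_to_rem: float = 0.25
    eeg_rate: float = 1000.0
    emg_rate: float = 1000.0
    photometry_rate: float = 1000.0
    lactate_rate: float = 1.0
    band_powers: dict = field(
        default_factory=lambda: {
            "wake": (1.5, 1.0, 1.0),
            "nrem": (6.0, 1.0, 1.0),
            "rem": (0.5, 3.0, 0.8),
        }
    )
    emg_levels: dict = field(
        default_factory=lambda: {"wake": (30.0, 8.0), "nrem": (8.0, 2.0), "rem": (4.0, 1.0)}
    )
    emg_bursts: tuple = ()  # (time_s, scale_vs_state_mean, duration_s)
    response_params: dict = field(default_factory=_default_response_params)
    trough_params: tuple = (0.010, 6.0)  # (depth, trough decay tau) for biphasic FRET lactate
    laconic_peak_delay: float = 15.0
    lactate_kernel_params: tuple = (5.0, 12.0, 10.0, 60.0, 150.0)
    # (early_amp %, early_tau, late_amp %, late_delay, late_tau)
    state_baseline_offsets: dict = field(
        default_factory=lambda: {"wake": 0.006, "nrem": 0.0, "rem": 0.004}
    )
    state_offset_tau: float = 3.0  # smoothing of state-dependent baseline steps
    bleach_tau: float = 4.0 * 3600.0
    drift_sd: float = 0.002
    noise_sd_ratio: float = 0.002
    lactate_noise_pct: float = 0.5
    stim_wake_prob: float = 0.8  # P(a sleep-state stimulation induces awakening)
    sensor_kind: str = "ATeam"
    stim: StimConfig = field(default_factory=StimConfig)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        for name in ("eeg_rate", "emg_rate", "photometry_rate", "lactate_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for s, m in self.state_dwell_means.items():
            if s not in STATES:
                raise ValueError(f"unknown state {s!r}")
        if all(m <= 0 for m in self.state_dwell_means.values()):
            raise ValueError("at least one state needs a positive dwell mean")
        if self.noise_sd_ratio < 0 or self.bleach_tau <= 0 or self.drift_sd < 0:
            raise ValueError("noise/bleach/drift parameters must be non-negative")
        for p in self.response_params.values():
            if not np.isfinite(p.amplitude):
                raise ValueError("response amplitude must be finite")
        if self.sensor_kind not in ("ATeam", "Laconic", "single", "lactate_amperometric"):
            raise ValueError(f"unknown sensor_kind {self.sensor_kind!r}")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-component random stream (stable across runs)."""
        key = zlib.crc32(stream.encode()) % (2**31)
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)


@dataclass
class GroundTruth:
    """Everything injected into a synthetic recording."""

    second_labels: np.ndarray
    bouts: list  # (state, start_s, duration_s)
    events: EventSet = field(default_factory=EventSet)
    response_params: dict = field(default_factory=dict)
    emg_burst_times: list = field(default_factory=list)
    fret_split: tuple = (0.6, -0.4)  # numerator / denominator share of ratio change
    notes: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "second_labels": self.second_labels.tolist(),
            "bouts": self.bouts,
            "events": self.events.to_dataframe().to_dict(orient="list"),
            "response_params": {
                s: asdict(p) if isinstance(p, ResponseParams) else p
                for s, p in self.response_params.items()
            },
            "emg_burst_times": self.emg_burst_times,
            "fret_split": self.fret_split,
            "notes": self.notes,
        }
        path.write_text(json.dumps(payload))
        return path


# ---------------------------------------------------------------------------
# response kernels


def diffexp_kernel(
    t: np.ndarray, amplitude: float, latency: float, rise_tau: float, decay_tau: float
) -> np.ndarray:
    """Difference-of-exponentials response, normalized to peak ``amplitude``.

    h(t) = A·(exp(-(t-lat)/decay) - exp(-(t-lat)/rise)) / h_max for
    t >= latency, 0 before.  Closed-form peak time: latency +
    rise·decay/(decay-rise)·ln(decay/rise).
    """
    if rise_tau <= 0 or decay_tau <= 0 or rise_tau >= decay_tau:
        raise ValueError("need 0 < rise_tau < decay_tau")
    tt = np.asarray(t, dtype=float) - latency
    out = np.zeros_like(tt)
    pos = tt > 0
    raw = np.exp(-tt[pos] / decay_tau) - np.exp(-tt[pos] / rise_tau)
    tp = rise_tau * decay_tau / (decay_tau - rise_tau) * np.log(decay_tau / rise_tau)
    norm = np.exp(-tp / decay_tau) - np.exp(-tp / rise_tau)
    out[pos] = amplitude * raw / norm
    return out


def diffexp_peak_time(latency: float, rise_tau: float, decay_tau: float) -> float:
    """Analytic peak time of :func:`diffexp_kernel`."""
    return latency + rise_tau * decay_tau / (decay_tau - rise_tau) * np.log(decay_tau / rise_tau)


def laconic_kernel(t: np.ndarray, config: SimConfig, state: str) -> np.ndarray:
    """Biphasic intracellular-lactate kernel: an initial trough followed
    by a delayed positive peak, on the ratio scale."""
    depth, trough_tau = config.trough_params
    p = config.response_params[state]
    neg = diffexp_kernel(t, depth, p.latency, 1.0, trough_tau)
    pos = diffexp_kernel(
        t, p.amplitude, p.latency + config.laconic_peak_delay, 5.0, max(p.decay_tau, 40.0)
    )
    return pos - neg


def lactate_kernel(t: np.ndarray, params: tuple) -> np.ndarray:
    """Bimodal extracellular-lactate kernel in percent of baseline:
    a fast component during the 30-s illumination plus a delayed slow
    component peaking in the 30-400 s window."""
    early_amp, early_tau, late_amp, late_delay, late_tau = params
    early = diffexp_kernel(t, early_amp, 0.5, 2.0, early_tau)
    late = diffexp_kernel(t, late_amp, late_delay, 20.0, late_tau)
    return early + late


# ---------------------------------------------------------------------------
# hypnogram


def simulate_hypnogram(config: SimConfig) -> tuple[np.ndarray, list]:
    """Semi-Markov vigilance-state sequence at 1-s resolution.

    Bout durations are shifted-exponential (minimum dwell plus an
    exponential whose mean preserves the configured state mean); wake
    alternates with NREM, REM is entered only from NREM (probability
    ``p_nrem_to_rem``) and exits to wake.  Returns per-second labels and
    the continuous-time bout list.
    """
    rng = config.rng("hypnogram")
    means = {s: m for s, m in config.state_dwell_means.items() if m > 0}
    avail = [s for s in STATES if s in means]
    if not avail:
        raise ValueError("no state with positive dwell mean")

    def draw(state: str) -> float:
        m = means[state]
        lo = min(config.min_dwell_s, m)
        return lo + rng.exponential(max(m - lo, 1e-9))

    def next_state(state: str) -> str:
        if len(avail) == 1:
            return state
        if state == "wake":
            return "nrem" if "nrem" in means else "wake"
        if state == "nrem":
            if "rem" in means and rng.random() < config.p_nrem_to_rem:
                return "rem"
            return "wake" if "wake" in means else ("rem" if "rem" in means else "nrem")
        # REM exits to wake; falls back to NREM if wake is disabled
        return "wake" if "wake" in means else "nrem"

    state = "wake" if "wake" in means else avail[0]
    t = 0.0
    bouts: list = []
    while t < config.duration:
        dur = draw(state)
        dur = min(dur, config.duration - t)
        bouts.append((state, t, dur))
        t += dur
        state = next_state(state)

    n_sec = int(np.ceil(config.duration))
    labels = np.empty(n_sec, dtype="<U4")
    for s, start, dur in bouts:
        i0 = int(np.floor(start))
        i1 = min(int(np.ceil(start + dur)), n_sec)
        # a second belongs to the bout covering its start
        labels[i0:i1] = s
    # re-walk starts to resolve seconds straddled by two bouts
    for s, start, dur in bouts:
        i0 = int(np.ceil(start))
        i1 = min(int(np.floor(start + dur)), n_sec)
        labels[i0:i1] = s
    return labels, bouts


def _labels_per_sample(labels_1s: np.ndarray, rate: float, n: int) -> np.ndarray:
    idx = np.minimum((np.arange(n) / rate).astype(int), len(labels_1s) - 1)
    return labels_1s[idx]


# ---------------------------------------------------------------------------
# EEG / EMG


def _band_noise(rng: np.random.Generator, n: int, rate: float, band: tuple) -> np.ndarray:
    lo, hi = band
    hi = min(hi, 0.45 * rate)
    x = rng.standard_normal(n)
    sos = spsig.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    y = spsig.sosfiltfilt(sos, x)
    return y / max(y.std(), 1e-12)


def simulate_eeg_emg(
    labels_1s: np.ndarray, config: SimConfig
) -> tuple[np.ndarray, np.ndarray, list]:
    """State-structured EEG and EMG.

    EEG is a sum of delta-, theta-, and broadband-limited unit-variance
    noises, each weighted per second by the square root of the state's
    relative band power (units µV, overall scale 20 µV).  EMG is white
    noise whose per-second amplitude is drawn from the state's (mean,
    sd); configured bursts multiply the state mean and are returned as
    ground truth.
    """
    unknown = set(np.unique(labels_1s)) - set(STATES)
    if unknown:
        raise ValueError(f"unknown state labels {sorted(unknown)}")
    n_eeg = int(round(config.duration * config.eeg_rate))
    rng_e = config.rng("eeg")
    bands = {
        "delta": _band_noise(rng_e, n_eeg, config.eeg_rate, DELTA_BAND),
        "theta": _band_noise(rng_e, n_eeg, config.eeg_rate, THETA_BAND),
        "broad": _band_noise(rng_e, n_eeg, config.eeg_rate, (0.5, 50.0)),
    }
    lab = _labels_per_sample(labels_1s, config.eeg_rate, n_eeg)
    eeg = np.zeros(n_eeg)
    for si, s in enumerate(STATES):
        mask = lab == s
        if not mask.any():
            continue
        d, th, br = config.band_powers[s]
        eeg[mask] = (
            np.sqrt(d) * bands["delta"][mask]
            + np.sqrt(th) * bands["theta"][mask]
            + np.sqrt(br) * bands["broad"][mask]
        )
    eeg *= 20.0

    n_emg = int(round(config.duration * config.emg_rate))
    rng_m = config.rng("emg")
    n_sec = len(labels_1s)
    level = np.empty(n_sec)
    for s in STATES:
        mask = labels_1s == s
        if not mask.any():
            continue
        mean, sd = config.emg_levels[s]
        level[mask] = np.maximum(rng_m.normal(mean, sd, mask.sum()), 0.05 * mean)
    burst_times = []
    for t_b, scale, dur in config.emg_bursts:
        i0, i1 = int(t_b), min(int(np.ceil(t_b + dur)), n_sec)
        if i0 >= n_sec:
            continue
        state_mean = config.emg_levels[str(labels_1s[i0])][0]
        level[i0:i1] = scale * state_mean
        burst_times.append(float(t_b))
    sigma = level[np.minimum((np.arange(n_emg) / config.emg_rate).astype(int), n_sec - 1)]
    emg = sigma * rng_m.standard_normal(n_emg)
    return eeg, emg, burst_times


# ---------------------------------------------------------------------------
# stimulation protocol


def simulate_stim_protocol(labels_1s: np.ndarray, config: SimConfig) -> EventSet:
    """Place blue/yellow stimulation pairs inside bouts of the target state.

    Onsets fall on seconds whose preceding ``min_state_run_s`` seconds
    are all the target state (the experimenter's online state judgment,
    here read off the true hypnogram; an optional gating-error
    probability relaxes it), with successive onsets separated by at
    least ``min_interval_s``.  In control sessions yellow light replaces
    blue at time 0.  Fewer pairs than requested (or none) triggers a
    warning.
    """
    stim = config.stim
    rng = config.rng("stim")
    n_req = stim.n_per_session if stim.n_per_session is not None else int(rng.integers(3, 8))
    if n_req == 0:
        return EventSet()
    n_sec = len(labels_1s)
    run = int(round(stim.min_state_run_s))
    tail = stim.yellow_offset + stim.yellow_dur
    in_state = labels_1s == stim.target_state
    ok = np.zeros(n_sec, dtype=bool)
    if run < n_sec:
        c = np.concatenate(([0], np.cumsum(in_state.astype(int))))
        for t in range(run, n_sec):
            if t + tail >= n_sec:
                break
            established = c[t + 1] - c[t - run] == run + 1
            if established or (
                stim.gating_error_prob > 0 and rng.random() < stim.gating_error_prob
            ):
                ok[t] = True
    candidates = np.flatnonzero(ok)
    onsets: list[float] = []
    t_min = 0.0
    for t in candidates:
        if len(onsets) >= n_req:
            break
        if t >= t_min:
            onsets.append(float(t))
            t_min = t + stim.min_interval_s
    if len(onsets) == 0:
        warnings.warn(
            f"no eligible {stim.target_state!r} bout for stimulation; empty event set"
        )
        return EventSet()
    if len(onsets) < n_req:
        warnings.warn(
            f"hypnogram hosts only {len(onsets)} of {n_req} requested stimulations"
        )
    events = []
    first_kind = "stim_yellow" if stim.control else "stim_blue"
    for t in onsets:
        color0 = "yellow" if stim.control else "blue"
        events.append(
            Event(t, stim.blue_dur, first_kind, {"color": color0, "role": "open"})
        )
        events.append(
            Event(
                t + stim.yellow_offset,
                stim.yellow_dur,
                "stim_yellow",
                {"color": "yellow", "role": "close"},
            )
        )
    return EventSet(events)


# ---------------------------------------------------------------------------
# sensors


def _smooth_state_offsets(
    labels_1s: np.ndarray, offsets: dict, tau: float, rate: float, n: int
) -> np.ndarray:
    step = np.array([offsets.get(str(s), 0.0) for s in labels_1s])
    per_sample = step[np.minimum((np.arange(n) / rate).astype(int), len(step) - 1)]
    if tau <= 0:
        return per_sample
    alpha = 1.0 / (tau * rate)
    b, a = [alpha], [1.0, -(1.0 - alpha)]
    return spsig.lfilter(b, a, per_sample, zi=[per_sample[0] * (1 - alpha)])[0]


def simulate_sensor(
    labels_1s: np.ndarray,
    events: EventSet,
    config: SimConfig,
    sensor_kind: str | None = None,
) -> tuple[dict, dict]:
    """Sensor channel(s) with state-conditioned stimulation responses.

    Each opsin-opening (blue) stimulation adds a kernel conditioned on
    the true state at onset: a positive difference-of-exponentials pulse
    for ``"ATeam"`` and ``"single"``, the biphasic trough-then-peak
    kernel for ``"Laconic"``, and the bimodal early/late kernel for
    ``"lactate_amperometric"``.  FRET responses are split
    anti-correlated across the two channels (60% on the numerator, 40%
    opposite sign on the denominator); every channel carries
    photobleaching, slow drift, and Gaussian noise.  Returns
    ``(channels, truth_notes)``.
    """
    kind = sensor_kind or config.sensor_kind
    rate = config.lactate_rate if kind == "lactate_amperometric" else config.photometry_rate
    n = int(round(config.duration * rate))
    t = np.arange(n) / rate
    rng = config.rng(f"sensor-{kind}")

    blue = [e for e in events if e.attributes.get("role") == "open" and e.kind == "stim_blue"]
    for e in blue:
        if not 0 <= e.onset <= config.duration:
            raise ValueError(f"event at {e.onset} outside recording")

    k = np.zeros(n)
    used: dict[float, str] = {}
    for e in blue:
        state = str(labels_1s[min(int(e.onset), len(labels_1s) - 1)])
        used[e.onset] = state
        rel = t - e.onset
        if kind == "Laconic":
            k += laconic_kernel(rel, config, state)
        elif kind == "lactate_amperometric":
            k += lactate_kernel(rel, config.lactate_kernel_params)
        else:
            p = config.response_params[state]
            k += diffexp_kernel(rel, p.amplitude, p.latency, p.rise_tau, p.decay_tau)

    drift = config.drift_sd * np.cumsum(rng.standard_normal(n)) / np.sqrt(max(n, 1))
    truth = {"responses": used, "kernel_kind": kind}

    if kind == "lactate_amperometric":
        base = 10.0  # nA
        noise = (config.lactate_noise_pct / 100.0) * base * rng.standard_normal(n)
        x = base * (1.0 + k / 100.0) * np.exp(-t / (10 * config.bleach_tau)) * (1.0 + drift)
        return {"lactate": Channel(x + noise, rate, units="nA", kind="amperometric")}, truth

    offsets = _smooth_state_offsets(
        labels_1s, config.state_baseline_offsets, config.state_offset_tau, rate, n
    )
    k = k + offsets

    if kind == "single":
        base = 1.0
        noise = config.noise_sd_ratio * base * rng.standard_normal(n)
        x = base * (1.0 + k) * np.exp(-t / config.bleach_tau) * (1.0 + drift)
        return {"F": Channel(x + noise, rate, units="a.u.", kind="fluorescence")}, truth

    # FRET pair: 60/40 anti-correlated split of the ratio change
    num_share, den_share = 0.6, -0.4
    bleach_num = np.exp(-t / config.bleach_tau)
    bleach_den = np.exp(-t / (1.2 * config.bleach_tau))
    ch_noise = config.noise_sd_ratio / np.sqrt(2.0)
    num = bleach_num * (1.0 + num_share * k) * (1.0 + drift) + ch_noise * rng.standard_normal(n)
    den = bleach_den * (1.0 + den_share * k) * (1.0 - drift) + ch_noise * rng.standard_normal(n)
    names = ("mVenus", "CFP") if kind == "ATeam" else ("CFP", "mVenus")
    truth["fret_split"] = (num_share, den_share)
    return (
        {
            names[0]: Channel(num, rate, units="a.u.", kind="fluorescence"),
            names[1]: Channel(den, rate, units="a.u.", kind="fluorescence"),
        },
        truth,
    )


# ---------------------------------------------------------------------------
# full recording


def _bouts_from_labels(labels: np.ndarray) -> list:
    bouts = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            bouts.append((str(labels[start]), float(start), float(i - start)))
            start = i
    return bouts


def _insert_evoked_awakenings(
    labels: np.ndarray, events: EventSet, config: SimConfig
) -> np.ndarray:
    """Stimulation-induced awakening: with probability ``stim_wake_prob``
    a blue stimulation delivered in sleep inserts a wake bout shortly
    after its onset, as serotonergic activation does in vivo."""
    if config.stim_wake_prob <= 0:
        return labels
    rng = config.rng("evoked-wake")
    labels = labels.copy()
    wake_mean = config.state_dwell_means.get("wake", 60.0)
    for e in events:
        if e.kind != "stim_blue" or e.attributes.get("role") != "open":
            continue
        i0 = int(e.onset)
        if i0 >= len(labels) or labels[i0] == "wake":
            continue
        if rng.random() >= config.stim_wake_prob:
            continue
        delay = int(rng.uniform(5, 15))
        dur = int(config.min_dwell_s + rng.exponential(max(wake_mean - config.min_dwell_s, 1)))
        start = min(i0 + delay, len(labels))
        labels[start : start + dur] = "wake"
    return labels


def simulate_recording(config: SimConfig) -> tuple[Recording, GroundTruth]:
    """Generate a complete synthetic session: hypnogram, EEG/EMG,
    stimulation events, and the configured sensor channel(s).

    Stimulations are gated on the pre-stimulation hypnogram; evoked
    awakenings (see ``stim_wake_prob``) are then folded into the labels
    before EEG/EMG and sensor synthesis, so the recorded physiology
    reflects the stimulation's arousal effect.
    """
    labels, bouts = simulate_hypnogram(config)
    events = simulate_stim_protocol(labels, config)
    labels = _insert_evoked_awakenings(labels, events, config)
    bouts = _bouts_from_labels(labels)
    eeg, emg, burst_times = simulate_eeg_emg(labels, config)
    sensor_channels, sensor_truth = simulate_sensor(labels, events, config)

    channels = {
        "EEG": Channel(eeg, config.eeg_rate, units="uV", kind="eeg"),
        "EMG": Channel(emg, config.emg_rate, units="uV", kind="emg"),
        **sensor_channels,
    }
    rec = Recording(
        channels=channels,
        events=events,
        metadata={"sensor_kind": config.sensor_kind, "seed": config.seed},
    )
    truth = GroundTruth(
        second_labels=labels,
        bouts=[(s, float(a), float(d)) for s, a, d in bouts],
        events=events,
        response_params=dict(config.response_params),
        emg_burst_times=burst_times,
        notes=sensor_truth,
    )
    return rec, truth


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of a config with a different seed (dataclasses.replace wrapper)."""
    return replace(config, seed=seed)
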