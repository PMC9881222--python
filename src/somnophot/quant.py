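"""Normalization and response metrics for biosensor traces.

Implements the quantification conventions used for event-triggered
FRET-ratio and intensity photometry: a 100-point moving average for
display/ratio construction and a 500-point moving average for
quantitative parameters (both at 1 kHz acquisition; windows scale with
rate), ΔR/R and ΔF/F against a 5-s pre-event baseline, percent
normalization for amperometric lactate, windowed trapezoidal AUC with
illumination-artifact exclusions, and peak/trough extraction including
the biphasic (trough-then-peak) mode used for intracellular lactate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BaselineSpec",
    "RatioTrace",
    "ResponseMetrics",
    "FlatTraceWarning",
    "moving_average",
    "compute_ratio",
    "normalize",
    "windowed_auc",
    "find_extrema",
    "split_signed_auc",
    "STIM_AUC_WINDOW",
    "STIM_AUC_EXCLUSIONS",
    "LACTATE_EARLY_WINDOW",
    "LACTATE_LATE_WINDOW",
]

# stimulation-aligned AUC: 30-s stimulation window minus 1 s of each
# light exposure (blue at 0 s, yellow at 30 s) -> effective [1, 30)
STIM_AUC_WINDOW = (0.0, 30.0)
STIM_AUC_EXCLUSIONS = ((0.0, 1.0), (30.0, 31.0))

# amperometric lactate phases: during vs after the 30-s illumination
LACTATE_EARLY_WINDOW = (0.0, 30.0)
LACTATE_LATE_WINDOW = (30.0, 400.0)


class FlatTraceWarning(UserWarning):
    """Extrema requested on a constant trace."""


@dataclass
class RatioTrace:
    """A ratiometric (or single-channel) trace with its convention.

    ``convention`` records which raw channel is the numerator:
    mVenus/CFP for the ATP sensor, CFP/mVenus for the FRET lactate
    sensor, or the channel name itself for intensity sensors.
    """

    values: np.ndarray
    rate: float
    convention: str = "mVenus/CFP"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ratio trace contains non-finite values")


@dataclass
class BaselineSpec:
    """Pre-event baseline window and normalization mode.

    The baseline is the mean over ``[anchor_time - duration,
    anchor_time)``: 5 s before a light onset or state transition, one
    4-s epoch before a sub-state onset.  Modes: ``delta_ratio`` /
    ``delta_f`` return (X - X0)/X0; ``percent`` returns 100·X/X0.
    """

    anchor_time: float
    duration: float = 5.0
    mode: str = "delta_ratio"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("baseline duration must be positive")
        if self.mode not in ("delta_ratio", "delta_f", "percent"):
            raise ValueError(f"unknown baseline mode {self.mode!r}")


@dataclass
class ResponseMetrics:
    """Scalar response quantities extracted from one normalized trace."""

    auc: float | None = None
    peak_value: float | None = None
    peak_time: float | None = None
    trough_value: float | None = None
    trough_time: float | None = None
    phase_aucs: dict = field(default_factory=dict)
    windows_used: dict = field(default_factory=dict)


def moving_average(x: np.ndarray, window_points: int) -> np.ndarray:
    """Centered moving average with truncated edge windows.

    The window covers ``window_points`` samples centered on each index
    (for even windows, one more sample on the left).  Near the edges the
    window is clipped to the available samples, so the output has the
    input's length and a constant input is returned unchanged.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("moving_average: empty input")
    w = int(window_points)
    if w < 1 or w > x.size:
        raise ValueError(f"window_points must be in [1, {x.size}], got {window_points}")
    left = w // 2
    right = w - 1 - left
    c = np.concatenate(([0.0], np.cumsum(x)))
    n = x.size
    i = np.arange(n)
    lo = np.maximum(i - left, 0)
    hi = np.minimum(i + right, n - 1)
    return (c[hi + 1] - c[lo]) / (hi + 1 - lo)


def compute_ratio(
    numerator: np.ndarray,
    denominator: np.ndarray,
    rate: float,
    convention: str = "mVenus/CFP",
    eps_scale: float = 1e-6,
) -> RatioTrace:
    """Elementwise FRET ratio R of two synchronized channels.

    The denominator must stay above ``eps_scale`` times its median;
    otherwise the first offending sample index is reported.
    """
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    if num.shape != den.shape:
        raise ValueError(f"channel length mismatch: {num.shape} vs {den.shape}")
    eps = eps_scale * abs(float(np.median(den)))
    bad = np.flatnonzero(den <= eps)
    if bad.size:
        raise ValueError(
            f"denominator <= {eps:g} at sample {bad[0]} (t={bad[0] / rate:.3f} s)"
        )
    return RatioTrace(values=num / den, rate=rate, convention=convention)


def _baseline_mask(n: int, rate: float, baseline: BaselineSpec, t0: float) -> np.ndarray:
    t = t0 + np.arange(n) / rate
    mask = (t >= baseline.anchor_time - baseline.duration) & (t < baseline.anchor_time)
    return mask


def normalize(
    values: np.ndarray,
    rate: float,
    baseline: BaselineSpec,
    t0: float = 0.0,
) -> np.ndarray:
    """Baseline-normalize a trace: ΔR/R, ΔF/F, or percent-of-baseline.

    ``t0`` is the time of the first sample.  The baseline value X0 is
    the mean of the (already filtered) trace over the baseline window;
    in delta modes the returned trace therefore averages exactly 0 over
    that window.
    """
    x = np.asarray(values, dtype=float)
    t_end = t0 + (x.size - 1) / rate
    lo = baseline.anchor_time - baseline.duration
    if lo < t0 - 1e-9 or baseline.anchor_time > t_end + 1.0 / rate + 1e-9:
        raise ValueError(
            f"baseline window [{lo}, {baseline.anchor_time}) not inside the trace"
        )
    mask = _baseline_mask(x.size, rate, baseline, t0)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    x0 = float(x[mask].mean())
    if baseline.mode == "percent":
        if x0 == 0:
            raise ValueError("baseline mean is 0; percent normalization undefined")
        return 100.0 * x / x0
    if x0 == 0:
        raise ValueError("baseline mean is 0; delta normalization undefined")
    return (x - x0) / x0


def _kept_intervals(
    window: tuple[float, float],
    exclusions: tuple[tuple[float, float], ...],
) -> list[tuple[float, float]]:
    """Subtract half-open exclusion intervals from the window."""
    a, b = float(window[0]), float(window[1])
    if b <= a:
        raise ValueError(f"empty analysis window {window}")
    kept = [(a, b)]
    for lo, hi in sorted((float(lo), float(hi)) for lo, hi in exclusions):
        nxt = []
        for ka, kb in kept:
            if hi <= ka or lo >= kb:
                nxt.append((ka, kb))
                continue
            if lo > ka:
                nxt.append((ka, lo))
            if hi < kb:
                nxt.append((hi, kb))
        kept = nxt
    kept = [(ka, kb) for ka, kb in kept if kb > ka]
    if not kept:
        raise ValueError("exclusions leave an empty effective window")
    return kept


def _segment_integral(x: np.ndarray, rate: float, t0: float, a: float, b: float) -> float:
    """Exact integral of the piecewise-linear interpolant over [a, b]."""
    n = x.size
    t_end = t0 + (n - 1) / rate
    a = max(a, t0)
    b = min(b, t_end)
    if b <= a:
        return 0.0
    i0 = int(np.ceil((a - t0) * rate - 1e-9))
    i1 = int(np.floor((b - t0) * rate + 1e-9))
    inner_t = t0 + np.arange(i0, i1 + 1) / rate
    ts = np.concatenate(([a], inner_t[(inner_t > a) & (inner_t < b)], [b]))
    vs = np.interp(ts, t0 + np.arange(n) / rate, x)
    return float(np.trapezoid(vs, ts))


def windowed_auc(
    values: np.ndarray,
    rate: float,
    window: tuple[float, float] = STIM_AUC_WINDOW,
    exclusions: tuple[tuple[float, float], ...] = STIM_AUC_EXCLUSIONS,
    t0: float = 0.0,
) -> float:
    """Signed area under a normalized trace over a window, minus exclusions.

    Trapezoidal rule at native sampling, with exact piecewise-linear
    handling of off-grid window/exclusion boundaries.  Default window and
    exclusions implement the stimulation-aligned convention (30-s window
    minus 1 s of each light exposure); units are (ΔR/R)·s or %·s.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("trace too short for integration")
    kept = _kept_intervals(window, exclusions)
    t_end = t0 + (x.size - 1) / rate
    if window[0] < t0 - 1e-9 or window[1] > t_end + 1e-9:
        raise ValueError(
            f"window {window} not contained in trace span [{t0}, {t_end:.6g}]"
        )
    return sum(_segment_integral(x, rate, t0, a, b) for a, b in kept)


def split_signed_auc(
    values: np.ndarray,
    rate: float,
    window: tuple[float, float],
    t0: float = 0.0,
) -> tuple[float, float]:
    """Positive and negative AUC components over a window.

    Zero crossings of the piecewise-linear trace are located exactly, so
    ``positive + negative`` equals :func:`windowed_auc` on the same
    window (no exclusions) to rounding error.
    """
    x = np.asarray(values, dtype=float)
    t = t0 + np.arange(x.size) / rate
    # insert exact zero crossings between samples of opposite sign
    s = np.sign(x)
    idx = np.flatnonzero(s[:-1] * s[1:] < 0)
    if idx.size:
        tc = t[idx] - x[idx] * (t[idx + 1] - t[idx]) / (x[idx + 1] - x[idx])
        t_all = np.concatenate([t, tc])
        x_all = np.concatenate([x, np.zeros_like(tc)])
        order = np.argsort(t_all, kind="stable")
        t, x = t_all[order], x_all[order]
    a, b = window
    if a < t[0] - 1e-9 or b > t[-1] + 1e-9:
        raise ValueError(f"window {window} not contained in trace span")
    keep = (t >= a) & (t <= b)
    ts = np.concatenate(([a], t[keep & (t > a) & (t < b)], [b]))
    vs = np.interp(ts, t, x)
    pos = float(np.trapezoid(np.maximum(vs, 0.0), ts))
    neg = float(np.trapezoid(np.minimum(vs, 0.0), ts))
    return pos, neg


def find_extrema(
    values: np.ndarray,
    rate: float,
    search_window: tuple[float, float],
    polarity: str = "peak",
    t0: float = 0.0,
    smooth_points: int | None = None,
) -> ResponseMetrics:
    """Locate peak and/or trough of a (smoothed) normalized trace.

    ``polarity``: ``"peak"`` (argmax), ``"trough"`` (argmin), or
    ``"biphasic"`` for trough-then-peak responses — the trough is
    searched before the global maximum, then the peak is re-searched
    after the trough, enforcing ``trough_time < peak_time``.  Ties break
    to the earliest sample.  Pass ``smooth_points`` to apply the
    quantification moving average first (500 points at 1 kHz).
    """
    if polarity not in ("peak", "trough", "biphasic"):
        raise ValueError(f"unknown polarity {polarity!r}")
    x = np.asarray(values, dtype=float)
    if smooth_points is not None:
        x = moving_average(x, smooth_points)
    t = t0 + np.arange(x.size) / rate
    a, b = search_window
    sel = np.flatnonzero((t >= a) & (t <= b))
    if sel.size == 0:
        raise ValueError(f"search window {search_window} contains no samples")
    xs, ts = x[sel], t[sel]
    if np.ptp(xs) == 0:
        warnings.warn("extrema requested on a flat trace", FlatTraceWarning)
    m = ResponseMetrics(windows_used={"search": tuple(search_window)})
    if polarity in ("peak", "biphasic"):
        i = int(np.argmax(xs))
        m.peak_value, m.peak_time = float(xs[i]), float(ts[i])
    if polarity == "trough":
        i = int(np.argmin(xs))
        m.trough_value, m.trough_time = float(xs[i]), float(ts[i])
        if i in (0, xs.size - 1):
            warnings.warn("trough at search-window boundary", FlatTraceWarning)
    if polarity == "biphasic":
        i_max = int(np.argmax(xs))
        j = int(np.argmin(xs[: i_max + 1]))
        m.trough_value, m.trough_time = float(xs[j]), float(ts[j])
        k = j + int(np.argmax(xs[j:]))
        m.peak_value, m.peak_time = float(xs[k]), float(ts[k])
        if not m.trough_time < m.peak_time:
            warnings.warn("degenerate biphasic trace: trough not before peak", FlatTraceWarning)
    return m
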