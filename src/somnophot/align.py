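"""Event-aligned snippet extraction, session rules, and group averages.

The session is the unit of statistical analysis: a stimulation session
is valid when it averages at least 3 repeated stimulations for one
animal; a transition session is a 30-minute measurement containing at
least one event.  Group traces are reported as mean ± SEM across
session means, and per-session metric tables feed the nonparametric
tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import quant
from .quant import BaselineSpec, ResponseMetrics

__all__ = [
    "TraceEnsemble",
    "SessionSummary",
    "GroupResult",
    "extract_snippets",
    "session_average",
    "group_average",
    "pair_conditions",
    "DEFAULT_WINDOWS",
]

logger = logging.getLogger(__name__)

# snippet windows (pre, post) in seconds by anchor kind
DEFAULT_WINDOWS = {
    "stim": (10.0, 120.0),
    "stim_lactate": (60.0, 400.0),
    "transition": (30.0, 60.0),
    "substate_onset": (8.0, 20.0),
}

MIN_STIM_EVENTS = 3  # "more than 3 repetitive stimulations", inclusive reading
TRANSITION_SESSION_S = 1800.0  # 30-minute measurement


@dataclass
class TraceEnsemble:
    """Event-aligned, per-event baseline-normalized snippets."""

    snippets: np.ndarray  # (n_events, n_time)
    time_axis: np.ndarray  # seconds relative to the anchor
    rate: float
    anchor_kind: str = "stim"
    normalization: BaselineSpec | None = None
    session_id: str = ""
    condition: str = ""
    skipped: list = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return self.snippets.shape[0]

    def mean(self) -> np.ndarray:
        return self.snippets.mean(axis=0)


@dataclass
class SessionSummary:
    """One session's mean trace and metrics, with its validity ruling."""

    mean_trace: np.ndarray
    time_axis: np.ndarray
    rate: float
    n_events: int
    metrics: ResponseMetrics
    valid: bool
    reason: str = ""
    session_id: str = ""
    condition: str = ""


@dataclass
class GroupResult:
    mean: np.ndarray
    sem: np.ndarray
    time_axis: np.ndarray
    n_sessions: int
    table: pd.DataFrame


def extract_snippets(
    values: np.ndarray,
    rate: float,
    event_onsets,
    pre: float,
    post: float,
    baseline: BaselineSpec | None = None,
    baseline_duration: float = 5.0,
    baseline_mode: str = "delta_ratio",
    t0: float = 0.0,
    anchor_kind: str = "stim",
    **ensemble_kwargs,
) -> TraceEnsemble:
    """Cut and normalize one snippet per event.

    Each event contributes the window ``[-pre, +post]`` around its
    onset, normalized to its own pre-event baseline; events whose
    analysis or baseline window leaves the recording are skipped and
    logged.  Raises if no event is usable.
    """
    if pre <= 0 or post <= 0:
        raise ValueError("pre and post must be positive")
    x = np.asarray(values, dtype=float)
    onsets = np.sort(np.asarray(event_onsets, dtype=float))
    n_pre = int(round(pre * rate))
    n_post = int(round(post * rate))
    time_axis = (np.arange(n_pre + n_post + 1) - n_pre) / rate
    t_end = t0 + (x.size - 1) / rate
    rows, skipped = [], []
    bl_dur = baseline.duration if baseline is not None else baseline_duration
    mode = baseline.mode if baseline is not None else baseline_mode
    for onset in onsets:
        lo = onset - max(pre, bl_dur)
        hi = onset + post
        if lo < t0 - 1e-9 or hi > t_end + 1e-9:
            skipped.append(float(onset))
            continue
        spec = BaselineSpec(anchor_time=onset, duration=bl_dur, mode=mode)
        normed = quant.normalize(x, rate, spec, t0=t0)
        i_anchor = int(round((onset - t0) * rate))
        rows.append(normed[i_anchor - n_pre : i_anchor + n_post + 1])
    if skipped:
        logger.info("skipped %d out-of-bounds events at %s", len(skipped), skipped)
    if not rows:
        raise ValueError("no event with a full analysis and baseline window in bounds")
    return TraceEnsemble(
        snippets=np.vstack(rows),
        time_axis=time_axis,
        rate=rate,
        anchor_kind=anchor_kind,
        normalization=BaselineSpec(anchor_time=0.0, duration=bl_dur, mode=mode),
        skipped=skipped,
        **ensemble_kwargs,
    )


def _default_metrics(
    mean_trace: np.ndarray, time_axis: np.ndarray, rate: float, anchor_kind: str,
    smooth_points: int | None, metric_windows: dict | None,
) -> ResponseMetrics:
    wins = metric_windows or {}
    x = mean_trace
    if smooth_points:
        x = quant.moving_average(x, min(smooth_points, x.size))
    t0 = float(time_axis[0])
    if anchor_kind == "stim_lactate":
        early = wins.get("early", quant.LACTATE_EARLY_WINDOW)
        late = wins.get("late", quant.LACTATE_LATE_WINDOW)
        m = quant.find_extrema(x, rate, late, polarity="peak", t0=t0)
        m.phase_aucs = {
            "early": quant.windowed_auc(x, rate, early, exclusions=(), t0=t0),
            "late": quant.windowed_auc(x, rate, late, exclusions=(), t0=t0),
        }
        m.auc = m.phase_aucs["early"] + m.phase_aucs["late"]
        m.windows_used |= {"early": early, "late": late}
        return m
    if anchor_kind == "stim":
        t_end = float(time_axis[-1])
        peak_win = wins.get("peak", (min(1.0, t_end / 2), min(120.0, t_end)))
        polarity = wins.get("polarity", "peak")
        m = quant.find_extrema(x, rate, peak_win, polarity=polarity, t0=t0)
        a, b = wins.get("auc", quant.STIM_AUC_WINDOW)
        auc_win = (max(a, t0), min(b, t_end))
        m.auc = quant.windowed_auc(
            x, rate, auc_win,
            exclusions=wins.get("exclusions", quant.STIM_AUC_EXCLUSIONS),
            t0=t0,
        )
        m.windows_used |= {"auc": auc_win}
        return m
    # transitions and sub-state onsets
    peak_win = wins.get("peak", (0.0, float(time_axis[-1])))
    m = quant.find_extrema(x, rate, peak_win, polarity="peak", t0=t0)
    m.auc = quant.windowed_auc(x, rate, peak_win, exclusions=(), t0=t0)
    return m


def session_average(
    ensemble: TraceEnsemble,
    design: str = "stim",
    min_events: int | None = None,
    smooth_points: int | None = 500,
    metric_windows: dict | None = None,
) -> SessionSummary:
    """Pointwise mean across events plus metrics on the smoothed mean.

    Validity: stimulation designs need ``n_events >= 3``; transition
    designs need at least one event in the 30-minute measurement.
    Invalid sessions are returned flagged (never silently dropped).
    ``smooth_points`` is the quantification moving average (500 points
    at 1 kHz; scale with rate).
    """
    if ensemble.n_events == 0:
        raise ValueError("empty ensemble")
    need = min_events if min_events is not None else (
        MIN_STIM_EVENTS if design.startswith("stim") else 1
    )
    valid = ensemble.n_events >= need
    reason = "" if valid else f"n_events<{need}"
    mean_trace = ensemble.mean()
    metrics = _default_metrics(
        mean_trace, ensemble.time_axis, ensemble.rate, ensemble.anchor_kind,
        smooth_points, metric_windows,
    )
    return SessionSummary(
        mean_trace=mean_trace,
        time_axis=ensemble.time_axis,
        rate=ensemble.rate,
        n_events=ensemble.n_events,
        metrics=metrics,
        valid=valid,
        reason=reason,
        session_id=ensemble.session_id,
        condition=ensemble.condition,
    )


def group_average(sessions) -> GroupResult:
    """Mean ± SEM across valid session means, plus the per-session
    metric table (one row per session — the unit of statistical
    analysis).  Requires at least 2 valid sessions."""
    valid = [s for s in sessions if s.valid]
    if len(valid) < 2:
        raise ValueError(f"need >= 2 valid sessions, got {len(valid)}")
    traces = np.vstack([s.mean_trace for s in valid])
    mean = traces.mean(axis=0)
    sem = traces.std(axis=0, ddof=1) / np.sqrt(len(valid))
    rows = []
    for s in valid:
        row = {
            "session_id": s.session_id,
            "condition": s.condition,
            "n_events": s.n_events,
            "auc": s.metrics.auc,
            "peak_value": s.metrics.peak_value,
            "peak_time": s.metrics.peak_time,
            "trough_value": s.metrics.trough_value,
            "trough_time": s.metrics.trough_time,
        }
        for phase, v in s.metrics.phase_aucs.items():
            row[f"auc_{phase}"] = v
        rows.append(row)
    return GroupResult(
        mean=mean,
        sem=sem,
        time_axis=valid[0].time_axis,
        n_sessions=len(valid),
        table=pd.DataFrame(rows),
    )


def pair_conditions(
    metric_table: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    pairing_key: str = "session_id",
    value_col: str = "auc",
) -> tuple[np.ndarray, np.ndarray, list]:
    """Key-aligned paired vectors for a two-condition comparison.

    Returns (values_a, values_b, unpaired_keys); order of input rows is
    irrelevant.  Raises when no complete pair exists; warns (via the
    returned list) about keys present in only one condition.
    """
    a = metric_table[metric_table["condition"] == condition_a].set_index(pairing_key)[value_col]
    b = metric_table[metric_table["condition"] == condition_b].set_index(pairing_key)[value_col]
    keys = sorted(set(a.index) & set(b.index))
    unpaired = sorted(set(a.index) ^ set(b.index))
    if not keys:
        raise ValueError(
            f"no complete {condition_a}/{condition_b} pairs under key {pairing_key!r}"
        )
    if unpaired:
        logger.warning("unpaired keys dropped: %s", unpaired)
    return a.loc[keys].to_numpy(float), b.loc[keys].to_numpy(float), unpaired
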