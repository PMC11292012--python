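"""Blink detection on EAR traces.

A blink is detected as a hysteresis-thresholded excursion of the smoothed
EAR signal below a fraction ``theta_p`` of the local open-eye baseline: a
candidate opens when the signal drops to or below ``theta_p * baseline``
(the counting threshold, a proxy for "pupil at least covered") and is only
released once the signal has recovered to ``hysteresis_fraction * baseline``,
which prevents chatter on noisy partial re-openings.  Onset and offset are
the linearly interpolated crossing times of the counting-threshold level, so
blink duration is the full width of the closure at that level.

The local baseline is a rolling upper percentile of the smoothed trace,
which tracks slow drift in eye openness while ignoring the minority of
samples that belong to blinks.  A quantile-bias correction (see
:func:`estimate_baseline`) keeps the baseline on the open-eye level rather
than on the upper envelope of the measurement noise.

Events closer together than ``merge_gap_ms`` are merged, and events with
duration outside ``[min_duration_ms, max_duration_ms]`` are discarded
(sub-frame noise and sustained closures are not blinks).  Each surviving
event is classified: ``counted`` (pupil covered) holds by construction;
``complete`` (lids meet) requires the event minimum EAR to be at or below
the absolute threshold ``theta_c``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.stats import norm

from .ear import EARTrace

__all__ = [
    "DetectionParams",
    "BlinkEvent",
    "smooth_trace",
    "estimate_baseline",
    "detect_blinks",
    "classify_blink",
    "events_to_frame",
    "write_events_csv",
    "read_events_csv",
    "AllZeroBaselineWarning",
]


class AllZeroBaselineWarning(UserWarning):
    """Raised (as a warning) when the trace never opens: baseline is all zero
    and detection will count no blinks."""


@dataclass(frozen=True)
class DetectionParams:
    """Tunable thresholds of the blink detector.

    The defaults are chosen for 240-fps recordings so that partial blinks of
    an acutely paretic eye (floor around EAR 0.13 against a 0.24 baseline)
    are still counted, while only closures reaching EAR <= 0.10 classify as
    complete; healthy and synkinetic closures (floors ~0.02-0.06) do,
    acute-paretic ones do not.
    """

    smooth_window_ms: float = 25.0
    baseline_window_s: float = 30.0
    baseline_percentile: float = 75.0
    theta_p: float = 0.7
    theta_c: float = 0.10
    hysteresis_fraction: float = 0.85
    min_duration_ms: float = 33.0
    max_duration_ms: float = 2000.0
    merge_gap_ms: float = 50.0
    noise_bias_correction: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.theta_p < self.hysteresis_fraction <= 1.0):
            raise ValueError("require 0 < theta_p < hysteresis_fraction <= 1")
        if self.theta_c < 0:
            raise ValueError("theta_c must be >= 0")
        if not self.min_duration_ms < self.max_duration_ms:
            raise ValueError("min_duration_ms must be < max_duration_ms")
        if self.smooth_window_ms < 0 or self.baseline_window_s <= 0:
            raise ValueError("window sizes must be positive")
        if not (0 < self.baseline_percentile <= 100):
            raise ValueError("baseline_percentile in (0, 100]")


@dataclass
class BlinkEvent:
    """One detected blink on one eye; times in seconds on the trace clock,
    interval half-open [onset, offset)."""

    onset_s: float
    offset_s: float
    min_ear: float
    baseline_ear: float
    counted: bool = True
    complete: bool = False

    def __post_init__(self) -> None:
        if not self.offset_s > self.onset_s:
            raise ValueError("offset_s must exceed onset_s")

    @property
    def duration_ms(self) -> float:
        return (self.offset_s - self.onset_s) * 1000.0


def _window_samples(window_ms: float, fps: float) -> int:
    return max(1, int(round(window_ms * fps / 1000.0)))


def smooth_trace(trace: EARTrace, window_ms: float) -> EARTrace:
    """Centred moving average; ``window_ms = 0`` is the identity.

    Edges hold the nearest value so constant traces pass through unchanged.
    """
    w = _window_samples(window_ms, trace.fps)
    if w > trace.n_samples:
        raise ValueError("smoothing window longer than trace")
    if w == 1:
        vals = trace.values.copy()
    else:
        vals = uniform_filter1d(trace.values, size=w, mode="nearest")
    return EARTrace(side=trace.side, fps=trace.fps, values=vals, gap_mask=trace.gap_mask.copy())


def _estimate_noise_sd(values: np.ndarray) -> float:
    """Robust SD of the additive sample noise from successive differences.

    For i.i.d. noise, successive differences have SD sqrt(2) * sigma; the
    median absolute difference over 0.6745 estimates that robustly even with
    blinks present (they occupy a minority of samples).
    """
    d = np.diff(values)
    if d.size == 0:
        return 0.0
    return float(np.median(np.abs(d)) / (np.sqrt(2.0) * norm.ppf(0.75)))


def _rolling_percentile(values: np.ndarray, window: int, q: float, stride: int) -> np.ndarray:
    """Centred rolling percentile evaluated on a strided grid and linearly
    interpolated back to full length (windows truncated at the edges)."""
    n = values.size
    half = window // 2
    centers = np.arange(0, n, max(1, stride))
    if centers[-1] != n - 1:
        centers = np.append(centers, n - 1)
    out = np.empty(centers.size)
    for k, c in enumerate(centers):
        lo = max(0, c - half)
        hi = min(n, c + half + 1)
        out[k] = np.percentile(values[lo:hi], q)
    if centers.size == 1:
        return np.full(n, out[0])
    return np.interp(np.arange(n), centers, out)


def estimate_baseline(trace: EARTrace, params: DetectionParams) -> np.ndarray:
    """Per-sample open-eye baseline of a trace.

    Rolling ``baseline_percentile`` of the smoothed trace over a centred
    ``baseline_window_s`` window.  With ``noise_bias_correction`` the
    Gaussian quantile offset ``z_q * sigma_smooth`` is subtracted, where
    ``sigma_smooth`` is the residual noise SD of the smoothed signal
    estimated from successive differences of the raw trace; this keeps the
    baseline on the open-eye level instead of the upper noise envelope,
    which matters for the interpolated crossing times of slow shallow
    blinks.  An all-zero trace returns an all-zero baseline with an
    :class:`AllZeroBaselineWarning`.
    """
    if trace.duration_s < params.baseline_window_s:
        raise ValueError("trace shorter than baseline window")
    smoothed = smooth_trace(trace, params.smooth_window_ms)
    s = smoothed.values
    if np.all(s == 0):
        warnings.warn("trace never opens; baseline is all zero", AllZeroBaselineWarning)
        return np.zeros_like(s)
    window = _window_samples(params.baseline_window_s * 1000.0, trace.fps)
    stride = _window_samples(250.0, trace.fps)  # 4 baseline samples per second
    base = _rolling_percentile(s, window, params.baseline_percentile, stride)
    if params.noise_bias_correction:
        w = _window_samples(params.smooth_window_ms, trace.fps)
        sigma_raw = _estimate_noise_sd(trace.values)
        sigma_smooth = sigma_raw / np.sqrt(w)
        base = base - norm.ppf(params.baseline_percentile / 100.0) * sigma_smooth
    return np.maximum(base, 0.0)


def classify_blink(event: BlinkEvent, params: DetectionParams) -> tuple[bool, bool]:
    """Set and return the (counted, complete) flags of an event.

    ``counted``: minimum EAR at or below ``theta_p * baseline`` (pupil at
    least covered).  ``complete``: minimum EAR at or below ``theta_c`` (lids
    meet).  Ties classify as closed.
    """
    counted = event.min_ear <= params.theta_p * event.baseline_ear
    complete = event.min_ear <= params.theta_c
    event.counted = counted
    event.complete = complete
    return counted, complete


def _cross_time(i0: int, i1: int, rel: np.ndarray, fps: float) -> float:
    """Time where the linear segment of rel = s - thr between samples i0 and
    i1 crosses zero."""
    a, b = rel[i0], rel[i1]
    if a == b:
        frac = 0.0
    else:
        frac = a / (a - b)
    return (i0 + frac * (i1 - i0)) / fps


def detect_blinks(trace: EARTrace, params: DetectionParams | None = None) -> list[BlinkEvent]:
    """Detect, merge, filter and classify blinks on one EAR trace.

    Returns time-ordered, disjoint events; every returned event has
    ``counted=True`` by construction of the counting threshold.
    """
    params = params or DetectionParams()
    if trace.duration_s < params.baseline_window_s:
        raise ValueError("trace duration shorter than baseline window")
    smoothed = smooth_trace(trace, params.smooth_window_ms)
    s = smoothed.values
    base = estimate_baseline(trace, params)
    thr = params.theta_p * base
    release_level = params.hysteresis_fraction * base
    n = s.size

    below = s <= thr
    if not below.any():
        return []
    edges = np.diff(below.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1))  # last below sample of each run
    if below[0]:
        starts.insert(0, 0)
    if below[-1]:
        ends.append(n - 1)

    # hysteresis: a run only releases once s >= hysteresis_fraction * base;
    # runs that recur before release merge into one candidate.
    above_release = s >= release_level
    idx = np.where(above_release, np.arange(n), n)
    next_release = np.minimum.accumulate(idx[::-1])[::-1]  # first release at or after i

    candidates: list[tuple[int, int]] = []  # (first below sample, last below sample)
    cur_start, cur_end = starts[0], ends[0]
    for st, en in zip(starts[1:], ends[1:]):
        release_at = next_release[min(cur_end + 1, n - 1)]  # n if it never releases
        if st < release_at:
            cur_end = en  # re-dip before release: same candidate
        else:
            candidates.append((cur_start, cur_end))
            cur_start, cur_end = st, en
    candidates.append((cur_start, cur_end))

    rel = s - thr
    events: list[BlinkEvent] = []
    for st, en in candidates:
        onset = _cross_time(st - 1, st, rel, trace.fps) if st > 0 else 0.0
        offset = _cross_time(en, en + 1, rel, trace.fps) if en < n - 1 else (n - 1) / trace.fps
        if not offset > onset:  # zero-width edge case at trace boundary
            offset = onset + 1.0 / trace.fps
        min_ear = float(s[st : en + 1].min())
        events.append(
            BlinkEvent(
                onset_s=onset,
                offset_s=offset,
                min_ear=min_ear,
                baseline_ear=float(base[st]),
            )
        )

    # merge events separated by less than merge_gap_ms
    merged: list[BlinkEvent] = []
    gap_s = params.merge_gap_ms / 1000.0
    for ev in events:
        if merged and ev.onset_s - merged[-1].offset_s < gap_s:
            prev = merged[-1]
            merged[-1] = BlinkEvent(
                onset_s=prev.onset_s,
                offset_s=ev.offset_s,
                min_ear=min(prev.min_ear, ev.min_ear),
                baseline_ear=prev.baseline_ear,
            )
        else:
            merged.append(ev)

    out = []
    for ev in merged:
        if params.min_duration_ms <= ev.duration_ms <= params.max_duration_ms:
            classify_blink(ev, params)
            out.append(ev)
    return out


def events_to_frame(events: Sequence[BlinkEvent], side: str) -> pd.DataFrame:
    """Tabulate events in the blink-event CSV dialect."""
    return pd.DataFrame(
        {
            "side": [side] * len(events),
            "onset_s": [e.onset_s for e in events],
            "offset_s": [e.offset_s for e in events],
            "duration_ms": [e.duration_ms for e in events],
            "min_ear": [e.min_ear for e in events],
            "baseline_ear": [e.baseline_ear for e in events],
            "counted": [e.counted for e in events],
            "complete": [e.complete for e in events],
        }
    )


def write_events_csv(events_by_side: dict[str, Sequence[BlinkEvent]], path) -> None:
    frames = [events_to_frame(evs, side) for side, evs in events_by_side.items()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_events_csv(path) -> dict[str, list[BlinkEvent]]:
    df = pd.read_csv(path)
    out: dict[str, list[BlinkEvent]] = {}
    for _, row in df.iterrows():
        ev = BlinkEvent(
            onset_s=float(row["onset_s"]),
            offset_s=float(row["offset_s"]),
            min_ear=float(row["min_ear"]),
            baseline_ear=float(row["baseline_ear"]),
            counted=bool(row["counted"]),
            complete=bool(row["complete"]),
        )
        out.setdefault(str(row["side"]), []).append(ev)
    return out
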