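"""Per-eye blink summary statistics and per-minute time courses.

Reduces an EAR trace plus its detected blink events to the clinimetric
summary reported per eye: blink-free average EAR, recording-wide minimum
and maximum EAR, blink counts normalised to 20 minutes, per-minute
frequencies, mean blink duration, and the complete-closure subset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .detect import BlinkEvent, DetectionParams, smooth_trace
from .ear import EARTrace

__all__ = [
    "EyeBlinkSummary",
    "TimeCourse",
    "blink_free_average_ear",
    "summarize_eye",
    "per_minute_timecourse",
    "summary_to_dict",
    "SUMMARY_PARAMETERS",
]

#: summary fields used as comparison parameters by the group statistics
SUMMARY_PARAMETERS = (
    "avg_ear",
    "min_ear",
    "max_ear",
    "n_blinks_20min",
    "freq_per_min",
    "mean_duration_ms",
    "n_complete_20min",
    "freq_complete_per_min",
)


@dataclass
class EyeBlinkSummary:
    """One eye's blink profile over a recording.

    ``mean_duration_ms`` is NaN when no blink was counted (an explicit
    undefined marker, never 0).  ``min_ear`` / ``max_ear`` are global
    extremes of the smoothed trace; ``min_ear_blinkmean`` (mean of per-blink
    minima) is reported alongside because the recording-global minimum and
    the typical blink floor answer different clinical questions.
    """

    side: str
    avg_ear: float
    min_ear: float
    max_ear: float
    min_ear_blinkmean: float
    n_blinks: int
    n_blinks_20min: float
    freq_per_min: float
    mean_duration_ms: float
    n_complete: int
    n_complete_20min: float
    freq_complete_per_min: float
    recording_duration_s: float

    def __post_init__(self) -> None:
        eps = 1e-9  # float tolerance: blink-free mean of a constant trace
        if not (self.min_ear - eps <= self.avg_ear <= self.max_ear + eps):
            raise ValueError("require min_ear <= avg_ear <= max_ear")
        if self.n_complete > self.n_blinks:
            raise ValueError("complete blinks are a subset of counted blinks")


@dataclass
class TimeCourse:
    """Per-minute blink counts and mean durations; empty bins carry NaN
    duration."""

    bin_minutes: np.ndarray
    counts_per_bin: np.ndarray
    mean_duration_per_bin_ms: np.ndarray


def _blink_free_intervals(events: Sequence[BlinkEvent], duration_s: float) -> list[tuple[float, float]]:
    """Complement of the event intervals within [0, duration_s)."""
    out = []
    cursor = 0.0
    for ev in sorted(events, key=lambda e: e.onset_s):
        if ev.onset_s > cursor:
            out.append((cursor, ev.onset_s))
        cursor = max(cursor, ev.offset_s)
    if cursor < duration_s:
        out.append((cursor, duration_s))
    return out


def blink_free_average_ear(
    trace: EARTrace,
    events: Sequence[BlinkEvent],
    window_s: float = 3.0,
    params: DetectionParams | None = None,
) -> float:
    """Average openness over the first ``window_s`` of every blink-free
    interval.

    The smoothed EAR is averaged over the union of the leading ``window_s``
    seconds of each inter-blink interval (shorter intervals contribute
    wholly); with no events the first ``window_s`` of the whole recording is
    used.  This estimates the habitual open-eye EAR while staying clear of
    the closures themselves.
    """
    params = params or DetectionParams()
    s = smooth_trace(trace, params.smooth_window_ms).values
    fps = trace.fps
    mask = np.zeros(s.size, dtype=bool)
    for t0, t1 in _blink_free_intervals(events, trace.duration_s):
        end = min(t1, t0 + window_s)
        i0 = int(np.ceil(t0 * fps))
        i1 = min(int(np.floor(end * fps)) + 1, s.size)
        if i1 > i0:
            mask[i0:i1] = True
    if not mask.any():
        raise ValueError("no blink-free samples")
    return float(s[mask].mean())


def summarize_eye(
    trace: EARTrace,
    events: Sequence[BlinkEvent],
    params: DetectionParams | None = None,
) -> EyeBlinkSummary:
    """Reduce one eye's trace and events to an :class:`EyeBlinkSummary`.

    Counts are normalised to a 20-minute recording
    (``n_blinks_20min = count * 1200 / duration_s``) so recordings of other
    lengths stay comparable; frequencies are counts per recorded minute.
    """
    params = params or DetectionParams()
    if trace.n_samples == 0:
        raise ValueError("zero-length trace")
    s = smooth_trace(trace, params.smooth_window_ms).values
    counted = [e for e in events if e.counted]
    complete = [e for e in counted if e.complete]
    duration_s = trace.duration_s
    minutes = duration_s / 60.0
    to20 = 1200.0 / duration_s
    mean_dur = float(np.mean([e.duration_ms for e in counted])) if counted else math.nan
    blinkmean = float(np.mean([e.min_ear for e in counted])) if counted else float(s.min())
    return EyeBlinkSummary(
        side=trace.side,
        avg_ear=blink_free_average_ear(trace, events, params=params),
        min_ear=float(s.min()),
        max_ear=float(s.max()),
        min_ear_blinkmean=blinkmean,
        n_blinks=len(counted),
        n_blinks_20min=len(counted) * to20,
        freq_per_min=len(counted) / minutes,
        mean_duration_ms=mean_dur,
        n_complete=len(complete),
        n_complete_20min=len(complete) * to20,
        freq_complete_per_min=len(complete) / minutes,
        recording_duration_s=duration_s,
    )


def per_minute_timecourse(events: Sequence[BlinkEvent], duration_s: float) -> TimeCourse:
    """Bin counted events by onset into half-open minute bins.

    Bin ``k`` (1-based) covers ``[60 (k-1), 60 k)`` seconds, so an onset at
    exactly 60.0 s falls in bin 2.  Empty bins have NaN mean duration.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n_bins = int(np.ceil(duration_s / 60.0))
    counts = np.zeros(n_bins, dtype=int)
    dur_sums = np.zeros(n_bins)
    for ev in events:
        if not ev.counted:
            continue
        if not (0.0 <= ev.onset_s < duration_s):
            raise ValueError(f"event onset {ev.onset_s} outside [0, {duration_s})")
        k = int(ev.onset_s // 60.0)
        counts[k] += 1
        dur_sums[k] += ev.duration_ms
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_dur = np.where(counts > 0, dur_sums / np.maximum(counts, 1), np.nan)
    return TimeCourse(
        bin_minutes=np.arange(1, n_bins + 1),
        counts_per_bin=counts,
        mean_duration_per_bin_ms=mean_dur,
    )


def summary_to_dict(summary: EyeBlinkSummary) -> dict:
    return {
        "side": summary.side,
        "avg_ear": summary.avg_ear,
        "min_ear": summary.min_ear,
        "max_ear": summary.max_ear,
        "min_ear_blinkmean": summary.min_ear_blinkmean,
        "n_blinks": summary.n_blinks,
        "n_blinks_20min": summary.n_blinks_20min,
        "freq_per_min": summary.freq_per_min,
        "mean_duration_ms": summary.mean_duration_ms,
        "n_complete": summary.n_complete,
        "n_complete_20min": summary.n_complete_20min,
        "freq_complete_per_min": summary.freq_complete_per_min,
        "recording_duration_s": summary.recording_duration_s,
    }


def timecourse_frame(tc: TimeCourse, subject: str = "", side: str = "") -> pd.DataFrame:
    """Time-course rows in the CSV dialect subject,side,minute,count,mean_duration_ms."""
    return pd.DataFrame(
        {
            "subject": subject,
            "side": side,
            "minute": tc.bin_minutes,
            "count": tc.counts_per_bin,
            "mean_duration_ms": tc.mean_duration_per_bin_ms,
        }
    )
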