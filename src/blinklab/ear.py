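"""Eye-aspect-ratio (EAR) extraction from eye-landmark tables.

The EAR summarises eye openness from six landmarks per eye: the two eye
corners (p1 temporal, p4 nasal) and two upper/lower lid pairs (p2, p6) and
(p3, p5)::

    EAR = (|p2 - p6| + |p3 - p5|) / (2 |p1 - p4|)

It is dimensionless and invariant to translation, rotation and uniform
scaling of the landmark set, hence to the distance between the eye and the
camera.  An open adult eye sits around 0.25-0.35; a closed eye approaches 0.

This module reads per-frame landmark tables, computes per-frame EAR and
palpebral fissure height, and assembles uniformly sampled per-eye
:class:`EARTrace` objects, the central object of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EyeLandmarkSet",
    "LandmarkFrame",
    "EARTrace",
    "compute_ear",
    "compute_fissure_height",
    "read_landmark_table",
    "write_landmark_table",
    "build_ear_traces",
    "palpebral_height_ratio",
    "read_ear_csv",
    "write_ear_csv",
    "LANDMARK_KEYS",
]

#: landmark names in column order: p1 temporal corner, p2/p3 upper lid,
#: p4 nasal corner, p5/p6 lower lid (image convention, y down).
LANDMARK_KEYS = ("p1", "p2", "p3", "p4", "p5", "p6")


@dataclass(frozen=True)
class EyeLandmarkSet:
    """Six 2-D eye landmarks (pixel units) for one eye in one frame."""

    p1: tuple[float, float]
    p2: tuple[float, float]
    p3: tuple[float, float]
    p4: tuple[float, float]
    p5: tuple[float, float]
    p6: tuple[float, float]

    def points(self) -> np.ndarray:
        """Return the landmarks as a (6, 2) array in p1..p6 order."""
        return np.asarray([self.p1, self.p2, self.p3, self.p4, self.p5, self.p6], dtype=float)

    def is_finite(self) -> bool:
        return bool(np.all(np.isfinite(self.points())))


@dataclass(frozen=True)
class LandmarkFrame:
    """One video frame: both eyes' landmarks plus a validity flag."""

    frame_index: int
    time_s: float
    left_eye: EyeLandmarkSet
    right_eye: EyeLandmarkSet
    valid: bool = True


@dataclass
class EARTrace:
    """Uniformly sampled per-eye openness signal.

    ``gap_mask`` flags samples that came from invalid frames and were filled
    by interpolation; downstream QC can report the gap fraction while the
    detector always sees a complete signal.
    """

    side: str
    fps: float
    values: np.ndarray
    gap_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.gap_mask is None:
            self.gap_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if self.gap_mask.shape != self.values.shape:
            raise ValueError("gap_mask and values must have the same length")
        good = self.values[~self.gap_mask]
        if good.size and (np.any(~np.isfinite(good)) or np.any(good < 0)):
            raise ValueError("non-gap EAR samples must be finite and >= 0")

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fps

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (frame k at k / fps)."""
        return np.arange(self.n_samples) / self.fps

    @property
    def gap_fraction(self) -> float:
        return float(self.gap_mask.mean()) if self.n_samples else 0.0


def _dist(a, b) -> float:
    return float(np.hypot(a[0] - b[0], a[1] - b[1]))


def compute_ear(eye: EyeLandmarkSet) -> float:
    """Eye aspect ratio of one landmark set.

    Raises
    ------
    ValueError
        If the eye-corner distance |p1 - p4| is zero (degenerate geometry).
    """
    width = _dist(eye.p1, eye.p4)
    if width == 0.0:
        raise ValueError("degenerate eye geometry: corner distance |p1 - p4| is zero")
    return (_dist(eye.p2, eye.p6) + _dist(eye.p3, eye.p5)) / (2.0 * width)


def compute_fissure_height(eye: EyeLandmarkSet) -> float:
    """Palpebral fissure height in pixels.

    Maximum vertical extent between the upper- and lower-lid landmark pairs
    (the highest to lowest point of the eye opening); which vertical chord
    carries the maximum is irrelevant for closed eyes where both vanish.
    """
    h_nasal = abs(eye.p2[1] - eye.p6[1])
    h_temporal = abs(eye.p3[1] - eye.p5[1])
    return max(h_nasal, h_temporal)


def _landmark_columns() -> list[str]:
    cols = []
    for side in ("left", "right"):
        for pk in LANDMARK_KEYS:
            cols.append(f"{side}_{pk}_x")
            cols.append(f"{side}_{pk}_y")
    return cols


def read_landmark_table(path) -> list[LandmarkFrame]:
    """Read a landmark CSV into a list of :class:`LandmarkFrame`.

    Expected header: ``frame,time_s,<eye>_<pk>_x,<eye>_<pk>_y`` for
    eye in {left, right} and pk in p1..p6.  Rows with non-finite coordinates
    are kept but flagged ``valid=False``; downstream gap handling deals with
    them.  Timestamps must be strictly increasing.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"landmark table {path} is empty")
    required = ["frame", "time_s"] + _landmark_columns()
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"landmark table missing columns: {missing[:4]}{'...' if len(missing) > 4 else ''}")
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(~np.isfinite(t)) or np.any(np.diff(t) <= 0):
        raise ValueError("time_s must be finite and strictly increasing")

    frames: list[LandmarkFrame] = []
    for _, row in df.iterrows():
        eyes = {}
        valid = True
        for side in ("left", "right"):
            pts = {}
            for pk in LANDMARK_KEYS:
                x, y = float(row[f"{side}_{pk}_x"]), float(row[f"{side}_{pk}_y"])
                pts[pk] = (x, y)
            eye = EyeLandmarkSet(**pts)
            if not eye.is_finite():
                valid = False
            eyes[side] = eye
        frames.append(
            LandmarkFrame(
                frame_index=int(row["frame"]),
                time_s=float(row["time_s"]),
                left_eye=eyes["left"],
                right_eye=eyes["right"],
                valid=valid,
            )
        )
    return frames


def write_landmark_table(frames: Iterable[LandmarkFrame], path) -> None:
    """Write landmark frames in the CSV dialect read_landmark_table expects."""
    records = []
    for fr in frames:
        rec: dict[str, float] = {"frame": fr.frame_index, "time_s": fr.time_s}
        for side, eye in (("left", fr.left_eye), ("right", fr.right_eye)):
            for pk in LANDMARK_KEYS:
                x, y = getattr(eye, pk)
                rec[f"{side}_{pk}_x"] = x
                rec[f"{side}_{pk}_y"] = y
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, index=False)


def _interpolate_gaps(values: np.ndarray, gap: np.ndarray) -> np.ndarray:
    """Fill gap samples by linear interpolation; edge gaps hold the nearest
    valid value."""
    out = values.astype(float).copy()
    if not gap.any():
        return out
    idx = np.arange(values.size)
    good = ~gap
    out[gap] = np.interp(idx[gap], idx[good], values[good])
    return out


def build_ear_traces(
    frames: Sequence[LandmarkFrame], fps: float, fps_tolerance: float = 0.01
) -> tuple[EARTrace, EARTrace]:
    """Compute per-eye EAR traces from landmark frames.

    Invalid frames become gap-masked samples filled by linear interpolation
    between the nearest valid neighbours (edge gaps held at the nearest valid
    value), so detection never sees missing samples while the gap mask is
    preserved for QC.

    Raises
    ------
    ValueError
        Fewer than two valid frames, or the frame timestamps disagree with
        ``fps`` by more than ``fps_tolerance`` (relative).
    """
    if not frames:
        raise ValueError("no frames")
    valid = np.array([f.valid for f in frames], dtype=bool)
    if valid.sum() < 2:
        raise ValueError("need at least 2 valid frames to build EAR traces")
    t = np.array([f.time_s for f in frames], dtype=float)
    if len(frames) >= 2:
        implied_fps = (len(frames) - 1) / (t[-1] - t[0])
        if abs(implied_fps - fps) > fps_tolerance * fps:
            raise ValueError(
                f"timestamps imply {implied_fps:.2f} fps, inconsistent with fps={fps} "
                f"beyond {100 * fps_tolerance:.0f}% tolerance"
            )

    traces = []
    for side, attr in (("left", "left_eye"), ("right", "right_eye")):
        vals = np.empty(len(frames))
        gap = ~valid
        for i, fr in enumerate(frames):
            if valid[i]:
                vals[i] = compute_ear(getattr(fr, attr))
            else:
                vals[i] = np.nan
        vals = _interpolate_gaps(vals, gap)
        traces.append(EARTrace(side=side, fps=fps, values=vals, gap_mask=gap))
    return traces[0], traces[1]


def _blink_free_mask(n: int, fps: float, events) -> np.ndarray:
    """Boolean mask of samples outside every blink event interval."""
    mask = np.ones(n, dtype=bool)
    for ev in events:
        i0 = max(0, int(np.floor(ev.onset_s * fps)))
        i1 = min(n, int(np.ceil(ev.offset_s * fps)) + 1)
        mask[i0:i1] = False
    return mask


def palpebral_height_ratio(
    paretic_heights: np.ndarray,
    contra_heights: np.ndarray,
    events_paretic,
    events_contra,
    fps: float,
) -> float:
    """Paretic-to-contralateral palpebral fissure height ratio, in percent.

    Both height sequences must be sampled on the same clock.  Blink frames
    (from either eye's event list) are excluded and the ratio of medians is
    returned; the median keeps residual blink contamination from dragging
    the open-eye height down.
    """
    ph = np.asarray(paretic_heights, dtype=float)
    ch = np.asarray(contra_heights, dtype=float)
    if ph.shape != ch.shape:
        raise ValueError("height sequences must share the same sampling")
    n = ph.size
    mask = _blink_free_mask(n, fps, events_paretic) & _blink_free_mask(n, fps, events_contra)
    if not mask.any():
        raise ValueError("no blink-free samples")
    med_c = float(np.median(ch[mask]))
    if med_c == 0.0:
        raise ValueError("contralateral median fissure height is zero")
    return 100.0 * float(np.median(ph[mask])) / med_c


def write_ear_csv(left: EARTrace, right: EARTrace, path) -> None:
    """Write a per-eye EAR trace pair as CSV.

    Header: ``frame,time_s,ear_left,ear_right,gap_left,gap_right``.
    """
    if left.n_samples != right.n_samples or left.fps != right.fps:
        raise ValueError("left and right traces must share length and fps")
    df = pd.DataFrame(
        {
            "frame": np.arange(left.n_samples),
            "time_s": left.times,
            "ear_left": left.values,
            "ear_right": right.values,
            "gap_left": left.gap_mask.astype(int),
            "gap_right": right.gap_mask.astype(int),
        }
    )
    df.to_csv(path, index=False)


def read_ear_csv(path) -> tuple[EARTrace, EARTrace]:
    """Read an EAR CSV written by :func:`write_ear_csv`."""
    df = pd.read_csv(path)
    required = ["frame", "time_s", "ear_left", "ear_right", "gap_left", "gap_right"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"EAR CSV missing columns: {missing}")
    if df.empty:
        raise ValueError(f"EAR CSV {path} is empty")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) >= 2:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("time_s must be strictly increasing")
        fps = (len(t) - 1) / (t[-1] - t[0])
    else:
        raise ValueError("EAR CSV needs at least 2 samples")
    left = EARTrace("left", fps, df["ear_left"].to_numpy(float), df["gap_left"].to_numpy(bool))
    right = EARTrace("right", fps, df["ear_right"].to_numpy(float), df["gap_right"].to_numpy(bool))
    return left, right
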