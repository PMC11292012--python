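"""Synthetic EAR-trace and cohort generation.

Patient videos behind the clinical blink profiles are not distributable, so
this module synthesises 240-fps EAR traces whose blink statistics match the
published per-eye group profiles (healthy, acute facial palsy and
postparalytic synkinesis, paretic and contralateral sides), together with
the ground-truth event lists needed to validate the detector.

Model
-----
Blink onsets follow a renewal process: inter-onset gap = refractory period
(0.5 s) + an exponential extra gap, giving a target mean rate of
``60 / (refractory_s + mean_extra_gap_s)`` blinks per minute.  Each blink is
a raised-cosine dip from the instantaneous open-eye level down to a floor:
the complete-closure floor ``floor_complete`` with probability
``p_complete``, else the subject's partial floor ``floor_partial``.  The dip
width is parameterised so that its full width at the detector's counting
level ``theta_p * baseline_ear`` equals the drawn duration — generator and
detector speak the same duration language.  A slow sinusoidal drift
modulates the open-eye level only (a closed eye is closed regardless of
openness drift, so the floor is anchored), occasional wide-opening bumps
provide maximum-EAR realism, and i.i.d. Gaussian sample noise is added
last.  Everything is driven by a single seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .detect import BlinkEvent, DetectionParams
from .ear import EARTrace, EyeLandmarkSet, LandmarkFrame

__all__ = [
    "BlinkGeneratorPreset",
    "SyntheticSubjectSpec",
    "Cohort",
    "preset_registry",
    "generate_ear_trace",
    "emit_landmarks",
    "generate_cohort",
    "render_subject",
    "PALPEBRAL_FISSURE_RATIO",
    "PROM_DISTRIBUTIONS",
]

#: paretic/contralateral palpebral fissure height ratio by patient group,
#: as a fraction (the clinical report prints 96% and 88%).
PALPEBRAL_FISSURE_RATIO = {"acute": 0.96, "synkinesis": 0.88}

#: wide-opening excursion bumps per minute (max-EAR realism)
_BUMP_RATE_PER_MIN = 2.0
_DRIFT_PERIOD_S = 300.0


@dataclass(frozen=True)
class BlinkGeneratorPreset:
    """Generative blink model of one eye condition.

    ``floor_partial`` is a subject-level constant: partial blinks of one eye
    bottom out at a reproducible level, so the recording-global minimum EAR
    recovers it (per-blink floor variability would bias the global minimum
    downward).
    """

    name: str
    baseline_ear: float
    refractory_s: float
    mean_extra_gap_s: float
    duration_mean_ms: float
    duration_sd_ms: float
    p_complete: float
    floor_complete: float
    floor_partial: float
    noise_sd: float = 0.01
    drift_amplitude: float = 0.02
    max_excursion: float = 0.10

    def __post_init__(self) -> None:
        theta_p = DetectionParams().theta_p
        if not (0.0 <= self.floor_complete <= self.floor_partial):
            raise ValueError("require 0 <= floor_complete <= floor_partial")
        if not (self.floor_partial < theta_p * self.baseline_ear <= self.baseline_ear):
            raise ValueError(
                "floors must sit below the counting threshold "
                f"(floor_partial={self.floor_partial} vs "
                f"theta_p*b={theta_p * self.baseline_ear:.3f})"
            )
        if not (0.0 <= self.p_complete <= 1.0):
            raise ValueError("p_complete in [0, 1]")
        if self.duration_mean_ms <= 0 or self.duration_sd_ms < 0:
            raise ValueError("durations must be positive")
        if self.refractory_s < 0 or self.mean_extra_gap_s < 0:
            raise ValueError("gaps must be nonnegative")

    @property
    def rate_per_min(self) -> float:
        """Target blink rate implied by the renewal gaps."""
        return 60.0 / (self.refractory_s + self.mean_extra_gap_s)

    @classmethod
    def from_rate(cls, name: str, baseline_ear: float, rate_per_min: float, **kw) -> "BlinkGeneratorPreset":
        """Construct with ``mean_extra_gap_s`` derived from a target rate."""
        refractory = kw.pop("refractory_s", 0.5)
        if rate_per_min <= 0:
            extra = math.inf
        else:
            extra = max(60.0 / rate_per_min - refractory, 0.0)
        return cls(
            name=name,
            baseline_ear=baseline_ear,
            refractory_s=refractory,
            mean_extra_gap_s=extra,
            **kw,
        )

    def with_rate(self, rate_per_min: float) -> "BlinkGeneratorPreset":
        extra = math.inf if rate_per_min <= 0 else max(60.0 / rate_per_min - self.refractory_s, 0.0)
        return replace(self, mean_extra_gap_s=extra)


def preset_registry() -> dict[str, BlinkGeneratorPreset]:
    """The five published per-eye blink profiles.

    Rates, baseline/minimum EAR values and mean durations follow the
    per-eye clinical summary table (healthy left eye; acute palsy and
    synkinesis, paretic and contralateral sides); ``p_complete`` is the
    ratio of complete-closure to all-blink frequency of the same column.
    """
    return {
        # healthy left eye: EAR 0.29, 12.7 blinks/min of which 7.4 complete,
        # duration 199.7 +- 42.8 ms
        "healthy_eye": BlinkGeneratorPreset.from_rate(
            "healthy_eye", 0.29, 12.7,
            duration_mean_ms=199.7, duration_sd_ms=42.8,
            p_complete=7.4 / 12.7, floor_complete=0.02, floor_partial=0.15,
            max_excursion=0.10,
        ),
        # acute palsy, paretic side: shallow rare blinks, no complete closure,
        # partial floor at the reported minimum EAR 0.13
        "acute_paretic": BlinkGeneratorPreset.from_rate(
            "acute_paretic", 0.24, 2.3,
            duration_mean_ms=364.0, duration_sd_ms=168.3,
            p_complete=0.0, floor_complete=0.02, floor_partial=0.13,
            max_excursion=0.21,
        ),
        # acute palsy, contralateral side: near-normal, nearly all complete
        "acute_contra": BlinkGeneratorPreset.from_rate(
            "acute_contra", 0.27, 12.2,
            duration_mean_ms=234.0, duration_sd_ms=40.0,
            p_complete=12.1 / 12.2, floor_complete=0.01, floor_partial=0.15,
            max_excursion=0.08,
        ),
        # synkinesis, paretic side: reduced rate, minority complete
        "synk_paretic": BlinkGeneratorPreset.from_rate(
            "synk_paretic", 0.30, 6.6,
            duration_mean_ms=240.8, duration_sd_ms=58.3,
            p_complete=1.7 / 6.6, floor_complete=0.02, floor_partial=0.12,
            max_excursion=0.16,
        ),
        # synkinesis, contralateral side
        "synk_contra": BlinkGeneratorPreset.from_rate(
            "synk_contra", 0.32, 11.1,
            duration_mean_ms=218.1, duration_sd_ms=41.5,
            p_complete=7.8 / 11.1, floor_complete=0.02, floor_partial=0.15,
            max_excursion=0.16,
        ),
    }


def _width_factor(a: float) -> float:
    """Fraction of a raised-cosine dip's total support spent at or below
    relative depth ``a`` (0 < a < 1)."""
    return 1.0 - math.acos(1.0 - 2.0 * a) / math.pi


def generate_ear_trace(
    preset: BlinkGeneratorPreset,
    duration_s: float = 1200.0,
    fps: float = 240.0,
    seed: int | Sequence[int] = 0,
    theta_p: float = 0.7,
    theta_c: float = 0.10,
    side: str = "left",
) -> tuple[EARTrace, list[BlinkEvent]]:
    """Render one synthetic EAR trace plus its ground-truth event list.

    Ground-truth events carry the drawn onset/duration (full width at the
    ``theta_p * baseline_ear`` level), the floor as ``min_ear`` and the
    completeness flag per ``theta_c``, so detector output can be validated
    one-to-one.  The renewal gaps are extended where needed so consecutive
    blink waveforms never overlap (affects a small fraction of short gaps).
    """
    if duration_s <= 0 or fps <= 0:
        raise ValueError("duration_s and fps must be positive")
    b = preset.baseline_ear
    if not preset.floor_partial < theta_p * b:
        raise ValueError("preset floors at or above counting threshold: undetectable blinks")
    if preset.p_complete > 0 and not preset.floor_complete < theta_p * b:
        raise ValueError("preset floors at or above counting threshold: undetectable blinks")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fps))
    t = np.arange(n) / fps

    # open-eye level: baseline + slow zero-mean drift
    phase = rng.uniform(0.0, 2.0 * math.pi)
    open_level = b + preset.drift_amplitude * np.sin(2.0 * math.pi * t / _DRIFT_PERIOD_S + phase)
    signal = open_level.copy()

    # blink onsets: refractory + exponential renewal
    events: list[BlinkEvent] = []
    supports: list[tuple[float, float]] = []
    margin = 0.06  # s of clear signal between consecutive blink supports
    onset = None
    prev_tail = 0.0  # time from previous onset to the end of its support
    cursor = 0.0
    while True:
        if math.isinf(preset.mean_extra_gap_s):
            break
        gap = preset.refractory_s + rng.exponential(preset.mean_extra_gap_s)
        dur_ms = max(60.0, rng.normal(preset.duration_mean_ms, preset.duration_sd_ms))
        floor = preset.floor_complete if rng.uniform() < preset.p_complete else preset.floor_partial
        onset = cursor + gap if onset is None else onset + gap
        # size the dip against the local (drift-shifted) open level: the
        # detector's rolling baseline tracks drift, so the drawn duration is
        # realised at the threshold the detector actually applies
        dur_s = dur_ms / 1000.0
        open_c = b + preset.drift_amplitude * math.sin(
            2.0 * math.pi * (onset + dur_s / 2.0) / _DRIFT_PERIOD_S + phase
        )
        a = (1.0 - theta_p) * open_c / (open_c - floor)
        total_s = dur_s / _width_factor(a)
        lead = (total_s - dur_s) / 2.0  # support start to counting-level onset
        # keep supports disjoint: push the onset if the waveforms would touch
        min_onset = (cursor + prev_tail + margin + lead) if supports else lead
        onset = max(onset, min_onset)
        support = (onset - lead, onset - lead + total_s)
        if support[1] > duration_s - margin:
            break
        supports.append(support)
        cursor = onset
        prev_tail = support[1] - onset
        i0 = max(0, int(math.ceil(support[0] * fps)))
        i1 = min(n, int(math.floor(support[1] * fps)) + 1)
        tau = t[i0:i1] - support[0]
        w = 0.5 * (1.0 - np.cos(2.0 * math.pi * tau / total_s))
        signal[i0:i1] = floor + (open_level[i0:i1] - floor) * (1.0 - w)
        events.append(
            BlinkEvent(
                onset_s=onset,
                offset_s=onset + dur_s,
                min_ear=floor,
                baseline_ear=b,
                counted=True,
                complete=floor <= theta_c,
            )
        )

    # occasional wide-opening bumps, placed clear of any blink support
    if preset.max_excursion > 0:
        n_bumps = rng.poisson(_BUMP_RATE_PER_MIN * duration_s / 60.0)
        sigma = 0.08
        for _ in range(n_bumps):
            for _try in range(50):
                c = rng.uniform(0.0, duration_s)
                if all(not (lo - 4 * sigma < c < hi + 4 * sigma) for lo, hi in supports):
                    break
            else:
                continue
            height = preset.max_excursion * rng.uniform(0.6, 1.0)
            i0 = max(0, int((c - 4 * sigma) * fps))
            i1 = min(n, int((c + 4 * sigma) * fps) + 1)
            signal[i0:i1] += height * np.exp(-0.5 * ((t[i0:i1] - c) / sigma) ** 2)

    if preset.noise_sd > 0:
        signal = signal + rng.normal(0.0, preset.noise_sd, size=n)
    np.clip(signal, 0.0, None, out=signal)
    return EARTrace(side=side, fps=fps, values=signal), events


def emit_landmarks(
    trace: EARTrace,
    eye_width_px: float = 100.0,
    fissure_scale: float = 1.0,
    trace_right: EARTrace | None = None,
    fissure_scale_right: float | None = None,
) -> list[LandmarkFrame]:
    """Render landmark frames whose per-frame EAR equals the trace exactly.

    ``fissure_scale`` scales each eye's landmark set uniformly (a smaller
    eye): EAR is scale-invariant so the trace round-trips unchanged, while
    the palpebral fissure height scales linearly — a paretic-side scale of
    0.96 yields a 96% height ratio.  With no ``trace_right`` the same trace
    drives both eyes.
    """
    if eye_width_px <= 0:
        raise ValueError("eye_width_px must be positive")
    right = trace_right if trace_right is not None else trace
    scale_r = fissure_scale_right if fissure_scale_right is not None else fissure_scale
    if right.n_samples != trace.n_samples or right.fps != trace.fps:
        raise ValueError("left and right traces must share sampling")
    if np.any(trace.values < 0) or np.any(right.values < 0):
        raise ValueError("negative EAR sample")

    frames = []
    fps = trace.fps
    for i in range(trace.n_samples):
        eyes = {}
        for side, (v, s, x0) in (
            ("left", (trace.values[i], fissure_scale, 0.0)),
            ("right", (right.values[i], scale_r, 2.0 * eye_width_px)),
        ):
            w = eye_width_px * s
            half = v * w / 2.0
            eyes[side] = EyeLandmarkSet(
                p1=(x0, 0.0),
                p2=(x0 + 0.25 * w, half),
                p3=(x0 + 0.75 * w, half),
                p4=(x0 + w, 0.0),
                p5=(x0 + 0.75 * w, -half),
                p6=(x0 + 0.25 * w, -half),
            )
        frames.append(
            LandmarkFrame(
                frame_index=i,
                time_s=i / fps,
                left_eye=eyes["left"],
                right_eye=eyes["right"],
                valid=True,
            )
        )
    return frames


# ---------------------------------------------------------------------------
# cohorts

#: per-group PROM score distributions (mean, SD, lower, upper) as published:
#: FaCE domains and totals on 0-100, FDI physical on -25-100, FDI social and
#: total on 0-100.
PROM_DISTRIBUTIONS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "healthy": {
        "face_facial_movement": (100.0, 0.0, 0.0, 100.0),
        "face_facial_comfort": (99.4, 3.0, 0.0, 100.0),
        "face_oral_function": (100.0, 0.0, 0.0, 100.0),
        "face_eye_comfort": (93.6, 17.6, 0.0, 100.0),
        "face_lacrimal_comfort": (100.0, 0.0, 0.0, 100.0),
        "face_social_function": (100.0, 0.0, 0.0, 100.0),
        "face_total": (99.1, 2.4, 0.0, 100.0),
        "fdi_physical": (99.2, 2.3, -25.0, 100.0),
        "fdi_social": (84.5, 15.4, 0.0, 100.0),
        "fdi_total": (91.9, 7.8, 0.0, 100.0),
    },
    "acute": {
        "face_facial_movement": (43.1, 40.3, 0.0, 100.0),
        "face_facial_comfort": (87.5, 13.7, 0.0, 100.0),
        "face_oral_function": (56.3, 36.9, 0.0, 100.0),
        "face_eye_comfort": (39.6, 29.0, 0.0, 100.0),
        "face_lacrimal_comfort": (50.0, 41.8, 0.0, 100.0),
        "face_social_function": (75.0, 19.4, 0.0, 100.0),
        "face_total": (62.2, 16.5, 0.0, 100.0),
        "fdi_physical": (58.3, 15.4, -25.0, 100.0),
        "fdi_social": (74.7, 14.9, 0.0, 100.0),
        "fdi_total": (66.5, 11.5, 0.0, 100.0),
    },
    "synkinesis": {
        "face_facial_movement": (42.7, 23.4, 0.0, 100.0),
        "face_facial_comfort": (41.3, 26.3, 0.0, 100.0),
        "face_oral_function": (60.9, 28.1, 0.0, 100.0),
        "face_eye_comfort": (43.2, 36.5, 0.0, 100.0),
        "face_lacrimal_comfort": (53.1, 32.4, 0.0, 100.0),
        "face_social_function": (58.3, 32.0, 0.0, 100.0),
        "face_total": (49.8, 21.7, 0.0, 100.0),
        "fdi_physical": (62.1, 16.5, -25.0, 100.0),
        "fdi_social": (58.7, 24.7, 0.0, 100.0),
        "fdi_total": (60.4, 18.4, 0.0, 100.0),
    },
}

#: probability the paretic side is the left one, per patient group
#: (observed cohort composition: acute 2 of 6 left, synkinesis 15 of 24)
_P_PARETIC_LEFT = {"acute": 2 / 6, "synkinesis": 15 / 24}

# subject-level heterogeneity: between-subject scatter of rate, habitual
# openness and blink duration (shared by both eyes of a subject)
_RATE_LOGSD = 0.7
_DURATION_LOGSD = 0.15
_BASELINE_SD = 0.03


@dataclass(frozen=True)
class SyntheticSubjectSpec:
    """Recipe for one synthetic subject: group, side assignment, per-eye
    presets and the seed that makes the subject reproducible."""

    subject_id: str
    group: str
    paretic_side: str  # "left" | "right" | "none"
    preset_left: BlinkGeneratorPreset
    preset_right: BlinkGeneratorPreset
    seed: int

    def __post_init__(self) -> None:
        if (self.group == "healthy") != (self.paretic_side == "none"):
            raise ValueError("healthy subjects (and only they) have paretic_side='none'")


@dataclass
class Cohort:
    subjects: list[SyntheticSubjectSpec]
    prom: pd.DataFrame  # indexed by subject_id; group, paretic_side + PROM scores


def _draw_prom(rng: np.random.Generator, dist: tuple[float, float, float, float]) -> float:
    mean, sd, lo, hi = dist
    if sd == 0.0:
        return mean
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _vary_preset(preset: BlinkGeneratorPreset, rate_mult: float, dur_mult: float, b_shift: float) -> BlinkGeneratorPreset:
    theta_p = DetectionParams().theta_p
    b_lo = (preset.floor_partial + 0.02) / theta_p
    b = float(np.clip(preset.baseline_ear + b_shift, b_lo, 0.45))
    p = replace(
        preset,
        baseline_ear=b,
        duration_mean_ms=max(80.0, preset.duration_mean_ms * dur_mult),
    )
    return p.with_rate(preset.rate_per_min * rate_mult)


def generate_cohort(
    n_healthy: int = 30,
    n_acute: int = 6,
    n_synk: int = 24,
    seed: int = 0,
    coupling: float = 0.0,
    subject_variability: bool = True,
) -> Cohort:
    """Draw a synthetic cohort mirroring the published study composition
    (30 healthy / 6 acute palsy / 24 synkinesis by default).

    Healthy subjects carry the healthy preset on both eyes; patients carry
    the paretic preset on the paretic side (drawn with the observed
    left/right proportions) and the contralateral preset on the other.
    With ``subject_variability`` a subject-level lognormal rate multiplier,
    duration multiplier and openness shift are shared across both eyes, so
    between-subject scatter is of the magnitude the clinical tables report.

    PROM scores are truncated normals with the published group means/SDs,
    independent of the blink parameters by default.  ``coupling`` in [0, 1]
    injects a monotone dependence between the paretic-side blink rate and
    the FaCE eye-comfort score (coupling=1: comfort ranks follow rate ranks
    exactly) for power-testing the correlation analysis.
    """
    if min(n_healthy, n_acute, n_synk) < 0:
        raise ValueError("group sizes must be nonnegative")
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling in [0, 1]")
    rng = np.random.default_rng(seed)
    registry = preset_registry()
    subjects: list[SyntheticSubjectSpec] = []
    prom_rows = []
    latent_rates = []

    plan = (
        [("healthy", i) for i in range(n_healthy)]
        + [("acute", i) for i in range(n_acute)]
        + [("synkinesis", i) for i in range(n_synk)]
    )
    for group, i in plan:
        subject_id = f"{group[:4]}{i + 1:03d}"
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if subject_variability:
            rate_mult = float(np.exp(rng.normal(-_RATE_LOGSD**2 / 2, _RATE_LOGSD)))
            dur_mult = float(np.exp(rng.normal(0.0, _DURATION_LOGSD)))
            b_shift = float(rng.normal(0.0, _BASELINE_SD))
        else:
            rate_mult, dur_mult, b_shift = 1.0, 1.0, 0.0

        if group == "healthy":
            paretic_side = "none"
            left = right = registry["healthy_eye"]
        else:
            paretic_side = "left" if rng.uniform() < _P_PARETIC_LEFT[group] else "right"
            key = "acute" if group == "acute" else "synk"
            par, con = registry[f"{key}_paretic"], registry[f"{key}_contra"]
            left, right = (par, con) if paretic_side == "left" else (con, par)
        left = _vary_preset(left, rate_mult, dur_mult, b_shift)
        right = _vary_preset(right, rate_mult, dur_mult, b_shift)
        subjects.append(
            SyntheticSubjectSpec(
                subject_id=subject_id,
                group=group,
                paretic_side=paretic_side,
                preset_left=left,
                preset_right=right,
                seed=sub_seed,
            )
        )
        paretic_like = left if paretic_side in ("left", "none") else right
        latent_rates.append(math.log(paretic_like.rate_per_min) if paretic_like.rate_per_min > 0 else -math.inf)

        row = {"subject_id": subject_id, "group": group, "paretic_side": paretic_side}
        for instrument, dist in PROM_DISTRIBUTIONS[group].items():
            row[instrument] = _draw_prom(rng, dist)
        prom_rows.append(row)

    prom = pd.DataFrame(prom_rows).set_index("subject_id")
    if coupling > 0.0 and len(prom) > 1:
        # reassign eye-comfort scores cohort-wide so their ranks follow a
        # blend of the latent paretic-side rate and independent noise
        scores = np.sort(prom["face_eye_comfort"].to_numpy())
        z_rate = np.asarray(latent_rates)
        z_rate = (z_rate - z_rate.mean()) / (z_rate.std() or 1.0)
        latent = coupling * z_rate + (1.0 - coupling) * rng.normal(size=len(z_rate))
        ranks = np.argsort(np.argsort(latent))
        prom["face_eye_comfort"] = scores[ranks]
    return Cohort(subjects=subjects, prom=prom)


def render_subject(
    spec: SyntheticSubjectSpec,
    duration_s: float = 1200.0,
    fps: float = 240.0,
) -> tuple[EARTrace, EARTrace, dict[str, list[BlinkEvent]]]:
    """Render both eyes of a subject; returns traces plus ground truth."""
    left, gt_left = generate_ear_trace(
        spec.preset_left, duration_s, fps, seed=[spec.seed, 0], side="left"
    )
    right, gt_right = generate_ear_trace(
        spec.preset_right, duration_s, fps, seed=[spec.seed, 1], side="right"
    )
    return left, right, {"left": gt_left, "right": gt_right}
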