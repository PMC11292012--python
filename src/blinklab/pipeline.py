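"""End-to-end conveniences tying extraction, detection and metrics together."""

from __future__ import annotations

from typing import Sequence

from .detect import BlinkEvent, DetectionParams, detect_blinks
from .ear import EARTrace
from .metrics import EyeBlinkSummary, TimeCourse, per_minute_timecourse, summarize_eye
from .simulate import Cohort, render_subject
from .stats import SubjectRecord

__all__ = ["analyze_trace", "build_subject_records"]


def analyze_trace(
    trace: EARTrace, params: DetectionParams | None = None
) -> tuple[list[BlinkEvent], EyeBlinkSummary, TimeCourse]:
    """Run smooth -> baseline -> detect -> classify -> summarise -> bin for
    one eye."""
    params = params or DetectionParams()
    events = detect_blinks(trace, params)
    summary = summarize_eye(trace, events, params)
    timecourse = per_minute_timecourse(events, trace.duration_s)
    return events, summary, timecourse


def build_subject_records(
    cohort: Cohort,
    duration_s: float = 1200.0,
    fps: float = 240.0,
    params: DetectionParams | None = None,
) -> list[SubjectRecord]:
    """Render every cohort subject and reduce it to a SubjectRecord.

    Traces are rendered, analysed and discarded one subject at a time, so
    memory stays flat even for full-length 240-fps cohorts.
    """
    params = params or DetectionParams()
    records = []
    for spec in cohort.subjects:
        left, right, _ = render_subject(spec, duration_s=duration_s, fps=fps)
        _, summ_l, _ = analyze_trace(left, params)
        _, summ_r, _ = analyze_trace(right, params)
        prom = cohort.prom.loc[spec.subject_id].drop(["group", "paretic_side"]).to_dict()
        records.append(
            SubjectRecord(
                subject_id=spec.subject_id,
                group=spec.group,
                paretic_side=spec.paretic_side,
                summary_left=summ_l,
                summary_right=summ_r,
                prom={k: float(v) for k, v in prom.items()},
            )
        )
    return records
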