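"""Geometry, landmark I/O and EAR-trace assembly."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blinklab.detect import BlinkEvent
from blinklab.ear import (
    EARTrace,
    EyeLandmarkSet,
    build_ear_traces,
    compute_ear,
    compute_fissure_height,
    palpebral_height_ratio,
    read_ear_csv,
    read_landmark_table,
    write_ear_csv,
    write_landmark_table,
)
from blinklab.simulate import emit_landmarks, generate_ear_trace, preset_registry

from .conftest import make_trace


def _transform(eye: EyeLandmarkSet, scale=1.0, angle=0.0, shift=(0.0, 0.0)) -> EyeLandmarkSet:
    c, s = math.cos(angle), math.sin(angle)
    pts = {}
    for pk in ("p1", "p2", "p3", "p4", "p5", "p6"):
        x, y = getattr(eye, pk)
        pts[pk] = (scale * (c * x - s * y) + shift[0], scale * (s * x + c * y) + shift[1])
    return EyeLandmarkSet(**pts)


class TestComputeEar:
    def test_worked_example(self, worked_eye):
        assert compute_ear(worked_eye) == pytest.approx(0.5, abs=1e-15)

    def test_closed_lids_give_zero(self):
        eye = EyeLandmarkSet(p1=(0, 0), p4=(4, 0), p2=(1, 0.3), p6=(1, 0.3), p3=(3, 0.1), p5=(3, 0.1))
        assert compute_ear(eye) == 0.0

    def test_uniform_scaling_invariance(self, worked_eye):
        assert compute_ear(_transform(worked_eye, scale=3.0)) == pytest.approx(0.5, rel=1e-12)

    def test_degenerate_corners_raise(self):
        eye = EyeLandmarkSet(p1=(2, 2), p4=(2, 2), p2=(1, 1), p6=(1, -1), p3=(3, 1), p5=(3, -1))
        with pytest.raises(ValueError, match="degenerate"):
            compute_ear(eye)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        scale=st.floats(0.1, 50.0),
        angle=st.floats(0.0, 2 * math.pi),
        dx=st.floats(-1e3, 1e3),
        dy=st.floats(-1e3, 1e3),
    )
    def test_rigid_motion_and_scale_invariance(self, scale, angle, dx, dy):
        eye = EyeLandmarkSet(p1=(0, 0), p4=(4, 0), p2=(1, 1), p6=(1, -1), p3=(3, 0.8), p5=(3, -0.6))
        ref = compute_ear(eye)
        moved = compute_ear(_transform(eye, scale=scale, angle=angle, shift=(dx, dy)))
        assert moved == pytest.approx(ref, rel=1e-12)


class TestFissureHeight:
    def test_worked_example(self, worked_eye):
        assert compute_fissure_height(worked_eye) == pytest.approx(2.0)

    def test_closed_eye_zero(self):
        eye = EyeLandmarkSet(p1=(0, 0), p4=(4, 0), p2=(1, 0.2), p6=(1, 0.2), p3=(3, 0.2), p5=(3, 0.2))
        assert compute_fissure_height(eye) == 0.0

    def test_scales_linearly(self, worked_eye):
        assert compute_fissure_height(_transform(worked_eye, scale=2.5)) == pytest.approx(5.0)


def _landmark_df(n=10, fps=100.0):
    tr = make_trace(np.full(n, 0.4), fps=fps)
    frames = emit_landmarks(tr, eye_width_px=10.0)
    rows = []
    for fr in frames:
        row = {"frame": fr.frame_index, "time_s": fr.time_s}
        for side, eye in (("left", fr.left_eye), ("right", fr.right_eye)):
            for pk in ("p1", "p2", "p3", "p4", "p5", "p6"):
                x, y = getattr(eye, pk)
                row[f"{side}_{pk}_x"] = x
                row[f"{side}_{pk}_y"] = y
        rows.append(row)
    return pd.DataFrame(rows)


class TestLandmarkTable:
    def test_well_formed_file(self, tmp_path):
        path = tmp_path / "lm.csv"
        _landmark_df(10).to_csv(path, index=False)
        frames = read_landmark_table(path)
        assert len(frames) == 10
        assert all(fr.valid for fr in frames)

    def test_nonfinite_coordinate_flags_frame(self, tmp_path):
        df = _landmark_df(10)
        df.loc[4, "left_p2_x"] = np.nan
        path = tmp_path / "lm.csv"
        df.to_csv(path, index=False)
        frames = read_landmark_table(path)
        assert not frames[4].valid
        assert sum(fr.valid for fr in frames) == 9

    def test_backwards_time_raises(self, tmp_path):
        df = _landmark_df(10)
        df["time_s"] = df["time_s"].to_numpy()[::-1]
        path = tmp_path / "lm.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="increasing"):
            read_landmark_table(path)

    def test_missing_column_raises(self, tmp_path):
        df = _landmark_df(5).drop(columns=["right_p6_y"])
        path = tmp_path / "lm.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing"):
            read_landmark_table(path)

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "lm.csv"
        _landmark_df(5).iloc[:0].to_csv(path, index=False)
        with pytest.raises(ValueError):
            read_landmark_table(path)

    def test_write_read_roundtrip(self, tmp_path):
        tr = make_trace([0.2, 0.3, 0.4, 0.25], fps=50.0)
        frames = emit_landmarks(tr, eye_width_px=80.0)
        path = tmp_path / "lm.csv"
        write_landmark_table(frames, path)
        back = read_landmark_table(path)
        assert len(back) == 4
        assert compute_ear(back[2].left_eye) == pytest.approx(0.4, abs=1e-12)


class TestBuildEarTraces:
    def test_constant_geometry_constant_traces(self):
        tr = make_trace(np.full(6, 0.35), fps=60.0)
        frames = emit_landmarks(tr, eye_width_px=20.0)
        left, right = build_ear_traces(frames, fps=60.0)
        assert np.allclose(left.values, 0.35)
        assert np.allclose(right.values, 0.35)
        assert not left.gap_mask.any()

    def test_sample_count_conserved(self):
        tr = make_trace(np.linspace(0.1, 0.4, 17), fps=60.0)
        frames = emit_landmarks(tr, eye_width_px=20.0)
        left, right = build_ear_traces(frames, fps=60.0)
        assert left.n_samples == right.n_samples == 17

    def test_invalid_frame_interpolated_and_masked(self):
        tr = make_trace([0.2, 0.3, 0.4], fps=60.0)
        frames = emit_landmarks(tr, eye_width_px=20.0)
        bad = frames[1]
        frames[1] = type(bad)(
            frame_index=bad.frame_index,
            time_s=bad.time_s,
            left_eye=bad.left_eye,
            right_eye=bad.right_eye,
            valid=False,
        )
        # the middle sample is a gap: linear interpolation between 0.2 and 0.4
        left, _ = build_ear_traces(frames, fps=60.0)
        assert left.values[1] == pytest.approx(0.3, abs=1e-12)
        assert left.gap_mask.tolist() == [False, True, False]

    def test_single_valid_frame_raises(self):
        tr = make_trace([0.2, 0.3], fps=60.0)
        frames = emit_landmarks(tr, eye_width_px=20.0)
        frames[1] = type(frames[1])(
            frame_index=1, time_s=frames[1].time_s,
            left_eye=frames[1].left_eye, right_eye=frames[1].right_eye, valid=False,
        )
        with pytest.raises(ValueError, match="valid frames"):
            build_ear_traces(frames, fps=60.0)

    def test_fps_mismatch_raises(self):
        tr = make_trace(np.full(20, 0.3), fps=60.0)
        frames = emit_landmarks(tr, eye_width_px=20.0)
        with pytest.raises(ValueError, match="fps"):
            build_ear_traces(frames, fps=100.0)

    def test_generator_roundtrip_exact(self):
        # landmark frames emitted from a synthetic trace reproduce it
        preset = preset_registry()["healthy_eye"]
        trace, _ = generate_ear_trace(preset, duration_s=10.0, fps=60.0, seed=5)
        frames = emit_landmarks(trace, eye_width_px=120.0)
        left, right = build_ear_traces(frames, fps=60.0)
        np.testing.assert_allclose(left.values, trace.values, atol=1e-9)
        np.testing.assert_allclose(right.values, trace.values, atol=1e-9)


class TestPalpebralHeightRatio:
    def _events(self, *spans):
        return [BlinkEvent(onset_s=a, offset_s=b, min_ear=0.05, baseline_ear=0.3) for a, b in spans]

    def test_identical_heights_100(self):
        h = np.full(100, 5.0)
        assert palpebral_height_ratio(h, h, [], [], fps=10.0) == pytest.approx(100.0)

    def test_scaled_heights(self):
        h = np.random.default_rng(0).uniform(4, 6, 200)
        assert palpebral_height_ratio(0.96 * h, h, [], [], fps=10.0) == pytest.approx(96.0, abs=1e-9)

    def test_zero_paretic_heights(self):
        h = np.full(50, 5.0)
        assert palpebral_height_ratio(np.zeros(50), h, [], [], fps=10.0) == 0.0

    def test_blink_frames_excluded(self):
        # paretic heights crash to 0 inside a blink; ratio must ignore it
        h = np.full(100, 5.0)
        hp = h.copy()
        hp[20:40] = 0.0
        events = self._events((2.0, 4.0))
        assert palpebral_height_ratio(hp, h, events, events, fps=10.0) == pytest.approx(100.0)

    def test_zero_contralateral_raises(self):
        with pytest.raises(ValueError, match="zero"):
            palpebral_height_ratio(np.full(50, 1.0), np.zeros(50), [], [], fps=10.0)


class TestEarCsv:
    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(1)
        left = make_trace(rng.uniform(0, 0.4, 100), fps=50.0, side="left")
        gap = np.zeros(100, bool)
        gap[3] = True
        right = EARTrace("right", 50.0, rng.uniform(0, 0.4, 100), gap)
        path = tmp_path / "ear.csv"
        write_ear_csv(left, right, path)
        l2, r2 = read_ear_csv(path)
        np.testing.assert_allclose(l2.values, left.values)
        np.testing.assert_allclose(r2.values, right.values)
        assert r2.gap_mask[3] and r2.gap_mask.sum() == 1
        assert l2.fps == pytest.approx(50.0)
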