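"""Gait-event detection and per-step kinematics against ground truth."""

import warnings

import numpy as np
import pytest

import terrarun as tr
from terrarun.kinematics import (
    MarkerTrajectorySet,
    align_track_frame,
    detect_stance_events,
    landing_velocity,
    per_step_metrics,
    trial_summary,
)

from conftest import non_turnaround_steps


def rotate_z(markers, angle):
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return MarkerTrajectorySet(
        markers.rate, {k: v @ rot.T for k, v in markers.markers.items()},
        dict(markers.standing_heights))


class TestAlignTrackFrame:
    def test_aligned_input_identity(self, clean_flat_trial):
        _, markers, _, _ = clean_flat_trial
        out = align_track_frame(markers)
        assert abs(out.meta["alignment_angle"]) < 1e-10

    def test_rotation_recovered(self, clean_flat_trial):
        """A trajectory rotated by +2 deg is recovered as a -2 deg
        misalignment and undone."""
        _, markers, _, _ = clean_flat_trial
        rotated = rotate_z(markers, np.radians(2.0))
        out = align_track_frame(rotated)
        assert np.degrees(out.meta["alignment_angle"]) == pytest.approx(
            -2.0, abs=0.01)
        assert np.allclose(out.com()[:, :2], markers.com()[:, :2], atol=1e-6)

    def test_large_rotation_clamped_with_warning(self, clean_flat_trial):
        _, markers, _, _ = clean_flat_trial
        rotated = rotate_z(markers, np.radians(8.0))
        with pytest.warns(UserWarning, match="clamping"):
            out = align_track_frame(rotated)
        assert abs(np.degrees(out.meta["alignment_angle"])) <= 5.0 + 1e-9

    def test_stationary_trajectory_rejected(self):
        still = {r: np.zeros((50, 3)) for r in tr.kinematics.HIP_ROLES}
        still["heel"] = np.zeros((50, 3))
        with pytest.raises(tr.DomainError):
            align_track_frame(MarkerTrajectorySet(300.0, still))


class TestDetectStanceEvents:
    def test_touchdowns_within_one_frame(self, clean_flat_trial, subject):
        _, markers, _, truth = clean_flat_trial
        events = detect_stance_events(markers, subject)
        det = np.array([e[0] for e in events])
        frame = 1.0 / markers.rate
        for k in non_turnaround_steps(truth):
            err = np.min(np.abs(det - truth.touchdown_times[k]))
            assert err <= frame + 1e-9

    def test_liftoffs_within_one_frame(self, clean_flat_trial, subject):
        _, markers, _, truth = clean_flat_trial
        events = detect_stance_events(markers, subject)
        det = np.array([e[1] for e in events])
        frame = 1.0 / markers.rate
        for k in non_turnaround_steps(truth):
            assert np.min(np.abs(det - truth.liftoff_times[k])) <= frame + 1e-9

    def test_elevated_heel_yields_no_stances(self, clean_flat_trial, subject):
        _, markers, _, _ = clean_flat_trial
        lifted = markers.translated((0.0, 0.0, 0.05))
        lifted.standing_heights = dict(markers.standing_heights)
        with pytest.warns(UserWarning, match="no stance"):
            events = detect_stance_events(lifted, subject)
        assert events == []

    def test_stance_on_terrain_peak_detected(self, subject):
        """A landing 12 mm above the standing height is still in stance
        (the 15 mm gate absorbs terrain height variation)."""
        peak = tr.TerrainField(np.full((1700, 121), 0.012), 0.005)
        gait = tr.GaitSpec(seed=5, duration_s=8.0, step_length_sd=0.0,
                           step_width_sd=0.0, foot_landing_speed_sd=0.0)
        markers, _, truth = tr.generate_trial(gait, peak)
        events = detect_stance_events(markers, subject)
        det = np.array([e[0] for e in events])
        for k in non_turnaround_steps(truth):
            assert np.min(np.abs(det - truth.touchdown_times[k])) < 0.01


class TestLandingVelocity:
    def test_exact_cubic_recovered(self):
        t = np.arange(0, 1.0, 1 / 300)
        coeffs = np.array([0.3, -1.2, 2.0, 0.5])
        pos = np.polyval(coeffs, t - 0.75)
        xyz = np.column_stack([pos, 2 * pos, -pos])
        v = landing_velocity(t, xyz, 0.75)
        expect = np.polyval(np.polyder(coeffs), 0.0)
        assert v == pytest.approx([expect, 2 * expect, -expect], rel=1e-9)

    def test_constant_position_zero_velocity(self):
        t = np.arange(0, 1.0, 1 / 300)
        v = landing_velocity(t, np.ones((t.size, 3)), 0.9)
        assert np.allclose(v, 0.0, atol=1e-9)

    def test_linear_trajectory_slope(self):
        t = np.arange(0, 1.0, 1 / 300)
        slope = np.array([1.0, -2.0, 0.5])
        xyz = t[:, None] * slope
        assert landing_velocity(t, xyz, 0.8) == pytest.approx(slope, rel=1e-9)

    def test_too_few_samples(self):
        t = np.arange(0, 1.0, 1 / 300)
        with pytest.raises(tr.DomainError):
            landing_velocity(t, np.zeros((t.size, 3)), 0.005)


class TestPerStepMetrics:
    def test_step_width_doubling_rule(self):
        """CoM along y at x = 0, stance heel at x = +0.02 -> width 0.04."""
        rate, n = 300.0, 400
        t = np.arange(n) / rate
        com = np.column_stack([np.zeros(n), 3.0 * t, np.ones(n)])
        heel = np.column_stack([np.full(n, 0.02), np.minimum(3.0 * t, 1.5),
                                np.full(n, 0.03)])
        heel[t > 0.55, 2] = 0.3   # lift after the stance
        markers = {"heel": heel, "toe": heel + [0, 0.19, 0],
                   "ankle": heel + [0, 0, 0.05]}
        for k, off in zip(tr.kinematics.HIP_ROLES,
                          [(-0.1, 0.05, 0), (0.1, 0.05, 0),
                           (-0.1, -0.05, 0), (0.1, -0.05, 0)]):
            markers[k] = com + np.asarray(off)
        mts = MarkerTrajectorySet(rate, markers, {"heel": 0.03})
        series = per_step_metrics(mts, [(0.5, 0.55)])
        assert series.records[0].step_width == pytest.approx(0.04, abs=1e-6)

    def test_recovery_against_ground_truth(self, clean_flat_trial, subject):
        _, markers, _, truth = clean_flat_trial
        events = detect_stance_events(markers, subject)
        frame = per_step_metrics(markers, events, subject).to_frame()
        tds = frame.touchdown_time.to_numpy()
        for k in non_turnaround_steps(truth):
            i = int(np.argmin(np.abs(tds - truth.touchdown_times[k])))
            if np.isfinite(truth.step_lengths[k]) and np.isfinite(
                    frame.step_length.iloc[i]):
                assert frame.step_length.iloc[i] == pytest.approx(
                    truth.step_lengths[k], abs=0.002)
            assert frame.step_width.iloc[i] == pytest.approx(
                truth.step_widths[k], abs=0.002)
            assert frame.foot_speed_froude.iloc[i] == pytest.approx(
                truth.foot_landing_speeds[k], abs=0.01)
            # CoM vertical landing speed (cosine excursion, cubic fit)
            assert frame.com_vz.iloc[i] == pytest.approx(-0.7, abs=0.1)

    def test_error_grows_with_marker_noise(self, flat_field, subject):
        errs = []
        for noise in (0.0, 0.001, 0.004):
            gait = tr.GaitSpec(seed=6, duration_s=20.0, marker_noise_sd=noise,
                               step_length_sd=0.0, step_width_sd=0.0,
                               foot_landing_speed_sd=0.0)
            markers, _, truth = tr.generate_trial(gait, flat_field)
            events = detect_stance_events(markers, subject)
            frame = per_step_metrics(markers, events, subject).to_frame()
            tds = frame.touchdown_time.to_numpy()
            e = []
            for k in non_turnaround_steps(truth):
                i = int(np.argmin(np.abs(tds - truth.touchdown_times[k])))
                if np.isfinite(frame.step_width.iloc[i]):
                    e.append(abs(frame.step_width.iloc[i]
                                 - truth.step_widths[k]))
            errs.append(np.median(e))
        assert errs[0] <= errs[1] <= errs[2]

    def test_frame_invariance_under_translation(self, clean_flat_trial, subject):
        _, markers, _, _ = clean_flat_trial
        events = detect_stance_events(markers, subject)
        base = per_step_metrics(markers, events, subject).to_frame()
        moved = markers.translated((1.5, -2.0, 0.25))
        moved.standing_heights = {
            k: v + 0.25 for k, v in markers.standing_heights.items()}
        events2 = detect_stance_events(moved, subject)
        shifted = per_step_metrics(moved, events2, subject).to_frame()
        for col in ("step_length", "step_width", "leg_angle_td",
                    "foot_speed_froude"):
            a = base[col].to_numpy()
            b = shifted[col].to_numpy()
            mask = np.isfinite(a) & np.isfinite(b)
            assert np.allclose(a[mask], b[mask], atol=1e-9)

    def test_meander_zero_for_straight_path(self, clean_flat_trial, subject):
        _, markers, _, _ = clean_flat_trial
        events = detect_stance_events(markers, subject)
        series = per_step_metrics(markers, events, subject)
        assert all(m >= -1e-12 for m in series.meanders)
        assert np.median(series.meanders) < 1e-6

    def test_froude_normalization(self, subject):
        assert subject.froude_speed == pytest.approx(2.955, abs=0.001)
        # v = sqrt(g l) corresponds to Froude speed 1
        assert 2.955 / subject.froude_speed == pytest.approx(1.0, abs=1e-3)


class TestTrialSummary:
    def test_identical_steps_zero_sd(self, clean_flat_trial, subject):
        _, markers, _, _ = clean_flat_trial
        events = detect_stance_events(markers, subject)
        series = per_step_metrics(markers, events, subject)
        summ = trial_summary(series, subject)
        assert summ.loc["step_width", "sd"] == pytest.approx(0.0, abs=1e-6)

    def test_percent_leg_length_normalization(self, subject):
        # 1.14 m steps on a 0.89 m leg are 128 %LL
        recs = []
        for k in range(5):
            r = tr.StepRecord(touchdown_time=0.35 * k,
                              liftoff_time=0.35 * k + 0.2, direction=1)
            r.step_length = 1.14
            r.step_duration = 0.35
            r.com_speed = 1.14 / 0.35
            r.step_width = 0.04
            recs.append(r)
        summ = trial_summary(tr.StepSeries(recs, [], subject), subject)
        assert summ.loc["step_length", "norm_mean"] == pytest.approx(
            128.09, abs=0.01)

    def test_hand_computed_five_step_fixture(self, subject):
        lengths = [1.10, 1.12, 1.14, 1.16, 1.18]
        recs = []
        for k, sl in enumerate(lengths):
            r = tr.StepRecord(touchdown_time=0.35 * k,
                              liftoff_time=0.35 * k + 0.2, direction=1)
            r.step_length = sl
            recs.append(r)
        summ = trial_summary(tr.StepSeries(recs, [], subject), subject)
        assert summ.loc["step_length", "mean"] == pytest.approx(1.14)
        assert summ.loc["step_length", "sd"] == pytest.approx(
            np.std(lengths, ddof=1))
        assert summ.loc["step_length", "median"] == pytest.approx(1.14)
        assert summ.loc["step_length", "iqr"] == pytest.approx(0.04)
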