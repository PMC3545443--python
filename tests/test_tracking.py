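import numpy as np
import pytest

from flygait import synth, tracking
from flygait.core import LEGS, BodyTrack, Calibration, StanceEvent
from flygait.imaging_io import FrameStack


@pytest.fixture
def cal():
    return Calibration(fps=250.0, um_per_px=40.0)


def straight_body_track(n, cal, step_px=2.0, start=(30.0, 50.0), length_px=62.5):
    centroids = np.column_stack([
        start[0] + step_px * np.arange(n),
        np.full(n, start[1]),
    ])
    return BodyTrack(
        centroid_px=centroids,
        length_px=np.full(n, length_px),
        axis=np.tile([1.0, 0.0], (n, 1)),
        valid=np.ones(n, dtype=bool),
        calibration=cal,
    )


class TestBackground:
    def test_pre_entry_frame_subtracts_to_zero(self, cal):
        rng = np.random.default_rng(0)
        frames = np.tile(rng.random((8, 8)).astype(np.float32), (5, 1, 1))
        stack = FrameStack(frames, cal)
        bg = tracking.estimate_background(stack, 3)
        assert np.allclose(tracking.subtract_background(stack.frames[0], bg), 0.0)

    def test_all_zero_pre_entry(self, cal):
        stack = FrameStack(np.zeros((5, 8, 8), dtype=np.float32), cal)
        bg = tracking.estimate_background(stack, 3)
        assert np.all(bg == 0)

    def test_zero_pre_entry_warns(self, cal):
        stack = FrameStack(np.zeros((5, 8, 8), dtype=np.float32), cal)
        with pytest.warns(UserWarning):
            bg = tracking.estimate_background(stack, 0)
        assert np.all(bg == 0)

    def test_bad_n_pre_entry(self, cal):
        stack = FrameStack(np.zeros((5, 8, 8), dtype=np.float32), cal)
        with pytest.raises(ValueError):
            tracking.estimate_background(stack, 5)

    def test_dust_suppressed_downstream(self, cal):
        # A constant dust spot present before entry yields no detections.
        frames = np.full((30, 40, 40), 0.05, dtype=np.float32)
        frames[:, 10, 10] = 0.8  # static dust, all frames
        stack = FrameStack(frames, cal)
        bg = tracking.estimate_background(stack, 10)
        dets = tracking.detect_footprints(stack, bg, spot_threshold=0.2)
        assert all(len(d) == 0 for d in dets)


class TestDetectFootprints:
    def test_round_trip_spot_positions(self, small_video):
        stack, truth, cfg = small_video
        bg = tracking.estimate_background(stack, cfg.n_pre_entry_frames)
        mad = tracking.noise_mad(stack, bg, cfg.n_pre_entry_frames)
        body = tracking.track_body(stack, bg, 2 * mad)
        dets = tracking.detect_footprints(stack, bg, 8 * mad,
                                          body_masks=body.masks)
        dt = stack.calibration.frame_interval_ms
        n_pre = cfg.n_pre_entry_frames
        for frame in (n_pre + 3, n_pre + 30, n_pre + 70):
            t = (frame - n_pre) * dt
            expected = [
                (e.x_um / cfg.um_per_px, e.y_um / cfg.um_per_px)
                for leg in LEGS for e in truth.pattern.events(leg) if e.covers(t)
            ]
            got = [(d.x_px, d.y_px) for d in dets[frame]]
            assert len(got) == len(expected)
            for ex, ey in expected:
                assert min(np.hypot(gx - ex, gy - ey) for gx, gy in got) <= 1.0

    def test_blank_frames_give_no_detections(self, cal):
        stack = FrameStack(np.zeros((5, 20, 20), dtype=np.float32), cal)
        dets = tracking.detect_footprints(stack, np.zeros((20, 20)), 0.1)
        assert all(len(d) == 0 for d in dets)

    def test_min_area_rejects_small_spot(self, cal):
        frames = np.zeros((3, 20, 20), dtype=np.float32)
        frames[:, 5, 5] = 0.9  # single-pixel spot
        stack = FrameStack(frames, cal)
        dets = tracking.detect_footprints(stack, np.zeros((20, 20)), 0.5,
                                          min_area=3)
        assert all(len(d) == 0 for d in dets)

    def test_threshold_validation(self, cal):
        stack = FrameStack(np.zeros((3, 8, 8), dtype=np.float32), cal)
        with pytest.raises(ValueError):
            tracking.detect_footprints(stack, np.zeros((8, 8)), 0.0)


class TestTrackBody:
    def test_axis_matches_heading(self, small_video):
        stack, truth, cfg = small_video
        bg = tracking.estimate_background(stack, cfg.n_pre_entry_frames)
        mad = tracking.noise_mad(stack, bg, cfg.n_pre_entry_frames)
        body = tracking.track_body(stack, bg, 2 * mad)
        post = np.arange(cfg.n_pre_entry_frames, stack.n_frames)
        ok = post[body.valid[post]]
        angles = np.degrees(np.arctan2(body.axis[ok, 1], body.axis[ok, 0]))
        assert np.max(np.abs(angles)) < 2.0

    def test_body_length_within_10pct(self, small_video):
        stack, truth, cfg = small_video
        bg = tracking.estimate_background(stack, cfg.n_pre_entry_frames)
        mad = tracking.noise_mad(stack, bg, cfg.n_pre_entry_frames)
        body = tracking.track_body(stack, bg, 2 * mad)
        rendered_major = 2 * cfg.body_axes_px[0]
        assert abs(body.body_length_px() - rendered_major) / rendered_major < 0.10

    def test_stationary_body_falls_back_to_orientation(self):
        spec = synth.GaitSpec(speed_mm_s=0.0, n_cycles=2)
        plan = synth.default_body_plan()
        truth = synth.simulate_walk(spec, plan, start_um=(3000.0, 2200.0))
        cfg = synth.RenderConfig(shape_px=(110, 150), noise_sigma=0.0)
        stack = synth.render_ftir_frames(truth, cfg, seed=0)
        bg = tracking.estimate_background(stack, cfg.n_pre_entry_frames)
        body = tracking.track_body(stack, bg, 0.04)
        post = body.valid & (np.arange(len(body)) >= cfg.n_pre_entry_frames)
        assert body.axis_fallback[post].all()
        # orientation of a horizontal ellipse: axis close to +-x
        assert np.all(np.abs(body.axis[post, 0]) > 0.99)

    def test_fly_not_found(self, cal):
        stack = FrameStack(np.zeros((10, 20, 20), dtype=np.float32), cal)
        with pytest.raises(ValueError, match="fly not found"):
            tracking.track_body(stack, np.zeros((20, 20)), 0.05)


class TestAssignLegIdentities:
    def test_round_trip_labels_match_truth(self, small_video, small_tracked):
        stack, truth, cfg = small_video
        pattern, body, prov = small_tracked
        dt = stack.calibration.frame_interval_ms
        offset = cfg.n_pre_entry_frames * dt
        for leg in LEGS:
            rec = pattern.onsets_ms(leg) - offset
            tru = truth.pattern.onsets_ms(leg)
            assert len(rec) == len(tru)
            assert np.max(np.abs(rec - tru)) <= dt

    def test_single_left_mid_print_labeled_LM(self, cal):
        n = 10
        body = straight_body_track(n, cal, step_px=0.0)
        # one detection left of the axis (image y above centroid), mid-body
        dets = [[] for _ in range(n)]
        for f in range(2, 6):
            dets[f] = [tracking.RawDetection(frame=f, x_px=30.0, y_px=35.0,
                                             area=10, peak=1.0)]
        labeled = tracking.assign_leg_identities(dets, body)
        assert len(labeled.tracks) == 1
        assert labeled.tracks[0].leg == "LM"

    def test_anterior_print_gets_anterior_label(self, cal):
        n = 6
        body = straight_body_track(n, cal, step_px=0.0)
        # two simultaneous new ipsilateral prints; anterior one -> LF
        dets = [[] for _ in range(n)]
        for f in range(1, 4):
            dets[f] = [
                tracking.RawDetection(frame=f, x_px=55.0, y_px=35.0, area=9, peak=1.0),
                tracking.RawDetection(frame=f, x_px=12.0, y_px=35.0, area=9, peak=1.0),
            ]
        labeled = tracking.assign_leg_identities(dets, body)
        by_x = sorted(labeled.tracks, key=lambda t: t.positions_px[0][0])
        assert by_x[-1].leg == "LF"
        assert by_x[0].leg == "LH"

    def test_seven_simultaneous_contacts_error(self, cal):
        n = 3
        body = straight_body_track(n, cal, step_px=0.0)
        dets = [[], [
            tracking.RawDetection(frame=1, x_px=10.0 + 7 * i, y_px=35.0,
                                  area=9, peak=1.0)
            for i in range(7)
        ], []]
        with pytest.raises(ValueError, match="frame 1"):
            tracking.assign_leg_identities(dets, body)


class TestEdits:
    def _labeled(self, cal):
        body = straight_body_track(12, cal, step_px=0.0)
        tracks = [
            tracking.ContactTrack(frames=[2, 3, 4],
                                  positions_px=[(30.0, 35.0)] * 3, leg="LM"),
            tracking.ContactTrack(frames=[3, 4],
                                  positions_px=[(40.0, 60.0)] * 2, leg="RM"),
        ]
        return tracking.LabeledTracks(tracks=tracks, body_track=body,
                                      calibration=cal)

    def test_empty_log_is_identity(self, cal):
        labeled = self._labeled(cal)
        before = [(t.leg, list(t.frames)) for t in labeled.tracks]
        out = tracking.apply_edits(labeled, [])
        assert [(t.leg, list(t.frames)) for t in out.tracks] == before

    def test_add_creates_contact(self, cal):
        labeled = self._labeled(cal)
        rec = tracking.EditRecord(frame=7, action="add", leg="LF",
                                  position_px=(50.0, 30.0))
        out = tracking.apply_edits(labeled, [rec])
        assert 7 in out.contacts("LF")
        pattern = tracking.extract_step_pattern(out, min_stance_frames=1)
        assert pattern.in_stance("LF", 7 * cal.frame_interval_ms)

    def test_remove_deletes_contact(self, cal):
        labeled = self._labeled(cal)
        rec = tracking.EditRecord(frame=3, action="remove", leg="RM")
        out = tracking.apply_edits(labeled, [rec])
        assert 3 not in out.contacts("RM")

    def test_remove_missing_contact_errors(self, cal):
        labeled = self._labeled(cal)
        rec = tracking.EditRecord(frame=9, action="remove", leg="RM")
        with pytest.raises(ValueError, match="record 0"):
            tracking.apply_edits(labeled, [rec])

    def test_relabel(self, cal):
        labeled = self._labeled(cal)
        rec = tracking.EditRecord(frame=3, action="relabel", leg="RM",
                                  new_leg="RH")
        out = tracking.apply_edits(labeled, [rec])
        assert out.contacts("RH") and not out.contacts("RM")

    def test_relabel_conflict_errors(self, cal):
        labeled = self._labeled(cal)
        rec = tracking.EditRecord(frame=3, action="relabel", leg="RM",
                                  new_leg="LM")  # LM active frames 2-4
        with pytest.raises(ValueError, match="two active stances"):
            tracking.apply_edits(labeled, [rec])


class TestExtractStepPattern:
    def _labeled_from_frames(self, cal, leg, frames):
        body = straight_body_track(max(frames) + 2, cal, step_px=0.0)
        tracks = [tracking.ContactTrack(frames=list(frames),
                                        positions_px=[(10.0, 35.0)] * len(frames),
                                        leg=leg)]
        return tracking.LabeledTracks(tracks=tracks, body_track=body,
                                      calibration=cal)

    def test_half_open_interval(self, cal):
        labeled = self._labeled_from_frames(cal, "LF", range(10, 20))
        pattern = tracking.extract_step_pattern(labeled)
        e = pattern.events("LF")[0]
        dt = cal.frame_interval_ms
        assert e.onset_ms == pytest.approx(10 * dt)
        assert e.offset_ms == pytest.approx(20 * dt)

    def test_gap_merging(self, cal):
        frames = list(range(10, 14)) + list(range(15, 20))  # gap at 14
        labeled = self._labeled_from_frames(cal, "LF", frames)
        pattern = tracking.extract_step_pattern(labeled, max_gap_frames=1)
        assert len(pattern.events("LF")) == 1
        e = pattern.events("LF")[0]
        assert (e.onset_ms, e.offset_ms) == (10 * 4.0, 20 * 4.0)

    def test_gap_not_merged_when_zero_allowed(self, cal):
        frames = list(range(10, 14)) + list(range(15, 20))
        labeled = self._labeled_from_frames(cal, "LF", frames)
        pattern = tracking.extract_step_pattern(labeled, max_gap_frames=0)
        assert len(pattern.events("LF")) == 2

    def test_short_run_dropped(self, cal):
        labeled = self._labeled_from_frames(cal, "LF", [5])
        pattern = tracking.extract_step_pattern(labeled, min_stance_frames=2)
        assert pattern.events("LF") == []


class TestEndToEnd:
    def test_onsets_within_one_frame_no_spurious_legs(self, small_video,
                                                      small_tracked):
        stack, truth, cfg = small_video
        pattern, body, prov = small_tracked
        dt = stack.calibration.frame_interval_ms
        offset = cfg.n_pre_entry_frames * dt
        assert prov["n_flagged_tracks"] == 0
        for leg in LEGS:
            rec_on = pattern.onsets_ms(leg) - offset
            rec_off = pattern.offsets_ms(leg) - offset
            tru_on = truth.pattern.onsets_ms(leg)
            tru_off = truth.pattern.offsets_ms(leg)
            assert len(rec_on) == len(tru_on)  # no spurious or missing stances
            assert np.max(np.abs(rec_on - tru_on)) <= dt
            assert np.max(np.abs(rec_off - tru_off)) <= dt
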