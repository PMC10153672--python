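import numpy as np
import pytest

from vidradiomics import tracking
from vidradiomics.errors import ConfigError, DegenerateTrackError, InputError
from vidradiomics.tracking import (
    Box,
    BoxStatus,
    BoxTrack,
    box_iou,
    clean_track,
    detect_boxes_naive,
    interpolate_track,
    read_track_csv,
    reject_outliers,
    track_from_masks,
    track_to_roi_masks,
    write_track_csv,
)

from oracles import iou_oracle


def make_track(coords, missing=()):
    """Track from a list of (x0, y0, x1, y1); indices in `missing` are gaps."""
    boxes, status = [], []
    for i, c in enumerate(coords):
        if i in missing:
            boxes.append(None)
            status.append(BoxStatus.MISSING)
        else:
            boxes.append(Box(i, *c))
            status.append(BoxStatus.OBSERVED)
    return BoxTrack(case_id="t", boxes=boxes, status=status)


class TestDetector:
    def test_detects_dark_ellipse_within_two_px_of_truth(self, noiseless_cohort):
        cases, _ = noiseless_cohort
        case = cases[0]
        track = detect_boxes_naive(case.frames)
        truth = track_from_masks(case.truth_masks)
        for b, tb in zip(track.boxes, truth.boxes):
            assert b is not None
            for attr in ("x_min", "y_min", "x_max", "y_max"):
                assert abs(getattr(b, attr) - getattr(tb, attr)) <= 2

    def test_blank_frames_are_flagged_missing(self):
        frames = np.full((3, 32, 32), 100.0)
        track = detect_boxes_naive(frames)
        assert all(s == BoxStatus.MISSING for s in track.status)
        assert all(b is None for b in track.boxes)

    def test_empty_stack_rejected(self):
        with pytest.raises(InputError):
            detect_boxes_naive(np.empty((0, 8, 8)))

    def test_bypass_mode_gives_tight_mask_bbox(self):
        masks = np.zeros((2, 16, 16), bool)
        masks[0, 3:7, 2:9] = True
        masks[1, 5:6, 5:6] = False  # frame 1 empty
        track = track_from_masks(masks)
        b = track.boxes[0]
        assert (b.x_min, b.y_min, b.x_max, b.y_max) == (2, 3, 8, 6)
        assert track.status[1] == BoxStatus.MISSING


class TestRejection:
    def test_identical_boxes_no_rejection(self):
        track = make_track([(10, 10, 30, 30)] * 7)
        out = reject_outliers(track)
        assert out.status == [BoxStatus.OBSERVED] * 7
        assert out.boxes == track.boxes

    def test_displaced_box_is_rejected(self):
        coords = [(10, 10, 30, 30)] * 9
        coords[4] = (60, 60, 80, 80)  # zero overlap with window median
        track = make_track(coords)
        # direct area arithmetic: IoU of displaced box with the window
        # median (the stable box) is 0 < 0.3
        assert iou_oracle((60, 60, 80, 80), (10, 10, 30, 30)) == 0.0
        out = reject_outliers(track, window=5, iou_min=0.3)
        assert out.status[4] == BoxStatus.REJECTED
        assert all(s == BoxStatus.OBSERVED for i, s in enumerate(out.status) if i != 4)

    def test_short_track_window_truncated(self):
        track = make_track([(10, 10, 30, 30)] * 3)
        out = reject_outliers(track, window=5)
        assert out.status == [BoxStatus.OBSERVED] * 3

    @pytest.mark.parametrize("window", [2, 4, 1])
    def test_even_or_tiny_window_rejected(self, window):
        track = make_track([(10, 10, 30, 30)] * 7)
        with pytest.raises(ConfigError):
            reject_outliers(track, window=window)

    def test_iou_matches_pixel_arithmetic(self, rng):
        for _ in range(50):
            a = np.sort(rng.integers(0, 30, size=2))
            b = np.sort(rng.integers(0, 30, size=2))
            c = np.sort(rng.integers(0, 30, size=2))
            d = np.sort(rng.integers(0, 30, size=2))
            ba = Box(0, a[0], b[0], a[1] + 1, b[1] + 1)
            bb = Box(0, c[0], d[0], c[1] + 1, d[1] + 1)
            expect = iou_oracle(
                (ba.x_min, ba.y_min, ba.x_max, ba.y_max),
                (bb.x_min, bb.y_min, bb.x_max, bb.y_max),
            )
            assert box_iou(ba, bb) == pytest.approx(expect, abs=1e-12)


class TestInterpolation:
    def test_midpoint_fill(self):
        track = make_track(
            [(10, 10, 30, 30), None, (20, 20, 40, 40)], missing={1}
        )
        out = interpolate_track(track)
        b = out.boxes[1]
        assert (b.x_min, b.y_min, b.x_max, b.y_max) == (15, 15, 35, 35)
        assert out.status[1] == BoxStatus.INTERPOLATED

    def test_no_gaps_is_identity(self):
        track = make_track([(10, 10, 30, 30)] * 5)
        out = interpolate_track(track)
        assert out.boxes == track.boxes
        assert out.status == track.status

    def test_interior_gap_lies_on_the_line(self):
        # observed at frames 0 and 4; the line is evaluated analytically
        track = make_track(
            [(10, 10, 30, 30), None, None, None, (50, 20, 70, 50)],
            missing={1, 2, 3},
        )
        out = interpolate_track(track)
        for i in (1, 2, 3):
            frac = i / 4
            assert out.boxes[i].x_min == pytest.approx(10 + frac * 40, abs=1e-12)
            assert out.boxes[i].y_max == pytest.approx(30 + frac * 20, abs=1e-12)

    def test_leading_trailing_gaps_copy_nearest(self):
        track = make_track(
            [None, (10, 10, 30, 30), (12, 12, 32, 32), None],
            missing={0, 3},
        )
        out = interpolate_track(track)
        assert out.boxes[0].coords.tolist() == [10, 10, 30, 30]
        assert out.boxes[3].coords.tolist() == [12, 12, 32, 32]

    def test_fewer_than_two_observed_raises(self):
        track = make_track([(10, 10, 30, 30), None, None], missing={1, 2})
        with pytest.raises(DegenerateTrackError):
            interpolate_track(track)


class TestRoiMasks:
    def test_two_by_two_box(self):
        track = make_track([(0, 0, 1, 1)])
        masks = track_to_roi_masks(track, (4, 4))
        assert masks[0].sum() == 4
        assert masks[0, :2, :2].all()

    def test_full_frame_box(self):
        track = make_track([(0, 0, 7, 7)])
        masks = track_to_roi_masks(track, (8, 8))
        assert masks.all()

    def test_pixel_count_matches_inclusive_area(self, rng):
        for _ in range(20):
            x0, y0 = rng.integers(0, 10, size=2)
            x1 = x0 + rng.integers(1, 10)
            y1 = y0 + rng.integers(1, 10)
            track = make_track([(x0, y0, x1, y1)])
            masks = track_to_roi_masks(track, (25, 25))
            assert masks[0].sum() == (x1 - x0 + 1) * (y1 - y0 + 1)

    def test_out_of_frame_box_clipped_with_warning(self):
        track = make_track([(-2, -2, 5, 5)])
        with pytest.warns(UserWarning, match="clipping"):
            masks = track_to_roi_masks(track, (8, 8))
        assert masks[0].sum() == 36


class TestCleanupProperties:
    def test_cleanup_is_idempotent(self):
        coords = [(10 + i, 10, 30 + i, 30) for i in range(9)]
        coords[4] = (60, 60, 80, 80)
        track = make_track(coords, missing={7})
        once = clean_track(track)
        twice = clean_track(once)
        assert [b.coords.tolist() for b in once.boxes] == [
            b.coords.tolist() for b in twice.boxes
        ]

    def test_cleanup_never_changes_kept_boxes(self):
        coords = [(10 + i, 10, 30 + i, 30) for i in range(9)]
        coords[4] = (60, 60, 80, 80)
        track = make_track(coords, missing={7})
        out = clean_track(track)
        for i in range(9):
            if i in (4, 7):
                continue
            assert out.boxes[i] == track.boxes[i]
            assert out.status[i] == BoxStatus.OBSERVED

    def test_noiseless_video_iou_above_080(self, noiseless_cohort):
        cases, _ = noiseless_cohort
        for case in cases[:3]:
            track = clean_track(detect_boxes_naive(case.frames))
            truth = track_from_masks(case.truth_masks)
            ious = [box_iou(b, tb) for b, tb in zip(track.boxes, truth.boxes)]
            assert np.mean(ious) >= 0.8


def test_track_csv_round_trip(tmp_path):
    track = make_track([(10, 10, 30, 30), None, (20, 20, 40, 40)], missing={1})
    path = tmp_path / "track.csv"
    write_track_csv(track, path)
    back = read_track_csv(path)
    assert back.case_id == track.case_id
    assert back.status == track.status
    assert back.boxes[0].coords.tolist() == [10, 10, 30, 30]
    assert back.boxes[1] is None
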