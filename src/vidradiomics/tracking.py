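"""Per-frame lesion ROI tracking with rejection-and-interpolation cleanup.

A detector (the built-in naive intensity detector, or supplied truth masks in
bypass mode) proposes one bounding box per frame; boxes that disagree with
the element-wise median box of their temporal window are rejected, and
missing/rejected frames are filled by coordinate-wise linear interpolation,
so that every frame ends up with exactly one coherent box.

Coordinates are 0-based pixel indices with x along columns and y along rows;
boxes are inclusive of both endpoints, so a box (x_min=0, x_max=1) spans two
pixel columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigError, DegenerateTrackError, InputError

__all__ = [
    "Box",
    "BoxStatus",
    "BoxTrack",
    "detect_boxes_naive",
    "track_from_masks",
    "box_iou",
    "reject_outliers",
    "interpolate_track",
    "track_to_roi_masks",
    "track_to_frame",
    "write_track_csv",
    "read_track_csv",
]


class BoxStatus(str, Enum):
    OBSERVED = "observed"
    REJECTED = "rejected"
    INTERPOLATED = "interpolated"
    MISSING = "missing"


@dataclass(frozen=True)
class Box:
    frame_index: int
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    confidence: float | None = None

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise InputError(
                f"degenerate box at frame {self.frame_index}: "
                f"({self.x_min},{self.y_min})-({self.x_max},{self.y_max})"
            )

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x_min, self.y_min, self.x_max, self.y_max], dtype=float)


@dataclass
class BoxTrack:
    """One box (or a gap) per frame of a video."""

    case_id: str
    boxes: list[Box | None]
    status: list[BoxStatus]

    def __post_init__(self) -> None:
        if len(self.boxes) != len(self.status):
            raise InputError("boxes and status must have equal length")

    def __len__(self) -> int:
        return len(self.boxes)

    @property
    def is_complete(self) -> bool:
        return all(
            b is not None and s in (BoxStatus.OBSERVED, BoxStatus.INTERPOLATED)
            for b, s in zip(self.boxes, self.status)
        )


def box_iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two inclusive pixel boxes."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min) + 1
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min) + 1
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    area_a = (a.x_max - a.x_min + 1) * (a.y_max - a.y_min + 1)
    area_b = (b.x_max - b.x_min + 1) * (b.y_max - b.y_min + 1)
    return float(inter / (area_a + area_b - inter))


def _mask_bbox(mask: np.ndarray, frame_index: int) -> Box | None:
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        return None
    return Box(
        frame_index=frame_index,
        x_min=float(xs.min()),
        y_min=float(ys.min()),
        x_max=float(xs.max()),
        y_max=float(ys.max()),
    )


def detect_boxes_naive(
    frames: np.ndarray,
    *,
    polarity: str = "dark",
    offset: float = 25.0,
    min_area: int = 25,
    case_id: str = "case",
) -> BoxTrack:
    """Threshold-based single-lesion detector (stand-in for a learned one).

    Each frame is thresholded at ``offset`` gray levels below (``polarity
    'dark'``) or above (``'bright'``) its median; the largest connected
    component of at least ``min_area`` pixels yields the frame's box.
    Frames with no such component are flagged missing.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise InputError("frames must be a nonempty (T, rows, cols) stack")
    if polarity not in ("dark", "bright"):
        raise ConfigError(f"polarity must be 'dark' or 'bright', got {polarity!r}")
    boxes: list[Box | None] = []
    status: list[BoxStatus] = []
    for t in range(frames.shape[0]):
        frame = frames[t]
        med = float(np.median(frame))
        bw = frame < med - offset if polarity == "dark" else frame > med + offset
        lbl, n = ndimage.label(bw)
        box = None
        if n:
            sizes = ndimage.sum_labels(np.ones_like(lbl), lbl, index=range(1, n + 1))
            k = int(np.argmax(sizes)) + 1
            if sizes[k - 1] >= min_area:
                box = _mask_bbox(lbl == k, t)
        boxes.append(box)
        status.append(BoxStatus.OBSERVED if box is not None else BoxStatus.MISSING)
    return BoxTrack(case_id=case_id, boxes=boxes, status=status)


def track_from_masks(masks: np.ndarray, *, case_id: str = "case") -> BoxTrack:
    """Bypass mode: tight bounding box of each supplied truth mask."""
    masks = np.asarray(masks)
    if masks.ndim != 3 or masks.shape[0] == 0:
        raise InputError("masks must be a nonempty (T, rows, cols) stack")
    boxes = [_mask_bbox(masks[t] > 0, t) for t in range(masks.shape[0])]
    status = [
        BoxStatus.OBSERVED if b is not None else BoxStatus.MISSING for b in boxes
    ]
    return BoxTrack(case_id=case_id, boxes=boxes, status=status)


def reject_outliers(track: BoxTrack, window: int = 5, iou_min: float = 0.3) -> BoxTrack:
    """Re-flag boxes that disagree with their temporal neighborhood.

    For each observed box, the element-wise median box over a centered window
    (truncated at the track edges; gaps skipped) is formed; boxes whose IoU
    with that median box falls below ``iou_min`` become ``rejected``.
    Decisions are made against a snapshot, so the pass order is irrelevant.
    """
    if window < 3 or window % 2 == 0:
        raise ConfigError(f"window must be an odd count >= 3, got {window}")
    if not 0.0 <= iou_min <= 1.0:
        raise ConfigError(f"iou_min must be in [0, 1], got {iou_min}")
    h = window // 2
    n = len(track)
    new_status = list(track.status)
    for i in range(n):
        if track.status[i] != BoxStatus.OBSERVED and track.status[i] != BoxStatus.INTERPOLATED:
            continue
        neigh = [
            track.boxes[j].coords
            for j in range(max(0, i - h), min(n, i + h + 1))
            if track.boxes[j] is not None
            and track.status[j] in (BoxStatus.OBSERVED, BoxStatus.INTERPOLATED)
        ]
        med = np.median(np.stack(neigh), axis=0)
        med_box = Box(i, *med)
        if box_iou(track.boxes[i], med_box) < iou_min:
            new_status[i] = BoxStatus.REJECTED
    return BoxTrack(case_id=track.case_id, boxes=list(track.boxes), status=new_status)


def interpolate_track(track: BoxTrack) -> BoxTrack:
    """Fill missing/rejected frames by coordinate-wise linear interpolation.

    Leading/trailing gaps copy the nearest kept box.  Boxes whose status is
    observed or already interpolated are never changed.
    """
    kept = [
        i
        for i, s in enumerate(track.status)
        if s in (BoxStatus.OBSERVED, BoxStatus.INTERPOLATED) and track.boxes[i] is not None
    ]
    if len(kept) < 2:
        raise DegenerateTrackError(
            f"track {track.case_id!r} has {len(kept)} usable boxes; need >= 2"
        )
    n = len(track)
    coords = np.stack([track.boxes[i].coords for i in kept])  # (k, 4)
    new_boxes: list[Box | None] = list(track.boxes)
    new_status = list(track.status)
    kept_arr = np.array(kept)
    for i in range(n):
        if i in kept:
            continue
        interp = np.array(
            [np.interp(i, kept_arr, coords[:, c]) for c in range(4)]
        )
        new_boxes[i] = Box(i, *interp)
        new_status[i] = BoxStatus.INTERPOLATED
    return BoxTrack(case_id=track.case_id, boxes=new_boxes, status=new_status)


def clean_track(track: BoxTrack, window: int = 5, iou_min: float = 0.3) -> BoxTrack:
    """Rejection followed by interpolation; the standard cleanup."""
    return interpolate_track(reject_outliers(track, window=window, iou_min=iou_min))


def track_to_roi_masks(track: BoxTrack, frame_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a cleaned track into per-frame binary box masks.

    Coordinates are rounded to the nearest pixel; boxes extending past the
    frame are clipped with a warning.  Both box endpoints are inclusive.
    """
    rows, cols = frame_shape
    masks = np.zeros((len(track), rows, cols), dtype=bool)
    for i, box in enumerate(track.boxes):
        if box is None:
            raise DegenerateTrackError(
                f"track {track.case_id!r} has no box at frame {i}; clean it first"
            )
        x0, y0 = int(round(box.x_min)), int(round(box.y_min))
        x1, y1 = int(round(box.x_max)), int(round(box.y_max))
        if x0 < 0 or y0 < 0 or x1 >= cols or y1 >= rows:
            warnings.warn(
                f"box at frame {i} extends past the frame; clipping", stacklevel=2
            )
        x0c, y0c = max(0, x0), max(0, y0)
        x1c, y1c = min(cols - 1, x1), min(rows - 1, y1)
        masks[i, y0c : y1c + 1, x0c : x1c + 1] = True
    return masks


def track_to_frame(track: BoxTrack) -> pd.DataFrame:
    rows = []
    for i, (box, st) in enumerate(zip(track.boxes, track.status)):
        rows.append(
            {
                "case_id": track.case_id,
                "frame_index": i,
                "x_min": box.x_min if box else np.nan,
                "y_min": box.y_min if box else np.nan,
                "x_max": box.x_max if box else np.nan,
                "y_max": box.y_max if box else np.nan,
                "status": st.value,
            }
        )
    return pd.DataFrame(rows)


def write_track_csv(track: BoxTrack, path: str | Path) -> None:
    track_to_frame(track).to_csv(path, index=False)


def read_track_csv(path: str | Path) -> BoxTrack:
    df = pd.read_csv(path).sort_values("frame_index")
    case_id = str(df["case_id"].iloc[0])
    boxes: list[Box | None] = []
    status: list[BoxStatus] = []
    for _, row in df.iterrows():
        if np.isnan(row["x_min"]):
            boxes.append(None)
        else:
            boxes.append(
                Box(
                    int(row["frame_index"]),
                    float(row["x_min"]),
                    float(row["y_min"]),
                    float(row["x_max"]),
                    float(row["y_max"]),
                )
            )
        status.append(BoxStatus(row["status"]))
    return BoxTrack(case_id=case_id, boxes=boxes, status=status)
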