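"""Static radiomics features: 91 per frame from a grayscale frame + ROI mask.

The registry partitions the 91 features into three families:

* 19 first-order intensity statistics of the ROI pixel values,
* 28 local-binary-pattern (LBP) texture histogram bins — uniform
  rotation-invariant codes for (P=8, R=1) giving 10 bins and (P=16, R=2)
  giving 18 bins,
* 44 gray-level co-occurrence matrix (GLCM) features — 11 Haralick-style
  statistics at each of the 4 standard distance-1 offsets (0deg, 45deg,
  90deg, 135deg).

Quantization for the GLCM uses a fixed number of levels over a *per-video*
global intensity range of the ROI pixels, so that frame-to-frame feature
variation reflects the image content rather than per-frame rescaling.

Degenerate-input conventions keep every output finite: statistics of a
constant region that would involve a 0/0 (skewness, kurtosis, coefficient of
variation, GLCM correlation) are 0; an offset with no valid pixel pair emits
zeros; an ROI too small for an LBP neighborhood emits an all-zero histogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import local_binary_pattern

from .errors import DegenerateROIError

__all__ = [
    "FeatureRegistry",
    "DEFAULT_REGISTRY",
    "StaticFeatureMatrix",
    "quantize_roi",
    "first_order_features",
    "glcm_features",
    "lbp_features",
    "extract_static_features",
]

FIRST_ORDER_NAMES = [
    "fo_mean",
    "fo_median",
    "fo_minimum",
    "fo_maximum",
    "fo_range",
    "fo_variance",
    "fo_std",
    "fo_skewness",
    "fo_kurtosis",
    "fo_energy",
    "fo_rms",
    "fo_entropy",
    "fo_uniformity",
    "fo_p10",
    "fo_p90",
    "fo_iqr",
    "fo_mad",
    "fo_rmad",
    "fo_cv",
]

GLCM_STAT_NAMES = [
    "contrast",
    "dissimilarity",
    "homogeneity",
    "asm",
    "energy",
    "correlation",
    "entropy",
    "cluster_shade",
    "cluster_prominence",
    "max_probability",
    "sum_average",
]

# (row, col) displacement for each direction, distance 1
GLCM_OFFSETS: dict[str, tuple[int, int]] = {
    "d000": (0, 1),
    "d045": (-1, 1),
    "d090": (-1, 0),
    "d135": (-1, -1),
}

LBP_SETTINGS: tuple[tuple[int, int], ...] = ((8, 1), (16, 2))


def _lbp_names(settings=LBP_SETTINGS) -> list[str]:
    names = []
    for p, r in settings:
        names.extend(f"lbp_p{p}r{r}_b{k:02d}" for k in range(p + 2))
    return names


def _glcm_names(offsets=GLCM_OFFSETS) -> list[str]:
    return [f"glcm_{d}_{s}" for d in offsets for s in GLCM_STAT_NAMES]


@dataclass(frozen=True)
class FeatureRegistry:
    """Ordered, named static-feature configuration (default 91 features)."""

    levels: int = 32
    offsets: dict = field(default_factory=lambda: dict(GLCM_OFFSETS))
    lbp_settings: tuple = LBP_SETTINGS
    entropy_bins: int = 32

    @property
    def first_order_names(self) -> list[str]:
        return list(FIRST_ORDER_NAMES)

    @property
    def binary_texture_names(self) -> list[str]:
        return _lbp_names(self.lbp_settings)

    @property
    def glcm_names(self) -> list[str]:
        return _glcm_names(self.offsets)

    @property
    def names(self) -> list[str]:
        return self.first_order_names + self.binary_texture_names + self.glcm_names

    @property
    def n_features(self) -> int:
        return len(self.names)


DEFAULT_REGISTRY = FeatureRegistry()


@dataclass
class StaticFeatureMatrix:
    """Per-case feature matrix: one row per frame, one column per feature."""

    case_id: str
    values: pd.DataFrame  # frame_count x n_features

    @property
    def n_frames(self) -> int:
        return len(self.values)


def quantize_roi(
    frame: np.ndarray,
    mask: np.ndarray,
    levels: int = 32,
    global_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Uniformly bin ROI pixels into integer levels 0..levels-1.

    ``global_range`` is the (lo, hi) intensity range computed once per video
    over all ROI pixels; ``hi == lo`` maps everything to level 0.  Returns a
    full-frame integer image (pixels outside the mask are 0 and must be
    ignored via the mask).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DegenerateROIError("empty ROI mask")
    if levels < 2:
        raise DegenerateROIError(f"levels must be >= 2, got {levels}")
    vals = np.asarray(frame, dtype=np.float64)
    if global_range is None:
        lo, hi = float(vals[mask].min()), float(vals[mask].max())
    else:
        lo, hi = global_range
    q = np.zeros(frame.shape, dtype=np.int64)
    if hi > lo:
        scaled = (vals - lo) / (hi - lo) * levels
        q_all = np.clip(np.floor(scaled), 0, levels - 1).astype(np.int64)
        q[mask] = q_all[mask]
    return q


def first_order_features(values: np.ndarray, entropy_bins: int = 32) -> dict[str, float]:
    """19 first-order statistics with population (n) denominators."""
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise DegenerateROIError("empty ROI: no pixels for first-order features")
    n = x.size
    mean = x.mean()
    var = x.var()  # population
    std = np.sqrt(var)
    if std > 0:
        skew = np.mean((x - mean) ** 3) / std**3
        kurt = np.mean((x - mean) ** 4) / var**2  # non-excess
    else:
        skew = 0.0
        kurt = 0.0
    hist, _ = np.histogram(x, bins=entropy_bins)
    p = hist / n
    pz = p[p > 0]
    entropy = float(-(pz * np.log2(pz)).sum())
    uniformity = float((p**2).sum())
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    sel = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(sel - sel.mean()).mean()) if sel.size else 0.0
    cv = float(std / mean) if mean != 0 else 0.0
    return {
        "fo_mean": float(mean),
        "fo_median": float(np.median(x)),
        "fo_minimum": float(x.min()),
        "fo_maximum": float(x.max()),
        "fo_range": float(x.max() - x.min()),
        "fo_variance": float(var),
        "fo_std": float(std),
        "fo_skewness": float(skew),
        "fo_kurtosis": float(kurt),
        "fo_energy": float((x**2).sum()),
        "fo_rms": float(np.sqrt((x**2).mean())),
        "fo_entropy": entropy,
        "fo_uniformity": uniformity,
        "fo_p10": float(p10),
        "fo_p90": float(p90),
        "fo_iqr": float(p75 - p25),
        "fo_mad": float(np.abs(x - mean).mean()),
        "fo_rmad": rmad,
        "fo_cv": cv,
    }


def _glcm_matrix(
    q: np.ndarray, mask: np.ndarray, offset: tuple[int, int], levels: int
) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix for one offset (may be all-zero)."""
    dr, dc = offset
    rows, cols = q.shape
    r0a, r1a = max(0, -dr), min(rows, rows - dr)
    c0a, c1a = max(0, -dc), min(cols, cols - dc)
    src = np.s_[r0a:r1a, c0a:c1a]
    dst = np.s_[r0a + dr : r1a + dr, c0a + dc : c1a + dc]
    valid = mask[src] & mask[dst]
    i = q[src][valid]
    j = q[dst][valid]
    counts = np.zeros((levels, levels), dtype=np.float64)
    np.add.at(counts, (i, j), 1.0)
    np.add.at(counts, (j, i), 1.0)  # symmetric accumulation
    total = counts.sum()
    if total > 0:
        counts /= total
    return counts


def _glcm_stats(P: np.ndarray) -> dict[str, float]:
    levels = P.shape[0]
    if P.sum() == 0:
        return {s: 0.0 for s in GLCM_STAT_NAMES}
    ii, jj = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
    diff = ii - jj
    mu_i = float((ii * P).sum())
    mu_j = float((jj * P).sum())
    var_i = float(((ii - mu_i) ** 2 * P).sum())
    var_j = float(((jj - mu_j) ** 2 * P).sum())
    if var_i > 0 and var_j > 0:
        corr = float(((ii - mu_i) * (jj - mu_j) * P).sum() / np.sqrt(var_i * var_j))
    else:
        corr = 0.0
    pz = P[P > 0]
    asm = float((P**2).sum())
    shade_base = ii + jj - mu_i - mu_j
    return {
        "contrast": float((diff**2 * P).sum()),
        "dissimilarity": float((np.abs(diff) * P).sum()),
        "homogeneity": float((P / (1.0 + diff**2)).sum()),
        "asm": asm,
        "energy": float(np.sqrt(asm)),
        "correlation": corr,
        "entropy": float(-(pz * np.log2(pz)).sum()),
        "cluster_shade": float((shade_base**3 * P).sum()),
        "cluster_prominence": float((shade_base**4 * P).sum()),
        "max_probability": float(P.max()),
        "sum_average": float(((ii + jj) * P).sum()),
    }


def glcm_features(
    q: np.ndarray,
    mask: np.ndarray,
    offsets: dict[str, tuple[int, int]] | None = None,
    levels: int = 32,
) -> dict[str, float]:
    """44 GLCM features: 11 statistics x 4 distance-1 offsets.

    ``q`` is a quantized full-frame image (see :func:`quantize_roi`); only
    pixel pairs with both ends inside ``mask`` contribute.  Offsets with no
    valid pair emit zeros.
    """
    offsets = offsets if offsets is not None else GLCM_OFFSETS
    mask = np.asarray(mask, dtype=bool)
    out: dict[str, float] = {}
    for name, off in offsets.items():
        P = _glcm_matrix(q, mask, off, levels)
        stats = _glcm_stats(P)
        for s in GLCM_STAT_NAMES:
            out[f"glcm_{name}_{s}"] = stats[s]
    return out


def lbp_features(
    frame: np.ndarray,
    mask: np.ndarray,
    settings: tuple[tuple[int, int], ...] = LBP_SETTINGS,
) -> dict[str, float]:
    """Uniform rotation-invariant LBP histograms, concatenated (10+18=28 bins).

    Codes are computed over the full frame with bilinear-interpolated
    neighbors (ties neighbor >= center count as 1); the histogram is taken
    only over pixels whose complete neighborhood lies inside the mask.  If no
    such pixel exists the histogram is all-zero.
    """
    frame = np.asarray(frame, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    out: dict[str, float] = {}
    for p, r in settings:
        with warnings.catch_warnings():
            # float frames are intended here; ties are handled by the
            # neighbor >= center convention
            warnings.filterwarnings("ignore", message=".*floating-point images.*")
            codes = local_binary_pattern(frame, P=p, R=r, method="uniform")
        rad = int(np.ceil(r))
        struct = np.ones((2 * rad + 1, 2 * rad + 1), dtype=bool)
        valid = ndimage.binary_erosion(mask, structure=struct, border_value=0)
        n_bins = p + 2
        if valid.any():
            hist, _ = np.histogram(
                codes[valid], bins=np.arange(n_bins + 1) - 0.5
            )
            hist = hist / hist.sum()
        else:
            hist = np.zeros(n_bins)
        for k in range(n_bins):
            out[f"lbp_p{p}r{r}_b{k:02d}"] = float(hist[k])
    return out


def extract_static_features(
    frames: np.ndarray,
    roi_masks: np.ndarray,
    registry: FeatureRegistry = DEFAULT_REGISTRY,
    case_id: str = "case",
) -> StaticFeatureMatrix:
    """Extract the full static feature matrix (frames x 91) for one video.

    Row ``t`` concatenates first-order, LBP and GLCM features of frame ``t``
    restricted to its ROI mask.  The GLCM quantization range is the global
    min/max of ROI pixels over the whole video.
    """
    frames = np.asarray(frames)
    roi_masks = np.asarray(roi_masks, dtype=bool)
    if frames.shape != roi_masks.shape or frames.ndim != 3:
        raise DegenerateROIError("frames and roi_masks must be matching (T, rows, cols) stacks")
    all_roi = frames[roi_masks]
    if all_roi.size == 0:
        raise DegenerateROIError("no ROI pixels anywhere in the video")
    global_range = (float(all_roi.min()), float(all_roi.max()))
    rows = []
    for t in range(frames.shape[0]):
        mask = roi_masks[t]
        if not mask.any():
            raise DegenerateROIError(f"empty ROI mask at frame {t}")
        vals = frames[t][mask]
        row: dict[str, float] = {}
        row.update(first_order_features(vals, entropy_bins=registry.entropy_bins))
        row.update(lbp_features(frames[t], mask, settings=registry.lbp_settings))
        q = quantize_roi(frames[t], mask, levels=registry.levels, global_range=global_range)
        row.update(glcm_features(q, mask, offsets=registry.offsets, levels=registry.levels))
        rows.append(row)
    df = pd.DataFrame(rows, columns=registry.names)
    df.insert(0, "frame_index", np.arange(frames.shape[0]))
    df = df.set_index("frame_index")
    return StaticFeatureMatrix(case_id=case_id, values=df)
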