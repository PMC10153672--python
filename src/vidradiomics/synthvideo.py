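"""Synthetic lesion-video cohort generator.

Produces grayscale speckle videos, each containing one elliptical lesion whose
echotexture (intensity contrast) and temporal modulation differ between the
two classes, together with class-shifted clinical covariates.  The generator
exists so that every downstream stage — tracking, static and dynamic feature
extraction, modeling and evaluation — can be exercised end-to-end without
patient data.

Model
-----
Each frame is a multiplicative-speckle image around a constant background
level ``b``.  The lesion interior has mean intensity

    m(t) = b * (1 - c * (1 + a * sin(2*pi*f*t)))

where ``c`` is the class's texture contrast (positive = hypoechoic lesion),
``a`` the relative modulation amplitude and ``f`` the class's temporal
frequency in cycles/frame.  With ``c = 0`` the lesion is indistinguishable
from the background at every ``t``; with ``noise_sigma = 0`` the rendered
interior equals ``m(t)`` exactly.  Speckle is gamma-distributed with mean 1
and a per-pixel shape chosen so the pixel standard deviation equals
``noise_sigma`` gray levels.

Frame rate is taken as 1 frame = 1 time unit; all frequencies are in
cycles/frame.  Frames are kept as float arrays in the 8-bit range [0, 255];
the PNG writer rounds to uint8.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "SynthConfig",
    "ClinicalRecord",
    "CaseParams",
    "VideoCase",
    "generate_cohort",
    "render_frame",
    "lesion_mean_intensity",
    "write_cohort",
    "read_cohort",
]

_NEG, _POS = "negative", "positive"


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of a synthetic cohort.

    ``texture_contrast`` and ``temporal_freq`` are per-class dicts keyed
    ``"negative"`` / ``"positive"``; contrast is the fractional intensity
    drop of the lesion interior relative to the background (positive values
    give a hypoechoic, i.e. darker, lesion) and frequency is in cycles/frame
    (must stay below the Nyquist limit 0.5).
    """

    n_cases: int = 200
    positive_fraction: float = 0.32
    frame_count: int = 64
    frame_shape: tuple[int, int] = (128, 128)
    lesion_axes_range: tuple[tuple[float, float], tuple[float, float]] = (
        (10.0, 22.0),
        (6.0, 14.0),
    )
    texture_contrast: dict = field(
        default_factory=lambda: {_NEG: 0.35, _POS: 0.45}
    )
    temporal_freq: dict = field(
        default_factory=lambda: {_NEG: 0.05, _POS: 0.20}
    )
    noise_sigma: float = 8.0
    seed: int = 0
    # secondary knobs, fixed defaults
    base_level: float = 180.0
    mod_amplitude: float = 0.3
    center_drift: float = 1.5

    def __post_init__(self) -> None:
        if self.n_cases < 2:
            raise ConfigError(f"n_cases must be >= 2, got {self.n_cases}")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ConfigError(
                f"positive_fraction must be in (0, 1), got {self.positive_fraction}"
            )
        if self.frame_count < 8:
            raise ConfigError(f"frame_count must be >= 8, got {self.frame_count}")
        if len(self.frame_shape) != 2 or min(self.frame_shape) < 16:
            raise ConfigError(f"frame_shape must be 2-D and >= 16 px, got {self.frame_shape}")
        for cls in (_NEG, _POS):
            if cls not in self.texture_contrast:
                raise ConfigError(f"texture_contrast missing class '{cls}'")
            if cls not in self.temporal_freq:
                raise ConfigError(f"temporal_freq missing class '{cls}'")
            f = self.temporal_freq[cls]
            if not 0.0 < f < 0.5:
                raise ConfigError(
                    f"temporal_freq[{cls!r}] must be in (0, 0.5) cycles/frame, got {f}"
                )
        if self.noise_sigma < 0:
            raise ConfigError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        (a_lo, a_hi), (b_lo, b_hi) = self.lesion_axes_range
        if not (0 < a_lo <= a_hi and 0 < b_lo <= b_hi):
            raise ConfigError(f"lesion_axes_range must be positive ordered pairs, got {self.lesion_axes_range}")


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-case clinical covariates.

    age in years; size_cm the largest lesion diameter in cm; meno menopause
    status; cN/cT/cTNM ordinal clinical stage codes.
    """

    age: float
    size_cm: float
    meno: int
    cN: int
    cT: int
    cTNM: int

    def __post_init__(self) -> None:
        if not 20.0 <= self.age <= 95.0:
            raise ConfigError(f"age must be in [20, 95], got {self.age}")
        if self.size_cm <= 0:
            raise ConfigError(f"size_cm must be > 0, got {self.size_cm}")
        if self.meno not in (0, 1):
            raise ConfigError(f"meno must be 0 or 1, got {self.meno}")
        if self.cN not in (0, 1, 2):
            raise ConfigError(f"cN must be in {{0,1,2}}, got {self.cN}")
        if self.cT not in (1, 2, 3):
            raise ConfigError(f"cT must be in {{1,2,3}}, got {self.cT}")
        if self.cTNM not in (1, 2, 3):
            raise ConfigError(f"cTNM must be in {{1,2,3}}, got {self.cTNM}")


@dataclass(frozen=True)
class CaseParams:
    """Geometry and signal parameters of one rendered case."""

    frame_shape: tuple[int, int]
    center: tuple[float, float]  # (row, col)
    axes: tuple[float, float]  # semi-axes (col-axis a, row-axis b), px
    base_level: float
    contrast: float
    freq: float  # cycles/frame
    mod_amplitude: float
    noise_sigma: float
    center_drift: float = 0.0
    frame_count: int = 64


@dataclass
class VideoCase:
    """One synthetic video: frames, per-frame truth masks, clinical record, label."""

    case_id: str
    frames: np.ndarray  # (T, rows, cols) float32 in [0, 255]
    truth_masks: np.ndarray  # (T, rows, cols) bool
    clinical: ClinicalRecord
    label: int
    params: CaseParams | None = None


def lesion_mean_intensity(t: float, params: CaseParams) -> float:
    """Closed-form lesion interior mean at frame ``t`` (gray levels)."""
    c, a, f = params.contrast, params.mod_amplitude, params.freq
    return params.base_level * (1.0 - c * (1.0 + a * math.sin(2.0 * math.pi * f * t)))


def _case_center(t: int, params: CaseParams) -> tuple[float, float]:
    # slow sinusoidal drift at 1/4 the modulation frequency keeps the
    # tracking stage honestly exercised without leaving the frame
    d = params.center_drift
    if d == 0.0:
        return params.center
    ph = 2.0 * math.pi * (params.freq / 4.0) * t
    return (params.center[0] + d * math.sin(ph), params.center[1] + d * math.cos(ph))


def render_frame(
    t: int, params: CaseParams, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Render frame ``t`` of a case; returns (frame, lesion mask).

    The frame is float32 in [0, 255]; the mask is the rendered ellipse
    support.  ``rng`` is required only when ``noise_sigma > 0``.
    """
    if not 0 <= t < params.frame_count:
        raise IndexError(f"frame index {t} out of range [0, {params.frame_count})")
    rows, cols = params.frame_shape
    cy, cx = _case_center(t, params)
    a, b = params.axes  # a along columns, b along rows
    yy, xx = np.mgrid[0:rows, 0:cols]
    mask = ((yy - cy) / b) ** 2 + ((xx - cx) / a) ** 2 <= 1.0

    mean_map = np.full((rows, cols), params.base_level, dtype=np.float64)
    mean_map[mask] = lesion_mean_intensity(t, params)

    sigma = params.noise_sigma
    if sigma > 0:
        if rng is None:
            raise ConfigError("noise_sigma > 0 requires an rng")
        # gamma speckle, mean 1, per-pixel std sigma/mean => pixel std = sigma
        shape = (mean_map / sigma) ** 2
        frame = rng.gamma(shape=shape, scale=mean_map / shape)
    else:
        frame = mean_map
    return np.clip(frame, 0.0, 255.0).astype(np.float32), mask


def _draw_clinical(rng: np.random.Generator, label: int) -> ClinicalRecord:
    # Covariate ranges follow a mid-size breast-cancer cohort; the positive
    # class is shifted: +0.4 cm mean lesion size and +0.15 probability of
    # nodal involvement (cN=1).
    age = float(np.clip(rng.normal(52.0, 10.6), 26.0, 83.0))
    size = float(np.clip(rng.normal(2.36 + 0.4 * label, 1.1), 0.5, 8.0))
    meno = int(rng.random() < 0.58)
    if label:
        p_cn = (0.63, 0.36, 0.01)
    else:
        p_cn = (0.78, 0.21, 0.01)
    cN = int(rng.choice(3, p=p_cn))
    cT = int(rng.choice(3, p=(0.48, 0.50, 0.02))) + 1
    cTNM = int(rng.choice(3, p=(0.42, 0.56, 0.02))) + 1
    return ClinicalRecord(age=age, size_cm=size, meno=meno, cN=cN, cT=cT, cTNM=cTNM)


def generate_cohort(config: SynthConfig) -> list[VideoCase]:
    """Generate a deterministic cohort of ``config.n_cases`` video cases.

    Exactly ``round(n_cases * positive_fraction)`` cases carry label 1; the
    label order is shuffled by the seed.  The same config (including seed)
    yields a bit-identical cohort.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    n_pos = round(n * config.positive_fraction)
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)

    rows, cols = config.frame_shape
    (a_lo, a_hi), (b_lo, b_hi) = config.lesion_axes_range
    cases: list[VideoCase] = []
    for i in range(n):
        label = int(labels[i])
        cls = _POS if label else _NEG
        a = rng.uniform(a_lo, a_hi)
        b = rng.uniform(b_lo, b_hi)
        margin_r = b + config.center_drift + 2.0
        margin_c = a + config.center_drift + 2.0
        cy = rng.uniform(margin_r, rows - margin_r)
        cx = rng.uniform(margin_c, cols - margin_c)
        params = CaseParams(
            frame_shape=config.frame_shape,
            center=(cy, cx),
            axes=(a, b),
            base_level=config.base_level,
            contrast=config.texture_contrast[cls],
            freq=config.temporal_freq[cls],
            mod_amplitude=config.mod_amplitude,
            noise_sigma=config.noise_sigma,
            center_drift=config.center_drift,
            frame_count=config.frame_count,
        )
        frames = np.empty((config.frame_count, rows, cols), dtype=np.float32)
        masks = np.empty((config.frame_count, rows, cols), dtype=bool)
        for t in range(config.frame_count):
            frames[t], masks[t] = render_frame(t, params, rng)
        clinical = _draw_clinical(rng, label)
        cases.append(
            VideoCase(
                case_id=f"case_{i:04d}",
                frames=frames,
                truth_masks=masks,
                clinical=clinical,
                label=label,
                params=params,
            )
        )
    return cases


# ---------------------------------------------------------------------------
# disk layout: per-case directory of PNG frames/masks + cohort clinical.csv


def clinical_table(cases: list[VideoCase]) -> pd.DataFrame:
    """Cohort clinical covariates as a DataFrame (one row per case)."""
    rows = [
        {
            "case_id": c.case_id,
            "age": c.clinical.age,
            "size_cm": c.clinical.size_cm,
            "meno": c.clinical.meno,
            "cN": c.clinical.cN,
            "cT": c.clinical.cT,
            "cTNM": c.clinical.cTNM,
            "label": c.label,
        }
        for c in cases
    ]
    return pd.DataFrame(rows)


def write_cohort(cases: list[VideoCase], outdir: str | Path, config: SynthConfig | None = None) -> None:
    """Write a cohort as PNG frames + masks per case plus clinical.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for case in cases:
        cdir = outdir / case.case_id
        cdir.mkdir(exist_ok=True)
        for t in range(case.frames.shape[0]):
            iio.imwrite(
                cdir / f"frame_{t:04d}.png",
                np.round(case.frames[t]).astype(np.uint8),
            )
            iio.imwrite(
                cdir / f"mask_{t:04d}.png",
                (case.truth_masks[t] * 255).astype(np.uint8),
            )
    clinical_table(cases).to_csv(outdir / "clinical.csv", index=False)
    if config is not None:
        cfg = dataclasses.asdict(config)
        with open(outdir / "synth_config.json", "w") as fh:
            json.dump(cfg, fh, indent=2, default=list)


def read_cohort(indir: str | Path) -> list[VideoCase]:
    """Read a cohort written by :func:`write_cohort`."""
    indir = Path(indir)
    clin = pd.read_csv(indir / "clinical.csv").set_index("case_id")
    cases = []
    for cdir in sorted(p for p in indir.iterdir() if p.is_dir()):
        frame_files = sorted(cdir.glob("frame_*.png"))
        mask_files = sorted(cdir.glob("mask_*.png"))
        if not frame_files:
            continue
        frames = np.stack([iio.imread(f).astype(np.float32) for f in frame_files])
        if mask_files:
            masks = np.stack([iio.imread(f) > 0 for f in mask_files])
        else:
            masks = np.zeros(frames.shape, dtype=bool)
        row = clin.loc[cdir.name]
        rec = ClinicalRecord(
            age=float(row["age"]),
            size_cm=float(row["size_cm"]),
            meno=int(row["meno"]),
            cN=int(row["cN"]),
            cT=int(row["cT"]),
            cTNM=int(row["cTNM"]),
        )
        cases.append(
            VideoCase(
                case_id=cdir.name,
                frames=frames,
                truth_masks=masks,
                clinical=rec,
                label=int(row["label"]),
            )
        )
    return cases
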