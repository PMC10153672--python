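"""Dynamic features of static-feature trajectories.

Each of the 91 static features traces a "dynamic change curve" across the
frames of a video.  Every curve is summarized by 24 numbers: 14 time-domain
statistics of the raw series and 10 frequency-domain statistics of its FFT
magnitude spectrum, giving a 91 x 24 = 2184-long vector per video.

Spectral conventions
--------------------
The magnitude spectrum is one-sided: ``P_k = |X_k|`` for bins
``k = 1 .. floor(N/2)`` at frequencies ``f_k = k/N`` cycles/frame; bin 0
feeds only the direct component ``dc = |X_0| / N``.  Spectral moments are
magnitude-weighted means over the positive-frequency bins; the spectral
entropy is normalized by ``log2 K`` so it lies in [0, 1].  No detrending or
windowing is applied by default (``detrend='linear'`` is available): the
signal level is carried by ``dc`` and the moments exclude bin 0, so a level
shift does not leak into the frequency features.

Zero-denominator conventions mirror the static module: skewness/kurtosis of
a zero-variance series, shape factors with a zero denominator, and spectral
moments of an empty (all-zero) positive spectrum are all 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import detrend as _detrend

from .errors import ShortSeriesError
from .staticfeat import StaticFeatureMatrix

__all__ = [
    "TIME_DOMAIN_NAMES",
    "FREQUENCY_DOMAIN_NAMES",
    "DYNAMIC_NAMES",
    "DynamicFeatureVector",
    "time_domain_features",
    "frequency_domain_features",
    "extract_dynamic_vector",
    "cohort_dynamic_table",
]

MIN_FRAMES = 8

TIME_DOMAIN_NAMES = [
    "mean",
    "abs_mean",
    "rms",
    "sra",
    "std",
    "variance",
    "maximum",
    "minimum",
    "peak_to_peak",
    "skewness",
    "kurtosis",
    "waveform_factor",
    "crest_factor",
    "impulse_factor",
]

FREQUENCY_DOMAIN_NAMES = [
    "dc",
    "mean_spectrum",
    "fc",
    "msf",
    "rmsf",
    "vf",
    "rvf",
    "spectral_skewness",
    "spectral_kurtosis",
    "spectral_entropy",
]

DYNAMIC_NAMES = TIME_DOMAIN_NAMES + FREQUENCY_DOMAIN_NAMES  # 24


@dataclass
class DynamicFeatureVector:
    """2184 named dynamic features for one video case."""

    case_id: str
    values: pd.Series  # index "<static>.<dynamic>"

    def __len__(self) -> int:
        return len(self.values)


def _check_series(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.size < MIN_FRAMES:
        raise ShortSeriesError(
            f"series has {x.size} samples; need >= {MIN_FRAMES} frames"
        )
    if not np.all(np.isfinite(x)):
        raise ShortSeriesError("series contains non-finite values")
    return x


def time_domain_features(values: np.ndarray) -> dict[str, float]:
    """14 time-domain statistics with population denominators.

    ``sra`` is the square-root amplitude ``(sum(sqrt|x|)/N)^2``; the three
    shape factors are waveform = rms/abs_mean, crest = max|x|/rms,
    impulse = max|x|/abs_mean (0 when the denominator is 0).
    """
    x = _check_series(values)
    n = x.size
    mean = x.mean()
    absx = np.abs(x)
    abs_mean = absx.mean()
    rms = float(np.sqrt((x**2).mean()))
    var = x.var()
    std = float(np.sqrt(var))
    if std > 0:
        skew = float(np.mean((x - mean) ** 3) / std**3)
        kurt = float(np.mean((x - mean) ** 4) / var**2)
    else:
        skew = kurt = 0.0
    peak = float(absx.max())
    return {
        "mean": float(mean),
        "abs_mean": float(abs_mean),
        "rms": rms,
        "sra": float((np.sqrt(absx).sum() / n) ** 2),
        "std": std,
        "variance": float(var),
        "maximum": float(x.max()),
        "minimum": float(x.min()),
        "peak_to_peak": float(x.max() - x.min()),
        "skewness": skew,
        "kurtosis": kurt,
        "waveform_factor": float(rms / abs_mean) if abs_mean > 0 else 0.0,
        "crest_factor": float(peak / rms) if rms > 0 else 0.0,
        "impulse_factor": float(peak / abs_mean) if abs_mean > 0 else 0.0,
    }


def frequency_domain_features(
    values: np.ndarray, detrend: str | None = None
) -> dict[str, float]:
    """10 frequency-domain statistics of the one-sided FFT magnitude spectrum.

    ``fc`` is the spectral center of gravity, ``msf`` the mean-square
    frequency, ``vf`` the frequency variance about ``fc`` (all weighted by
    the magnitude spectrum); ``rmsf``/``rvf`` are their square roots.  If the
    positive spectrum is identically zero all spectral moments are 0.
    """
    x = _check_series(values)
    if detrend == "linear":
        x = _detrend(x, type="linear")
    n = x.size
    X = np.fft.rfft(x)
    dc = float(np.abs(X[0]) / n)
    k_max = n // 2
    P = np.abs(X[1 : k_max + 1])
    f = np.arange(1, k_max + 1) / n
    total = P.sum()
    out = dict.fromkeys(FREQUENCY_DOMAIN_NAMES, 0.0)
    out["dc"] = dc
    out["mean_spectrum"] = float(total / k_max)
    if total > 0:
        p = P / total
        fc = float((f * p).sum())
        msf = float((f**2 * p).sum())
        vf = float(((f - fc) ** 2 * p).sum())
        rvf = float(np.sqrt(vf))
        out["fc"] = fc
        out["msf"] = msf
        out["rmsf"] = float(np.sqrt(msf))
        out["vf"] = vf
        out["rvf"] = rvf
        if rvf > 0:
            out["spectral_skewness"] = float(((f - fc) ** 3 * p).sum() / rvf**3)
            out["spectral_kurtosis"] = float(((f - fc) ** 4 * p).sum() / rvf**4)
        if k_max > 1:
            pz = p[p > 0]
            out["spectral_entropy"] = float(
                -(pz * np.log2(pz)).sum() / np.log2(k_max)
            )
    return out


def extract_dynamic_vector(
    sfm: StaticFeatureMatrix, detrend: str | None = None
) -> DynamicFeatureVector:
    """24 dynamic features for each static-feature curve of one video.

    Output order follows the static registry; within each static feature the
    14 time-domain values precede the 10 frequency-domain values, named
    ``<static_feature>.<dynamic_feature>``.
    """
    if sfm.n_frames < MIN_FRAMES:
        raise ShortSeriesError(
            f"case {sfm.case_id!r} has {sfm.n_frames} frames; need >= {MIN_FRAMES}"
        )
    names: list[str] = []
    vals: list[float] = []
    for col in sfm.values.columns:
        curve = sfm.values[col].to_numpy()
        td = time_domain_features(curve)
        fd = frequency_domain_features(curve, detrend=detrend)
        for k in TIME_DOMAIN_NAMES:
            names.append(f"{col}.{k}")
            vals.append(td[k])
        for k in FREQUENCY_DOMAIN_NAMES:
            names.append(f"{col}.{k}")
            vals.append(fd[k])
    return DynamicFeatureVector(
        case_id=sfm.case_id, values=pd.Series(vals, index=names, dtype=float)
    )


def cohort_dynamic_table(vectors: list[DynamicFeatureVector]) -> pd.DataFrame:
    """Stack per-case dynamic vectors into a cases x 2184 DataFrame."""
    df = pd.DataFrame(
        {v.case_id: v.values for v in vectors}
    ).T
    df.index.name = "case_id"
    return df
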