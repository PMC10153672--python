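"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written from the defining formulas — loops, direct DFT
summation, exhaustive pair enumeration — and deliberately shares no code
with the package internals it checks.
"""

import math

import numpy as np


def first_order_oracle(values, entropy_bins=32):
    """First-order statistics from their definitions (population denominators)."""
    x = sorted(float(v) for v in values)
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    std = math.sqrt(var)

    def pct(q):
        h = (n - 1) * q / 100.0
        lo = int(math.floor(h))
        hi = min(lo + 1, n - 1)
        return x[lo] + (h - lo) * (x[hi] - x[lo])

    lo_v, hi_v = x[0], x[-1]
    if hi_v > lo_v:
        edges = [lo_v + (hi_v - lo_v) * k / entropy_bins for k in range(entropy_bins + 1)]
        counts = [0] * entropy_bins
        for v in x:
            for b in range(entropy_bins):
                if edges[b] <= v < edges[b + 1] or (b == entropy_bins - 1 and v == hi_v):
                    counts[b] += 1
                    break
    else:
        counts = [n] + [0] * (entropy_bins - 1)
    p = [c / n for c in counts]
    entropy = -sum(pi * math.log2(pi) for pi in p if pi > 0)
    uniformity = sum(pi**2 for pi in p)
    if std > 0:
        skew = sum((v - mean) ** 3 for v in x) / n / std**3
        kurt = sum((v - mean) ** 4 for v in x) / n / var**2
    else:
        skew = kurt = 0.0
    p10, p25, p75, p90 = pct(10), pct(25), pct(75), pct(90)
    sel = [v for v in x if p10 <= v <= p90]
    if sel:
        smean = sum(sel) / len(sel)
        rmad = sum(abs(v - smean) for v in sel) / len(sel)
    else:
        rmad = 0.0
    return {
        "fo_mean": mean,
        "fo_median": pct(50),
        "fo_minimum": x[0],
        "fo_maximum": x[-1],
        "fo_range": x[-1] - x[0],
        "fo_variance": var,
        "fo_std": std,
        "fo_skewness": skew,
        "fo_kurtosis": kurt,
        "fo_energy": sum(v**2 for v in x),
        "fo_rms": math.sqrt(sum(v**2 for v in x) / n),
        "fo_entropy": entropy,
        "fo_uniformity": uniformity,
        "fo_p10": p10,
        "fo_p90": p90,
        "fo_iqr": p75 - p25,
        "fo_mad": sum(abs(v - mean) for v in x) / n,
        "fo_rmad": rmad,
        "fo_cv": std / mean if mean != 0 else 0.0,
    }


def glcm_oracle(q, mask, offset, levels):
    """Co-occurrence features by exhaustive enumeration of ordered pixel pairs."""
    rows, cols = q.shape
    dr, dc = offset
    counts = {}
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols and mask[r, c] and mask[r2, c2]:
                for i, j in ((int(q[r, c]), int(q[r2, c2])), (int(q[r2, c2]), int(q[r, c]))):
                    counts[(i, j)] = counts.get((i, j), 0) + 1
    total = sum(counts.values())
    names = [
        "contrast", "dissimilarity", "homogeneity", "asm", "energy", "correlation",
        "entropy", "cluster_shade", "cluster_prominence", "max_probability", "sum_average",
    ]
    if total == 0:
        return dict.fromkeys(names, 0.0)
    P = {k: v / total for k, v in counts.items()}
    mu_i = sum(i * p for (i, _), p in P.items())
    mu_j = sum(j * p for (_, j), p in P.items())
    var_i = sum((i - mu_i) ** 2 * p for (i, _), p in P.items())
    var_j = sum((j - mu_j) ** 2 * p for (_, j), p in P.items())
    asm = sum(p**2 for p in P.values())
    corr = (
        sum((i - mu_i) * (j - mu_j) * p for (i, j), p in P.items())
        / math.sqrt(var_i * var_j)
        if var_i > 0 and var_j > 0
        else 0.0
    )
    return {
        "contrast": sum((i - j) ** 2 * p for (i, j), p in P.items()),
        "dissimilarity": sum(abs(i - j) * p for (i, j), p in P.items()),
        "homogeneity": sum(p / (1 + (i - j) ** 2) for (i, j), p in P.items()),
        "asm": asm,
        "energy": math.sqrt(asm),
        "correlation": corr,
        "entropy": -sum(p * math.log2(p) for p in P.values() if p > 0),
        "cluster_shade": sum((i + j - mu_i - mu_j) ** 3 * p for (i, j), p in P.items()),
        "cluster_prominence": sum((i + j - mu_i - mu_j) ** 4 * p for (i, j), p in P.items()),
        "max_probability": max(P.values()),
        "sum_average": sum((i + j) * p for (i, j), p in P.items()),
    }


def dft_magnitude_oracle(x):
    """One-sided DFT magnitudes by direct summation: (|X_0|, [|X_1|..|X_K|])."""
    n = len(x)
    k_max = n // 2
    mags = []
    for k in range(k_max + 1):
        re = sum(x[t] * math.cos(2 * math.pi * k * t / n) for t in range(n))
        im = -sum(x[t] * math.sin(2 * math.pi * k * t / n) for t in range(n))
        mags.append(math.hypot(re, im))
    return mags[0], mags[1:]


def frequency_oracle(x):
    """Frequency-domain features from the direct-summation DFT."""
    n = len(x)
    x0, P = dft_magnitude_oracle(x)
    k_max = n // 2
    f = [(k + 1) / n for k in range(k_max)]
    total = sum(P)
    out = {
        "dc": x0 / n,
        "mean_spectrum": total / k_max,
        "fc": 0.0, "msf": 0.0, "rmsf": 0.0, "vf": 0.0, "rvf": 0.0,
        "spectral_skewness": 0.0, "spectral_kurtosis": 0.0, "spectral_entropy": 0.0,
    }
    if total > 0:
        p = [v / total for v in P]
        fc = sum(fi * pi for fi, pi in zip(f, p))
        msf = sum(fi**2 * pi for fi, pi in zip(f, p))
        vf = sum((fi - fc) ** 2 * pi for fi, pi in zip(f, p))
        rvf = math.sqrt(vf)
        out.update(fc=fc, msf=msf, rmsf=math.sqrt(msf), vf=vf, rvf=rvf)
        if rvf > 0:
            out["spectral_skewness"] = sum((fi - fc) ** 3 * pi for fi, pi in zip(f, p)) / rvf**3
            out["spectral_kurtosis"] = sum((fi - fc) ** 4 * pi for fi, pi in zip(f, p)) / rvf**4
        if k_max > 1:
            out["spectral_entropy"] = -sum(pi * math.log2(pi) for pi in p if pi > 0) / math.log2(k_max)
    return out


def time_oracle(x):
    """Time-domain features from their defining formulas."""
    n = len(x)
    mean = sum(x) / n
    abs_mean = sum(abs(v) for v in x) / n
    rms = math.sqrt(sum(v**2 for v in x) / n)
    var = sum((v - mean) ** 2 for v in x) / n
    std = math.sqrt(var)
    peak = max(abs(v) for v in x)
    return {
        "mean": mean,
        "abs_mean": abs_mean,
        "rms": rms,
        "sra": (sum(math.sqrt(abs(v)) for v in x) / n) ** 2,
        "std": std,
        "variance": var,
        "maximum": max(x),
        "minimum": min(x),
        "peak_to_peak": max(x) - min(x),
        "skewness": sum((v - mean) ** 3 for v in x) / n / std**3 if std > 0 else 0.0,
        "kurtosis": sum((v - mean) ** 4 for v in x) / n / var**2 if var > 0 else 0.0,
        "waveform_factor": rms / abs_mean if abs_mean > 0 else 0.0,
        "crest_factor": peak / rms if rms > 0 else 0.0,
        "impulse_factor": peak / abs_mean if abs_mean > 0 else 0.0,
    }


def auc_oracle(probs, labels):
    """AUC as the Mann-Whitney all-pairs concordance."""
    pos = [p for p, y in zip(probs, labels) if y == 1]
    neg = [p for p, y in zip(probs, labels) if y == 0]
    score = 0.0
    for pp in pos:
        for pn in neg:
            if pp > pn:
                score += 1.0
            elif pp == pn:
                score += 0.5
    return score / (len(pos) * len(neg))


def iou_oracle(a, b):
    """Box IoU by direct pixel-area arithmetic on inclusive boxes."""
    ax = set(range(int(a[0]), int(a[2]) + 1))
    ay = set(range(int(a[1]), int(a[3]) + 1))
    bx = set(range(int(b[0]), int(b[2]) + 1))
    by = set(range(int(b[1]), int(b[3]) + 1))
    inter = len(ax & bx) * len(ay & by)
    union = len(ax) * len(ay) + len(bx) * len(by) - inter
    return inter / union
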