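"""Classifier performance metrics with bootstrap CIs and paired resampling.

Implements AUC (Mann-Whitney concordance), accuracy, sensitivity,
specificity and the Youden index (YI = SEN + SPC - 1), percentile-bootstrap
95% confidence intervals, and a paired multi-model comparison: R repeated
resamples of the test set (the same indices for every model within a
repetition) summarized per model and compared with paired t-tests.

Probability ties at the decision threshold count as positive calls
(``p >= tau``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import CIError, UndefinedMetricError

__all__ = [
    "ConfusionCounts",
    "EvalMetrics",
    "ComparisonReport",
    "roc_auc",
    "confusion_at_threshold",
    "metrics_from_confusion",
    "evaluate_predictions",
    "bootstrap_ci",
    "metrics_with_ci",
    "repeated_resample_compare",
    "roc_points",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvalMetrics:
    """AUC/ACC/SEN/SPC/YI as fractions; optional 95% CI per metric."""

    auc: float | None
    acc: float
    sen: float
    spc: float
    yi: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {"auc": self.auc, "acc": self.acc, "sen": self.sen, "spc": self.spc, "yi": self.yi}


def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if not np.isin(y, (0, 1)).all():
        raise UndefinedMetricError("labels must be binary 0/1")
    return y


def roc_auc(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve = Mann-Whitney concordance probability."""
    y = _check_binary(labels)
    p = np.asarray(probabilities, dtype=float)
    if y.min() == y.max():
        raise UndefinedMetricError("AUC undefined: labels contain a single class")
    return float(roc_auc_score(y, p))


def confusion_at_threshold(
    probabilities: np.ndarray, labels: np.ndarray, tau: float = 0.5
) -> ConfusionCounts:
    """Confusion counts calling positive iff p >= tau."""
    y = _check_binary(labels)
    calls = np.asarray(probabilities, dtype=float) >= tau
    return ConfusionCounts(
        tp=int(np.sum(calls & (y == 1))),
        fp=int(np.sum(calls & (y == 0))),
        tn=int(np.sum(~calls & (y == 0))),
        fn=int(np.sum(~calls & (y == 1))),
    )


def metrics_from_confusion(c: ConfusionCounts, auc: float | None = None) -> EvalMetrics:
    if c.n == 0:
        raise UndefinedMetricError("accuracy undefined: no predictions")
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive cases")
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative cases")
    sen = c.tp / (c.tp + c.fn)
    spc = c.tn / (c.tn + c.fp)
    return EvalMetrics(
        auc=auc,
        acc=(c.tp + c.tn) / c.n,
        sen=sen,
        spc=spc,
        yi=sen + spc - 1.0,
    )


def evaluate_predictions(
    probabilities: np.ndarray, labels: np.ndarray, tau: float = 0.5
) -> EvalMetrics:
    """All five metrics of one prediction set at threshold ``tau``."""
    auc = roc_auc(probabilities, labels)
    return metrics_from_confusion(
        confusion_at_threshold(probabilities, labels, tau), auc=auc
    )


def _resample_indices(
    rng: np.random.Generator, n: int, m: int, labels: np.ndarray, max_redraw: int = 10
) -> np.ndarray | None:
    """Draw m indices with replacement, redrawing if a class is absent."""
    for _ in range(max_redraw):
        idx = rng.integers(0, n, size=m)
        if labels[idx].min() != labels[idx].max():
            return idx
    return None


def bootstrap_ci(
    metric_fn,
    probabilities: np.ndarray,
    labels: np.ndarray,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile-bootstrap CI of ``metric_fn(probabilities, labels)``.

    Resamples of size n are drawn with replacement; a resample lacking one
    of the classes is redrawn up to 10 times, then skipped with a warning.
    """
    if B < 100:
        raise CIError(f"B must be >= 100, got {B}")
    p = np.asarray(probabilities, dtype=float)
    y = _check_binary(labels)
    n = y.size
    rng = np.random.default_rng(seed)
    vals = []
    skipped = 0
    for _ in range(B):
        idx = _resample_indices(rng, n, n, y)
        if idx is None:
            skipped += 1
            continue
        vals.append(metric_fn(p[idx], y[idx]))
    if skipped:
        warnings.warn(f"{skipped}/{B} bootstrap resamples skipped (single class)")
    if not vals:
        raise CIError("metric undefined on every bootstrap resample")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(vals, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def metrics_with_ci(
    probabilities: np.ndarray,
    labels: np.ndarray,
    tau: float = 0.5,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> EvalMetrics:
    """Point metrics plus percentile-bootstrap CIs for all five metrics."""
    m = evaluate_predictions(probabilities, labels, tau)

    def metric(name):
        def f(p, y):
            em = evaluate_predictions(p, y, tau)
            return getattr(em, name)

        return f

    for name in ("auc", "acc", "sen", "spc", "yi"):
        m.ci[name] = bootstrap_ci(
            metric(name), probabilities, labels, B=B, level=level, seed=seed
        )
    return m


@dataclass
class ComparisonReport:
    """Per-model metric distributions over R paired resamples + paired t-tests."""

    distributions: dict[str, pd.DataFrame]  # metric -> (R x models)
    pairwise: pd.DataFrame  # metric, model_a, model_b, t, p
    winners: dict[str, str]  # metric -> model with highest mean

    @property
    def n_repetitions(self) -> int:
        return len(next(iter(self.distributions.values())))


def repeated_resample_compare(
    predictions: dict[str, np.ndarray],
    labels: np.ndarray,
    R: int = 1000,
    m: int | None = None,
    tau: float = 0.5,
    seed: int = 0,
) -> ComparisonReport:
    """Compare models by R repeated with-replacement resamples of the test set.

    Within each repetition one index set of size ``m`` (default: the test-set
    size) is drawn and every model is evaluated on it, so the per-repetition
    metric differences are paired; pairwise two-sided paired t-tests are
    reported for AUC, ACC and YI.
    """
    if len(predictions) < 2:
        raise UndefinedMetricError("need >= 2 models to compare")
    y = _check_binary(labels)
    n = y.size
    m = n if m is None else m
    names = list(predictions)
    for name, p in predictions.items():
        if len(p) != n:
            raise UndefinedMetricError(f"model {name!r} has {len(p)} predictions for {n} cases")
    rng = np.random.default_rng(seed)
    rows: dict[str, list[list[float]]] = {"auc": [], "acc": [], "yi": []}
    for _ in range(R):
        idx = _resample_indices(rng, n, m, y)
        while idx is None:  # pathological but keep R repetitions
            idx = _resample_indices(rng, n, m, y)
        rep = {"auc": [], "acc": [], "yi": []}
        for name in names:
            em = evaluate_predictions(np.asarray(predictions[name])[idx], y[idx], tau)
            rep["auc"].append(em.auc)
            rep["acc"].append(em.acc)
            rep["yi"].append(em.yi)
        for k in rows:
            rows[k].append(rep[k])
    dists = {k: pd.DataFrame(rows[k], columns=names) for k in rows}
    pair_rows = []
    for metric, df in dists.items():
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                diff = df[a] - df[b]
                if np.allclose(diff, 0.0):
                    t, pval = 0.0, 1.0
                else:
                    t, pval = stats.ttest_rel(df[a], df[b])
                pair_rows.append(
                    {"metric": metric, "model_a": a, "model_b": b, "t": float(t), "p": float(pval)}
                )
    pairwise = pd.DataFrame(pair_rows)
    winners = {k: str(df.mean().idxmax()) for k, df in dists.items()}
    return ComparisonReport(distributions=dists, pairwise=pairwise, winners=winners)


def roc_points(probabilities: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """ROC curve points (fpr, tpr, threshold) for plotting or export."""
    y = _check_binary(labels)
    fpr, tpr, thr = roc_curve(y, np.asarray(probabilities, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
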