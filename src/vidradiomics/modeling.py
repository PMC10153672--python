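"""Two-branch classifier fusion: imaging (PCA + classifier) and clinical.

The imaging branch standardizes the 2184 dynamic features with training
statistics, reduces them by PCA (smallest number of components reaching the
retained-variance threshold, default 0.95) and fits one of four base
classifiers; the clinical branch standardizes age and lesion size (the
ordinal codes meno/cN/cT/cTNM enter as integers) and fits another base
classifier.  The fused probability is the weighted average
``w * p_imaging + (1 - w) * p_clinical`` (default w = 0.5); the binary call
thresholds the fused probability at tau (default 0.5).

All fitting — scaler statistics, PCA mean/components, classifiers — uses
training rows only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from . import evaluation
from .errors import (
    CohortTooSmallError,
    ConfigError,
    DegenerateLabelError,
    ShapeError,
)

__all__ = [
    "CLASSIFIER_KINDS",
    "CLINICAL_COLUMNS",
    "SplitSpec",
    "BaseClassifierSpec",
    "PCAProjection",
    "Branch",
    "FusionModel",
    "PredictionSet",
    "split_cohort",
    "fit_pca",
    "apply_pca",
    "encode_clinical",
    "fit_branch",
    "predict_branch",
    "fuse",
    "fit_fusion",
    "predict_fusion",
    "run_model_grid",
    "GridResult",
]

CLASSIFIER_KINDS = ("SVM", "RF", "LR", "XGBoost")
CLINICAL_COLUMNS = ["age", "size_cm", "meno", "cN", "cT", "cTNM"]


@dataclass(frozen=True)
class SplitSpec:
    """Random train/test split: train fraction, seed, optional stratification."""

    ratio: float = 0.8
    seed: int = 0
    stratified: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.ratio < 1.0:
            raise ConfigError(f"ratio must be in (0, 1), got {self.ratio}")


def split_cohort(
    case_ids: list[str], labels: np.ndarray, spec: SplitSpec
) -> tuple[list[str], list[str]]:
    """Split case ids into train/test; |train| = round(n * ratio).

    Unstratified by default; stratified mode apportions the train quota over
    the classes by largest-remainder rounding so class fractions are
    preserved within rounding.
    """
    ids = list(case_ids)
    y = np.asarray(labels).astype(int)
    n = len(ids)
    if n < 5:
        raise CohortTooSmallError(f"need >= 5 cases to split, got {n}")
    if len(y) != n:
        raise ShapeError("case_ids and labels length mismatch")
    n_train = round(n * spec.ratio)
    rng = np.random.default_rng(spec.seed)
    if not spec.stratified:
        perm = rng.permutation(n)
        train_idx = set(perm[:n_train].tolist())
    else:
        train_idx = set()
        classes = np.unique(y)
        quotas = {c: n_train * np.sum(y == c) / n for c in classes}
        base = {c: int(np.floor(q)) for c, q in quotas.items()}
        rem = n_train - sum(base.values())
        order = sorted(classes, key=lambda c: quotas[c] - base[c], reverse=True)
        for c in order[:rem]:
            base[c] += 1
        for c in classes:
            members = np.flatnonzero(y == c)
            perm = rng.permutation(members)
            train_idx.update(perm[: base[c]].tolist())
    train = [ids[i] for i in range(n) if i in train_idx]
    test = [ids[i] for i in range(n) if i not in train_idx]
    return train, test


@dataclass
class PCAProjection:
    """Training-fit PCA retaining a cumulative explained-variance threshold."""

    mean: np.ndarray
    components: np.ndarray  # (n_components, n_features), orthonormal rows
    threshold: float
    n_components: int
    explained_variance_ratio: np.ndarray


def fit_pca(train_matrix: np.ndarray, threshold: float = 0.95) -> PCAProjection:
    """Fit PCA on training rows; keep the smallest component count whose
    cumulative explained variance reaches ``threshold`` (threshold >= 1
    keeps every component)."""
    X = np.ascontiguousarray(train_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ShapeError("train matrix must be 2-D with >= 2 rows")
    if threshold >= 1.0:
        pca = PCA(n_components=min(X.shape), svd_solver="full")
    else:
        pca = PCA(n_components=threshold, svd_solver="full")
    pca.fit(X)
    return PCAProjection(
        mean=pca.mean_.copy(),
        components=pca.components_.copy(),
        threshold=threshold,
        n_components=pca.components_.shape[0],
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


def apply_pca(proj: PCAProjection, matrix: np.ndarray) -> np.ndarray:
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] != proj.mean.size:
        raise ShapeError(
            f"matrix has {X.shape[-1] if X.ndim == 2 else '?'} columns; "
            f"projection expects {proj.mean.size}"
        )
    return (X - proj.mean) @ proj.components.T


@dataclass(frozen=True)
class BaseClassifierSpec:
    """One of the four base classifier kinds with documented defaults."""

    kind: str
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ConfigError(
                f"kind must be one of {CLASSIFIER_KINDS}, got {self.kind!r}"
            )


def _build_classifier(spec: BaseClassifierSpec):
    kind, seed = spec.kind, spec.seed
    if kind == "SVM":
        defaults = dict(kernel="rbf", C=1.0, gamma="scale", probability=True)
        defaults.update(spec.params)
        return SVC(random_state=seed, **defaults)
    if kind == "RF":
        defaults = dict(n_estimators=200, n_jobs=1)
        defaults.update(spec.params)
        return RandomForestClassifier(random_state=seed, **defaults)
    if kind == "LR":
        defaults = dict(max_iter=2000, C=1.0)
        defaults.update(spec.params)
        return LogisticRegression(random_state=seed, **defaults)
    defaults = dict(
        n_estimators=200,
        max_depth=3,
        learning_rate=0.1,
        n_jobs=1,
        eval_metric="logloss",
        verbosity=0,
    )
    defaults.update(spec.params)
    return XGBClassifier(random_state=seed, **defaults)


class _ColumnScaler:
    """Standardize a subset of columns with training statistics."""

    def __init__(self, columns: list[int] | None = None):
        self.columns = columns  # None = all
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "_ColumnScaler":
        X = np.asarray(X, dtype=float)
        cols = range(X.shape[1]) if self.columns is None else self.columns
        self.mean_ = np.zeros(X.shape[1])
        self.scale_ = np.ones(X.shape[1])
        for c in cols:
            self.mean_[c] = X[:, c].mean()
            s = X[:, c].std()
            self.scale_[c] = s if s > 0 else 1.0
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_


@dataclass
class Branch:
    """A fitted branch: scaler (+ optional PCA) + base classifier."""

    spec: BaseClassifierSpec
    scaler: object
    pca: PCAProjection | None
    classifier: object
    n_features_in: int


def fit_branch(
    features: np.ndarray,
    labels: np.ndarray,
    spec: BaseClassifierSpec,
    pca_threshold: float | None = None,
    scale_columns: list[int] | None = None,
) -> Branch:
    """Fit one branch on training rows only.

    ``pca_threshold`` enables the PCA step (imaging branch);
    ``scale_columns`` restricts standardization to the named column indices
    (clinical branch: age and size only), default all columns.
    """
    # C-contiguous copy: summation order (hence fitted statistics) must not
    # depend on the caller's array memory layout
    X = np.ascontiguousarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ShapeError("features must be 2-D with one row per label")
    if np.unique(y).size < 2:
        raise DegenerateLabelError("training labels contain a single class")
    if scale_columns is None:
        scaler = StandardScaler().fit(X)
    else:
        scaler = _ColumnScaler(scale_columns).fit(X)
    Xs = scaler.transform(X)
    proj = None
    if pca_threshold is not None:
        proj = fit_pca(Xs, threshold=pca_threshold)
        Xs = apply_pca(proj, Xs)
    clf = _build_classifier(spec)
    clf.fit(Xs, y)
    return Branch(
        spec=spec, scaler=scaler, pca=proj, classifier=clf, n_features_in=X.shape[1]
    )


def predict_branch(branch: Branch, features: np.ndarray) -> np.ndarray:
    """Class-1 probabilities of a fitted branch."""
    X = np.ascontiguousarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != branch.n_features_in:
        raise ShapeError(
            f"features have {X.shape[-1] if X.ndim == 2 else '?'} columns; "
            f"branch expects {branch.n_features_in}"
        )
    Xs = branch.scaler.transform(X)
    if branch.pca is not None:
        Xs = apply_pca(branch.pca, Xs)
    return branch.classifier.predict_proba(Xs)[:, 1]


def encode_clinical(df: pd.DataFrame) -> np.ndarray:
    """Clinical covariates as a float matrix in canonical column order."""
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ShapeError(f"clinical table missing columns: {missing}")
    return df[CLINICAL_COLUMNS].to_numpy(dtype=float)


def fuse(p_imaging: np.ndarray, p_clinical: np.ndarray, w: float = 0.5) -> np.ndarray:
    """Weighted probability average ``w * p_imaging + (1 - w) * p_clinical``."""
    if not 0.0 <= w <= 1.0:
        raise ConfigError(f"fusion weight w must be in [0, 1], got {w}")
    pi = np.asarray(p_imaging, dtype=float)
    pc = np.asarray(p_clinical, dtype=float)
    if pi.shape != pc.shape:
        raise ShapeError(f"branch probability shapes differ: {pi.shape} vs {pc.shape}")
    return w * pi + (1.0 - w) * pc


@dataclass
class FusionModel:
    imaging: Branch
    clinical: Branch
    w: float = 0.5
    tau: float = 0.5


@dataclass
class PredictionSet:
    case_ids: list[str]
    labels: np.ndarray
    p_fused: np.ndarray
    p_imaging: np.ndarray
    p_clinical: np.ndarray
    calls: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "case_id": self.case_ids,
                "label": self.labels,
                "p_imaging": self.p_imaging,
                "p_clinical": self.p_clinical,
                "p_fused": self.p_fused,
                "call": self.calls.astype(int),
            }
        )


def fit_fusion(
    imaging_features: np.ndarray,
    clinical_features: np.ndarray,
    labels: np.ndarray,
    imaging_spec: BaseClassifierSpec,
    clinical_spec: BaseClassifierSpec,
    pca_threshold: float = 0.95,
    w: float = 0.5,
    tau: float = 0.5,
) -> FusionModel:
    """Fit both branches on the training cohort."""
    imaging = fit_branch(imaging_features, labels, imaging_spec, pca_threshold=pca_threshold)
    clinical = fit_branch(
        clinical_features, labels, clinical_spec, scale_columns=[0, 1]
    )
    return FusionModel(imaging=imaging, clinical=clinical, w=w, tau=tau)


def predict_fusion(
    model: FusionModel,
    imaging_features: np.ndarray,
    clinical_features: np.ndarray,
    labels: np.ndarray,
    case_ids: list[str] | None = None,
) -> PredictionSet:
    p_i = predict_branch(model.imaging, imaging_features)
    p_c = predict_branch(model.clinical, clinical_features)
    p_f = fuse(p_i, p_c, model.w)
    y = np.asarray(labels).astype(int)
    ids = list(case_ids) if case_ids is not None else [str(i) for i in range(y.size)]
    return PredictionSet(
        case_ids=ids,
        labels=y,
        p_fused=p_f,
        p_imaging=p_i,
        p_clinical=p_c,
        calls=p_f >= model.tau,
    )


@dataclass
class GridResult:
    """4x4 fused grid + single-branch rows, with the best fused pair."""

    table: pd.DataFrame
    best: tuple[str, str]
    predictions: dict[tuple[str, str], PredictionSet]


def _metric_row(p: np.ndarray, y: np.ndarray, tau: float, prefix: str) -> dict:
    em = evaluation.evaluate_predictions(p, y, tau)
    return {f"{prefix}_{k}": v for k, v in em.as_dict().items()}


def run_model_grid(
    imaging_train: np.ndarray,
    clinical_train: np.ndarray,
    y_train: np.ndarray,
    imaging_test: np.ndarray,
    clinical_test: np.ndarray,
    y_test: np.ndarray,
    kinds: tuple[str, ...] = CLASSIFIER_KINDS,
    seed: int = 0,
    pca_threshold: float = 0.95,
    w: float = 0.5,
    tau: float = 0.5,
) -> GridResult:
    """Fit and evaluate every (imaging kind x clinical kind) fusion pair.

    The table holds 4 imaging-only rows, 4 clinical-only rows and 16 fused
    rows, each with train and test AUC/ACC/SEN/SPC/YI.  The best fused pair
    maximizes test AUC, ties broken by higher test Youden index then by
    lexicographic kind names.
    """
    y_tr = np.asarray(y_train).astype(int)
    y_te = np.asarray(y_test).astype(int)
    imaging_branches = {
        k: fit_branch(
            imaging_train, y_tr, BaseClassifierSpec(kind=k, seed=seed),
            pca_threshold=pca_threshold,
        )
        for k in kinds
    }
    clinical_branches = {
        k: fit_branch(
            clinical_train, y_tr, BaseClassifierSpec(kind=k, seed=seed),
            scale_columns=[0, 1],
        )
        for k in kinds
    }
    p_img_tr = {k: predict_branch(b, imaging_train) for k, b in imaging_branches.items()}
    p_img_te = {k: predict_branch(b, imaging_test) for k, b in imaging_branches.items()}
    p_cl_tr = {k: predict_branch(b, clinical_train) for k, b in clinical_branches.items()}
    p_cl_te = {k: predict_branch(b, clinical_test) for k, b in clinical_branches.items()}

    rows = []
    predictions: dict[tuple[str, str], PredictionSet] = {}
    for k in kinds:
        row = {"model": "imaging", "imaging_kind": k, "clinical_kind": ""}
        row.update(_metric_row(p_img_tr[k], y_tr, tau, "train"))
        row.update(_metric_row(p_img_te[k], y_te, tau, "test"))
        rows.append(row)
    for k in kinds:
        row = {"model": "clinical", "imaging_kind": "", "clinical_kind": k}
        row.update(_metric_row(p_cl_tr[k], y_tr, tau, "train"))
        row.update(_metric_row(p_cl_te[k], y_te, tau, "test"))
        rows.append(row)
    for ik in kinds:
        for ck in kinds:
            pf_tr = fuse(p_img_tr[ik], p_cl_tr[ck], w)
            pf_te = fuse(p_img_te[ik], p_cl_te[ck], w)
            row = {"model": "fused", "imaging_kind": ik, "clinical_kind": ck}
            row.update(_metric_row(pf_tr, y_tr, tau, "train"))
            row.update(_metric_row(pf_te, y_te, tau, "test"))
            rows.append(row)
            predictions[(ik, ck)] = PredictionSet(
                case_ids=[str(i) for i in range(y_te.size)],
                labels=y_te,
                p_fused=pf_te,
                p_imaging=p_img_te[ik],
                p_clinical=p_cl_te[ck],
                calls=pf_te >= tau,
            )
    table = pd.DataFrame(rows)
    fused = table[table["model"] == "fused"]
    best_row = fused.sort_values(
        by=["test_auc", "test_yi", "imaging_kind", "clinical_kind"],
        ascending=[False, False, True, True],
    ).iloc[0]
    best = (str(best_row["imaging_kind"]), str(best_row["clinical_kind"]))
    return GridResult(table=table, best=best, predictions=predictions)
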