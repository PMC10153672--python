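"""End-to-end convenience layer: video cases -> features -> fitted models.

Chains detection (or truth-mask bypass), rejection/interpolation cleanup,
static and dynamic feature extraction across a cohort, and wires the result
into the two-branch fusion models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dynfeat, evaluation, modeling, staticfeat, tracking
from .synthvideo import VideoCase, clinical_table

__all__ = ["CohortFeatures", "extract_case_vector", "cohort_features", "fit_and_evaluate"]


@dataclass
class CohortFeatures:
    """Cohort-level feature tables ready for modeling."""

    dynamic: pd.DataFrame  # cases x 2184, indexed by case_id
    clinical: pd.DataFrame  # cases x clinical columns + label
    labels: pd.Series  # indexed by case_id


def extract_case_vector(
    case: VideoCase,
    use_truth_masks: bool = False,
    registry: staticfeat.FeatureRegistry = staticfeat.DEFAULT_REGISTRY,
    window: int = 5,
    iou_min: float = 0.3,
    detector_kwargs: dict | None = None,
) -> dynfeat.DynamicFeatureVector:
    """Track, clean, and featurize a single video case."""
    if use_truth_masks:
        track = tracking.track_from_masks(case.truth_masks, case_id=case.case_id)
    else:
        track = tracking.detect_boxes_naive(
            case.frames, case_id=case.case_id, **(detector_kwargs or {})
        )
    track = tracking.clean_track(track, window=window, iou_min=iou_min)
    roi = tracking.track_to_roi_masks(track, case.frames.shape[1:])
    sfm = staticfeat.extract_static_features(
        case.frames, roi, registry=registry, case_id=case.case_id
    )
    return dynfeat.extract_dynamic_vector(sfm)


def cohort_features(
    cases: list[VideoCase],
    use_truth_masks: bool = False,
    registry: staticfeat.FeatureRegistry = staticfeat.DEFAULT_REGISTRY,
    **kwargs,
) -> CohortFeatures:
    """Featurize every case of a cohort into modeling-ready tables."""
    vectors = [
        extract_case_vector(c, use_truth_masks=use_truth_masks, registry=registry, **kwargs)
        for c in cases
    ]
    dyn = dynfeat.cohort_dynamic_table(vectors)
    clin = clinical_table(cases).set_index("case_id")
    labels = clin["label"]
    return CohortFeatures(dynamic=dyn, clinical=clin, labels=labels)


def fit_and_evaluate(
    feats: CohortFeatures,
    imaging_kind: str = "XGBoost",
    clinical_kind: str = "LR",
    split: modeling.SplitSpec | None = None,
    pca_threshold: float = 0.95,
    w: float = 0.5,
    tau: float = 0.5,
    seed: int = 0,
) -> dict:
    """Split the cohort, fit one fused model, and evaluate both cohorts.

    Returns a dict with the fitted model, train/test PredictionSets, and
    train/test EvalMetrics for the fused and single-branch predictions.
    """
    split = split or modeling.SplitSpec(seed=seed)
    ids = list(feats.dynamic.index)
    y = feats.labels.loc[ids].to_numpy()
    train_ids, test_ids = modeling.split_cohort(ids, y, split)

    Ximg_tr = feats.dynamic.loc[train_ids].to_numpy()
    Ximg_te = feats.dynamic.loc[test_ids].to_numpy()
    Xcl_tr = modeling.encode_clinical(feats.clinical.loc[train_ids])
    Xcl_te = modeling.encode_clinical(feats.clinical.loc[test_ids])
    y_tr = feats.labels.loc[train_ids].to_numpy()
    y_te = feats.labels.loc[test_ids].to_numpy()

    model = modeling.fit_fusion(
        Ximg_tr,
        Xcl_tr,
        y_tr,
        modeling.BaseClassifierSpec(kind=imaging_kind, seed=seed),
        modeling.BaseClassifierSpec(kind=clinical_kind, seed=seed),
        pca_threshold=pca_threshold,
        w=w,
        tau=tau,
    )
    pred_tr = modeling.predict_fusion(model, Ximg_tr, Xcl_tr, y_tr, case_ids=train_ids)
    pred_te = modeling.predict_fusion(model, Ximg_te, Xcl_te, y_te, case_ids=test_ids)

    def _ev(p: np.ndarray, y_: np.ndarray) -> evaluation.EvalMetrics:
        return evaluation.evaluate_predictions(p, y_, tau)

    return {
        "model": model,
        "train_ids": train_ids,
        "test_ids": test_ids,
        "predictions_train": pred_tr,
        "predictions_test": pred_te,
        "metrics_train": _ev(pred_tr.p_fused, y_tr),
        "metrics_test": _ev(pred_te.p_fused, y_te),
        "metrics_test_imaging": _ev(pred_te.p_imaging, y_te),
        "metrics_test_clinical": _ev(pred_te.p_clinical, y_te),
    }
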