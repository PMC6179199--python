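"""Radius-matched precision/recall evaluation of point detections.

A detection is a true positive if a ground-truth center lies within the
match radius (default 25, the same circular range used for suppression);
detections claim centers in rank order, each taking its nearest unclaimed
center, so a detection circle holding two centers yields one TP and leaves
the other center a false negative.  Sweeping the detection threshold gives
the precision-recall curve and its maximum F-measure, the headline metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detection import Detection, DetectionConfig, detect
from .synthetic import GroundTruth
from .voting import ScoreMap

__all__ = ["MatchResult", "PRCurve", "match", "pr_curve", "pooled_pr_curve"]


@dataclass(frozen=True)
class MatchResult:
    true_positives: list[tuple[Detection, int]]  # (detection, index of claimed center)
    false_positives: list[Detection]
    false_negatives: list[int]  # indices of unclaimed centers
    match_radius: float

    @property
    def precision(self) -> float:
        n_det = len(self.true_positives) + len(self.false_positives)
        return len(self.true_positives) / n_det if n_det else 0.0

    @property
    def recall(self) -> float:
        n_gt = len(self.true_positives) + len(self.false_negatives)
        return len(self.true_positives) / n_gt if n_gt else 0.0

    @property
    def f_measure(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r > 0 else 0.0


@dataclass(frozen=True)
class PRCurve:
    thresholds: np.ndarray  # ascending
    precision: np.ndarray
    recall: np.ndarray
    f_measure: np.ndarray
    max_f: float


def match(
    detections: list[Detection], truth: GroundTruth, match_radius: float = 25.0
) -> MatchResult:
    """Assign detections to ground-truth centers within ``match_radius``.

    Detections are processed in rank order (highest score first); each
    claims its nearest unclaimed center within the radius or becomes a
    false positive.  Every center is claimed at most once.
    """
    if match_radius <= 0:
        raise ValueError("match_radius must be > 0")
    centers = truth.centers
    claimed = np.zeros(len(centers), dtype=bool)
    tps: list[tuple[Detection, int]] = []
    fps: list[Detection] = []
    for det in sorted(detections, key=lambda d: d.rank):
        if len(centers) == 0:
            fps.append(det)
            continue
        d = np.hypot(centers[:, 0] - det.center[0], centers[:, 1] - det.center[1])
        d[claimed] = np.inf
        j = int(np.argmin(d))
        if d[j] <= match_radius:
            claimed[j] = True
            tps.append((det, j))
        else:
            fps.append(det)
    fns = [int(j) for j in np.nonzero(~claimed)[0]]
    return MatchResult(tps, fps, fns, match_radius)


def _default_thresholds(max_value: float, n: int = 200) -> np.ndarray:
    if max_value <= 0:
        max_value = 1.0
    return np.linspace(0.0, max_value, n)


def _curve_from_counts(thresholds, tp, fp, fn) -> PRCurve:
    tp, fp, fn = (np.asarray(a, dtype=float) for a in (tp, fp, fn))
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        r = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f = np.where(p + r > 0, 2 * p * r / (p + r), 0.0)
    return PRCurve(
        thresholds=np.asarray(thresholds, dtype=float),
        precision=p,
        recall=r,
        f_measure=f,
        max_f=float(f.max()) if len(f) else 0.0,
    )


def pr_curve(
    score_map: ScoreMap,
    truth: GroundTruth,
    det_config: DetectionConfig = DetectionConfig(),
    thresholds: np.ndarray | None = None,
    method: str = "truncate",
) -> PRCurve:
    """Precision-recall sweep over detection thresholds.

    ``method="truncate"`` runs the greedy detector once at the lowest
    threshold and truncates the ranked list per threshold;
    ``method="resuppress"`` re-runs detection at every threshold.  The two
    agree exactly because greedy selection with a higher threshold is a
    prefix of the lower-threshold run.
    """
    if thresholds is None:
        thresholds = _default_thresholds(float(np.max(score_map.values)))
    thresholds = np.sort(np.asarray(thresholds, dtype=float))
    if len(thresholds) == 0:
        raise ValueError("thresholds must be non-empty")

    tp, fp, fn = [], [], []
    if method == "truncate":
        import dataclasses

        base = dataclasses.replace(det_config, threshold=float(thresholds[0]))
        dets = detect(score_map, base)
        for t in thresholds:
            kept = [d for d in dets if d.score >= t]
            m = match(kept, truth, det_config.suppression_radius)
            tp.append(len(m.true_positives))
            fp.append(len(m.false_positives))
            fn.append(len(m.false_negatives))
    elif method == "resuppress":
        import dataclasses

        for t in thresholds:
            dets = detect(score_map, dataclasses.replace(det_config, threshold=float(t)))
            m = match(dets, truth, det_config.suppression_radius)
            tp.append(len(m.true_positives))
            fp.append(len(m.false_positives))
            fn.append(len(m.false_negatives))
    else:
        raise ValueError(f"unknown method {method!r}")
    return _curve_from_counts(thresholds, tp, fp, fn)


def pooled_pr_curve(
    score_maps: list[ScoreMap],
    truths: list[GroundTruth],
    det_config: DetectionConfig = DetectionConfig(),
    thresholds: np.ndarray | None = None,
) -> PRCurve:
    """PR sweep pooled over a test set: TP/FP/FN are summed across images at
    each common threshold before computing precision and recall."""
    if len(score_maps) != len(truths):
        raise ValueError("score_maps and truths length mismatch")
    if thresholds is None:
        global_max = max(float(np.max(m.values)) for m in score_maps)
        thresholds = _default_thresholds(global_max)
    thresholds = np.sort(np.asarray(thresholds, dtype=float))

    import dataclasses

    per_image: list[list[Detection]] = []
    for m in score_maps:
        base = dataclasses.replace(det_config, threshold=float(thresholds[0]))
        per_image.append(detect(m, base))

    tp = np.zeros(len(thresholds))
    fp = np.zeros(len(thresholds))
    fn = np.zeros(len(thresholds))
    for dets, truth in zip(per_image, truths):
        for i, t in enumerate(thresholds):
            kept = [d for d in dets if d.score >= t]
            mres = match(kept, truth, det_config.suppression_radius)
            tp[i] += len(mres.true_positives)
            fp[i] += len(mres.false_positives)
            fn[i] += len(mres.false_negatives)
    return _curve_from_counts(thresholds, tp, fp, fn)
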