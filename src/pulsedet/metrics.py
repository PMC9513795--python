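"""Evaluation suite: adapted mAP, coverage, boundary errors, standard 1D mAP.

For pulse detection the usual IoU true-positive criterion is replaced by an
adapted one: a score-ranked prediction is a true positive when the distance
between its midpoint and the matched ground-truth midpoint, expressed as a
percentage of the ground-truth duration, falls strictly below a threshold.
The adapted mAP averages the average precision over thresholds from 100% to
400% in 10% steps (31 thresholds).  Coverage is the recovered fraction of
ground-truth pulses at a single threshold.  The classical COCO-style mAP on
1D IoU (thresholds 0.50:0.05:0.95) is kept for comparison.

Scenes (windows or traces) without any ground-truth pulse are excluded:
average precision is not defined for scenes without objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

ADAPTED_THRESHOLDS_PCT = tuple(float(t) for t in range(100, 401, 10))
STANDARD_IOU_THRESHOLDS = tuple(np.arange(0.50, 0.951, 0.05).round(2))
DEFAULT_COVERAGE_THRESHOLD_PCT = 100.0


def _interval(obj) -> tuple[float, float]:
    if hasattr(obj, "segment"):
        obj = obj.segment
    if hasattr(obj, "start_ms"):
        return float(obj.start_ms), float(obj.end_ms)
    return float(obj[0]), float(obj[1])


def _score(det) -> float:
    if hasattr(det, "score"):
        return float(det.score)
    return float(det[2])


def midpoint_distance_pct(pred, truth) -> float:
    """100 x |midpoint difference| / ground-truth duration."""
    p0, p1 = _interval(pred)
    t0, t1 = _interval(truth)
    length = t1 - t0
    if length <= 0:
        raise ValueError("ground-truth segment must have positive length")
    return 100.0 * abs((p0 + p1) / 2 - (t0 + t1) / 2) / length


@dataclass
class MatchResult:
    """Score-ordered TP/FP labels of one scene plus the matched pairs."""

    scores: np.ndarray          # descending
    tp: np.ndarray              # bool, aligned with scores
    n_truths: int
    pairs: list[tuple[tuple[float, float], tuple[float, float]]] = field(default_factory=list)

    @property
    def n_tp(self) -> int:
        return int(self.tp.sum())


def match_at_threshold(predictions: Sequence, truths: Sequence,
                       threshold_pct: float) -> MatchResult:
    """Greedy one-to-one matching by midpoint distance, in score order.

    Each prediction (best score first) is paired with the nearest still
    unmatched truth; the pair is a true positive iff the relative midpoint
    distance is strictly below the threshold.  Predictions that find no
    truth below the threshold are false positives; unmatched truths are
    false negatives.
    """
    order = np.argsort([-_score(p) for p in predictions], kind="stable")
    truth_iv = [_interval(t) for t in truths]
    taken = np.zeros(len(truth_iv), dtype=bool)
    scores = np.array([_score(predictions[i]) for i in order], dtype=float)
    tp = np.zeros(len(order), dtype=bool)
    pairs = []
    for rank, i in enumerate(order):
        pred_iv = _interval(predictions[i])
        best_j, best_d = -1, np.inf
        for j, tiv in enumerate(truth_iv):
            if taken[j]:
                continue
            d = midpoint_distance_pct(pred_iv, tiv)
            if d < best_d:
                best_j, best_d = j, d
        if best_j >= 0 and best_d < threshold_pct:
            taken[best_j] = True
            tp[rank] = True
            pairs.append((pred_iv, truth_iv[best_j]))
    return MatchResult(scores=scores, tp=tp, n_truths=len(truth_iv), pairs=pairs)


def _match_at_iou(predictions: Sequence, truths: Sequence, iou_threshold: float) -> MatchResult:
    from .matching import overlap_1d

    order = np.argsort([-_score(p) for p in predictions], kind="stable")
    truth_iv = [_interval(t) for t in truths]
    taken = np.zeros(len(truth_iv), dtype=bool)
    scores = np.array([_score(predictions[i]) for i in order], dtype=float)
    tp = np.zeros(len(order), dtype=bool)
    for rank, i in enumerate(order):
        pred_iv = _interval(predictions[i])
        if pred_iv[1] <= pred_iv[0]:
            continue
        best_j, best_iou = -1, 0.0
        for j, tiv in enumerate(truth_iv):
            if taken[j]:
                continue
            iou, _ = overlap_1d(pred_iv, tiv)
            if iou > best_iou:
                best_j, best_iou = j, iou
        if best_j >= 0 and best_iou >= iou_threshold:
            taken[best_j] = True
            tp[rank] = True
    return MatchResult(scores=scores, tp=tp, n_truths=len(truth_iv))


def _is_interval_like(x) -> bool:
    if hasattr(x, "start_ms") or hasattr(x, "segment"):
        return True
    try:
        return np.isscalar(x[0]) or isinstance(x[0], (int, float, np.floating))
    except (TypeError, IndexError):
        return False


def _is_scene_list(truths) -> bool:
    return bool(truths) and isinstance(truths[0], (list, tuple)) \
        and not _is_interval_like(truths[0])


def _as_scenes(predictions, truths) -> tuple[list, list]:
    """Accept either one scene or parallel lists of scenes; drop truth-free scenes."""
    if _is_scene_list(truths) or (not truths and predictions
                                  and isinstance(predictions[0], (list, tuple))
                                  and not _is_interval_like(predictions[0])):
        pred_scenes, truth_scenes = list(predictions), list(truths)
    else:
        pred_scenes, truth_scenes = [list(predictions)], [list(truths)]
    if len(pred_scenes) != len(truth_scenes):
        raise ValueError("predictions and truths must have the same number of scenes")
    keep = [(p, t) for p, t in zip(pred_scenes, truth_scenes) if len(t) > 0]
    return [p for p, _ in keep], [t for _, t in keep]


def _ap_from_matches(matches: list[MatchResult]) -> float:
    n_truths = sum(m.n_truths for m in matches)
    if n_truths == 0:
        raise ValueError("average precision is undefined without ground truths")
    scores = np.concatenate([m.scores for m in matches]) if matches else np.array([])
    tp = np.concatenate([m.tp for m in matches]) if matches else np.array([], bool)
    if scores.size == 0:
        return 0.0
    order = np.argsort(-scores, kind="stable")
    tp = tp[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(~tp)
    recall = cum_tp / n_truths
    precision = cum_tp / (cum_tp + cum_fp)
    # all-point interpolation: running maximum of precision from the right
    precision = np.maximum.accumulate(precision[::-1])[::-1]
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def average_precision(predictions, truths, threshold_pct: float) -> float:
    """AP (area under the all-point interpolated PR curve) at one threshold."""
    pred_scenes, truth_scenes = _as_scenes(predictions, truths)
    matches = [match_at_threshold(p, t, threshold_pct)
               for p, t in zip(pred_scenes, truth_scenes)]
    return _ap_from_matches(matches)


def adapted_map(predictions, truths,
                thresholds_pct: Sequence[float] = ADAPTED_THRESHOLDS_PCT) -> float:
    """Mean AP over the relative-midpoint-distance threshold sweep."""
    return float(np.mean([average_precision(predictions, truths, t)
                          for t in thresholds_pct]))


def standard_map_1d(predictions, truths,
                    iou_thresholds: Sequence[float] = STANDARD_IOU_THRESHOLDS) -> float:
    """COCO-style mAP with a 1D-IoU true-positive criterion."""
    pred_scenes, truth_scenes = _as_scenes(predictions, truths)
    aps = []
    for thr in iou_thresholds:
        matches = [_match_at_iou(p, t, thr) for p, t in zip(pred_scenes, truth_scenes)]
        aps.append(_ap_from_matches(matches))
    return float(np.mean(aps))


def coverage(predictions, truths,
             threshold_pct: float = DEFAULT_COVERAGE_THRESHOLD_PCT) -> float:
    """Fraction of ground-truth pulses recovered as true positives."""
    pred_scenes, truth_scenes = _as_scenes(predictions, truths)
    matches = [match_at_threshold(p, t, threshold_pct)
               for p, t in zip(pred_scenes, truth_scenes)]
    n_truths = sum(m.n_truths for m in matches)
    if n_truths == 0:
        raise ValueError("coverage is undefined without ground truths")
    return sum(m.n_tp for m in matches) / n_truths


@dataclass
class ErrorStats:
    duration_rel_error_mean: float
    duration_rel_error_std: float
    start_error_ms_mean: float
    start_error_ms_std: float
    end_error_ms_mean: float
    end_error_ms_std: float
    n_pairs: int


def error_metrics(pairs: Sequence[tuple]) -> ErrorStats:
    """Duration / boundary errors over matched (prediction, truth) pairs.

    Per pair: |predicted - true duration| / true duration, and the absolute
    start and end differences in ms.  False positives and negatives carry no
    error and are excluded by construction.
    """
    if not pairs:
        raise ValueError("error metrics need at least one matched pair")
    dur_err, start_err, end_err = [], [], []
    for pred, truth in pairs:
        p0, p1 = _interval(pred)
        t0, t1 = _interval(truth)
        dur_err.append(abs((p1 - p0) - (t1 - t0)) / (t1 - t0))
        start_err.append(abs(p0 - t0))
        end_err.append(abs(p1 - t1))
    return ErrorStats(
        duration_rel_error_mean=float(np.mean(dur_err)),
        duration_rel_error_std=float(np.std(dur_err)),
        start_error_ms_mean=float(np.mean(start_err)),
        start_error_ms_std=float(np.std(start_err)),
        end_error_ms_mean=float(np.mean(end_err)),
        end_error_ms_std=float(np.std(end_err)),
        n_pairs=len(pairs),
    )


@dataclass
class EvalReport:
    """Summary of a full evaluation, with optional per-group breakdowns."""

    adapted_map: float
    coverage: float
    errors: ErrorStats | None
    standard_map: float | None = None
    coverage_threshold_pct: float = DEFAULT_COVERAGE_THRESHOLD_PCT
    thresholds_pct: tuple[float, ...] = ADAPTED_THRESHOLDS_PCT
    by_group: dict[str, "EvalReport"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "adapted_map": self.adapted_map,
            "coverage": self.coverage,
            "coverage_threshold_pct": self.coverage_threshold_pct,
            "n_thresholds": len(self.thresholds_pct),
            "standard_map": self.standard_map,
        }
        if self.errors is not None:
            out["duration_rel_error_mean"] = self.errors.duration_rel_error_mean
            out["duration_rel_error_std"] = self.errors.duration_rel_error_std
            out["start_error_ms_mean"] = self.errors.start_error_ms_mean
            out["end_error_ms_mean"] = self.errors.end_error_ms_mean
            out["n_matched_pairs"] = self.errors.n_pairs
        if self.by_group:
            out["by_group"] = {k: v.to_dict() for k, v in self.by_group.items()}
        return out


def evaluate(predictions, truths, group_labels: Sequence | None = None,
             coverage_threshold_pct: float = DEFAULT_COVERAGE_THRESHOLD_PCT,
             with_standard_map: bool = True) -> EvalReport:
    """Full report over scenes, optionally broken down by a per-scene label
    (e.g. the set pulse duration or the SNR of the source dataset)."""
    pred_scenes, truth_scenes = _as_scenes(predictions, truths)

    def build(preds, trs) -> EvalReport:
        matches = [match_at_threshold(p, t, coverage_threshold_pct)
                   for p, t in zip(preds, trs)]
        pairs = [pair for m in matches for pair in m.pairs]
        return EvalReport(
            adapted_map=adapted_map(preds, trs),
            coverage=coverage(preds, trs, coverage_threshold_pct),
            errors=error_metrics(pairs) if pairs else None,
            standard_map=standard_map_1d(preds, trs) if with_standard_map else None,
            coverage_threshold_pct=coverage_threshold_pct,
        )

    report = build(pred_scenes, truth_scenes)
    if group_labels is not None:
        # labels parallel the *original* scene list; re-filter per group
        if _is_scene_list(truths):
            all_preds, all_truths = list(predictions), list(truths)
        else:
            all_preds, all_truths = [list(predictions)], [list(truths)]
        if len(group_labels) != len(all_preds):
            raise ValueError("one group label per scene required")
        for label in sorted(set(group_labels), key=str):
            idx = [i for i, g in enumerate(group_labels) if g == label]
            preds = [all_preds[i] for i in idx]
            trs = [all_truths[i] for i in idx]
            preds, trs = _as_scenes(preds, trs)
            if trs:
                report.by_group[str(label)] = build(preds, trs)
    return report
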