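"""Bipartite matching between predicted and true segments, and the set loss.

Training treats detection as direct set prediction: the network emits a
fixed-size set of N candidate segments, an optimal one-to-one assignment to
the ground-truth pulses is found by the Hungarian algorithm on a pairwise
cost (class confidence, L1 distance in normalised center/width coordinates,
and a generalised-IoU term), and the training loss is computed over the
matched pairs plus a down-weighted "no pulse" classification term for the
unmatched candidates.

The matching itself is combinatorial and gradient-free (costs are evaluated
on detached values); only the loss is differentiated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import nn

# class-index convention for the 2-way classifier head
PULSE_CLASS = 0
NO_PULSE_CLASS = 1


@dataclass(frozen=True)
class MatchCostWeights:
    """Loss/cost coefficients (detection-transformer convention)."""

    class_weight: float = 1.0
    l1_weight: float = 5.0
    overlap_weight: float = 2.0
    no_object_downweight: float = 0.1

    def __post_init__(self):
        if min(self.class_weight, self.l1_weight, self.overlap_weight,
               self.no_object_downweight) < 0:
            raise ValueError("cost weights must be >= 0")


@dataclass(frozen=True)
class Assignment:
    """One-to-one pairing (prediction index, truth index) with its total cost."""

    pairs: tuple[tuple[int, int], ...]
    total_cost: float


def _to_interval(seg) -> tuple[float, float]:
    if hasattr(seg, "start_ms"):
        return float(seg.start_ms), float(seg.end_ms)
    start, end = seg
    return float(start), float(end)


def overlap_1d(a, b) -> tuple[float, float]:
    """(IoU, gIoU) of two intervals; gIoU penalises the empty hull gap."""
    a0, a1 = _to_interval(a)
    b0, b1 = _to_interval(b)
    if a1 <= a0 or b1 <= b0:
        raise ValueError("segments must have positive length")
    inter = max(0.0, min(a1, b1) - max(a0, b0))
    union = (a1 - a0) + (b1 - b0) - inter
    hull = max(a1, b1) - min(a0, b0)
    iou = inter / union
    giou = iou - (hull - union) / hull
    return iou, giou


def cw_to_se(cw: np.ndarray) -> np.ndarray:
    """(center, width) rows -> (start, end) rows."""
    cw = np.asarray(cw, dtype=np.float64).reshape(-1, 2)
    return np.stack([cw[:, 0] - cw[:, 1] / 2, cw[:, 0] + cw[:, 1] / 2], axis=1)


def pairwise_iou_giou(pred_se: np.ndarray, truth_se: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised (N, M) IoU and gIoU matrices of (start, end) rows."""
    p0, p1 = pred_se[:, 0, None], pred_se[:, 1, None]
    t0, t1 = truth_se[None, :, 0], truth_se[None, :, 1]
    inter = np.clip(np.minimum(p1, t1) - np.maximum(p0, t0), 0.0, None)
    union = (p1 - p0) + (t1 - t0) - inter
    hull = np.maximum(p1, t1) - np.minimum(p0, t0)
    iou = inter / union
    giou = iou - (hull - union) / hull
    return iou, giou


def cost_matrix(pulse_probs: np.ndarray, pred_cw: np.ndarray, truth_cw: np.ndarray,
                weights: MatchCostWeights) -> np.ndarray:
    """Pairwise matching cost: -p(pulse) + L1 on (c, w) + (1 - gIoU)."""
    pred_cw = np.asarray(pred_cw, dtype=np.float64).reshape(-1, 2)
    truth_cw = np.asarray(truth_cw, dtype=np.float64).reshape(-1, 2)
    l1 = np.abs(pred_cw[:, None, :] - truth_cw[None, :, :]).sum(axis=2)
    _, giou = pairwise_iou_giou(cw_to_se(pred_cw), cw_to_se(truth_cw))
    return (weights.class_weight * (-np.asarray(pulse_probs)[:, None])
            + weights.l1_weight * l1
            + weights.overlap_weight * (1.0 - giou))


def match_hungarian(pulse_probs: np.ndarray, pred_cw: np.ndarray, truth_cw: np.ndarray,
                    weights: MatchCostWeights | None = None) -> Assignment:
    """Optimal one-to-one assignment of predictions to ground truths."""
    weights = weights or MatchCostWeights()
    truth_cw = np.asarray(truth_cw, dtype=np.float64).reshape(-1, 2)
    n_pred = np.asarray(pred_cw).reshape(-1, 2).shape[0]
    if truth_cw.shape[0] > n_pred:
        raise ValueError(f"{truth_cw.shape[0]} truths exceed {n_pred} predictions")
    if truth_cw.shape[0] == 0:
        return Assignment(pairs=(), total_cost=0.0)
    costs = cost_matrix(pulse_probs, pred_cw, truth_cw, weights)
    rows, cols = linear_sum_assignment(costs)
    order = np.argsort(cols)
    pairs = tuple((int(rows[i]), int(cols[i])) for i in order)
    return Assignment(pairs=pairs, total_cost=float(costs[rows, cols].sum()))


# ---------------------------------------------------------------------------
# differentiable loss
# ---------------------------------------------------------------------------

def _giou_tensor(pred_cw: nn.Tensor, truth_se: np.ndarray) -> nn.Tensor:
    """gIoU of matched (center, width) tensor rows vs fixed truth intervals."""
    c = pred_cw[:, 0]
    w = pred_cw[:, 1]
    p0 = c - w * 0.5
    p1 = c + w * 0.5
    t0 = nn.Tensor(truth_se[:, 0])
    t1 = nn.Tensor(truth_se[:, 1])
    inter = nn.relu(nn.minimum(p1, t1) - nn.maximum(p0, t0))
    union = (p1 - p0) + nn.Tensor(truth_se[:, 1] - truth_se[:, 0]) - inter
    hull = nn.maximum(p1, t1) - nn.minimum(p0, t0)
    iou = nn.div(inter, union)
    return iou - nn.div(hull - union, hull)


def hungarian_loss(class_logits: nn.Tensor, pred_cw: nn.Tensor, truth_cw: np.ndarray,
                   assignment: Assignment, weights: MatchCostWeights | None = None,
                   ) -> tuple[nn.Tensor, dict[str, float]]:
    """Set-prediction loss for one window.

    Cross-entropy over all N candidates (matched -> pulse, rest -> no-pulse
    with the no-object down-weight) plus L1 and (1 - gIoU) terms over the
    matched pairs, normalised by the number of ground truths.  Returns the
    scalar loss tensor and detached per-component values for logging.
    """
    weights = weights or MatchCostWeights()
    truth_cw = np.asarray(truth_cw, dtype=np.float64).reshape(-1, 2)
    n_pred = class_logits.shape[0]
    n_truth = truth_cw.shape[0]
    if n_truth == 0:
        raise ValueError("training windows must contain at least one pulse")

    targets = np.full(n_pred, NO_PULSE_CLASS, dtype=int)
    pred_idx = np.array([p for p, _ in assignment.pairs], dtype=int)
    truth_idx = np.array([t for _, t in assignment.pairs], dtype=int)
    targets[pred_idx] = PULSE_CLASS
    class_w = np.where(targets == PULSE_CLASS, 1.0, weights.no_object_downweight)

    logp = nn.log_softmax(class_logits, axis=-1)
    picked = logp[np.arange(n_pred), targets]
    ce = nn.mul(nn.sum_(nn.mul(picked, -class_w)), 1.0 / class_w.sum())

    matched_cw = pred_cw[pred_idx]
    matched_truth = truth_cw[truth_idx]
    l1 = nn.mul(nn.sum_(nn.abs_(matched_cw - nn.Tensor(matched_truth))), 1.0 / n_truth)
    giou = _giou_tensor(matched_cw, cw_to_se(matched_truth))
    giou_loss = nn.mul(nn.sum_(1.0 - giou), 1.0 / n_truth)

    total = (weights.class_weight * ce
             + weights.l1_weight * l1
             + weights.overlap_weight * giou_loss)
    parts = {"ce": float(ce.data), "l1": float(l1.data),
             "giou": float(giou_loss.data)}
    return total, parts
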