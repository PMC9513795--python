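"""Training loops for the detector and the pulse counter.

The detector is trained on non-empty standardised windows with the
Hungarian set-prediction loss, Adam with decoupled weight decay, a step
learning-rate schedule (divide by `lr_decay_factor` every
`decay_period_epochs`), and a smaller constant multiplier on the backbone
parameters.  Validation runs on a schedule (epoch 50, epoch 100, then
every 5) using the standard 1D-IoU mAP; the checkpoint with the highest
validation mAP is kept.  The adapted mAP is reserved for testing.

The counter is trained separately (its own optimiser, squared-error
regression on per-window counts, empty windows included); it takes no part
in detector training or validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import matching, metrics, nn
from .dataset import Window, filter_nonempty, standardize
from .model import ModelConfig, PulseCounter, PulseDetector

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-5
    lr_decay_factor: float = 10.0
    decay_period_epochs: int = 100
    backbone_lr_multiplier: float = 0.1
    batch_size: int = 6
    val_first_epoch: int = 50
    val_second_epoch: int = 100
    val_every: int = 5
    max_epochs: int = 300
    weight_decay: float = 1e-4
    loss_weights: matching.MatchCostWeights = field(default_factory=matching.MatchCostWeights)
    pretrain_epochs: int = 0
    pretrain_lr: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        for name in ("learning_rate", "lr_decay_factor", "decay_period_epochs",
                     "backbone_lr_multiplier", "batch_size", "val_first_epoch",
                     "val_second_epoch", "val_every", "max_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Step decay: lr / factor^(epoch // period)."""
    return config.learning_rate / config.lr_decay_factor ** (epoch // config.decay_period_epochs)


def validation_epochs(config: TrainConfig, max_epochs: int | None = None) -> list[int]:
    """Epochs after which validation runs: 50, 100, 105, 110, ... plus the
    final epoch (so a checkpoint is always selected on short runs)."""
    last = max_epochs if max_epochs is not None else config.max_epochs
    epochs = set()
    if config.val_first_epoch <= last:
        epochs.add(config.val_first_epoch)
    e = config.val_second_epoch
    while e <= last:
        epochs.add(e)
        e += config.val_every
    epochs.add(last)
    return sorted(epochs)


@dataclass
class LogRow:
    epoch: int
    lr: float
    loss: float
    loss_ce: float
    loss_l1: float
    loss_giou: float
    val_map: float | None = None


def _standardized(windows: list[Window]) -> list[Window]:
    return [w if w.scale != 1.0 or w.offset != 0.0 else standardize(w)
            for w in windows]


def window_predictions(model: PulseDetector, windows: list[Window],
                       class_threshold: float | None = None):
    """Per-window detections and ground truths (absolute ms), counter bypassed."""
    preds, truths = [], []
    for w in windows:
        preds.append(model.predict_window(w, class_threshold))
        truths.append(w.targets_ms())
    return preds, truths


def validate(model: PulseDetector, windows: list[Window], metric: str = "standard",
             class_threshold: float | None = None) -> float:
    """mAP of the ungated detector over the non-empty windows.

    `metric` selects the standard 1D-IoU mAP (validation) or the adapted
    midpoint-distance mAP (testing).
    """
    windows = _standardized(filter_nonempty(windows))
    if not windows:
        raise ValueError("validation requires non-empty windows")
    preds, truths = window_predictions(model, windows, class_threshold)
    if metric == "standard":
        return metrics.standard_map_1d(preds, truths)
    if metric == "adapted":
        return metrics.adapted_map(preds, truths)
    raise ValueError(f"unknown metric {metric!r}")


def pretrain_backbone(model: PulseDetector, windows: list[Window],
                      epochs: int, lr: float = 1e-3, batch_size: int = 6,
                      seed: int = 0) -> list[float]:
    """Warm up the backbone with a pooled regression pretext task.

    A throwaway linear head regresses per-window summary features (pulse
    count and mean normalised pulse width) from globally pooled backbone
    features, mirroring how the feature-prediction path of a two-branch
    counting/feature network is pre-trained before reuse as a detection
    backbone.  The head is discarded; only backbone weights remain.
    """
    windows = _standardized(windows)
    rng = np.random.default_rng(seed + 17)
    head = nn.Linear(model.backbone.out_channels, 2, rng=rng)
    optimizer = nn.Adam([{"params": model.backbone_parameters() + head.parameters()}],
                        lr=lr)
    samples = np.stack([w.samples for w in windows])[:, None, :]
    # targets scaled to O(1): count / 4 and mean width x 50
    raw_targets = np.stack([
        [w.targets.shape[0] / 4.0,
         50.0 * (w.targets[:, 1].mean() if w.targets.size else 0.0)]
        for w in windows])
    losses = []
    for _epoch in range(epochs):
        order = rng.permutation(len(windows))
        total, n_batches = 0.0, 0
        for lo in range(0, len(order), batch_size):
            idx = order[lo:lo + batch_size]
            feats = model.backbone(nn.Tensor(samples[idx]))
            pred = head(nn.mean(feats, axis=2))
            err = nn.sub(pred, nn.Tensor(raw_targets[idx]))
            loss = nn.mean(nn.mul(err, err))
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            total += float(loss.data)
            n_batches += 1
        losses.append(total / n_batches)
    return losses


def train_detector(train_windows: list[Window], val_windows: list[Window] | None = None,
                   model_config: ModelConfig | None = None,
                   train_config: TrainConfig | None = None,
                   ) -> tuple[PulseDetector, list[LogRow]]:
    """Train the detector; returns the best-validation-mAP model and the log."""
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    windows = _standardized(filter_nonempty(train_windows))
    if not windows:
        raise ValueError("no non-empty training windows")
    max_truths = max(w.targets.shape[0] for w in windows)
    if model_config.n_queries < max_truths:
        raise ValueError(f"n_queries={model_config.n_queries} below the densest "
                         f"window ({max_truths} pulses)")
    lengths = {w.samples.size for w in windows}
    if len(lengths) != 1:
        raise ValueError("all training windows must share one length")

    model = PulseDetector(replace(model_config, init_seed=train_config.seed))
    if train_config.pretrain_epochs > 0:
        pretrain_backbone(model, windows, train_config.pretrain_epochs,
                          train_config.pretrain_lr, train_config.batch_size,
                          train_config.seed)
    backbone_ids = {id(p) for p in model.backbone_parameters()}
    head_params = [p for p in model.parameters() if id(p) not in backbone_ids]
    optimizer = nn.Adam(
        [{"params": head_params},
         {"params": model.backbone_parameters(),
          "lr_scale": train_config.backbone_lr_multiplier}],
        lr=train_config.learning_rate,
        weight_decay=train_config.weight_decay)

    rng = np.random.default_rng(train_config.seed)
    samples = np.stack([w.samples for w in windows])[:, None, :]
    targets = [w.targets for w in windows]
    val_schedule = set(validation_epochs(train_config, train_config.max_epochs))
    best_map, best_state = -1.0, None
    log: list[LogRow] = []

    for epoch in range(train_config.max_epochs):
        optimizer.lr = lr_at_epoch(train_config, epoch)
        order = rng.permutation(len(windows))
        totals = np.zeros(4)
        n_batches = 0
        for lo in range(0, len(order), train_config.batch_size):
            idx = order[lo:lo + train_config.batch_size]
            x = nn.Tensor(samples[idx])
            logits, segments = model(x)
            probs = 1.0 / (1.0 + np.exp(-(logits.data[..., 0] - logits.data[..., 1])))
            batch_loss = None
            parts_sum = np.zeros(3)
            for b, wi in enumerate(idx):
                assign = matching.match_hungarian(
                    probs[b], segments.data[b], targets[wi],
                    train_config.loss_weights)
                loss_b, parts = matching.hungarian_loss(
                    logits[b], segments[b], targets[wi], assign,
                    train_config.loss_weights)
                parts_sum += [parts["ce"], parts["l1"], parts["giou"]]
                batch_loss = loss_b if batch_loss is None else nn.add(batch_loss, loss_b)
            batch_loss = nn.mul(batch_loss, 1.0 / len(idx))
            optimizer.zero_grad()
            batch_loss.backward()
            optimizer.step()
            totals += [float(batch_loss.data), *(parts_sum / len(idx))]
            n_batches += 1
        row = LogRow(epoch=epoch + 1, lr=optimizer.lr,
                     loss=totals[0] / n_batches, loss_ce=totals[1] / n_batches,
                     loss_l1=totals[2] / n_batches, loss_giou=totals[3] / n_batches)
        if (epoch + 1) in val_schedule and val_windows:
            row.val_map = validate(model, val_windows, metric="standard")
            # ties go to the later epoch (more training at equal validation)
            if row.val_map >= best_map:
                best_map = row.val_map
                best_state = model.state_dict()
            logger.info("epoch %d loss %.4f val mAP %.3f", row.epoch, row.loss, row.val_map)
        log.append(row)
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, log


def train_counter(windows: list[Window], train_config: TrainConfig | None = None,
                  base_width: int = 16, blocks: tuple[int, ...] = (1, 1, 1, 1),
                  ) -> PulseCounter:
    """Train the pulse counter by squared-error count regression.

    Unlike the detector, empty windows are part of the training set - the
    counter's whole job is telling empty windows apart from occupied ones.
    """
    train_config = train_config or TrainConfig()
    if not windows:
        raise ValueError("no training windows")
    windows = _standardized(windows)
    counter = PulseCounter(base_width=base_width, blocks=blocks,
                           init_seed=train_config.seed)
    optimizer = nn.Adam([{"params": counter.parameters()}],
                        lr=train_config.learning_rate,
                        weight_decay=train_config.weight_decay)
    rng = np.random.default_rng(train_config.seed + 1)
    samples = np.stack([w.samples for w in windows])[:, None, :]
    counts = np.array([w.targets.shape[0] for w in windows], dtype=float)
    for epoch in range(train_config.max_epochs):
        optimizer.lr = lr_at_epoch(train_config, epoch)
        order = rng.permutation(len(windows))
        for lo in range(0, len(order), train_config.batch_size):
            idx = order[lo:lo + train_config.batch_size]
            pred = counter(nn.Tensor(samples[idx]))
            err = nn.sub(nn.reshape(pred, (len(idx),)), nn.Tensor(counts[idx]))
            loss = nn.mean(nn.mul(err, err))
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
    counter.trained = True
    return counter


def counter_accuracy(counter: PulseCounter, windows: list[Window]) -> float:
    """Fraction of windows whose rounded predicted count is exact."""
    windows = _standardized(windows)
    hits = [counter.count(w) == w.targets.shape[0] for w in windows]
    return float(np.mean(hits))


def log_to_tsv(log: list[LogRow], path) -> None:
    with open(path, "w") as f:
        f.write("epoch\tlr\tloss\tloss_ce\tloss_l1\tloss_giou\tval_map\n")
        for row in log:
            val = "" if row.val_map is None else f"{row.val_map:.6f}"
            f.write(f"{row.epoch}\t{row.lr:.3e}\t{row.loss:.6f}\t{row.loss_ce:.6f}"
                    f"\t{row.loss_l1:.6f}\t{row.loss_giou:.6f}\t{val}\n")
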