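"""Training, evaluation and repeated-experiment protocol for the network.

Training minimises per-pixel cross-entropy with Adam under a
piecewise-constant learning-rate schedule (initial rate multiplied by the
drop factor after each completed drop period), shuffling the sample order
every epoch.  Everything is seeded: the same data, configuration and seed
reproduce the loss history and the trained weights bit for bit on CPU.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .metrics import MaskPair, aggregate, confusion, per_class_metrics
from .model import PeMNet, PeMNetConfig, TrainConfig, build_model, predict_mask
from .nn import softmax_cross_entropy
from .nn.optim import Adam, piecewise_constant_lr
from .phantom import LabeledImage

__all__ = ["train", "evaluate_model", "repeat_experiment", "RepeatResult",
           "to_arrays"]


def to_arrays(dataset):
    """Stack a dataset into (X, y): float32 (N,1,H,W) on the 8-bit scale and
    integer masks (N,H,W).  Accepts LabeledImage items or (image, mask) pairs."""
    if not dataset:
        raise ValueError("dataset is empty")
    imgs, masks = [], []
    for item in dataset:
        if isinstance(item, LabeledImage):
            img, mask = item.image, item.pectoral_mask
        else:
            img, mask = item
        img = np.asarray(img)
        mask = np.asarray(mask)
        if img.shape != mask.shape:
            raise ValueError(f"image {img.shape} and mask {mask.shape} disagree")
        if not np.isin(mask, (0, 1)).all():
            raise ValueError("masks must be {0,1}-valued")
        imgs.append(img.astype(np.float32))
        masks.append(mask.astype(np.int64))
    return np.stack(imgs)[:, None], np.stack(masks)


def train(model: PeMNet, dataset, tc: TrainConfig | None = None):
    """Train in place; returns a history of per-epoch mean loss and lr."""
    tc = tc or TrainConfig()
    x, y = to_arrays(dataset)
    n = x.shape[0]
    rng = np.random.default_rng(tc.seed)
    opt = Adam(model.parameters(), lr=tc.initial_lr)
    weights = None if tc.class_weights is None else np.asarray(tc.class_weights, np.float32)
    history = []
    for epoch in range(1, tc.max_epochs + 1):
        opt.lr = piecewise_constant_lr(tc.initial_lr, tc.lr_drop_factor,
                                       tc.lr_drop_period, epoch)
        order = rng.permutation(n) if tc.shuffle_per_epoch else np.arange(n)
        losses = []
        for start in range(0, n, tc.minibatch_size):
            idx = order[start:start + tc.minibatch_size]
            opt.zero_grad()
            logits = model.forward(x[idx])
            loss = softmax_cross_entropy(logits, y[idx], class_weights=weights)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append({"epoch": epoch, "lr": opt.lr,
                        "loss": float(np.mean(losses))})
    return history


def evaluate_model(model: PeMNet, dataset):
    """Per-image MetricSets (with confusion counts) on a held-out set."""
    results = []
    for item in dataset:
        img = item.image if isinstance(item, LabeledImage) else item[0]
        truth = item.pectoral_mask if isinstance(item, LabeledImage) else item[1]
        pred = predict_mask(model, img)
        c = confusion(MaskPair(truth, pred))
        results.append((per_class_metrics(c), c))
    return results


@dataclass
class RepeatResult:
    runs: list            # per run: list of MetricSet
    seeds: list
    histories: list
    report: "object"      # AggregateReport over runs


def repeat_experiment(cfg: PeMNetConfig, tc: TrainConfig, k: int,
                      train_set, eval_set, base_seed: int = 0) -> RepeatResult:
    """k independently seeded train+eval cycles, aggregated mean +/- std."""
    if k < 1:
        raise ValueError("k must be >= 1")
    seeds = [int(s) for s in np.random.default_rng(base_seed).integers(2 ** 31, size=k)]
    runs, histories = [], []
    for seed in seeds:
        model = build_model(cfg, seed=seed)
        hist = train(model, train_set, dataclasses.replace(tc, seed=seed))
        per_image = [ms for ms, _ in evaluate_model(model, eval_set)]
        runs.append(per_image)
        histories.append(hist)
    return RepeatResult(runs=runs, seeds=seeds, histories=histories,
                        report=aggregate(None, per_run=runs))
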