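"""MLO / CC view classification.

A compact convolutional classifier trained from scratch on resized breast
crops.  The two mammographic projections differ structurally - only the
MLO view carries the bright pectoral wedge in the top corner - so a small
three-block CNN with global average pooling separates them reliably.
Inference is deterministic; training is fully seeded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .nn import Tensor, softmax_cross_entropy
from .nn.layers import Conv2d, Linear, Module
from .nn.optim import Adam

__all__ = ["ViewClassifier", "ViewTrainConfig", "train_view_classifier",
           "classify_view"]

CLASSES = ("CC", "MLO")   # class index order


@dataclass(frozen=True)
class ViewTrainConfig:
    input_size: int = 64
    epochs: int = 30
    minibatch_size: int = 32
    lr: float = 3e-3
    seed: int = 0


class ViewClassifier(Module):
    """Three conv blocks, global average pooling, linear head."""

    def __init__(self, input_size: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.input_size = input_size
        self.conv1 = Conv2d(1, 8, 3, stride=2, padding=1, rng=rng)
        self.conv2 = Conv2d(8, 16, 3, stride=2, padding=1, rng=rng)
        self.conv3 = Conv2d(16, 32, 3, stride=2, padding=1, rng=rng)
        self.fc = Linear(32, len(CLASSES), rng=rng)

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        h = self.conv1(x).relu()
        h = self.conv2(h).relu()
        h = self.conv3(h).relu()
        return self.fc(h.mean(axis=(2, 3)))


def _prepare(images, size: int) -> np.ndarray:
    out = np.empty((len(images), 1, size, size), dtype=np.float32)
    for i, img in enumerate(images):
        arr = np.asarray(img, dtype=np.float64)
        if arr.shape != (size, size):
            arr = resize(arr, (size, size), anti_aliasing=True, preserve_range=True)
        out[i, 0] = arr / 255.0
    return out


def train_view_classifier(train_data, config: ViewTrainConfig | None = None) -> ViewClassifier:
    """Train on (image, label) pairs with labels in {'MLO', 'CC'}."""
    config = config or ViewTrainConfig()
    images = [img for img, _ in train_data]
    labels = [lab for _, lab in train_data]
    bad = sorted(set(labels) - set(CLASSES))
    if bad:
        raise ValueError(f"unknown view labels {bad}; expected {CLASSES}")
    if len(set(labels)) < 2:
        raise ValueError("training data must contain both MLO and CC examples")
    x = _prepare(images, config.input_size)
    y = np.array([CLASSES.index(lab) for lab in labels], dtype=np.int64)
    clf = ViewClassifier(config.input_size, seed=config.seed)
    rng = np.random.default_rng(config.seed)
    opt = Adam(clf.parameters(), lr=config.lr)
    for _ in range(config.epochs):
        order = rng.permutation(len(y))
        for start in range(0, len(y), config.minibatch_size):
            idx = order[start:start + config.minibatch_size]
            opt.zero_grad()
            loss = softmax_cross_entropy(clf.forward(x[idx]), y[idx])
            loss.backward()
            opt.step()
    return clf


def classify_view(clf: ViewClassifier, image) -> str:
    """Argmax class of one image; ties resolve to the first class."""
    logits = clf.forward(_prepare([image], clf.input_size)).data[0]
    return CLASSES[int(logits.argmax())]
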