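"""Binary stenosis screening CNN on video frames.

Architecture: four convolution blocks (3×3 kernels, ReLU, filters
32→64→128→256, each followed by 2×2 max pooling), a flatten, a dense
layer of 512 ReLU units, and a 2-unit softmax head.  Training uses the
Adam optimizer on categorical cross-entropy, mini-batches of 100
frames, at most ten epochs, with early stopping that monitors the test
loss and restores the best weights.

The network is implemented directly on NumPy (im2col convolutions,
explicit backward passes).  That keeps the dependency surface small and
the whole training loop single-threaded and reproducible; it is sized
for frame classification at modest input resolutions (64–128 px), not
for GPU-scale workloads.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize

from .augment import HAS_STENOSIS, NO_STENOSIS, LabelledImageSet
from .errors import ValidationError, VideoIOError
from .video_io import extract_frames

#: Class order fixed across the package: index 0 is the positive class.
CLASS_NAMES: tuple[str, str] = (HAS_STENOSIS, NO_STENOSIS)


@dataclass(frozen=True)
class CNNSpec:
    conv_filters: tuple[int, ...] = (32, 64, 128, 256)
    kernel: int = 3
    dense_units: int = 512
    n_classes: int = 2
    input_size: int = 128
    batch_size: int = 100
    max_epochs: int = 10
    learning_rate: float = 1e-3
    patience: int = 3
    min_delta: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.conv_filters) != sorted(self.conv_filters) or len(
            set(self.conv_filters)
        ) != len(self.conv_filters):
            raise ValidationError("conv_filters must be strictly increasing")
        if self.input_size < 1 or self.batch_size < 1:
            raise ValidationError("input_size and batch_size must be positive")


# ---------------------------------------------------------------- layers


class _Conv:
    """Valid-padding 2-D convolution via im2col.

    The input gradient is assembled as nine shifted GEMMs (one per
    kernel tap) rather than a second im2col, which avoids materializing
    the large padded-window tensor.  The first layer of a network sets
    ``is_input`` and skips the input gradient entirely.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int,
        rng: np.random.Generator,
        is_input: bool = False,
    ):
        scale = np.sqrt(2.0 / (k * k * c_in))  # He initialization
        self.w = (rng.standard_normal((k * k * c_in, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.c_in = c_in
        self.is_input = is_input

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, _ = x.shape
        win = sliding_window_view(x, (self.k, self.k), axis=(1, 2))
        # (n, oh, ow, c, k, k) -> (n, oh, ow, k, k, c) to match weight layout
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            n, h - self.k + 1, w - self.k + 1, -1
        )
        self._x_shape, self._cols_cache = x.shape, cols
        return cols @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray | None:
        n, oh, ow, c_out = grad.shape
        g2 = grad.reshape(-1, c_out)
        self.dw = self._cols_cache.reshape(-1, self.w.shape[0]).T @ g2
        self.db = g2.sum(axis=0)
        self._cols_cache = None
        if self.is_input:
            return None
        k, c_in = self.k, self.c_in
        w4 = self.w.reshape(k, k, c_in, c_out)
        dx = np.zeros(self._x_shape, dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                contrib = (g2 @ w4[ki, kj].T).reshape(n, oh, ow, c_in)
                dx[:, ki : ki + oh, kj : kj + ow, :] += contrib
        return dx

    params = property(lambda self: [self.w, self.b])
    grads = property(lambda self: [self.dw, self.db])


class _MaxPool2:
    """2×2 max pooling, stride 2; odd trailing rows/cols are dropped.

    Gradient routing is first-wins on ties (deterministic raster order).
    """

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        r = x[:, : 2 * h2, : 2 * w2].reshape(n, h2, 2, w2, 2, c)
        out = np.maximum(
            np.maximum(r[:, :, 0, :, 0], r[:, :, 0, :, 1]),
            np.maximum(r[:, :, 1, :, 0], r[:, :, 1, :, 1]),
        )
        self._r, self._out, self._in_shape = r, out, x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h2, w2, c = grad.shape
        dr = np.zeros((n, h2, 2, w2, 2, c), dtype=np.float32)
        assigned = np.zeros(grad.shape, dtype=bool)
        for i in (0, 1):
            for j in (0, 1):
                sel = (self._r[:, :, i, :, j] == self._out) & ~assigned
                assigned |= sel
                dr[:, :, i, :, j][sel] = grad[sel]
        dx = np.zeros(self._in_shape, dtype=np.float32)
        dx[:, : 2 * h2, : 2 * w2] = dr.reshape(n, 2 * h2, 2 * w2, c)
        self._r = self._out = None
        return dx

    params = property(lambda self: [])
    grads = property(lambda self: [])


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask

    params = property(lambda self: [])
    grads = property(lambda self: [])


class _Flatten:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)

    params = property(lambda self: [])
    grads = property(lambda self: [])


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.w.T

    params = property(lambda self: [self.w, self.b])
    grads = property(lambda self: [self.dw, self.db])


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ----------------------------------------------------------------- model


class Model:
    """The stacked network plus its spec; logits in, probabilities out."""

    def __init__(self, layers: list, spec: CNNSpec):
        self.layers = layers
        self.spec = spec

    def _logits(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def predict_proba(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        """Per-sample class probabilities; rows sum to 1."""
        outs = [
            _softmax(self._logits(x[i : i + batch].astype(np.float32)))
            for i in range(0, len(x), batch)
        ]
        return np.concatenate(outs)

    def train_step(self, x: np.ndarray, y: np.ndarray) -> float:
        probs = _softmax(self._logits(x))
        n = len(y)
        loss = -float(np.log(probs[np.arange(n), y] + 1e-12).mean())
        grad = probs
        grad[np.arange(n), y] -= 1.0
        grad /= n
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return loss

    @property
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_params(self) -> int:
        return int(sum(p.size for p in self.parameters))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        for p, w in zip(self.parameters, weights):
            p[...] = w

    def save(self, path: str | Path) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self.parameters)}
        np.savez(path, spec=json.dumps(asdict(self.spec)), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "Model":
        with np.load(path, allow_pickle=False) as data:
            raw = json.loads(str(data["spec"]))
            raw["conv_filters"] = tuple(raw["conv_filters"])
            spec = CNNSpec(**raw)
            model = build_model(spec)
            model.set_weights([data[f"p{i}"] for i in range(len(model.parameters))])
        return model


def build_model(spec: CNNSpec) -> Model:
    """Assemble the network and validate that the input size survives it."""
    rng = np.random.default_rng(spec.seed)
    size, channels = spec.input_size, 3
    layers: list = []
    for f in spec.conv_filters:
        if size < spec.kernel:
            raise ValidationError(
                f"input_size {spec.input_size} is too small for "
                f"{len(spec.conv_filters)} conv/pool stages"
            )
        layers += [
            _Conv(channels, f, spec.kernel, rng, is_input=not layers),
            _ReLU(),
            _MaxPool2(),
        ]
        size = (size - spec.kernel + 1) // 2
        if size < 1:
            raise ValidationError(
                f"input_size {spec.input_size} pools below 1×1 after stage "
                f"with {f} filters"
            )
        channels = f
    layers += [
        _Flatten(),
        _Dense(size * size * channels, spec.dense_units, rng),
        _ReLU(),
        _Dense(spec.dense_units, spec.n_classes, rng),
    ]
    return Model(layers, spec)


# -------------------------------------------------------------- training


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr, self.b1, self.b2, self.eps = lr, 0.9, 0.999, 1e-7
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def encode_labels(labels: Sequence[str]) -> np.ndarray:
    return np.array([CLASS_NAMES.index(l) for l in labels], dtype=np.int64)


def prepare_images(images: LabelledImageSet, input_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Resize to the model input and normalize intensities to [0, 1]."""
    x = np.stack(
        [
            resize(img, (input_size, input_size), preserve_range=True, anti_aliasing=True)
            for img in images.images
        ]
    ).astype(np.float32) / 255.0
    return x, encode_labels(images.labels)


def train(
    model: Model,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    y_test: np.ndarray,
    seed: int = 0,
) -> dict[str, list[float]]:
    """Mini-batch Adam training with early stopping on the test loss.

    Returns a history dict with per-epoch train/test loss and accuracy.
    Stops when the test loss has not improved by more than ``min_delta``
    for ``patience`` consecutive epochs; the best weights (lowest test
    loss) are restored before returning.
    """
    if len(x_train) == 0 or len(x_test) == 0:
        raise ValidationError("training and test sets must be non-empty")
    if len(set(y_train.tolist())) < 2:
        raise ValidationError("training set must contain both classes")
    spec = model.spec
    history: dict[str, list[float]] = {
        "train_loss": [], "train_accuracy": [], "test_loss": [], "test_accuracy": []
    }
    if spec.max_epochs == 0:
        return history
    rng = np.random.default_rng(seed)
    opt = _Adam(model.parameters, spec.learning_rate)
    best_loss, best_weights, stale = np.inf, model.get_weights(), 0
    for _ in range(spec.max_epochs):
        order = rng.permutation(len(x_train))
        losses = []
        for i in range(0, len(order), spec.batch_size):
            idx = order[i : i + spec.batch_size]
            losses.append(model.train_step(x_train[idx].astype(np.float32), y_train[idx]))
            opt.step(model.parameters, model.gradients)
        tr = evaluate_arrays(model, x_train, y_train)
        te = evaluate_arrays(model, x_test, y_test)
        history["train_loss"].append(tr["loss"])
        history["train_accuracy"].append(tr["accuracy"])
        history["test_loss"].append(te["loss"])
        history["test_accuracy"].append(te["accuracy"])
        if te["loss"] < best_loss - spec.min_delta:
            best_loss, best_weights, stale = te["loss"], model.get_weights(), 0
        else:
            stale += 1
            if stale >= spec.patience:
                break
    model.set_weights(best_weights)
    return history


def evaluate_arrays(model: Model, x: np.ndarray, y: np.ndarray) -> dict:
    """Accuracy, cross-entropy loss, and the 2×2 confusion matrix.

    ``has_stenosis`` (class 0) is the positive class: the matrix is
    ``[[TP, FN], [FP, TN]]`` and its entries sum to the sample count.
    """
    if len(x) == 0:
        raise ValidationError("cannot evaluate on an empty set")
    probs = model.predict_proba(x)
    loss = -float(np.log(probs[np.arange(len(y)), y] + 1e-12).mean())
    pred = probs.argmax(axis=1)
    tp = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 1) & (y == 0)).sum())
    fp = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 1) & (y == 1)).sum())
    return {
        "accuracy": float((pred == y).mean()),
        "loss": loss,
        "confusion": np.array([[tp, fn], [fp, tn]]),
    }


def evaluate(model: Model, test_set: LabelledImageSet) -> dict:
    x, y = prepare_images(test_set, model.spec.input_size)
    return evaluate_arrays(model, x, y)


@dataclass(frozen=True)
class VideoPrediction:
    """Frame-by-frame probabilities and the aggregated video verdict."""

    frame_probabilities: np.ndarray  # (n_frames, 2), rows sum to 1
    verdict: str  # HAS_STENOSIS or NO_STENOSIS

    @property
    def frame_classes(self) -> list[str]:
        return [CLASS_NAMES[i] for i in self.frame_probabilities.argmax(axis=1)]


def aggregate_frame_votes(frame_class_idx: np.ndarray) -> str:
    """Majority vote over frame argmax classes.

    Ties go to ``has_stenosis`` — the clinically conservative call.
    """
    votes_pos = int((np.asarray(frame_class_idx) == 0).sum())
    return HAS_STENOSIS if votes_pos >= len(frame_class_idx) - votes_pos else NO_STENOSIS


def predict_video(model: Model, video_path: str | Path) -> VideoPrediction:
    """Classify every frame of a video and aggregate by majority vote.

    Frames are resized to the model input and normalized to [0, 1].
    """
    seq = extract_frames(video_path)
    if not seq.frames:
        raise VideoIOError(f"{video_path}: no frames")
    s = model.spec.input_size
    x = np.stack(
        [
            resize(f, (s, s), preserve_range=True, anti_aliasing=True)
            for f in seq.frames
        ]
    ).astype(np.float32) / 255.0
    probs = model.predict_proba(x)
    verdict = aggregate_frame_votes(probs.argmax(axis=1))
    return VideoPrediction(frame_probabilities=probs, verdict=verdict)
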