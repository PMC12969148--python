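"""Tiny trainable lesion segmenter standing in for a full transformer model.

A per-pixel classifier over colour and local-context features at a small
working resolution, with an MLP head whose width, depth, context window
and learning rate are configurable — so it exposes the same kind of
hyperparameter surface a large segmentation network would, while training
in seconds on one CPU.  Used as the evaluation target of the evolutionary
optimizer and in the end-to-end augmentation experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import transform

from . import metrics as _metrics
from .gmfdef import Genome, ObjectiveVector
from .preprocess import rec601_gray
from .synthgen import DatasetManifest, read_image

__all__ = ["SurrogateConfig", "SurrogateSegmenter", "surrogate_seg_evaluator", "load_samples"]


@dataclass
class SurrogateConfig:
    """Hyperparameters of the surrogate segmenter."""

    hidden_width: int = 16
    depth: int = 1
    window: int = 4  # context blur radius in working-resolution pixels
    learning_rate: float = 0.05
    steps: int = 150  # full-batch gradient steps
    working_size: tuple[int, int] = (32, 32)
    seed: int = 0


def _pixel_features(image: np.ndarray, window: int) -> np.ndarray:
    """Per-pixel feature vectors: RGB, luma, blurred luma, local SD."""
    img = np.asarray(image, dtype=float)
    gray = rec601_gray(img)
    sigma = max(window / 2.0, 0.5)
    blur = ndimage.gaussian_filter(gray, sigma)
    sq = ndimage.gaussian_filter(gray**2, sigma)
    local_sd = np.sqrt(np.maximum(sq - blur**2, 0.0))
    feats = [img[..., c] for c in range(3)] + [gray, blur, local_sd]
    return np.stack(feats, axis=-1).reshape(-1, len(feats))


class SurrogateSegmenter:
    """Per-pixel MLP lesion classifier, trained with full-batch Adam on
    binary cross-entropy.  Deterministic under its seed; zero training
    steps leave the randomly initialized model untouched."""

    N_FEATURES = 6

    def __init__(self, config: SurrogateConfig | None = None):
        self.config = config or SurrogateConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        dims = [self.N_FEATURES] + [cfg.hidden_width] * cfg.depth + [1]
        self.weights = []
        self.biases = []
        for n_in, n_out in zip(dims[:-1], dims[1:]):
            scale = np.sqrt(2.0 / (n_in + n_out))
            self.weights.append(rng.normal(0.0, scale, size=(n_in, n_out)))
            self.biases.append(np.zeros(n_out))

    def _forward(self, x: np.ndarray) -> tuple[np.ndarray, list]:
        acts = [x]
        a = x
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ w + b
            a = 1.0 / (1.0 + np.exp(-z)) if i == len(self.weights) - 1 else np.tanh(z)
            acts.append(a)
        return a[:, 0], acts

    def _resize(self, image: np.ndarray, order: int) -> np.ndarray:
        return transform.resize(
            np.asarray(image, dtype=float),
            self.config.working_size,
            order=order,
            anti_aliasing=False,
            preserve_range=True,
        )

    def fit(self, samples: list[tuple[np.ndarray, np.ndarray]]) -> list[float]:
        """Train on (image, mask) pairs; returns the per-step loss curve."""
        cfg = self.config
        xs, ys = [], []
        for img, m in samples:
            img_r = self._resize(img[..., :3], order=1)
            m_r = self._resize(m, order=0) > 0.5
            xs.append(_pixel_features(img_r, cfg.window))
            ys.append(m_r.ravel().astype(float))
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        ms = [np.zeros_like(w) for w in self.weights + self.biases]
        vs = [np.zeros_like(w) for w in self.weights + self.biases]
        b1, b2, eps = 0.9, 0.999, 1e-8
        curve = []
        for t in range(1, cfg.steps + 1):
            p, acts = self._forward(x)
            p = np.clip(p, 1e-9, 1 - 1e-9)
            loss = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
            curve.append(loss)
            delta = ((p - y) / len(y))[:, None]
            grads_w, grads_b = [], []
            for i in range(len(self.weights) - 1, -1, -1):
                grads_w.insert(0, acts[i].T @ delta)
                grads_b.insert(0, delta.sum(axis=0))
                if i > 0:
                    delta = delta @ self.weights[i].T
                    delta = delta * (1 - acts[i] ** 2)
            params = self.weights + self.biases
            grads = grads_w + grads_b
            for p_, g, m_, v_ in zip(params, grads, ms, vs):
                m_ *= b1
                m_ += (1 - b1) * g
                v_ *= b2
                v_ += (1 - b2) * g * g
                p_ -= cfg.learning_rate * (m_ / (1 - b1**t)) / (
                    np.sqrt(v_ / (1 - b2**t)) + eps
                )
        return curve

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Predicted {0,1} mask at the working resolution."""
        img_r = self._resize(np.asarray(image)[..., :3], order=1)
        feats = _pixel_features(img_r, self.config.window)
        p, _ = self._forward(feats)
        return (p.reshape(self.config.working_size) >= 0.5).astype(np.uint8)

    def evaluate(
        self, samples: list[tuple[np.ndarray, np.ndarray]]
    ) -> ObjectiveVector:
        """Mean Dice/IoU/BA and mean Hausdorff over a sample list,
        compared at the working resolution."""
        dices, ious, bas, hds = [], [], [], []
        for img, m in samples:
            pred = self.predict(img)
            truth = (self._resize(m, order=0) > 0.5).astype(np.uint8)
            counts = _metrics.confusion(pred, truth)
            dices.append(_metrics.dice(counts))
            ious.append(_metrics.iou(counts))
            ba = _metrics.boundary_accuracy(pred, truth)
            bas.append(ba.value if ba.defined else 0.0)
            hd = _metrics.hausdorff_masks(pred, truth)
            diag = float(np.hypot(*self.config.working_size))
            hds.append(hd.value if hd.defined else diag)
        return ObjectiveVector(
            dice=float(np.mean(dices)),
            iou=float(np.mean(ious)),
            boundary_accuracy=float(np.mean(bas)),
            hausdorff=float(np.mean(hds)),
        )


def load_samples(manifest: DatasetManifest) -> list[tuple[np.ndarray, np.ndarray]]:
    """Read (image, mask) float arrays for every manifest record."""
    samples = []
    for rec in manifest.records:
        img = read_image(rec["image"])[..., :3]
        m = read_image(rec["mask"])
        if m.ndim == 3:
            m = m[..., 0]
        samples.append((img, (m > 0.5).astype(np.uint8)))
    return samples


def surrogate_seg_evaluator(
    genome: Genome,
    train_set: list[tuple[np.ndarray, np.ndarray]],
    val_set: list[tuple[np.ndarray, np.ndarray]],
    steps_budget: int = 120,
    seed: int = 0,
) -> ObjectiveVector:
    """Train a surrogate segmenter from a genome's hyperparameters and
    return its validation objectives.

    Genome genes map onto the surrogate: ``learning_rate`` directly,
    ``window_size`` to the context window, ``embed_dim`` to the hidden
    width (scaled down 8x), ``depth`` to the MLP depth.  Zero budget
    returns the untrained model's metrics, deterministically.
    """
    v = genome.values
    cfg = SurrogateConfig(
        hidden_width=max(4, int(v.get("embed_dim", 96)) // 8),
        depth=int(v.get("depth", 1)),
        window=int(v.get("window_size", 4)),
        learning_rate=float(v.get("learning_rate", 1e-4)) * 500.0,
        steps=steps_budget,
        seed=seed,
    )
    model = SurrogateSegmenter(cfg)
    if steps_budget > 0:
        model.fit(train_set)
    return model.evaluate(val_set)
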