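"""Small seeded numpy neural building blocks.

A dense autoencoder (used for the morphology-aware latent space), a
fixed-random convolutional feature extractor (the perceptual-feature map
of the composite synthesis loss), and a tiny discriminator head.  All
parameters are drawn from a ``numpy.random.Generator`` seeded explicitly,
so every forward pass and training run is a pure function of its inputs
and seeds.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["MLPAutoencoder", "RandomFeatureNet", "TinyDiscriminator"]


def _init_layer(rng, n_in: int, n_out: int) -> tuple[np.ndarray, np.ndarray]:
    scale = np.sqrt(2.0 / (n_in + n_out))
    return rng.normal(0.0, scale, size=(n_in, n_out)), np.zeros(n_out)


class _Adam:
    """Minimal Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        if self.lr == 0.0:
            return
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class MLPAutoencoder:
    """Dense tanh autoencoder with a sigmoid output layer.

    Encoder: ``input -> hidden[0] -> ... -> latent`` (tanh activations,
    linear latent).  Decoder mirrors the encoder and squashes the output
    through a sigmoid so decoded rasters always lie in (0, 1).
    """

    def __init__(
        self,
        input_dim: int,
        latent_dim: int,
        hidden: tuple[int, ...] = (128,),
        seed: int = 0,
    ):
        if latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        self.input_dim = input_dim
        self.latent_dim = latent_dim
        self.hidden = tuple(hidden)
        rng = np.random.default_rng(seed)
        dims = [input_dim, *hidden, latent_dim, *reversed(hidden), input_dim]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for n_in, n_out in zip(dims[:-1], dims[1:]):
            w, b = _init_layer(rng, n_in, n_out)
            self.weights.append(w)
            self.biases.append(b)
        self._n_enc = len(hidden) + 1  # layers up to and including the latent

    # -- forward ---------------------------------------------------------

    def _forward(self, x: np.ndarray) -> tuple[np.ndarray, list]:
        """Full forward pass; returns output and per-layer activations."""
        acts = [x]
        a = x
        n_layers = len(self.weights)
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ w + b
            if i == n_layers - 1:
                a = 1.0 / (1.0 + np.exp(-z))  # sigmoid output
            elif i == self._n_enc - 1:
                a = z  # linear latent
            else:
                a = np.tanh(z)
            acts.append(a)
        return a, acts

    def encode(self, x: np.ndarray) -> np.ndarray:
        a = np.atleast_2d(np.asarray(x, dtype=float))
        for i in range(self._n_enc):
            z = a @ self.weights[i] + self.biases[i]
            a = z if i == self._n_enc - 1 else np.tanh(z)
        return a if np.asarray(x).ndim == 2 else a[0]

    def decode(self, z: np.ndarray) -> np.ndarray:
        zz = np.asarray(z, dtype=float)
        if zz.shape[-1] != self.latent_dim:
            raise ValueError(
                f"latent dimension {zz.shape[-1]} does not match decoder "
                f"({self.latent_dim})"
            )
        a = np.atleast_2d(zz)
        n_layers = len(self.weights)
        for i in range(self._n_enc, n_layers):
            zlin = a @ self.weights[i] + self.biases[i]
            a = 1.0 / (1.0 + np.exp(-zlin)) if i == n_layers - 1 else np.tanh(zlin)
        return a if zz.ndim == 2 else a[0]

    # -- training --------------------------------------------------------

    def fit(
        self,
        x: np.ndarray,
        epochs: int = 50,
        batch_size: int = 16,
        lr: float = 1e-3,
        seed: int = 0,
    ) -> list[float]:
        """Minimize mean squared reconstruction error; returns the
        per-epoch loss curve (evaluated on the full set after each epoch,
        preceded by the initial loss)."""
        x = np.asarray(x, dtype=float)
        rng = np.random.default_rng(seed)
        opt = _Adam(self.weights + self.biases, lr=lr)
        n = len(x)

        def full_loss() -> float:
            out, _ = self._forward(x)
            return float(np.mean((out - x) ** 2))

        curve = [full_loss()]
        for _ in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                batch = x[order[start : start + batch_size]]
                self._step(batch, opt)
            loss = full_loss()
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"autoencoder training diverged (loss={loss}); "
                    f"lr={lr}, epochs so far={len(curve) - 1}"
                )
            curve.append(loss)
        return curve

    def _step(self, batch: np.ndarray, opt: _Adam) -> None:
        out, acts = self._forward(batch)
        n_layers = len(self.weights)
        m = len(batch)
        grads_w = [None] * n_layers
        grads_b = [None] * n_layers
        # d loss / d out for MSE
        delta = 2.0 * (out - batch) / (m * batch.shape[1])
        delta = delta * out * (1 - out)  # sigmoid derivative
        for i in range(n_layers - 1, -1, -1):
            a_prev = acts[i]
            grads_w[i] = a_prev.T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.weights[i].T
                if i - 1 == self._n_enc - 1:
                    pass  # linear latent layer
                else:
                    a = acts[i]
                    delta = delta * (1 - a * a)  # tanh derivative
        opt.step(grads_w + grads_b)


class RandomFeatureNet:
    """Fixed-seed random convolutional feature map.

    Two 3x3 convolution layers (ReLU, stride-2 subsampling) with frozen
    random filters, flattened into a feature vector.  Serves as the fixed
    perceptual feature extractor of the composite synthesis loss.
    """

    def __init__(self, in_channels: int = 3, widths: tuple[int, int] = (8, 8), seed: int = 7):
        rng = np.random.default_rng(seed)
        self.filters: list[np.ndarray] = []
        c_in = in_channels
        for c_out in widths:
            f = rng.normal(0.0, 1.0 / np.sqrt(9 * c_in), size=(c_out, c_in, 3, 3))
            self.filters.append(f)
            c_in = c_out

    def __call__(self, image: np.ndarray) -> np.ndarray:
        x = np.asarray(image, dtype=float)
        if x.ndim == 2:
            x = x[..., None]
        x = np.moveaxis(x, -1, 0)  # C,H,W
        for bank in self.filters:
            out = np.empty((bank.shape[0], x.shape[1], x.shape[2]))
            for j in range(bank.shape[0]):
                acc = np.zeros(x.shape[1:])
                for c in range(x.shape[0]):
                    acc += ndimage.correlate(x[c], bank[j, c], mode="reflect")
                out[j] = acc
            x = np.maximum(out, 0.0)[:, ::2, ::2]  # ReLU + stride-2 subsample
        return x.ravel()


class TinyDiscriminator:
    """Frozen random discriminator: random features + logistic head.

    Scores an (image, condition) pair with a probability in (0, 1).  The
    condition (a class index) shifts the logit through a per-class bias so
    the score is genuinely conditional.
    """

    def __init__(self, feature_net: RandomFeatureNet | None = None, seed: int = 11):
        self.features = feature_net or RandomFeatureNet(seed=seed)
        self._rng_seed = seed
        self._head: np.ndarray | None = None

    def score(self, image: np.ndarray, cond: int = 0) -> float:
        feats = self.features(image)
        if self._head is None or len(self._head) != len(feats):
            rng = np.random.default_rng(self._rng_seed + 1)
            self._head = rng.normal(0.0, 1.0 / np.sqrt(len(feats)), size=len(feats))
        logit = float(feats @ self._head) + 0.1 * float(cond)
        return 1.0 / (1.0 + np.exp(-logit))
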