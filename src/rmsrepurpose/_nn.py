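"""Compact feedforward neural-network core (numpy, manual backprop).

Provides the three trainable pieces the drug-response models are built
from: a bottleneck autoencoder, a sigmoid binary classifier, and a
triplet-loss embedding encoder. Training is full-batch-shuffled
mini-batch Adam; all randomness flows through an explicit
``numpy.random.Generator`` so runs are reproducible bit for bit.

Inputs are standardized internally (mean/sd learned on the training
data) so layer scales are comparable across omics.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


class _Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float, beta1=0.9, beta2=0.999):
        self.lr, self.b1, self.b2 = lr, beta1, beta2
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + 1e-8)


class MLP:
    """Fully connected network with per-layer activations.

    ``activations`` entries are 'relu', 'linear' or 'sigmoid', one per
    weight layer.
    """

    def __init__(self, dims: list[int], activations: list[str], rng: np.random.Generator):
        assert len(activations) == len(dims) - 1
        self.activations = activations
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            scale = np.sqrt(2.0 / d_in)
            self.W.append(rng.standard_normal((d_in, d_out)) * scale)
            self.b.append(np.zeros(d_out))

    @property
    def params(self) -> list[np.ndarray]:
        return [*self.W, *self.b]

    def forward(self, X: np.ndarray):
        """Return (output, cache of post-activation values per layer)."""
        a = X
        cache = [a]
        for W, b, act in zip(self.W, self.b, self.activations):
            z = a @ W + b
            if act == "relu":
                a = np.maximum(z, 0.0)
            elif act == "sigmoid":
                a = 1.0 / (1.0 + np.exp(-z))
            else:
                a = z
            cache.append(a)
        return a, cache

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[0]

    def backward(self, cache, delta: np.ndarray):
        """Backpropagate ``delta`` = dL/d(pre-activation of last layer).

        For the sigmoid+cross-entropy and linear+MSE pairings the caller
        passes the combined (output - target)-style residual, which is
        exactly that derivative.
        """
        gW = [np.empty(0)] * len(self.W)
        gb = [np.empty(0)] * len(self.b)
        for i in range(len(self.W) - 1, -1, -1):
            gW[i] = cache[i].T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.W[i].T
                if self.activations[i - 1] == "relu":
                    delta = delta * (cache[i] > 0)
        return [*gW, *gb]


class _Standardizer:
    def fit(self, X: np.ndarray) -> "_Standardizer":
        self.mean_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0)
        self.sd_[self.sd_ < _EPS] = 1.0
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.sd_


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


class Autoencoder:
    """Symmetric bottleneck autoencoder trained on reconstruction MSE.

    ``hidden_dims`` may be empty, giving a purely linear
    encode/decode pair. The bottleneck and output are linear; hidden
    layers use ReLU.
    """

    def __init__(
        self,
        bottleneck_dim: int,
        hidden_dims: tuple[int, ...] = (64,),
        learning_rate: float = 1e-3,
        batch_size: int = 64,
        epochs: int = 20,
        seed: int = 0,
    ):
        self.bottleneck_dim = bottleneck_dim
        self.hidden_dims = tuple(hidden_dims)
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed

    def fit(self, X: np.ndarray) -> "Autoencoder":
        if not np.isfinite(X).all():
            raise ValueError("autoencoder input contains non-finite values")
        n, d = X.shape
        if d < self.bottleneck_dim:
            raise ValueError("bottleneck_dim exceeds the input dimension")
        rng = np.random.default_rng(self.seed)
        self.scaler_ = _Standardizer().fit(X)
        Xs = self.scaler_.transform(X)
        h = list(self.hidden_dims)
        dims = [d, *h, self.bottleneck_dim, *reversed(h), d]
        acts = ["relu"] * len(h) + ["linear"] + ["relu"] * len(h) + ["linear"]
        self.net_ = MLP(dims, acts, rng)
        self._n_encoder_layers = len(h) + 1
        opt = _Adam(self.net_.params, self.learning_rate)
        self.loss_trace_ = []
        for _ in range(self.epochs):
            losses = []
            for idx in _batches(n, self.batch_size, rng):
                xb = Xs[idx]
                out, cache = self.net_.forward(xb)
                resid = out - xb
                losses.append(float((resid**2).mean()))
                delta = 2.0 * resid / resid.size
                grads = self.net_.backward(cache, delta)
                opt.step(self.net_.params, grads)
            self.loss_trace_.append(float(np.mean(losses)))
        return self

    def encode(self, X: np.ndarray) -> np.ndarray:
        a = self.scaler_.transform(X)
        for i in range(self._n_encoder_layers):
            z = a @ self.net_.W[i] + self.net_.b[i]
            a = np.maximum(z, 0.0) if self.net_.activations[i] == "relu" else z
        return a

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self.net_(self.scaler_.transform(X))

    def reconstruction_mse(self, X: np.ndarray) -> float:
        Xs = self.scaler_.transform(X)
        return float(((self.net_(Xs) - Xs) ** 2).mean())


class SigmoidClassifier:
    """Binary classifier with ReLU hidden layers and a sigmoid output.

    ``partial_fit`` trains one epoch at a time so callers can snapshot
    predicted probabilities after every epoch.
    """

    def __init__(
        self,
        hidden_dims: tuple[int, ...] = (64,),
        learning_rate: float = 1e-3,
        batch_size: int = 64,
        seed: int = 0,
    ):
        self.hidden_dims = tuple(hidden_dims)
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.seed = seed
        self.net_ = None

    def _init(self, d: int) -> None:
        self._rng = np.random.default_rng(self.seed)
        h = list(self.hidden_dims)
        self.net_ = MLP([d, *h, 1], ["relu"] * len(h) + ["sigmoid"], self._rng)
        self._opt = _Adam(self.net_.params, self.learning_rate)

    def partial_fit(self, X: np.ndarray, y: np.ndarray) -> "SigmoidClassifier":
        if self.net_ is None:
            self._init(X.shape[1])
        n = len(X)
        for idx in _batches(n, self.batch_size, self._rng):
            out, cache = self.net_.forward(X[idx])
            delta = (out - y[idx, None]) / len(idx)  # d(BCE)/d(logit)
            self._opt.step(self.net_.params, self.net_.backward(cache, delta))
        return self

    def fit(self, X: np.ndarray, y: np.ndarray, epochs: int = 10) -> "SigmoidClassifier":
        for _ in range(epochs):
            self.partial_fit(X, y)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.net_(X)[:, 0]


class TripletEncoder:
    """Supervised embedding trained with a margin triplet loss.

    Within each mini-batch every sample with an available same-class
    partner anchors one (anchor, positive, negative) triplet; the loss
    ``max(0, ||a-p||^2 - ||a-n||^2 + margin)`` pulls same-class
    embeddings together and pushes different-class ones apart.
    """

    def __init__(
        self,
        embedding_dim: int = 32,
        hidden_dims: tuple[int, ...] = (64,),
        margin: float = 1.0,
        learning_rate: float = 1e-3,
        batch_size: int = 64,
        epochs: int = 10,
        seed: int = 0,
    ):
        if margin <= 0:
            raise ValueError("triplet margin must be positive")
        self.embedding_dim = embedding_dim
        self.hidden_dims = tuple(hidden_dims)
        self.margin = margin
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "TripletEncoder":
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("triplet training requires both classes")
        rng = np.random.default_rng(self.seed)
        self.scaler_ = _Standardizer().fit(X)
        Xs = self.scaler_.transform(X)
        h = list(self.hidden_dims)
        self.net_ = MLP(
            [X.shape[1], *h, self.embedding_dim], ["relu"] * len(h) + ["linear"], rng
        )
        opt = _Adam(self.net_.params, self.learning_rate)
        self.loss_trace_ = []
        for _ in range(self.epochs):
            losses = []
            for idx in _batches(len(Xs), self.batch_size, rng):
                loss = self._step(Xs[idx], y[idx], rng, opt)
                if loss is not None:
                    losses.append(loss)
            self.loss_trace_.append(float(np.mean(losses)) if losses else 0.0)
        return self

    def _step(self, xb, yb, rng, opt):
        z, cache = self.net_.forward(xb)
        anchors, positives, negatives = [], [], []
        for i in range(len(yb)):
            same = np.flatnonzero(yb == yb[i])
            same = same[same != i]
            diff = np.flatnonzero(yb != yb[i])
            if len(same) == 0 or len(diff) == 0:
                continue
            anchors.append(i)
            positives.append(rng.choice(same))
            negatives.append(rng.choice(diff))
        if not anchors:
            return None
        a, p, n = (np.asarray(v) for v in (anchors, positives, negatives))
        d_ap = ((z[a] - z[p]) ** 2).sum(axis=1)
        d_an = ((z[a] - z[n]) ** 2).sum(axis=1)
        hinge = d_ap - d_an + self.margin
        active = hinge > 0
        loss = float(np.maximum(hinge, 0.0).mean())
        dz = np.zeros_like(z)
        scale = 2.0 / len(a)
        for ai, pi, ni, act in zip(a, p, n, active):
            if not act:
                continue
            dz[ai] += scale * (z[ni] - z[pi])
            dz[pi] += scale * (z[pi] - z[ai])
            dz[ni] += scale * (z[ai] - z[ni])
        opt.step(self.net_.params, self.net_.backward(cache, dz))
        return loss

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.net_(self.scaler_.transform(X))
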