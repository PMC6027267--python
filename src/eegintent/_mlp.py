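"""Single-hidden-layer perceptron trained by full-batch error backpropagation.

Both the intention classifier and the distal-motion estimators in this
package are three-layer perceptrons with sigmoidal units, trained by
gradient descent on the mean squared error — the classical
error-backpropagation setup. The output layer is sigmoidal as well; its
[0, 1] range is affinely mapped onto the target range (``[-1, 1]`` for
intention codes, the training min/max for kinematic targets).

Updates are full-batch, so duplicating every training row leaves the
gradient direction (and hence the fit under a fixed seed) unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BackpropNet"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class BackpropNet:
    """Feedforward net with one sigmoidal hidden layer and sigmoidal output.

    Parameters
    ----------
    n_inputs, n_hidden, n_outputs
        Layer widths. A single hidden layer only.
    lr
        Learning rate of the full-batch gradient steps.
    momentum
        Classical momentum on the parameter updates; accelerates the
        plain-gradient rule without changing its fixed points.
    epochs
        Maximum number of full-batch epochs.
    tol
        Early stop when the epoch-to-epoch MSE improvement stays below
        this value for ``patience`` consecutive epochs (sigmoid nets
        plateau early before escaping, so a single slow epoch must not
        stop training).
    patience
        Number of consecutive sub-``tol`` epochs tolerated.
    seed
        Seed for the weight initialisation; fixed seed + fixed data gives
        a bit-identical fit.
    """

    n_inputs: int
    n_hidden: int
    n_outputs: int = 1
    lr: float = 1.0
    momentum: float = 0.9
    epochs: int = 800
    tol: float = 1e-6
    patience: int = 300
    seed: int = 0
    loss_history: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.seed)
        s1 = 1.0 / np.sqrt(self.n_inputs)
        s2 = 1.0 / np.sqrt(self.n_hidden)
        self.w1 = rng.uniform(-s1, s1, size=(self.n_inputs, self.n_hidden))
        self.b1 = np.zeros(self.n_hidden)
        self.w2 = rng.uniform(-s2, s2, size=(self.n_hidden, self.n_outputs))
        self.b2 = np.zeros(self.n_outputs)

    # -- forward -----------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Network output in [0, 1] per output unit."""
        h = _sigmoid(x @ self.w1 + self.b1)
        return _sigmoid(h @ self.w2 + self.b2)

    # -- training ----------------------------------------------------------
    def fit(self, x: np.ndarray, y01: np.ndarray) -> "BackpropNet":
        """Full-batch backpropagation on MSE; targets must lie in [0, 1]."""
        x = np.asarray(x, dtype=float)
        y01 = np.asarray(y01, dtype=float).reshape(len(x), self.n_outputs)
        v = [np.zeros_like(p) for p in (self.w1, self.b1, self.w2, self.b2)]
        best = np.inf
        stall = 0
        self.loss_history = []
        for _ in range(self.epochs):
            h = _sigmoid(x @ self.w1 + self.b1)
            out = _sigmoid(h @ self.w2 + self.b2)
            err = out - y01
            loss = float(np.mean(err**2))
            self.loss_history.append(loss)
            # d(MSE)/d(out) with sigmoid derivatives at each layer; the
            # 1/err.size factor makes every gradient a batch mean, so
            # duplicating rows leaves the step direction unchanged
            d_out = (2.0 / err.size) * err * out * (1.0 - out)
            g_w2 = h.T @ d_out
            g_b2 = d_out.sum(axis=0)
            d_h = (d_out @ self.w2.T) * h * (1.0 - h)
            g_w1 = x.T @ d_h
            g_b1 = d_h.sum(axis=0)
            params = (self.w1, self.b1, self.w2, self.b2)
            for i, (p, g) in enumerate(zip(params, (g_w1, g_b1, g_w2, g_b2))):
                v[i] = self.momentum * v[i] - self.lr * g
                p += v[i]
            if best - loss < self.tol:
                stall += 1
                if stall >= self.patience:
                    break
            else:
                stall = 0
            best = min(best, loss)
        return self
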