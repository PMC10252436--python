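"""A compact stacked-LSTM regressor for one-step-ahead series forecasting.

Implemented directly on numpy: two (configurable) recurrent hidden layers,
each followed by inverted dropout, and a dense linear output of size one.
Training minimizes mean absolute error with Adam and global gradient-norm
clipping; inputs and targets are min–max scaled to [0, 1] internally and
predictions are inverse-transformed back to the original scale.  All
randomness (weight init, batch shuffling, dropout masks) flows from a
single seed, so fits are bit-reproducible.

The cell is the standard gated parameterization: with gates
i, f, o = sigmoid(z) and candidate g = phi(z_g),

    c_t = f * c_{t-1} + i * g,    h_t = o * phi(c_t),

where phi is the layer activation (sigmoid by default here, tanh
available).  Gradients are exact backpropagation through time, verified
against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import NotFittedError

from .exceptions import ValidationError


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


_ACTIVATIONS = {
    # value -> (phi(value), derivative expressed through phi(value))
    "sigmoid": (_sigmoid, lambda a: a * (1.0 - a)),
    "tanh": (np.tanh, lambda a: 1.0 - a * a),
}


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class _LSTMLayer:
    """One recurrent layer; holds weights and the caches for BPTT."""

    def __init__(self, d_in: int, units: int, activation: str, rng: np.random.Generator):
        self.d_in, self.units = d_in, units
        self.phi, self.dphi = _ACTIVATIONS[activation]
        h = units
        self.Wx = _glorot(rng, d_in, 4 * h, (d_in, 4 * h))
        self.Wh = _glorot(rng, h, 4 * h, (h, 4 * h))
        self.b = np.zeros(4 * h)
        self.b[h : 2 * h] = 1.0  # forget-gate bias

    @property
    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (B, T, d_in) -> h sequence (B, T, units); caches intermediates."""
        B, T, _ = x.shape
        h = self.units
        hs = np.zeros((B, T + 1, h))
        cs = np.zeros((B, T + 1, h))
        gates = np.zeros((B, T, 4, h))  # i, f, g, o (post-activation)
        hc = np.zeros((B, T, h))  # phi(c_t)
        for t in range(T):
            z = x[:, t] @ self.Wx + hs[:, t] @ self.Wh + self.b
            zi, zf, zg, zo = np.split(z, 4, axis=1)
            i, f, o = _sigmoid(zi), _sigmoid(zf), _sigmoid(zo)
            g = self.phi(zg)
            c = f * cs[:, t] + i * g
            pc = self.phi(c)
            cs[:, t + 1] = c
            hs[:, t + 1] = o * pc
            gates[:, t, 0], gates[:, t, 1], gates[:, t, 2], gates[:, t, 3] = i, f, g, o
            hc[:, t] = pc
        self._cache = (x, hs, cs, gates, hc)
        return hs[:, 1:]

    def backward(self, dh_seq: np.ndarray):
        """dh_seq: (B, T, units) gradient wrt the output sequence.

        Returns (dx_seq, [dWx, dWh, db])."""
        x, hs, cs, gates, hc = self._cache
        B, T, _ = x.shape
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, self.units))
        dc_next = np.zeros((B, self.units))
        for t in range(T - 1, -1, -1):
            i, f, g, o = (gates[:, t, j] for j in range(4))
            dh = dh_seq[:, t] + dh_next
            do = dh * hc[:, t]
            dc = dc_next + dh * o * self.dphi(hc[:, t])
            di = dc * g
            df = dc * cs[:, t]
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * self.dphi(g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dWx += x[:, t].T @ dz
            dWh += hs[:, t].T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        return dx, [dWx, dWh, db]


class LSTMRegressor(RegressorMixin, BaseEstimator):
    """Stacked-LSTM one-step-ahead regressor on lag windows.

    Parameters
    ----------
    units : tuple of int
        Hidden width of each recurrent layer (two layers by default).
    dropout : float
        Dropout rate applied after each recurrent layer during training.
    activation : {"sigmoid", "tanh"}
        Candidate/cell activation (gates are always sigmoid).
    loss : {"mae", "mse"}
        Training loss; mean absolute error by default.
    learning_rate : float
        Adam initial learning rate.
    clipnorm : float
        Global gradient-norm clipping threshold.
    epochs, batch_size : int
        Training schedule.
    seed : int
        Seed for init, shuffling and dropout.
    """

    def __init__(
        self,
        units: tuple[int, ...] = (64, 32),
        dropout: float = 0.2,
        activation: str = "sigmoid",
        loss: str = "mae",
        learning_rate: float = 0.05,
        clipnorm: float = 1.0,
        epochs: int = 150,
        batch_size: int = 8,
        seed: int = 0,
    ):
        self.units = units
        self.dropout = dropout
        self.activation = activation
        self.loss = loss
        self.learning_rate = learning_rate
        self.clipnorm = clipnorm
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed

    # ---- scaling -------------------------------------------------------
    def _fit_scaler(self, X: np.ndarray, y: np.ndarray) -> None:
        vmin = min(X.min(), y.min())
        vmax = max(X.max(), y.max())
        span = vmax - vmin
        if span <= 0:
            # constant series: scale by its own magnitude so the residual
            # fitting error stays proportional to the data scale
            span = abs(vmax) if vmax != 0 else 1.0
        self.scale_min_ = vmin
        self.scale_span_ = span

    def _scale(self, v: np.ndarray) -> np.ndarray:
        return (v - self.scale_min_) / self.scale_span_

    def _unscale(self, v: np.ndarray) -> np.ndarray:
        return v * self.scale_span_ + self.scale_min_

    # ---- model ---------------------------------------------------------
    def _init_layers(self, rng: np.random.Generator) -> None:
        if self.activation not in _ACTIVATIONS:
            raise ValidationError(f"unknown activation '{self.activation}'")
        if self.loss not in ("mae", "mse"):
            raise ValidationError(f"unknown loss '{self.loss}'")
        self.layers_ = []
        d_in = 1
        for u in self.units:
            self.layers_.append(_LSTMLayer(d_in, int(u), self.activation, rng))
            d_in = int(u)
        self.Wd_ = _glorot(rng, d_in, 1, (d_in, 1))
        self.bd_ = np.zeros(1)

    def _params(self):
        ps = []
        for layer in self.layers_:
            ps.extend(layer.params)
        ps.extend([self.Wd_, self.bd_])
        return ps

    def _forward(self, X: np.ndarray, rng=None):
        """X: (B, T, 1) scaled.  rng enables dropout (training mode)."""
        keep = 1.0 - self.dropout
        masks = []
        out = X
        for layer in self.layers_:
            out = layer.forward(out)
            if rng is not None and self.dropout > 0:
                mask = rng.random(out.shape) < keep
                out = out * mask / keep
                masks.append(mask)
            else:
                masks.append(None)
        h_last = out[:, -1]
        yhat = (h_last @ self.Wd_ + self.bd_).ravel()
        self._fw_cache = (out, masks)
        return yhat

    def _loss_grad(self, yhat: np.ndarray, y: np.ndarray):
        r = yhat - y
        n = len(y)
        if self.loss == "mae":
            return float(np.mean(np.abs(r))), np.sign(r) / n
        return float(np.mean(r**2)), 2.0 * r / n

    def _backward(self, X: np.ndarray, dyhat: np.ndarray):
        out, masks = self._fw_cache
        keep = 1.0 - self.dropout
        h_last = out[:, -1]
        dWd = h_last.T @ dyhat[:, None]
        dbd = np.array([dyhat.sum()])
        dh_seq = np.zeros_like(out)
        dh_seq[:, -1] = dyhat[:, None] * self.Wd_.T
        grads_rev = [[dWd, dbd]]
        for li in range(len(self.layers_) - 1, -1, -1):
            if masks[li] is not None:
                dh_seq = dh_seq * masks[li] / keep
            dh_seq, layer_grads = self.layers_[li].backward(dh_seq)
            grads_rev.append(layer_grads)
        grads = []
        for g in reversed(grads_rev[1:]):
            grads.extend(g)
        grads.extend(grads_rev[0])
        return grads

    def loss_and_gradients(self, X: np.ndarray, y: np.ndarray):
        """Loss and exact parameter gradients on already-scaled data with
        dropout disabled (used for gradient verification)."""
        yhat = self._forward(np.asarray(X, float), rng=None)
        loss, dyhat = self._loss_grad(yhat, np.asarray(y, float))
        return loss, self._backward(np.asarray(X, float), dyhat)

    # ---- sklearn API ---------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim == 2:
            X = X[:, :, None]
        if X.ndim != 3 or X.shape[2] != 1 or len(X) != len(y) or len(y) == 0:
            raise ValidationError("fit expects X (n, timesteps[, 1]) and y (n,)")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValidationError("non-finite values in training data")

        rng = np.random.default_rng(self.seed)
        self._fit_scaler(X, y)
        Xs, ys = self._scale(X), self._scale(y)
        self._init_layers(rng)

        params = self._params()
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        n = len(ys)
        self.loss_history_ = []
        for _ in range(int(self.epochs)):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, int(self.batch_size)):
                idx = order[start : start + int(self.batch_size)]
                yhat = self._forward(Xs[idx], rng=rng if self.dropout > 0 else None)
                loss, dyhat = self._loss_grad(yhat, ys[idx])
                grads = self._backward(Xs[idx], dyhat)
                gnorm = np.sqrt(sum(float(np.sum(g**2)) for g in grads))
                if self.clipnorm and gnorm > self.clipnorm:
                    grads = [g * (self.clipnorm / gnorm) for g in grads]
                step += 1
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi *= b1
                    mi += (1 - b1) * g
                    vi *= b2
                    vi += (1 - b2) * g * g
                    mhat = mi / (1 - b1**step)
                    vhat = vi / (1 - b2**step)
                    p -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)
                epoch_loss += loss * len(idx)
            self.loss_history_.append(epoch_loss / n)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "layers_"):
            raise NotFittedError("LSTMRegressor is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, :, None]
        if not np.all(np.isfinite(X)):
            raise ValidationError("non-finite values in prediction input")
        yhat = self._forward(self._scale(X), rng=None)
        return self._unscale(yhat)
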