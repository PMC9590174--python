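"""A minimal fully-connected autoencoder in numpy.

Implements exactly what the reference-selection stage needs: an MLP
encoder/decoder with ReLU activations, batch normalization and
(inverted) dropout between layers, trained with Adam on mean squared
reconstruction error.  Everything is driven by a single seeded
Generator, so training is bit-reproducible on one machine.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLPAutoencoder"]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


class _Dense:
    def __init__(self, rng, n_in, n_out):
        # He initialization, suited to the ReLU hidden layers
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [("W", self), ("b", self)]


class _BatchNorm:
    def __init__(self, n):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.run_mean = np.zeros(n)
        self.run_var = np.ones(n)

    def forward(self, x, training):
        if training:
            m = x.mean(axis=0)
            v = x.var(axis=0)
            self.run_mean = _BN_MOMENTUM * self.run_mean + (1 - _BN_MOMENTUM) * m
            self.run_var = _BN_MOMENTUM * self.run_var + (1 - _BN_MOMENTUM) * v
        else:
            m, v = self.run_mean, self.run_var
        self._istd = 1.0 / np.sqrt(v + _BN_EPS)
        self._xhat = (x - m) * self._istd
        self._xc = x - m
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        B = grad.shape[0]
        self.dgamma = (grad * self._xhat).sum(axis=0)
        self.dbeta = grad.sum(axis=0)
        dxhat = grad * self.gamma
        dvar = (dxhat * self._xc).sum(axis=0) * (-0.5) * self._istd**3
        dmean = -(dxhat.sum(axis=0)) * self._istd + dvar * (-2.0 / B) * self._xc.sum(axis=0)
        return dxhat * self._istd + dvar * 2.0 * self._xc / B + dmean / B

    def params(self):
        return [("gamma", self), ("beta", self)]


class MLPAutoencoder:
    """Encoder widths -> bottleneck -> mirrored decoder.

    Hidden layers are Linear -> BatchNorm -> ReLU -> Dropout; the
    bottleneck and the reconstruction output are linear.
    """

    def __init__(self, n_features, n_encoded, hidden_widths=(512, 128), dropout_rate=0.1, seed=0):
        self.n_features = int(n_features)
        self.n_encoded = int(n_encoded)
        self.hidden_widths = list(hidden_widths)
        self.dropout_rate = float(dropout_rate)
        self.seed = int(seed)
        self.rng = np.random.default_rng(seed)

        enc_dims = [self.n_features] + self.hidden_widths
        dec_dims = [self.n_encoded] + self.hidden_widths[::-1]
        self.enc_layers = [
            (_Dense(self.rng, enc_dims[i], enc_dims[i + 1]), _BatchNorm(enc_dims[i + 1]))
            for i in range(len(self.hidden_widths))
        ]
        self.enc_out = _Dense(self.rng, enc_dims[-1], self.n_encoded)
        self.dec_layers = [
            (_Dense(self.rng, dec_dims[i], dec_dims[i + 1]), _BatchNorm(dec_dims[i + 1]))
            for i in range(len(self.hidden_widths))
        ]
        self.dec_out = _Dense(self.rng, dec_dims[-1], self.n_features)
        self._adam_state: dict[tuple[int, str], tuple[np.ndarray, np.ndarray]] = {}
        self._adam_t = 0

    # ------------------------------------------------------------------ fwd

    def _forward_block(self, x, layers, training):
        caches = []
        for dense, bn in layers:
            z = dense.forward(x)
            h = bn.forward(z, training)
            relu_mask = h > 0
            h = h * relu_mask
            if training and self.dropout_rate > 0:
                drop = (self.rng.uniform(size=h.shape) >= self.dropout_rate) / (
                    1.0 - self.dropout_rate
                )
            else:
                drop = None
            if drop is not None:
                h = h * drop
            caches.append((dense, bn, relu_mask, drop))
            x = h
        return x, caches

    def encode(self, x, training=False):
        h, caches = self._forward_block(x, self.enc_layers, training)
        code = self.enc_out.forward(h)
        return code, caches

    def forward(self, x, training=False):
        code, enc_caches = self.encode(x, training)
        h, dec_caches = self._forward_block(code, self.dec_layers, training)
        recon = self.dec_out.forward(h)
        return recon, (enc_caches, dec_caches)

    # ------------------------------------------------------------------ bwd

    @staticmethod
    def _backward_block(grad, caches):
        for dense, bn, relu_mask, drop in reversed(caches):
            if drop is not None:
                grad = grad * drop
            grad = grad * relu_mask
            grad = bn.backward(grad)
            grad = dense.backward(grad)
        return grad

    def _all_modules(self):
        mods = []
        for dense, bn in self.enc_layers:
            mods += [dense, bn]
        mods.append(self.enc_out)
        for dense, bn in self.dec_layers:
            mods += [dense, bn]
        mods.append(self.dec_out)
        return mods

    def _adam_step(self, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for mod in self._all_modules():
            for name, obj in mod.params():
                grad = getattr(obj, "d" + name)
                key = (id(obj), name)
                if key not in self._adam_state:
                    self._adam_state[key] = (np.zeros_like(grad), np.zeros_like(grad))
                m, v = self._adam_state[key]
                m = beta1 * m + (1 - beta1) * grad
                v = beta2 * v + (1 - beta2) * grad**2
                self._adam_state[key] = (m, v)
                mhat = m / (1 - beta1**t)
                vhat = v / (1 - beta2**t)
                setattr(obj, name, getattr(obj, name) - lr * mhat / (np.sqrt(vhat) + eps))

    # ------------------------------------------------------------------ api

    def reconstruction_mse(self, x):
        recon, _ = self.forward(x, training=False)
        return float(np.mean((recon - x) ** 2))

    def fit(self, x, epochs, batch_size, learning_rate):
        n = x.shape[0]
        history = []
        for _ in range(int(epochs)):
            order = self.rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                if len(idx) < 2:
                    continue  # batch statistics undefined for a single sample
                xb = x[idx]
                recon, (enc_caches, dec_caches) = self.forward(xb, training=True)
                diff = recon - xb
                epoch_loss += float(np.sum(diff**2))
                grad = 2.0 * diff / diff.size
                grad = self.dec_out.backward(grad)
                grad = self._backward_block(grad, dec_caches)
                grad = self.enc_out.backward(grad)
                self._backward_block(grad, enc_caches)
                self._adam_step(learning_rate)
            history.append(epoch_loss / x.size)
        return history

    def transform(self, x):
        code, _ = self.encode(x, training=False)
        return code

    # ------------------------------------------------------------- (de)serialize

    def state_arrays(self):
        state = {}
        for i, mod in enumerate(self._all_modules()):
            for attr in ("W", "b", "gamma", "beta", "run_mean", "run_var"):
                if hasattr(mod, attr):
                    state[f"m{i}_{attr}"] = getattr(mod, attr)
        return state

    def load_state_arrays(self, state):
        for i, mod in enumerate(self._all_modules()):
            for attr in ("W", "b", "gamma", "beta", "run_mean", "run_var"):
                if hasattr(mod, attr):
                    setattr(mod, attr, np.asarray(state[f"m{i}_{attr}"]))
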