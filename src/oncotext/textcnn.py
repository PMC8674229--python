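"""A small 1-D convolutional text classifier over token embeddings.

Architecture: learned token embeddings; parallel 1-D convolutions of several
widths; ReLU; global max pooling per filter; dropout; a dense layer to one
or two sigmoid outputs.  With two outputs the first is always the shared
"any cancer" head and the second the outcome of interest, and the training
loss is the unweighted sum of the two binary cross-entropies.

The raw (pre-sigmoid) outputs are log odds; ensembling elsewhere mean-pools
these linear outputs, not probabilities.

Everything runs on CPU in float32 numpy; training uses Adam and is
deterministic for a fixed ``seed``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class ConvTextClassifier(BaseEstimator):
    """Kim-style convolutional classifier on padded token-index sequences.

    Parameters
    ----------
    vocab_size : int
        Number of token indices (0 = padding, 1 = unknown).
    n_outputs : int
        1 (single head) or 2 (shared any-cancer head + specific outcome).
    embed_dim, conv_widths, n_filters : architecture sizes.
    dropout : dropout rate on the pooled feature vector during training.
    epochs, batch_size, lr : Adam training schedule.
    seed : seeds initialization, shuffling and dropout masks.

    Attributes
    ----------
    params_ : dict of fitted weight arrays.
    loss_history_ : per-epoch mean loss, one column per output head.
    """

    def __init__(self, vocab_size=1000, n_outputs=1, embed_dim=16,
                 conv_widths=(2, 3, 4, 5), n_filters=8, dropout=0.5,
                 epochs=3, batch_size=64, lr=1e-2, seed=0):
        self.vocab_size = vocab_size
        self.n_outputs = n_outputs
        self.embed_dim = embed_dim
        self.conv_widths = conv_widths
        self.n_filters = n_filters
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.seed = seed

    # -- parameter plumbing -------------------------------------------
    def _init_params(self, rng):
        D, F = self.embed_dim, self.n_filters
        p = {"E": (rng.standard_normal((self.vocab_size, D)) * 0.05).astype(np.float32)}
        p["E"][0] = 0.0  # padding row starts at zero
        for w in self.conv_widths:
            p[f"W{w}"] = (
                rng.standard_normal((w * D, F)) * np.sqrt(2.0 / (w * D))
            ).astype(np.float32)
            p[f"b{w}"] = np.zeros(F, dtype=np.float32)
        feat = F * len(self.conv_widths)
        p["Wo"] = (rng.standard_normal((feat, self.n_outputs)) * np.sqrt(1.0 / feat)).astype(
            np.float32
        )
        p["bo"] = np.zeros(self.n_outputs, dtype=np.float32)
        return p

    @staticmethod
    def _windows(X_emb, w):
        # (B, L, D) -> (B, L-w+1, w*D) without copying twice
        B, L, D = X_emb.shape
        parts = [X_emb[:, i : L - w + 1 + i, :] for i in range(w)]
        return np.concatenate(parts, axis=2)

    def _forward(self, p, X, train_mask=None):
        """Returns logits (B, K) and a cache for backprop."""
        Xe = p["E"][X]  # (B, L, D)
        pooled = []
        cache = {"Xe": Xe}
        for w in self.conv_widths:
            win = self._windows(Xe, w)  # (B, Lw, wD)
            z = win @ p[f"W{w}"] + p[f"b{w}"]  # (B, Lw, F)
            a = np.maximum(z, 0.0)
            arg = a.argmax(axis=1)  # (B, F)
            mx = np.take_along_axis(a, arg[:, None, :], axis=1)[:, 0, :]
            pooled.append(mx)
            cache[f"win{w}"] = win
            cache[f"z{w}"] = z
            cache[f"arg{w}"] = arg
        feat = np.concatenate(pooled, axis=1)  # (B, F*len(widths))
        if train_mask is not None:
            feat = feat * train_mask
        cache["feat"] = feat
        logits = feat @ p["Wo"] + p["bo"]
        return logits, cache

    def _backward(self, p, X, cache, dlogits):
        g = {}
        feat = cache["feat"]
        g["Wo"] = feat.T @ dlogits
        g["bo"] = dlogits.sum(axis=0)
        dfeat = dlogits @ p["Wo"].T
        F = self.n_filters
        dXe = np.zeros_like(cache["Xe"])
        B, L, D = cache["Xe"].shape
        for k, w in enumerate(self.conv_widths):
            dmx = dfeat[:, k * F : (k + 1) * F]  # (B, F)
            z = cache[f"z{w}"]
            arg = cache[f"arg{w}"]
            dz = np.zeros_like(z)
            np.put_along_axis(dz, arg[:, None, :], dmx[:, None, :], axis=1)
            dz *= z > 0
            win = cache[f"win{w}"]
            Lw = win.shape[1]
            g[f"W{w}"] = win.reshape(B * Lw, -1).T @ dz.reshape(B * Lw, F)
            g[f"b{w}"] = dz.sum(axis=(0, 1))
            dwin = dz @ p[f"W{w}"].T  # (B, Lw, w*D)
            for i in range(w):
                dXe[:, i : Lw + i, :] += dwin[:, :, i * D : (i + 1) * D]
        g["E"] = np.zeros_like(p["E"])
        np.add.at(g["E"], X.ravel(), dXe.reshape(-1, D))
        g["E"][0] = 0.0  # padding embedding stays fixed
        return g

    # -- sklearn-style API --------------------------------------------
    def fit(self, X, Y):
        """Fit on ``X`` (n, L) int token indices and ``Y`` (n, K) binary."""
        X = np.asarray(X, dtype=np.int64)
        Y = np.asarray(Y, dtype=np.float32)
        if Y.ndim == 1:
            Y = Y[:, None]
        if Y.shape[1] != self.n_outputs:
            raise ValueError(
                f"Y has {Y.shape[1]} columns, model expects {self.n_outputs}"
            )
        if X.shape[1] < max(self.conv_widths):
            raise ValueError("sequence length shorter than the widest convolution")
        rng = np.random.default_rng(self.seed)
        p = self._init_params(rng)
        m = {k: np.zeros_like(v) for k, v in p.items()}
        v2 = {k: np.zeros_like(v) for k, v in p.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        n = len(X)
        step = 0
        self.loss_history_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = np.zeros(self.n_outputs)
            n_batches = 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = X[idx], Y[idx]
                if self.dropout > 0:
                    mask = (
                        rng.random((len(idx), p["Wo"].shape[0])) >= self.dropout
                    ).astype(np.float32) / (1.0 - self.dropout)
                else:
                    mask = None
                logits, cache = self._forward(p, xb, train_mask=mask)
                probs = _sigmoid(logits)
                eps_ = 1e-7
                epoch_loss += -np.mean(
                    yb * np.log(probs + eps_) + (1 - yb) * np.log(1 - probs + eps_),
                    axis=0,
                )
                n_batches += 1
                dlogits = (probs - yb).astype(np.float32) / len(idx)
                g = self._backward(p, xb, cache, dlogits)
                step += 1
                for k in p:
                    m[k] = beta1 * m[k] + (1 - beta1) * g[k]
                    v2[k] = beta2 * v2[k] + (1 - beta2) * g[k] ** 2
                    mhat = m[k] / (1 - beta1 ** step)
                    vhat = v2[k] / (1 - beta2 ** step)
                    p[k] = p[k] - self.lr * mhat / (np.sqrt(vhat) + eps)
            self.loss_history_.append(epoch_loss / max(n_batches, 1))
        self.params_ = p
        return self

    def decision_function(self, X, batch_size=512):
        """Pre-sigmoid log-odds outputs, shape (n, n_outputs)."""
        X = np.asarray(X, dtype=np.int64)
        out = np.empty((len(X), self.n_outputs), dtype=np.float32)
        for start in range(0, len(X), batch_size):
            logits, _ = self._forward(self.params_, X[start : start + batch_size])
            out[start : start + len(logits)] = logits
        return out

    def predict_proba(self, X):
        return _sigmoid(self.decision_function(X))

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)
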