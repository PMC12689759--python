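"""Independently coded plain-autoencoder trainer used as an equivalence oracle.

A from-scratch MSE autoencoder (affine+ReLU encoder, mirrored decoder with a
sigmoid head) trained by Adam, sharing only the initialization and batch-order
conventions of the package trainer so that the ae_only ablation can be compared
against it epoch by epoch.
"""

import math

import numpy as np


def glorot_layers(dims, rng):
    out = []
    for i in range(len(dims) - 1):
        lim = math.sqrt(6.0 / (dims[i] + dims[i + 1]))
        out.append([rng.uniform(-lim, lim, size=(dims[i + 1], dims[i])),
                    np.zeros(dims[i + 1])])
    return out


def train_plain_ae(X, hidden, latent, init_seed, train_seed, *, lr=1e-4,
                   epochs=100, batch_size=64, l2=0.001, val_fraction=0.1,
                   patience=5, early_stopping=True):
    """Returns (per-epoch mean batch MSE list, final layer list)."""
    X = np.asarray(X, dtype=float)
    d = X.shape[1]
    rng_init = np.random.default_rng(init_seed)
    enc = glorot_layers([d] + list(hidden) + [latent], rng_init)
    dec = glorot_layers([latent] + list(hidden)[::-1] + [d], rng_init)
    layers = enc + dec
    n_enc = len(enc)

    rng = np.random.default_rng(train_seed)
    m = X.shape[0]
    n_val = int(np.floor(val_fraction * m))
    perm = rng.permutation(m)
    X_val, X_tr = X[perm[:n_val]], X[perm[n_val:]]
    bs = min(batch_size, X_tr.shape[0])

    mom = [[np.zeros_like(W), np.zeros_like(b)] for W, b in layers]
    vel = [[np.zeros_like(W), np.zeros_like(b)] for W, b in layers]
    t = 0

    def fwd(xb):
        acts = [xb]
        pre = []
        h = xb
        for k, (W, b) in enumerate(layers):
            a = h @ W.T + b
            pre.append(a)
            last = k == len(layers) - 1
            h = 1.0 / (1.0 + np.exp(-a)) if last else np.maximum(a, 0.0)
            acts.append(h)
        return acts, pre

    history = []
    best_val, best_bad = np.inf, 0
    for _ in range(epochs):
        order = rng.permutation(X_tr.shape[0])
        losses = []
        for s in range(0, X_tr.shape[0], bs):
            xb = X_tr[order[s : s + bs]]
            acts, pre = fwd(xb)
            xh = acts[-1]
            losses.append(np.mean((xb - xh) ** 2))
            delta = 2.0 * (xh - xb) / xb.size
            grads = [None] * len(layers)
            for k in reversed(range(len(layers))):
                a = pre[k]
                if k == len(layers) - 1:
                    s_ = acts[-1]
                    da = delta * s_ * (1.0 - s_)
                else:
                    da = delta * (a > 0)
                gW = da.T @ acts[k] + 2.0 * l2 * layers[k][0]
                gb = da.sum(axis=0)
                grads[k] = (gW, gb)
                delta = da @ layers[k][0]
            t += 1
            b1c = 1.0 - 0.9**t
            b2c = 1.0 - 0.999**t
            for k, (gW, gb) in enumerate(grads):
                for j, g in enumerate((gW, gb)):
                    mom[k][j] = 0.9 * mom[k][j] + 0.1 * g
                    vel[k][j] = 0.999 * vel[k][j] + 0.001 * g * g
                    layers[k][j] = layers[k][j] - lr * (mom[k][j] / b1c) / (
                        np.sqrt(vel[k][j] / b2c) + 1e-8
                    )
        history.append(float(np.mean(losses)))
        if n_val and early_stopping:
            acts, _ = fwd(X_val)
            v = float(np.mean((X_val - acts[-1]) ** 2))
            if v < best_val:
                best_val, best_bad = v, 0
            else:
                best_bad += 1
                if best_bad >= patience:
                    break
    return history, layers
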