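"""Training loop: Adam on the weighted reconstruction + KL objective.

Protocol defaults: batch size 64, up to 100 epochs, learning rate 1e-4,
early stopping with patience 5 on a held-out 10% validation slice of the
normal training rows, l2 weight decay (as an explicit penalty) with
lambda = 0.001.  Per-batch noise for the variational branch is drawn from a
seeded generator; validation passes use zero noise so the early-stopping
monitor is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ave_core import ModelConfig, ModelParams, backward_batch, forward_batch, init_params
from .losses import kl_loss, mse_loss, total_loss

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "TrainHistory", "Adam", "l2_penalty", "train_model"]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 64
    epochs: int = 100
    learning_rate: float = 0.0001
    optimizer: str = "adam"
    early_stopping: bool = True
    patience: int = 5
    validation_fraction: float = 0.1
    l2_lambda: float = 0.001
    kl_weight: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.early_stopping and self.patience < 1:
            raise ValueError("patience must be >= 1 when early stopping is on")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in [0, 1)")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.l2_lambda < 0 or self.kl_weight < 0:
            raise ValueError("l2_lambda and kl_weight must be nonnegative")


@dataclass
class TrainHistory:
    """Per-epoch loss trajectory and the early-stopping outcome."""

    train_total: list[float] = field(default_factory=list)
    val_total: list[float] = field(default_factory=list)
    mse: list[float] = field(default_factory=list)
    kl: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False

    @property
    def n_epochs(self) -> int:
        return len(self.train_total)


class Adam:
    """Adam with the conventional (0.9, 0.999, 1e-8) moment parameters."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: ModelParams, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for name, arr in params.named_arrays():
            g = grads.get(name)
            if g is None:
                continue
            g = np.asarray(g, dtype=float)
            m = self.m.setdefault(name, np.zeros_like(arr))
            v = self.v.setdefault(name, np.zeros_like(arr))
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            mhat = m / b1t
            vhat = v / b2t
            params.set_array(name, arr - self.lr * mhat / (np.sqrt(vhat) + self.eps))


def l2_penalty(params: ModelParams, l2_lambda: float) -> float:
    """lambda * sum of squared entries over weight matrices (biases excluded)."""
    if l2_lambda < 0:
        raise ValueError("l2_lambda must be nonnegative")
    if l2_lambda == 0:
        return 0.0
    return float(l2_lambda * sum(np.sum(W**2) for _, W in params.weight_matrices()))


def _epoch_losses(X, params, config, kl_weight):
    """Deterministic (eps=0) loss components on a full matrix."""
    xh, lat, _ = forward_batch(X, params, config, epsilon=None)
    m = mse_loss(X, xh)
    k = kl_loss(lat.mu_x, lat.sigma_x) if lat.mu_x is not None else 0.0
    return m, k, total_loss(m, k, kl_weight)


def train_model(
    X_normal,
    model_config: ModelConfig,
    train_config: TrainConfig = TrainConfig(),
) -> tuple[ModelParams, TrainHistory]:
    """Fit AVE to the (already MinMax-scaled) normal rows.

    Weights are initialized from ``model_config.seed``; batch order,
    validation split, and per-batch noise come from ``train_config.seed``.
    Early stopping monitors the validation total loss (zero-noise forward)
    and restores the best-epoch weights.  Fully reproducible given
    (seeds, data).
    """
    X = np.asarray(X_normal, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("training matrix must be 2-D with at least one row")
    m = X.shape[0]
    cfg, tc = model_config, train_config
    use_vae = cfg.branch != "ae_only"

    rng = np.random.default_rng(tc.seed)
    n_val = int(np.floor(tc.validation_fraction * m))
    perm = rng.permutation(m)
    X_val, X_tr = X[perm[:n_val]], X[perm[n_val:]]
    if X_tr.shape[0] == 0:
        raise ValueError("validation split left no training rows")
    batch = min(tc.batch_size, X_tr.shape[0])

    params = init_params(cfg, seed=cfg.seed)
    opt = Adam(tc.learning_rate)
    hist = TrainHistory()
    best_val = np.inf
    best_params = params.copy()
    best_epoch = 0
    bad_epochs = 0

    for epoch in range(tc.epochs):
        order = rng.permutation(X_tr.shape[0])
        batch_totals, batch_mses, batch_kls = [], [], []
        for start in range(0, X_tr.shape[0], batch):
            xb = X_tr[order[start : start + batch]]
            eps = rng.standard_normal((xb.shape[0], cfg.latent_dim)) if use_vae else None
            xh, lat, cache = forward_batch(xb, params, cfg, epsilon=eps)
            bm = mse_loss(xb, xh)
            bk = kl_loss(lat.mu_x, lat.sigma_x) if use_vae else 0.0
            bt = total_loss(bm, bk, tc.kl_weight)
            if not np.isfinite(bt):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {start // batch}"
                )
            grads = backward_batch(cache, params, cfg, tc.kl_weight)
            if tc.l2_lambda:
                for name, W in params.weight_matrices():
                    grads[name] = grads.get(name, 0.0) + 2.0 * tc.l2_lambda * W
            opt.step(params, grads)
            batch_totals.append(bt)
            batch_mses.append(bm)
            batch_kls.append(bk)

        hist.train_total.append(float(np.mean(batch_totals)))
        hist.mse.append(float(np.mean(batch_mses)))
        hist.kl.append(float(np.mean(batch_kls)))

        if n_val >= 1:
            _, _, val_tot = _epoch_losses(X_val, params, cfg, tc.kl_weight)
        else:
            val_tot = hist.train_total[-1]
        hist.val_total.append(val_tot)
        logger.info(
            "epoch %d train=%.6f val=%.6f mse=%.6f kl=%.6f",
            epoch, hist.train_total[-1], val_tot, hist.mse[-1], hist.kl[-1],
        )

        if val_tot < best_val:
            best_val = val_tot
            best_params = params.copy()
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if tc.early_stopping and bad_epochs >= tc.patience:
                hist.stopped_early = True
                break

    hist.best_epoch = best_epoch
    if tc.early_stopping:
        params = best_params
    return params, hist
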