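"""Training objective: reconstruction losses, KL regularizer, weighted total.

The total loss is ``MSE + lambda * KL`` with a small KL weight (default 0.1),
so the network primarily learns to reconstruct normal rows while the
variational branch's posterior is gently pulled toward N(0, I).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LossBreakdown", "mse_loss", "bce_loss", "kl_loss", "total_loss"]

DEFAULT_KL_WEIGHT = 0.1


@dataclass(frozen=True)
class LossBreakdown:
    """One evaluation of the objective, split into its components."""

    mse: float
    kl: float
    total: float
    kl_weight: float
    bce: float | None = None


def _check_pair(X, X_hat):
    X = np.asarray(X, dtype=float)
    X_hat = np.asarray(X_hat, dtype=float)
    if X.shape != X_hat.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {X_hat.shape}")
    if X.size == 0:
        raise ValueError("empty batch")
    return X, X_hat


def mse_loss(X, X_hat) -> float:
    """Mean squared error over all n*d elements."""
    X, X_hat = _check_pair(X, X_hat)
    return float(np.mean((X - X_hat) ** 2))


def bce_loss(X, X_hat) -> float:
    """Binary cross-entropy for inputs in [0,1], averaged over all elements.

    Predictions are clamped to [eps, 1-eps] at machine-epsilon margins so the
    logs stay finite.
    """
    X, X_hat = _check_pair(X, X_hat)
    if np.any(X < 0) or np.any(X > 1):
        raise ValueError("bce_loss requires targets in [0, 1]")
    eps = np.finfo(float).eps
    Xh = np.clip(X_hat, eps, 1.0 - eps)
    return float(-np.mean(X * np.log(Xh) + (1.0 - X) * np.log(1.0 - Xh)))


def kl_loss(mu_x, sigma_x) -> float:
    """KL divergence of the posterior N(mu, e^{sigma}) from the N(0,1) prior.

    ``sigma_x`` is the log-variance.  The value is the per-entry mean of
    ``-0.5 * (sigma - mu^2 - e^sigma + 1)`` over all batch and latent
    dimensions; it is zero exactly at the standard-normal posterior and
    positive everywhere else.
    """
    mu_x = np.asarray(mu_x, dtype=float)
    sigma_x = np.asarray(sigma_x, dtype=float)
    if mu_x.shape != sigma_x.shape:
        raise ValueError(f"shape mismatch: {mu_x.shape} vs {sigma_x.shape}")
    return float(-0.5 * np.mean(sigma_x - mu_x**2 - np.exp(sigma_x) + 1.0))


def total_loss(mse: float, kl: float, kl_weight: float = DEFAULT_KL_WEIGHT) -> float:
    """Weighted sum mse + kl_weight * kl."""
    if kl_weight < 0:
        raise ValueError("kl_weight must be nonnegative")
    return float(mse + kl_weight * kl)
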