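"""Anomaly scoring: per-sample reconstruction error, the contamination-driven
dynamic threshold, and binary prediction.

The anomaly score of a row is its mean squared reconstruction error.  The
threshold adapts to the score distribution: with an assumed contamination
rate ``c``, the errors are sorted ascending and the threshold is placed at
the order statistic below which the expected ``k = floor(N*c)`` anomalies
begin; samples strictly exceeding it are flagged.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .ave_core import ModelConfig, ModelParams, forward_batch
from .data_prep import TabularDataset

__all__ = [
    "ScoreResult",
    "reconstruction_error",
    "dynamic_threshold",
    "predict",
    "score_dataset",
    "write_scores",
]


@dataclass
class ScoreResult:
    """Per-sample errors plus the threshold decision."""

    errors: np.ndarray
    threshold: float
    contamination: float
    predicted: np.ndarray


def reconstruction_error(X, X_hat) -> np.ndarray:
    """Row-wise mean squared difference; its mean equals the batch MSE loss."""
    X = np.asarray(X, dtype=float)
    X_hat = np.asarray(X_hat, dtype=float)
    if X.shape != X_hat.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {X_hat.shape}")
    return np.mean((X - X_hat) ** 2, axis=-1)


def dynamic_threshold(errors, c: float) -> float:
    """Threshold at the point where the expected anomalies begin.

    Sorting the N errors ascending as e(1) <= ... <= e(N) and expecting
    k = floor(N*c) anomalies, the threshold is e(N-k) for k >= 1 and the
    maximum error for k = 0 (nothing exceeds it).  Ties at the threshold are
    not flagged (prediction uses strict >).
    """
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("empty error vector")
    if not 0.0 <= c < 1.0:
        raise ValueError(f"contamination must lie in [0, 1), got {c}")
    srt = np.sort(errors)
    k = math.floor(errors.size * c)
    if k >= 1:
        return float(srt[errors.size - k - 1])
    return float(srt[-1])


def predict(errors, threshold: float) -> np.ndarray:
    """Binary labels: 1 where the error strictly exceeds the threshold."""
    errors = np.asarray(errors, dtype=float)
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return (errors > threshold).astype(int)


def score_dataset(
    test: TabularDataset,
    params: ModelParams,
    model_config: ModelConfig,
    c: float,
    epsilon_mode="zero",
    train_X=None,
) -> ScoreResult:
    """Score a (pre-scaled) test set end to end.

    ``epsilon_mode`` is "zero" (deterministic, the default), an integer seed,
    or a numpy Generator for sampled latents.  When ``train_X`` is given the
    threshold is computed on the training-set errors instead of the test
    errors (a deployment mode for settings without test-set access).
    """
    if epsilon_mode == "zero" or epsilon_mode is None:
        eps_src = None
    elif isinstance(epsilon_mode, (int, np.integer)):
        eps_src = np.random.default_rng(int(epsilon_mode))
    else:
        eps_src = epsilon_mode
    xh, _, _ = forward_batch(test.X, params, model_config, epsilon=eps_src)
    errors = reconstruction_error(test.X, xh)
    if train_X is not None:
        xh_tr, _, _ = forward_batch(train_X, params, model_config, epsilon=None)
        theta = dynamic_threshold(reconstruction_error(train_X, xh_tr), c)
    else:
        theta = dynamic_threshold(errors, c)
    return ScoreResult(errors, theta, float(c), predict(errors, theta))


def write_scores(result: ScoreResult, path, seed: int | None = None) -> None:
    """Delimited-text scores plus a JSON sidecar with threshold metadata."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "sample_index": np.arange(result.errors.size),
            "error": result.errors,
            "predicted": result.predicted,
        }
    )
    df.to_csv(path, index=False)
    meta = {
        "threshold": result.threshold,
        "contamination": result.contamination,
        "seed": seed,
        "n": int(result.errors.size),
        "n_flagged": int(result.predicted.sum()),
    }
    with open(str(path) + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
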