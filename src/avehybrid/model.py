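"""Model-object facade: :class:`AVEDetector` (built from data, ``fit()``)
and :class:`AVEResults` (estimates, diagnostics, scoring, ``summary()``).

This is the convenience layer most users should start from::

    ds = generate_synthetic(n=2000, d=10, contamination=0.05, seed=0)
    model = AVEDetector(ds)            # or AVEDetector.from_dataframe(df)
    res = model.fit(seed=0)
    print(res.summary())
    scores = res.score()               # ScoreResult on the held-out test split

The functional modules (:mod:`~avehybrid.ave_core`, :mod:`~avehybrid.training`,
:mod:`~avehybrid.scoring`, ...) remain the primitive surface underneath.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .ave_core import ModelConfig, ModelParams, load_checkpoint, save_checkpoint
from .data_prep import (
    SplitSpec,
    TabularDataset,
    compute_outlier_fraction,
    contamination_rate,
)
from .evaluation import EvalReport, confusion_matrix, multi_trial_evaluate, run_trial
from .scoring import ScoreResult
from .training import TrainConfig, TrainHistory

__all__ = ["AVEDetector", "AVEResults"]


class AVEDetector:
    """Hybrid AE/VAE anomaly detector bound to a labeled tabular dataset.

    Parameters
    ----------
    data : TabularDataset, or array-like X
    y : array-like of {0,1}, required when ``data`` is a plain matrix
    config : ModelConfig, optional
        Architecture; defaults to hidden widths (64, 32), latent d/4
        clamped to [2, 32], averaged fusion, KL weight 0.1.
    """

    def __init__(self, data, y=None, config: ModelConfig | None = None, name="dataset"):
        if isinstance(data, TabularDataset):
            self.dataset = data
        else:
            if y is None:
                raise ValueError("y is required when data is a plain matrix")
            self.dataset = TabularDataset(np.asarray(data, dtype=float), y, name=name)
        self.config = (config or ModelConfig(input_dim=self.dataset.d)).replace(
            input_dim=self.dataset.d
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label_col: str = "y",
        config: ModelConfig | None = None, name: str = "dataset",
    ) -> "AVEDetector":
        if label_col not in df.columns:
            raise ValueError(f"label column {label_col!r} not in dataframe")
        X = df.drop(columns=[label_col])
        ds = TabularDataset(
            X.to_numpy(dtype=float), df[label_col].to_numpy(),
            [str(c) for c in X.columns], name,
        )
        return cls(ds, config=config)

    @property
    def contamination(self) -> float:
        """The dataset-adaptive contamination estimate f/3."""
        return contamination_rate(compute_outlier_fraction(self.dataset.y))

    def fit(
        self,
        train_config: TrainConfig | None = None,
        seed: int = 0,
        split_spec: SplitSpec | None = None,
        noise_rho: float = 0.0,
        contamination_override: float | None = None,
    ) -> "AVEResults":
        """Run one full pipeline pass (split, scale, filter, train, score)."""
        tc = train_config or TrainConfig(seed=seed, kl_weight=self.config.kl_weight)
        result, test, metrics = run_trial(
            self.dataset, self.config, tc, seed=seed, split_spec=split_spec,
            noise_rho=noise_rho, contamination_override=contamination_override,
        )
        return AVEResults(self, metrics["params"], metrics["history"], metrics["scaler"],
                          test, result, metrics, seed)

    def fit_trials(
        self, n_trials: int = 10, base_seed: int = 0,
        train_config: TrainConfig | None = None, noise_rho: float = 0.0,
    ) -> EvalReport:
        """Benchmark-style evaluation: mean +/- sd over independent trials."""
        tc = train_config or TrainConfig(kl_weight=self.config.kl_weight)
        return multi_trial_evaluate(
            self.dataset, self.config, tc, n_trials, base_seed, noise_rho=noise_rho
        )


class AVEResults:
    """Fitted-model container: parameters, training history, test scores."""

    def __init__(self, model: AVEDetector, params: ModelParams, history: TrainHistory,
                 scaler, test: TabularDataset, score_result: ScoreResult,
                 metrics: dict, seed: int):
        self.model = model
        self.params = params
        self.history = history
        self.scaler = scaler
        self.test = test
        self._score = score_result
        self.metrics = {k: metrics[k] for k in ("precision", "tpr", "fpr", "roc_auc")}
        self.confusion = metrics["confusion"]
        self.seed = seed

    def score(self) -> ScoreResult:
        """Per-sample errors, threshold, and predictions on the test split."""
        return self._score

    def predict(self) -> np.ndarray:
        return self._score.predicted

    def save(self, path) -> None:
        """Write a versioned single-file JSON checkpoint."""
        save_checkpoint(self.params, self.model.config, path)

    @staticmethod
    def load_params(path) -> tuple[ModelParams, ModelConfig]:
        return load_checkpoint(path)

    def summary(self) -> str:
        cfg = self.model.config
        c = self.confusion
        h = self.history
        lines = [
            "AVE hybrid anomaly detector — fit summary",
            "=" * 45,
            f"dataset:        {self.model.dataset.name} "
            f"(n={self.model.dataset.n}, d={self.model.dataset.d})",
            f"branch/fusion:  {cfg.branch} / {cfg.fusion_mode}",
            f"latent dim:     {cfg.latent_dim}   hidden: {list(cfg.hidden_dims)}",
            f"kl weight:      {cfg.kl_weight}   reparam: {cfg.reparam_variant}",
            f"seed:           {self.seed}",
            f"epochs run:     {h.n_epochs} (best {h.best_epoch}, "
            f"early stop: {h.stopped_early})",
            f"final val loss: {h.val_total[h.best_epoch]:.6f}",
            f"contamination:  {self._score.contamination:.6f}",
            f"threshold:      {self._score.threshold:.6f}",
            f"test flagged:   {int(self._score.predicted.sum())} of {self.test.n}",
            f"precision:      {self.metrics['precision']:.4f}",
            f"TPR / FPR:      {self.metrics['tpr']:.4f} / {self.metrics['fpr']:.4f}",
            f"ROC-AUC:        {self.metrics['roc_auc']:.4f}",
            f"confusion:      TP={c.tp} FP={c.fp} FN={c.fn} TN={c.tn}",
        ]
        return "\n".join(lines)

    # -- plotting (thin optional layer) -----------------------------------

    def plot_history(self, ax=None):
        """Training/validation loss curves per epoch."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        epochs = np.arange(self.history.n_epochs)
        ax.plot(epochs, self.history.train_total, label="train total")
        ax.plot(epochs, self.history.val_total, label="validation total")
        ax.axvline(self.history.best_epoch, ls="--", c="grey", label="best epoch")
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss")
        ax.legend()
        return ax

    def plot_errors(self, ax=None, bins=40):
        """Histogram of test reconstruction errors with the threshold."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        err = self._score.errors
        ax.hist(err[self.test.y == 0], bins=bins, alpha=0.6, label="normal")
        ax.hist(err[self.test.y == 1], bins=bins, alpha=0.6, label="outlier")
        ax.axvline(self._score.threshold, c="k", ls="--", label="threshold")
        ax.set_xlabel("reconstruction error")
        ax.set_ylabel("count")
        ax.legend()
        return ax
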