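"""Evaluation: confusion counts, precision, TPR/FPR, ROC-AUC, and the
multi-trial pipeline harness.

Outliers are the positive class throughout.  ROC-AUC is computed from the
continuous reconstruction errors (never from thresholded labels) and equals
the probability that a random outlier outscores a random inlier, ties
counting one half.  Benchmark-style results average 10 independent trials,
each re-splitting the data 60/40 and re-initializing the network.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .ave_core import ModelConfig
from .data_prep import (
    NoiseSpec,
    SplitSpec,
    TabularDataset,
    apply_minmax,
    compute_outlier_fraction,
    contamination_rate,
    filter_normals,
    fit_minmax,
    inject_label_noise,
    train_test_split,
)
from .scoring import score_dataset
from .training import TrainConfig, train_model

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion_matrix",
    "precision",
    "tpr_fpr",
    "roc_auc",
    "run_trial",
    "multi_trial_evaluate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class EvalReport:
    """Aggregated metrics over one or more trials."""

    dataset: str
    n: int
    d: int
    contamination: float
    n_trials: int
    precision_per_trial: list[float]
    roc_auc_per_trial: list[float]
    tpr_per_trial: list[float]
    fpr_per_trial: list[float]
    confusion: ConfusionCounts
    n_warnings: int = 0
    config: dict = field(default_factory=dict)

    @property
    def precision_mean(self) -> float:
        return float(np.mean(self.precision_per_trial))

    @property
    def precision_sd(self) -> float:
        return float(np.std(self.precision_per_trial))

    @property
    def roc_auc_mean(self) -> float:
        return float(np.mean(self.roc_auc_per_trial))

    @property
    def roc_auc_sd(self) -> float:
        return float(np.std(self.roc_auc_per_trial))

    def to_dict(self) -> dict:
        return {
            "dataset": self.dataset,
            "n": self.n,
            "d": self.d,
            "contamination": self.contamination,
            "trials": self.n_trials,
            "precision_mean": self.precision_mean,
            "precision_sd": self.precision_sd,
            "roc_auc_mean": self.roc_auc_mean,
            "roc_auc_sd": self.roc_auc_sd,
            "precision_per_trial": self.precision_per_trial,
            "roc_auc_per_trial": self.roc_auc_per_trial,
            "confusion": dataclasses.asdict(self.confusion),
            "n_warnings": self.n_warnings,
            "config": self.config,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kw)

    def to_text(self) -> str:
        lines = [f"dataset: {self.dataset} (n={self.n}, d={self.d})"]
        lines.append(f"contamination: {self.contamination:.6f}")
        lines.append(f"trials: {self.n_trials}")
        lines.append(f"precision: {self.precision_mean:.4f} +/- {self.precision_sd:.4f}")
        lines.append(f"roc_auc: {self.roc_auc_mean:.4f} +/- {self.roc_auc_sd:.4f}")
        c = self.confusion
        lines.append(f"confusion (last trial): TP={c.tp} FP={c.fp} FN={c.fn} TN={c.tn}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# metrics


def confusion_matrix(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    return ConfusionCounts(tp, fp, fn, tn)


def precision(cc: ConfusionCounts) -> float:
    """TP / (TP + FP); 0 with a warning when nothing was flagged."""
    if cc.tp + cc.fp == 0:
        warnings.warn("precision undefined (no predicted positives); returning 0")
        return 0.0
    return cc.tp / (cc.tp + cc.fp)


def tpr_fpr(cc: ConfusionCounts) -> tuple[float, float]:
    """(TP/(TP+FN), FP/(FP+TN)); degenerate denominators give 0 with a warning."""
    if cc.tp + cc.fn == 0:
        warnings.warn("TPR undefined (no actual positives); returning 0")
        tpr = 0.0
    else:
        tpr = cc.tp / (cc.tp + cc.fn)
    if cc.fp + cc.tn == 0:
        warnings.warn("FPR undefined (no actual negatives); returning 0")
        fpr = 0.0
    else:
        fpr = cc.fp / (cc.fp + cc.tn)
    return tpr, fpr


def roc_auc(scores, y_true) -> float:
    """Area under the ROC curve over all score thresholds (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true).astype(int)
    if scores.shape != y_true.shape:
        raise ValueError(f"length mismatch: {scores.shape} vs {y_true.shape}")
    if np.unique(y_true).size < 2:
        raise ValueError("AUC undefined: y_true contains a single class")
    return float(roc_auc_score(y_true, scores))


# ---------------------------------------------------------------------------
# multi-trial pipeline


def run_trial(
    ds: TabularDataset,
    model_config: ModelConfig,
    train_config: TrainConfig,
    seed: int,
    split_spec: SplitSpec | None = None,
    noise_rho: float = 0.0,
    contamination_override: float | None = None,
):
    """One full pipeline pass: split, (noise), scale, filter, train, score.

    The contamination estimate uses the full dataset's labels (the benchmark
    convention) unless overridden.  Returns (ScoreResult, test split,
    metrics dict).
    """
    split_spec = split_spec or SplitSpec(seed=seed)
    if split_spec.seed != seed:
        split_spec = dataclasses.replace(split_spec, seed=seed)
    f = compute_outlier_fraction(ds.y)
    c = contamination_rate(f, override=contamination_override)

    train, test = train_test_split(ds, split_spec)
    if noise_rho > 0:
        train = inject_label_noise(train, NoiseSpec(rho=noise_rho, seed=seed))
    scaler = fit_minmax(train.X)
    X_normal = apply_minmax(filter_normals(train), scaler)

    mc = model_config.replace(seed=seed)
    tc = dataclasses.replace(train_config, seed=seed)
    params, history = train_model(X_normal, mc, tc)

    test_scaled = TabularDataset(
        apply_minmax(test.X, scaler), test.y, list(test.feature_names), test.name
    )
    result = score_dataset(test_scaled, params, mc, c)

    cc = confusion_matrix(test.y, result.predicted)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        prec = precision(cc)
        tpr, fpr = tpr_fpr(cc)
        n_warn = len(caught)
    auc = roc_auc(result.errors, test.y)
    metrics = {
        "precision": prec,
        "tpr": tpr,
        "fpr": fpr,
        "roc_auc": auc,
        "confusion": cc,
        "n_warnings": n_warn,
        "history": history,
        "params": params,
        "scaler": scaler,
    }
    return result, test, metrics


def multi_trial_evaluate(
    ds: TabularDataset,
    model_config: ModelConfig,
    train_config: TrainConfig = TrainConfig(),
    n_trials: int = 10,
    base_seed: int = 0,
    noise_rho: float = 0.0,
    contamination_override: float | None = None,
) -> EvalReport:
    """Average the pipeline over ``n_trials`` seeds (base_seed + t)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    precs, aucs, tprs, fprs = [], [], [], []
    cc = None
    n_warn = 0
    for t in range(n_trials):
        seed = base_seed + t
        try:
            _, _, m = run_trial(
                ds,
                model_config,
                train_config,
                seed=seed,
                noise_rho=noise_rho,
                contamination_override=contamination_override,
            )
        except Exception as exc:
            raise RuntimeError(f"trial with seed {seed} failed: {exc}") from exc
        precs.append(m["precision"])
        aucs.append(m["roc_auc"])
        tprs.append(m["tpr"])
        fprs.append(m["fpr"])
        cc = m["confusion"]
        n_warn += m["n_warnings"]

    f = compute_outlier_fraction(ds.y)
    return EvalReport(
        dataset=ds.name,
        n=ds.n,
        d=ds.d,
        contamination=contamination_rate(f, override=contamination_override),
        n_trials=n_trials,
        precision_per_trial=precs,
        roc_auc_per_trial=aucs,
        tpr_per_trial=tprs,
        fpr_per_trial=fprs,
        confusion=cc,
        n_warnings=n_warn,
        config={
            "model": dataclasses.asdict(model_config),
            "train": dataclasses.asdict(train_config),
            "base_seed": base_seed,
            "noise_rho": noise_rho,
        },
    )
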