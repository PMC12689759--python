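"""Dataset I/O, preprocessing chain, contamination arithmetic, label-noise
injection, and the synthetic benchmark generator.

The preprocessing chain mirrors the detector's intended deployment: optional
feature selection, a stratified 60/40 train/test split, MinMax scaling fitted
on the training rows only, and filtering of the training split down to its
normal (label 0) rows, since the model is fitted to normal data exclusively.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split as _sk_split

logger = logging.getLogger(__name__)

__all__ = [
    "TabularDataset",
    "ScalerParams",
    "SplitSpec",
    "NoiseSpec",
    "ThresholdInputs",
    "BENCHMARK_TABLE",
    "load_dataset",
    "select_features",
    "train_test_split",
    "fit_minmax",
    "apply_minmax",
    "filter_normals",
    "compute_outlier_fraction",
    "contamination_rate",
    "inject_label_noise",
    "generate_synthetic",
]


@dataclass
class TabularDataset:
    """A labeled tabular dataset: rows are samples, label 1 marks outliers."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    name: str = "dataset"

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {self.X.shape}")
        if self.y.ndim == 2 and self.y.shape[1] == 1:
            self.y = self.y.ravel()
        if self.y.ndim != 1 or self.y.shape[0] != self.X.shape[0]:
            raise ValueError(
                f"label length {self.y.shape} does not match {self.X.shape[0]} rows"
            )
        vals = np.unique(self.y)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError(f"labels must be binary 0/1, found values {vals}")
        self.y = self.y.astype(int)
        if np.isnan(self.X).any():
            i, j = np.argwhere(np.isnan(self.X))[0]
            raise ValueError(f"NaN value at row {i}, column {j}")
        if not self.feature_names:
            self.feature_names = [f"f{i + 1}" for i in range(self.X.shape[1])]
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length does not match number of columns")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def n_outliers(self) -> int:
        return int(self.y.sum())

    def subset(self, idx, name_suffix: str = "") -> "TabularDataset":
        return TabularDataset(
            self.X[idx], self.y[idx], list(self.feature_names), self.name + name_suffix
        )

    def to_dataframe(self, label_col: str = "y") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df[label_col] = self.y
        return df


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature min/max learned from training rows only."""

    min_: np.ndarray
    max_: np.ndarray


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.6
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly between 0 and 1")


@dataclass(frozen=True)
class NoiseSpec:
    """Flip floor(rho * #train anomalies) anomaly labels to normal."""

    rho: float
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("noise rate rho must lie in [0, 1]")


@dataclass(frozen=True)
class ThresholdInputs:
    outlier_fraction: float
    contamination: float


# The 16 public outlier-detection benchmarks commonly used for this task
# (ODDS convention): name, domain, n samples, d features, outlier count,
# printed outlier percentage.
BENCHMARK_TABLE = [
    ("Arrhythmia", "Healthcare", 452, 274, 66, 14.6),
    ("Cardio", "Healthcare", 1831, 21, 176, 9.61),
    ("Glass", "Forensic", 214, 7, 9, 4.21),
    ("Ionosphere", "Oryctognosy", 351, 33, 126, 35.9),
    ("Letter", "Image", 1600, 32, 100, 6.25),
    ("Lympho", "Healthcare", 148, 18, 6, 4.05),
    ("Mnist", "Image", 7603, 100, 700, 9.21),
    ("Musk", "Chemistry", 3062, 166, 97, 3.17),
    ("Optdigits", "Image", 5216, 64, 150, 2.88),
    ("Pendigits", "Image", 6870, 16, 156, 2.27),
    ("Pima", "Healthcare", 768, 8, 268, 34.9),
    ("Satellite", "Astronautics", 6435, 36, 2036, 31.64),
    ("satimage-2", "Astronautics", 5803, 36, 71, 1.22),
    ("Shuttle", "Astronautics", 49097, 9, 3511, 7.15),
    ("Vowels", "Linguistics", 1456, 12, 50, 3.43),
    ("Wbc", "Healthcare", 378, 30, 21, 5.56),
]


# ---------------------------------------------------------------------------
# loading


def load_dataset(path, format: str | None = None, label_col: str = "y", name: str | None = None):
    """Load a labeled dataset from disk.

    Formats: ``delimited_text`` (header row, label column, default name "y"),
    ``array_container`` (.npz with arrays X and y), ``odds_matrix`` (.mat with
    variables X (n x d) and y (n x 1)).  ``format=None`` infers from the
    file extension.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {
            ".csv": "delimited_text",
            ".tsv": "delimited_text",
            ".txt": "delimited_text",
            ".npz": "array_container",
            ".mat": "odds_matrix",
        }.get(path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer format from extension {path.suffix!r}")
    name = name or path.stem

    if format == "delimited_text":
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        df = pd.read_csv(path, sep=sep)
        if label_col not in df.columns:
            raise ValueError(
                f"label column {label_col!r} not found; columns are {list(df.columns)}"
            )
        y = df[label_col].to_numpy()
        Xdf = df.drop(columns=[label_col])
        if Xdf.isna().any().any():
            col = Xdf.columns[Xdf.isna().any()][0]
            row = int(Xdf[col].isna().idxmax())
            raise ValueError(f"NaN value at row {row}, column {col!r}")
        ds = TabularDataset(Xdf.to_numpy(dtype=float), y, list(Xdf.columns), name)
    elif format == "array_container":
        with np.load(path) as z:
            if "X" not in z or "y" not in z:
                raise ValueError("array container must hold arrays named X and y")
            ds = TabularDataset(z["X"], z["y"], name=name)
    elif format == "odds_matrix":
        from scipy.io import loadmat

        mat = loadmat(path)
        if "X" not in mat or "y" not in mat:
            raise ValueError("matrix file must hold variables named X and y")
        ds = TabularDataset(mat["X"], np.asarray(mat["y"]).ravel(), name=name)
    else:
        raise ValueError(f"unknown format {format!r}")

    logger.info(
        "loaded %s: n=%d d=%d outliers=%d fraction=%.4f",
        ds.name, ds.n, ds.d, ds.n_outliers, ds.n_outliers / ds.n,
    )
    return ds


# ---------------------------------------------------------------------------
# preprocessing


def select_features(ds: TabularDataset, method: str = "identity", threshold: float = 0.0):
    """Optional feature selection: no-op, or drop low-variance features."""
    if method == "identity":
        return ds
    if method == "variance_threshold":
        var = ds.X.var(axis=0)
        keep = var > threshold
        if not keep.any():
            raise ValueError("variance_threshold would drop every feature")
        names = [n for n, k in zip(ds.feature_names, keep) if k]
        return TabularDataset(ds.X[:, keep], ds.y, names, ds.name)
    raise ValueError(f"unknown feature-selection method {method!r}")


def train_test_split(ds: TabularDataset, spec: SplitSpec = SplitSpec()):
    """Seeded (stratified by default) split into train/test TabularDatasets."""
    idx = np.arange(ds.n)
    strat = ds.y if spec.stratified else None
    if spec.stratified:
        counts = np.bincount(ds.y, minlength=2)
        if counts.min() < 2:
            raise ValueError(
                "stratified split needs at least 2 members per class "
                f"(counts {counts.tolist()}); use stratified=False"
            )
    tr, te = _sk_split(
        idx,
        train_size=spec.train_fraction,
        random_state=spec.seed,
        stratify=strat,
        shuffle=True,
    )
    return ds.subset(np.sort(tr), ":train"), ds.subset(np.sort(te), ":test")


def fit_minmax(train_X) -> ScalerParams:
    """Learn per-feature min/max from training rows only."""
    train_X = np.asarray(train_X, dtype=float)
    if train_X.ndim != 2 or train_X.shape[0] == 0:
        raise ValueError("training matrix must be 2-D and non-empty")
    return ScalerParams(train_X.min(axis=0), train_X.max(axis=0))


def apply_minmax(X, scaler: ScalerParams) -> np.ndarray:
    """(x - min) / (max - min); constant features map to 0; no clipping, so
    test values outside the training range legitimately leave [0, 1]."""
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != scaler.min_.shape[0]:
        raise ValueError(
            f"scaler expects {scaler.min_.shape[0]} features, got {X.shape[-1]}"
        )
    span = scaler.max_ - scaler.min_
    safe = np.where(span == 0, 1.0, span)
    return (X - scaler.min_) / safe


def filter_normals(train: TabularDataset) -> np.ndarray:
    """Training rows with label 0, order preserved (the model's training set)."""
    mask = train.y == 0
    if not mask.any():
        raise ValueError("no normal (label 0) rows available for training")
    return train.X[mask]


def compute_outlier_fraction(y) -> float:
    """f = (number of anomalies) / n."""
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("empty label vector")
    return float(np.sum(y)) / y.size


def contamination_rate(f: float, override: float | None = None) -> float:
    """c = f / 3, the conservative contamination estimate; an explicit
    ``override`` replaces the computed value."""
    if override is not None:
        return float(override)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"outlier fraction must lie in [0, 1], got {f}")
    return f / 3.0


def inject_label_noise(train: TabularDataset, spec: NoiseSpec) -> TabularDataset:
    """Flip floor(rho * #anomalies) anomaly labels (1 -> 0), seeded, X untouched.

    Applied to the training split before normal-filtering, so flipped
    anomalies contaminate the normal-only training pool.
    """
    anom_idx = np.flatnonzero(train.y == 1)
    n_flip = math.floor(spec.rho * anom_idx.size)
    y = train.y.copy()
    if n_flip > 0:
        rng = np.random.default_rng(spec.seed)
        flip = rng.choice(anom_idx, size=n_flip, replace=False)
        y[flip] = 0
    return TabularDataset(train.X.copy(), y, list(train.feature_names), train.name)


# ---------------------------------------------------------------------------
# synthetic benchmark generator

_MECHANISMS = ("uniform_background", "shifted_cluster", "scaled_covariance")


def generate_synthetic(
    n: int = 2000,
    d: int = 10,
    contamination: float = 0.05,
    mechanism: str = "shifted_cluster",
    separation: float = 8.0,
    n_clusters: int = 1,
    seed: int = 0,
    name: str | None = None,
) -> TabularDataset:
    """Gaussian inlier clusters with a planted fraction of outliers.

    Inliers are drawn from a mixture of ``n_clusters`` unit-covariance
    Gaussians (cluster centres at N(0, 9 I) when there is more than one).
    Outliers, ``round(n * contamination)`` of them, follow the chosen
    mechanism:

    - ``uniform_background``: uniform over the box enclosing the inliers,
      widened by one unit per side;
    - ``shifted_cluster``: a unit-covariance Gaussian whose centre is
      displaced from the inlier centre of mass by ``separation`` (in inlier
      standard deviations) along a random direction;
    - ``scaled_covariance``: centred on the inlier clusters but with
      covariance ``separation * I``.
    """
    if not 0.0 < contamination < 0.5:
        raise ValueError("contamination must lie in (0, 0.5)")
    if separation < 0:
        raise ValueError("separation must be nonnegative")
    if mechanism not in _MECHANISMS:
        raise ValueError(f"mechanism must be one of {_MECHANISMS}")
    rng = np.random.default_rng(seed)
    n_out = int(round(n * contamination))
    n_in = n - n_out

    if n_clusters == 1:
        centers = np.zeros((1, d))
    else:
        centers = rng.normal(0.0, 3.0, size=(n_clusters, d))
    assign = rng.integers(0, n_clusters, size=n_in)
    X_in = centers[assign] + rng.standard_normal((n_in, d))

    if mechanism == "uniform_background":
        lo, hi = X_in.min(axis=0) - 1.0, X_in.max(axis=0) + 1.0
        X_out = rng.uniform(lo, hi, size=(n_out, d))
    elif mechanism == "shifted_cluster":
        u = rng.standard_normal(d)
        u /= np.linalg.norm(u)
        center_out = centers.mean(axis=0) + separation * u
        X_out = center_out + rng.standard_normal((n_out, d))
    else:  # scaled_covariance
        assign_out = rng.integers(0, n_clusters, size=n_out)
        X_out = centers[assign_out] + math.sqrt(max(separation, 1e-12)) * rng.standard_normal(
            (n_out, d)
        )

    X = np.vstack([X_in, X_out])
    y = np.concatenate([np.zeros(n_in, dtype=int), np.ones(n_out, dtype=int)])
    perm = rng.permutation(n)
    return TabularDataset(
        X[perm], y[perm], name=name or f"synthetic-{mechanism}"
    )
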