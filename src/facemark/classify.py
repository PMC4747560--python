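"""KNN and PNN emotion classifiers with stratified cross-validation.

The K-nearest-neighbour rule uses the Euclidean metric and majority
vote (default K=5).  The probabilistic neural network is a Parzen
classifier with an isotropic Gaussian kernel: the score of class c for
a query x is the class-averaged kernel sum

    score_c(x) = (1/n_c) * sum_{i in c} exp(-||x - x_i||^2 / (2 sigma^2))

and the prediction is the argmax over classes.  The spread sigma is
swept over a grid (default 0.01–0.1 in 0.01 steps) and the best value
per table cell is reported alongside the accuracies.

Recognition rates are tabulated per emotion, in percent, with Average
and Std Dev (n-1) summary rows over the six emotions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .features import SCHEMES, NormalizationSpec

#: The six basic emotions, in canonical (alphabetical) order.
EMOTIONS: tuple[str, ...] = (
    "anger", "disgust", "fear", "happiness", "sadness", "surprise",
)

DEFAULT_SIGMA_GRID: tuple[float, ...] = tuple(
    round(0.01 * i, 2) for i in range(1, 11)
)


class ClassifierError(ValueError):
    pass


@dataclass
class LabeledTrialSet:
    """Feature matrix with emotion labels (and optional subject ids)."""

    X: np.ndarray
    y: np.ndarray
    subjects: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ClassifierError("feature matrix and labels disagree")
        if self.subjects is not None:
            self.subjects = np.asarray(self.subjects)
            if len(self.subjects) != len(self.y):
                raise ClassifierError("subjects and labels disagree")

    def __len__(self) -> int:
        return len(self.y)


def knn_predict(
    X_train: np.ndarray, y_train: np.ndarray, query: np.ndarray, k: int = 5
) -> str:
    """Majority label among the k Euclidean-nearest training rows.

    Ties are broken by the smallest summed distance of the tied labels'
    neighbours, then lexicographically.
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    y_train = np.asarray(y_train)
    n = len(X_train)
    if n == 0:
        raise ClassifierError("empty training set")
    if not 1 <= k <= n:
        raise ClassifierError(f"k={k} outside [1, {n}]")
    d = np.linalg.norm(X_train - np.asarray(query, dtype=np.float64), axis=1)
    idx = np.argsort(d, kind="stable")[:k]
    labels, counts = np.unique(y_train[idx], return_counts=True)
    best = counts.max()
    tied = labels[counts == best]
    if len(tied) == 1:
        return str(tied[0])
    sums = {
        lab: d[idx][y_train[idx] == lab].sum() for lab in tied
    }
    min_sum = min(sums.values())
    finalists = sorted(lab for lab, s in sums.items() if s == min_sum)
    return str(finalists[0])


def pnn_scores(
    X_train: np.ndarray, y_train: np.ndarray, query: np.ndarray, sigma: float
) -> dict[str, float]:
    """Parzen class scores (class-averaged Gaussian kernel sums)."""
    if sigma <= 0:
        raise ClassifierError("sigma must be positive")
    X_train = np.asarray(X_train, dtype=np.float64)
    y_train = np.asarray(y_train)
    if len(X_train) == 0:
        raise ClassifierError("empty training set")
    q = np.asarray(query, dtype=np.float64)
    sq = np.sum((X_train - q) ** 2, axis=1)
    kern = np.exp(-sq / (2.0 * sigma**2))
    scores: dict[str, float] = {}
    for lab in np.unique(y_train):
        mask = y_train == lab
        if not mask.any():
            warnings.warn(f"class {lab!r} has no training examples; excluded")
            continue
        scores[str(lab)] = float(kern[mask].mean())
    return scores


def pnn_predict(
    X_train: np.ndarray, y_train: np.ndarray, query: np.ndarray, sigma: float
) -> tuple[str, dict[str, float]]:
    """Argmax PNN prediction; ties resolve lexicographically."""
    scores = pnn_scores(X_train, y_train, query, sigma)
    best = max(scores.values())
    label = sorted(lab for lab, s in scores.items() if s == best)[0]
    return label, scores


@dataclass
class AccuracyTable:
    """Per-emotion recognition rates (%) with summary rows."""

    rates: dict[str, float]
    sigma: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def average(self) -> float:
        return float(np.mean(list(self.rates.values())))

    @property
    def std_dev(self) -> float:
        return float(np.std(list(self.rates.values()), ddof=1))


def summarize_rates(rates: Sequence[float]) -> tuple[float, float]:
    """Average and Std Dev (n-1) summary of per-emotion rates."""
    arr = np.asarray(rates, dtype=np.float64)
    return float(arr.mean()), float(arr.std(ddof=1))


@dataclass
class ClassifierConfig:
    kind: str = "pnn"                      # "knn" | "pnn"
    k: int = 5
    sigma: float | None = None             # fixed spread; None -> sweep grid
    sigma_grid: Sequence[float] = DEFAULT_SIGMA_GRID


def _predict_fold(
    X_tr: np.ndarray, y_tr: np.ndarray, X_te: np.ndarray,
    cfg: ClassifierConfig, sigma: float | None,
) -> list[str]:
    preds = []
    for q in X_te:
        if cfg.kind == "knn":
            preds.append(knn_predict(X_tr, y_tr, q, k=cfg.k))
        elif cfg.kind == "pnn":
            preds.append(pnn_predict(X_tr, y_tr, q, sigma)[0])
        else:
            raise ClassifierError(f"unknown classifier kind {cfg.kind!r}")
    return preds


def _cv_rates(
    data: LabeledTrialSet,
    cfg: ClassifierConfig,
    sigma: float | None,
    normalization: str,
    folds: list[tuple[np.ndarray, np.ndarray]],
) -> dict[str, float]:
    correct: dict[str, int] = {}
    total: dict[str, int] = {}
    for train_idx, test_idx in folds:
        X_tr, X_te = data.X[train_idx], data.X[test_idx]
        y_tr, y_te = data.y[train_idx], data.y[test_idx]
        if normalization != "none":
            spec = NormalizationSpec(normalization).fit(X_tr)
            X_tr, X_te = spec.apply(X_tr), spec.apply(X_te)
        preds = _predict_fold(X_tr, y_tr, X_te, cfg, sigma)
        for truth, pred in zip(y_te, preds):
            total[truth] = total.get(truth, 0) + 1
            if truth == pred:
                correct[truth] = correct.get(truth, 0) + 1
    return {
        lab: 100.0 * correct.get(lab, 0) / total[lab] for lab in sorted(total)
    }


def make_folds(
    data: LabeledTrialSet,
    n_folds: int = 10,
    seed: int = 0,
    subject_grouped: bool = False,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified (optionally subject-grouped) fold index pairs."""
    _, counts = np.unique(data.y, return_counts=True)
    if counts.min() < n_folds:
        raise ClassifierError(
            f"cannot build {n_folds} stratified folds with only "
            f"{counts.min()} trials in the smallest class"
        )
    if counts.min() < 10:
        warnings.warn(
            f"fewer than 10 trials per emotion ({counts.min()}); "
            "rates will be coarse"
        )
    if subject_grouped:
        if data.subjects is None:
            raise ClassifierError("subject-grouped CV needs subject ids")
        splitter = StratifiedGroupKFold(
            n_splits=n_folds, shuffle=True, random_state=seed
        )
        return list(splitter.split(data.X, data.y, groups=data.subjects))
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(splitter.split(data.X, data.y))


def cross_validate(
    data: LabeledTrialSet,
    config: ClassifierConfig | Mapping | None = None,
    seed: int = 0,
    *,
    normalization: str = "none",
    n_folds: int = 10,
    subject_grouped: bool = False,
) -> AccuracyTable:
    """Stratified k-fold cross-validated recognition rates.

    Per-emotion rate = correctly classified trials of that emotion over
    all trials of that emotion, pooled across folds, in percent.  For a
    PNN without a fixed sigma the spread grid is swept and the value
    with the highest mean rate is reported.
    """
    if isinstance(config, Mapping):
        config = ClassifierConfig(**config)
    cfg = config or ClassifierConfig()
    if normalization not in SCHEMES:
        raise ClassifierError(f"unknown normalization {normalization!r}")
    folds = make_folds(data, n_folds=n_folds, seed=seed,
                       subject_grouped=subject_grouped)
    meta = {"classifier": cfg.kind.upper(), "normalization": normalization,
            "n_folds": n_folds, "seed": seed}
    if cfg.kind == "knn":
        rates = _cv_rates(data, cfg, None, normalization, folds)
        meta["k"] = cfg.k
        return AccuracyTable(rates, meta=meta)
    sigmas = [cfg.sigma] if cfg.sigma is not None else list(cfg.sigma_grid)
    best: AccuracyTable | None = None
    for sigma in sigmas:
        rates = _cv_rates(data, cfg, sigma, normalization, folds)
        table = AccuracyTable(rates, sigma=sigma, meta=meta)
        if best is None or table.average > best.average:
            best = table
    assert best is not None
    return best


def accuracy_grid_frame(
    tables: Mapping[tuple[str, str], AccuracyTable]
) -> pd.DataFrame:
    """Lay out accuracy tables keyed by (normalization, statistic) as
    one table: emotion rows plus Average and Std Dev, one column per
    (normalization, statistic) cell."""
    cols = {}
    for (norm, stat), table in tables.items():
        col = {emo: table.rates.get(emo, np.nan) for emo in EMOTIONS}
        col["Average"] = table.average
        col["Std Dev"] = table.std_dev
        name = f"{norm}/{stat}" + (
            f" (sig={table.sigma:g})" if table.sigma is not None else ""
        )
        cols[name] = col
    return pd.DataFrame(cols)
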