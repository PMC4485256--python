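"""Nearest-shrunken-centroid classification.

The classifier standardizes each class centroid's deviation from the
overall centroid,

    d_ik = (xbar_ik - xbar_i) / (m_k * (s_i + s0)),
    m_k  = sqrt(1/n_k - 1/n),

where s_i is the pooled within-class standard deviation of feature i
(n - K degrees of freedom) and s0 = median_i(s_i) guards against
near-zero variances. Soft-thresholding by Delta,

    d'_ik = sign(d_ik) * max(|d_ik| - Delta, 0),

zeroes uninformative features; a sample x is assigned to the class
minimizing the discriminant

    delta_k(x) = sum_i (x_i - xbar'_ik)^2 / (s_i + s0)^2 - 2 log(pi_k),

where xbar'_ik = xbar_i + m_k (s_i + s0) d'_ik is the shrunken centroid.
m_k uses 1/n_k - 1/n, the exact variance factor of (class mean - overall
mean); ties are broken lexicographically by class label.

Cross-validation sweeps a Delta grid and records overall and per-class
misclassification; the operating threshold is the largest grid value
attaining the minimum overall error — the smallest gene set immediately
before the error rate escalates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CentroidModel:
    """Fitted NSC state. Arrays are features x classes unless noted."""

    features: tuple[str, ...]
    classes: tuple[str, ...]  # lexicographically sorted
    n_k: np.ndarray  # per class
    centroids: np.ndarray  # xbar_ik
    overall: np.ndarray  # xbar_i, per feature
    s: np.ndarray  # pooled within-class SD, per feature
    s0: float
    m_k: np.ndarray  # per class
    d: np.ndarray  # unshrunk standardized deviations
    d_shrunk: np.ndarray
    priors: np.ndarray  # per class, sums to 1
    delta: float = 0.0

    @property
    def n(self) -> int:
        return int(self.n_k.sum())

    @property
    def shrunken_centroids(self) -> np.ndarray:
        return self.overall[:, None] + self.m_k[None, :] * (
            (self.s + self.s0)[:, None] * self.d_shrunk
        )


def fit(
    expr: pd.DataFrame, labels: pd.Series, priors: str = "proportions"
) -> CentroidModel:
    """Fit class centroids and standardized deviations (no shrinkage yet).

    ``expr`` is features x samples; ``labels`` maps sample id to class.
    ``priors`` is ``"proportions"`` (n_k/n) or ``"uniform"``.
    """
    labels = labels.reindex(expr.columns)
    if labels.isna().any():
        raise ValueError("every sample column needs a class label")
    classes = tuple(sorted(labels.unique()))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if expr.shape[0] < 1:
        raise ValueError("need at least 1 feature")

    X = expr.to_numpy(float)
    n = X.shape[1]
    K = len(classes)
    n_k = np.array([(labels == k).sum() for k in classes])
    if (n_k < 2).any():
        bad = [k for k, c in zip(classes, n_k) if c < 2]
        raise ValueError(f"classes with fewer than 2 samples: {bad}")

    centroids = np.column_stack(
        [X[:, (labels == k).to_numpy()].mean(axis=1) for k in classes]
    )
    overall = X.mean(axis=1)
    within_ss = np.zeros(X.shape[0])
    for j, k in enumerate(classes):
        sub = X[:, (labels == k).to_numpy()]
        within_ss += ((sub - centroids[:, j][:, None]) ** 2).sum(axis=1)
    s = np.sqrt(within_ss / (n - K))
    s0 = float(np.median(s))
    m_k = np.sqrt(1.0 / n_k - 1.0 / n)
    d = (centroids - overall[:, None]) / (m_k[None, :] * (s + s0)[:, None])

    if priors == "proportions":
        pi = n_k / n
    elif priors == "uniform":
        pi = np.full(K, 1.0 / K)
    else:
        raise ValueError("priors must be 'proportions' or 'uniform'")

    return CentroidModel(
        features=tuple(expr.index),
        classes=classes,
        n_k=n_k,
        centroids=centroids,
        overall=overall,
        s=s,
        s0=s0,
        m_k=m_k,
        d=d,
        d_shrunk=d.copy(),
        priors=pi,
        delta=0.0,
    )


def shrink(model: CentroidModel, delta: float) -> CentroidModel:
    """Soft-threshold the standardized deviations by ``delta``."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    d_shrunk = np.sign(model.d) * np.maximum(np.abs(model.d) - delta, 0.0)
    return replace(model, d_shrunk=d_shrunk, delta=float(delta))


def discriminant_scores(model: CentroidModel, X: pd.DataFrame) -> pd.DataFrame:
    """Per-sample, per-class discriminant delta_k(x) (lower is closer)."""
    missing = [f for f in model.features if f not in X.index]
    if missing:
        raise KeyError(f"sample profile missing model features: {missing[:5]}")
    V = X.loc[list(model.features)].to_numpy(float)  # features x samples
    sc = model.shrunken_centroids
    denom = (model.s + model.s0) ** 2
    scores = np.empty((V.shape[1], len(model.classes)))
    for j in range(len(model.classes)):
        scores[:, j] = (
            ((V - sc[:, j][:, None]) ** 2) / denom[:, None]
        ).sum(axis=0) - 2.0 * np.log(model.priors[j])
    return pd.DataFrame(scores, index=X.columns, columns=list(model.classes))


def predict(model: CentroidModel, X: pd.DataFrame) -> pd.Series:
    """Class label per sample; ties go to the lexicographically first class."""
    scores = discriminant_scores(model, X)
    # columns are sorted class labels, so idxmin's first-match rule is the
    # documented lexicographic tie-break
    return scores.idxmin(axis=1).rename("predicted")


def selected_genes(model: CentroidModel, delta: float | None = None) -> pd.DataFrame:
    """Features with a surviving (nonzero) shrunken deviation in any class.

    Returns a features x classes table of d' values for the survivors —
    the signature export behind per-class heat maps.
    """
    m = model if delta is None else shrink(model, delta)
    mask = (m.d_shrunk != 0).any(axis=1)
    return pd.DataFrame(
        m.d_shrunk[mask], index=[f for f, keep in zip(m.features, mask) if keep],
        columns=list(m.classes),
    )


def default_grid(model: CentroidModel, n_points: int = 30) -> np.ndarray:
    """Evenly spaced Delta grid from 0 to max |d_ik| inclusive."""
    return np.linspace(0.0, float(np.abs(model.d).max()), n_points)


def _make_folds(
    labels: pd.Series, folds: int | None, seed: int
) -> list[np.ndarray]:
    """Stratified fold assignment; leave-one-out when a class is small."""
    n = len(labels)
    min_class = labels.value_counts().min()
    if folds is None:
        folds = n if min_class < 8 else min(10, int(min_class))
    if folds >= n:  # leave-one-out: deterministic, no randomness
        return [np.array([i]) for i in range(n)]
    if folds > min_class:
        raise ValueError(
            f"{folds} folds exceed the smallest class size {min_class}"
        )
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    for k in labels.unique():
        idx = np.flatnonzero((labels == k).to_numpy())
        idx = rng.permutation(idx)
        for fold, chunk in enumerate(np.array_split(idx, folds)):
            assignment[chunk] = fold
    return [np.flatnonzero(assignment == f) for f in range(folds)]


def cross_validate(
    expr: pd.DataFrame,
    labels: pd.Series,
    grid: np.ndarray | None = None,
    folds: int | None = None,
    seed: int = 0,
    priors: str = "proportions",
) -> pd.DataFrame:
    """Misclassification-vs-threshold curve by (stratified or LOO) CV.

    Returns one row per grid Delta: overall CV error, per-class error
    columns ``err_<class>``, and the number of features surviving that
    Delta in the full-data fit (non-increasing in Delta).
    """
    labels = labels.reindex(expr.columns)
    full = fit(expr, labels, priors=priors)
    if grid is None:
        grid = default_grid(full)
    grid = np.asarray(grid, dtype=float)

    fold_indices = _make_folds(labels, folds, seed)
    classes = full.classes
    y = labels.to_numpy()
    wrong = np.zeros(len(grid))
    wrong_per_class = np.zeros((len(grid), len(classes)))
    for test_idx in fold_indices:
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        train_labels = labels.iloc[train_mask.nonzero()[0]]
        if set(train_labels.unique()) != set(classes):
            raise ValueError("a class is absent from a training fold")
        m = fit(expr.iloc[:, train_mask], train_labels, priors=priors)
        test_X = expr.iloc[:, test_idx]
        for gi, delta in enumerate(grid):
            pred = predict(shrink(m, delta), test_X).to_numpy()
            miss = pred != y[test_idx]
            wrong[gi] += miss.sum()
            for j, k in enumerate(classes):
                wrong_per_class[gi, j] += (miss & (y[test_idx] == k)).sum()

    n = len(y)
    n_per_class = np.array([(y == k).sum() for k in classes])
    curve = pd.DataFrame({"delta": grid, "error": wrong / n})
    for j, k in enumerate(classes):
        curve[f"err_{k}"] = wrong_per_class[:, j] / n_per_class[j]
    curve["n_genes"] = [
        int((np.abs(full.d) > delta).any(axis=1).sum()) for delta in grid
    ]
    return curve


def select_threshold(curve: pd.DataFrame) -> float:
    """Largest grid Delta attaining the minimum overall CV error.

    This is the fewest-genes point at minimal error: the threshold
    immediately before the error rate escalates.
    """
    if curve.empty:
        raise ValueError("empty threshold curve")
    best = curve["error"].min()
    return float(curve.loc[curve["error"] == best, "delta"].max())
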