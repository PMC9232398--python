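"""Joint density-based differential interaction network analysis (JDINAC).

Classifies samples from the continuous expression layer using gene-pair
interaction features. For each pair (i, j), bivariate kernel densities are
fitted separately in the short-survival class (f_ij) and the long-survival
class (g_ij); the feature is the log density ratio ln f_ij / g_ij, positive
where the pair is more tightly related in class 1. Features enter an
L1-penalized logistic regression

    logit(P) = beta0 + sum_{i<j} beta_ij ln f_ij(x_i, x_j) / g_ij(x_i, x_j)

fitted over repeated stratified half/half data splits (densities on one
half, regression on the other). Predictions are averaged across splits and
the number of splits in which a pair's coefficient is nonzero (its edge
count) measures differential-interaction stability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .ingest import LabeledDataset
from .network import EdgeSet

__all__ = [
    "PairDensity",
    "PairDensityModel",
    "SplitModel",
    "JdinacModel",
    "fit_pair_density",
    "log_density_ratio",
    "fit_split",
    "run_jdinac",
    "jdinac_edges",
]

#: Density floor preventing infinite log-ratios.
DENSITY_FLOOR = 1e-10

#: Inverse-regularization grid for the penalized logistic fit.
C_GRID = np.logspace(-2.0, 1.0, 7)


@dataclass
class PairDensity:
    """Bivariate Gaussian product-kernel density for one class of one pair."""

    points: np.ndarray  # (n, 2) training points
    bandwidths: np.ndarray  # (2,) per-axis bandwidth
    floor: float = DENSITY_FLOOR

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """Evaluate at (m, 2) query points; never below the floor."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        h = self.bandwidths
        z1 = (x[:, 0:1] - self.points[None, :, 0]) / h[0]
        z2 = (x[:, 1:2] - self.points[None, :, 1]) / h[1]
        kernel = np.exp(-0.5 * (z1 * z1 + z2 * z2))
        dens = kernel.sum(axis=1) / (
            self.points.shape[0] * 2.0 * np.pi * h[0] * h[1]
        )
        return np.maximum(dens, self.floor)


def fit_pair_density(points: np.ndarray, floor: float = DENSITY_FLOOR) -> PairDensity:
    """Fit one class-conditional bivariate KDE.

    Bandwidth per axis by the normal reference rule ``h_k = sigma_k *
    n^(-1/6)``; a zero-variance axis gets a floor bandwidth of
    ``1e-6 * (range + 1)`` so the density stays well defined.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if pts.shape[0] < 5:
        raise ValueError("need at least 5 points to fit a pair density")
    if not np.isfinite(pts).all():
        raise ValueError("non-finite values in density training points")
    n = pts.shape[0]
    h = pts.std(axis=0, ddof=1) * n ** (-1.0 / 6.0)
    rng_span = pts.max(axis=0) - pts.min(axis=0)
    h = np.maximum(h, 1e-6 * (rng_span + 1.0))
    return PairDensity(points=pts, bandwidths=h, floor=floor)


@dataclass
class PairDensityModel:
    """Class-1 (f) and class-0 (g) densities for one gene pair."""

    pair: tuple[str, str]
    f: PairDensity
    g: PairDensity


def log_density_ratio(model: PairDensityModel, x: np.ndarray) -> np.ndarray:
    """``ln f(x) - ln g(x)`` at (m, 2) query points; finite by the floor."""
    return np.log(model.f(x)) - np.log(model.g(x))


@dataclass
class SplitModel:
    """One half/half split: densities, penalized-logistic fit, partition."""

    densities: dict[tuple[str, str], PairDensityModel]
    coef: dict[tuple[str, str], float]  # nonzero coefficients only
    intercept: float
    chosen_c: float
    density_half: np.ndarray  # sample positions used for densities
    model_half: np.ndarray
    # feature standardization (glmnet-style) applied before the L1 fit
    feature_center: dict[tuple[str, str], float] = field(default_factory=dict)
    feature_scale: dict[tuple[str, str], float] = field(default_factory=dict)

    def predict(self, matrix: pd.DataFrame) -> np.ndarray:
        """Probability of class 1; features computed only for active pairs."""
        logit = np.full(matrix.shape[0], self.intercept)
        for pair, beta in self.coef.items():
            x = matrix[[pair[0], pair[1]]].to_numpy(dtype=float)
            feat = log_density_ratio(self.densities[pair], x)
            feat = (feat - self.feature_center.get(pair, 0.0)) / self.feature_scale.get(
                pair, 1.0
            )
            logit += beta * feat
        return 1.0 / (1.0 + np.exp(-logit))


def _feature_matrix(
    densities: dict[tuple[str, str], PairDensityModel],
    matrix: pd.DataFrame,
    pairs: list[tuple[str, str]],
) -> np.ndarray:
    values = matrix.to_numpy(dtype=float)
    col = {g: k for k, g in enumerate(matrix.columns)}
    feats = np.empty((values.shape[0], len(pairs)))
    for k, pair in enumerate(pairs):
        x = values[:, [col[pair[0]], col[pair[1]]]]
        feats[:, k] = log_density_ratio(densities[pair], x)
    return feats


def _fit_l1_logistic(c: float) -> LogisticRegression:
    return LogisticRegression(
        l1_ratio=1.0,
        C=float(c),
        solver="liblinear",
        intercept_scaling=10.0,
        random_state=0,
        max_iter=200,
        tol=1e-3,
    )


def _cv_one_se_c(features: np.ndarray, labels: np.ndarray, seed: int) -> float:
    """Pick C by 5-fold cross-validated deviance with the 1-SE rule.

    The strongest penalty (smallest C) whose mean per-sample deviance lies
    within one standard error of the minimum is selected. Folds are built by
    a per-class round robin over one seeded permutation, which keeps the
    assignment invariant under relabeling the classes.
    """
    n_folds = min(5, int(np.bincount(labels).min()))
    if n_folds < 2:
        return float(C_GRID[len(C_GRID) // 2])
    rng = np.random.default_rng(seed % (2**31))
    fold_of = np.empty(labels.size, dtype=int)
    seen = [0, 0]
    for i in rng.permutation(labels.size):
        cls = int(labels[i])
        fold_of[i] = seen[cls] % n_folds
        seen[cls] += 1
    folds = [
        (np.flatnonzero(fold_of != f), np.flatnonzero(fold_of == f))
        for f in range(n_folds)
    ]
    dev = np.empty((len(C_GRID), len(folds)))
    for ci, c in enumerate(C_GRID):
        for fi, (tr, te) in enumerate(folds):
            if len(np.unique(labels[tr])) < 2:
                dev[ci, fi] = np.inf
                continue
            clf = _fit_l1_logistic(c).fit(features[tr], labels[tr])
            p = np.clip(clf.predict_proba(features[te])[:, 1], 1e-12, 1 - 1e-12)
            y = labels[te]
            dev[ci, fi] = -2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
    mean = dev.mean(axis=1)
    se = dev.std(axis=1, ddof=1) / np.sqrt(dev.shape[1])
    best = int(np.argmin(mean))
    limit = mean[best] + se[best]
    for ci in range(len(C_GRID)):  # smallest C first = strongest penalty
        if mean[ci] <= limit:
            return float(C_GRID[ci])
    return float(C_GRID[best])


def fit_split(
    density_matrix: pd.DataFrame,
    density_labels: np.ndarray,
    model_matrix: pd.DataFrame,
    model_labels: np.ndarray,
    pairs: list[tuple[str, str]],
    seed: int = 0,
    density_half: np.ndarray | None = None,
    model_half: np.ndarray | None = None,
) -> SplitModel:
    """Fit one half/half split.

    Class-conditional pair densities are fitted on the density half;
    log-ratio features of the model half then enter the L1-penalized
    logistic regression, with the penalty chosen by internal 5-fold
    cross-validated deviance under the 1-SE rule.
    """
    for name, lab in (("density", density_labels), ("model", model_labels)):
        if len(np.unique(lab)) < 2:
            raise ValueError(f"{name} half does not contain both classes")
    densities: dict[tuple[str, str], PairDensityModel] = {}
    values = density_matrix.to_numpy(dtype=float)
    col = {g: k for k, g in enumerate(density_matrix.columns)}
    d1 = values[np.asarray(density_labels) == 1]
    d0 = values[np.asarray(density_labels) == 0]
    for pair in pairs:
        idx = [col[pair[0]], col[pair[1]]]
        densities[pair] = PairDensityModel(
            pair=pair,
            f=fit_pair_density(d1[:, idx]),
            g=fit_pair_density(d0[:, idx]),
        )
    feats = _feature_matrix(densities, model_matrix, pairs)
    labels = np.asarray(model_labels, dtype=int)
    center = feats.mean(axis=0)
    scale = feats.std(axis=0)
    scale[scale < 1e-12] = 1.0
    feats = (feats - center) / scale
    c = _cv_one_se_c(feats, labels, seed)
    clf = _fit_l1_logistic(c).fit(feats, labels)
    active = [k for k in range(len(pairs)) if abs(clf.coef_[0, k]) > 1e-12]
    return SplitModel(
        densities=densities,
        coef={pairs[k]: float(clf.coef_[0, k]) for k in active},
        intercept=float(clf.intercept_[0]),
        chosen_c=c,
        density_half=density_half if density_half is not None else np.array([]),
        model_half=model_half if model_half is not None else np.array([]),
        feature_center={pairs[k]: float(center[k]) for k in active},
        feature_scale={pairs[k]: float(scale[k]) for k in active},
    )


@dataclass
class JdinacModel:
    """Aggregate over repeated splits: stability counts and mean predictions."""

    splits: list[SplitModel]
    pairs: list[tuple[str, str]]
    n_splits: int
    edge_counts: dict[tuple[str, str], int]
    mean_abs_coef: dict[tuple[str, str], float]
    mean_probability: pd.Series  # averaged prediction for the training samples
    log_scale: bool = False

    def predict(self, matrix: pd.DataFrame) -> np.ndarray:
        """Final prediction probability: mean over the split models."""
        if self.log_scale:
            matrix = np.log(matrix)
        probs = np.stack([s.predict(matrix) for s in self.splits])
        return probs.mean(axis=0)

    def edge_report(self) -> pd.DataFrame:
        rows = [
            {
                "gene_i": p[0],
                "gene_j": p[1],
                "edge_count": self.edge_counts.get(p, 0),
                "mean_abs_coef": self.mean_abs_coef.get(p, 0.0),
            }
            for p in self.pairs
        ]
        df = pd.DataFrame(rows)
        return df.sort_values(
            ["edge_count", "mean_abs_coef", "gene_i", "gene_j"],
            ascending=[False, False, True, True],
        ).reset_index(drop=True)


def _stratified_halves(
    labels: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random half/half partition keeping both classes in each half.

    One global permutation is walked with per-class quotas, so the partition
    is invariant under relabeling the classes (needed for the label-swap
    symmetry of the fitted models when class counts are equal).
    """
    counts = np.bincount(labels, minlength=2)
    quota = [int(c) // 2 for c in counts]
    for cls in (0, 1):
        if counts[cls] % 2 == 1 and rng.random() < 0.5:
            quota[cls] += 1
    taken = [0, 0]
    half_a: list[int] = []
    half_b: list[int] = []
    for i in rng.permutation(labels.size):
        cls = int(labels[i])
        if taken[cls] < quota[cls]:
            half_a.append(int(i))
            taken[cls] += 1
        else:
            half_b.append(int(i))
    return np.sort(np.array(half_a)), np.sort(np.array(half_b))


def run_jdinac(
    dataset: LabeledDataset,
    pairs: list[tuple[str, str]] | None = None,
    n_splits: int = 100,
    seed: int = 0,
    max_pairs: int = 20_000,
    log_scale: bool | None = None,
) -> JdinacModel:
    """Fit JDINAC over ``n_splits`` stratified half/half partitions.

    ``pairs`` defaults to all gene pairs of the dataset's (screened)
    matrix. Edge counts tally the splits in which each pair's coefficient
    is nonzero; the training samples' mean predicted probability across
    splits is stored as the final prediction.

    ``log_scale`` (default: automatic, on for strictly positive matrices)
    fits the kernel densities on log-transformed values. The population
    log density ratio is invariant under a common monotone transform — the
    Jacobians of f and g cancel — while the finite-sample KDE behaves far
    better on the symmetrized scale than on skewed TPM-like values.
    """
    matrix, labels = dataset.matrix, np.asarray(dataset.labels, dtype=int)
    if log_scale is None:
        log_scale = bool((matrix.to_numpy() > 0).all())
    if log_scale:
        matrix = np.log(matrix)
    genes = [str(g) for g in matrix.columns]
    if pairs is None:
        pairs = [
            (genes[i], genes[j])
            for i in range(len(genes))
            for j in range(i + 1, len(genes))
        ]
    if len(pairs) > max_pairs:
        raise ValueError(
            f"{len(pairs)} gene pairs exceeds the cap of {max_pairs}; "
            "tighten the screening step"
        )
    counts = np.bincount(labels, minlength=2)
    if counts.min() < 20:
        warnings.warn(
            f"fewer than 20 samples in a class (counts={counts.tolist()}); "
            "density estimates will be coarse",
            stacklevel=2,
        )
    if counts.min() < 10:
        raise ValueError("need at least 10 samples per class")

    rng = np.random.default_rng(seed)
    splits: list[SplitModel] = []
    edge_counts: dict[tuple[str, str], int] = {}
    abs_coef: dict[tuple[str, str], float] = {}
    prob_sum = np.zeros(matrix.shape[0])
    for _ in range(n_splits):
        split_seed = int(rng.integers(2**31))
        for attempt in range(20):
            half_a, half_b = _stratified_halves(labels, rng)
            if (
                len(np.unique(labels[half_a])) == 2
                and len(np.unique(labels[half_b])) == 2
            ):
                break
        else:
            raise RuntimeError("could not form a split with both classes per half")
        sm = fit_split(
            matrix.iloc[half_a],
            labels[half_a],
            matrix.iloc[half_b],
            labels[half_b],
            pairs,
            seed=split_seed,
            density_half=half_a,
            model_half=half_b,
        )
        splits.append(sm)
        for pair, beta in sm.coef.items():
            edge_counts[pair] = edge_counts.get(pair, 0) + 1
            abs_coef[pair] = abs_coef.get(pair, 0.0) + abs(beta)
        prob_sum += sm.predict(matrix)

    mean_abs = {p: abs_coef[p] / edge_counts[p] for p in edge_counts}
    return JdinacModel(
        splits=splits,
        pairs=pairs,
        n_splits=n_splits,
        edge_counts=edge_counts,
        mean_abs_coef=mean_abs,
        mean_probability=pd.Series(prob_sum / n_splits, index=matrix.index),
        log_scale=log_scale,
    )


def jdinac_edges(
    model: JdinacModel, min_count: int | None = None, layer: str = "mrna"
) -> EdgeSet:
    """Stable differential-interaction edges: edge_count >= ``min_count``.

    Default threshold is 10% of the number of splits; the full ranking
    remains available through :meth:`JdinacModel.edge_report`.
    """
    if min_count is None:
        min_count = max(1, model.n_splits // 10)
    es = EdgeSet(layer=layer)
    for pair, count in model.edge_counts.items():
        if count >= min_count:
            es.add(pair[0], pair[1], float(count))
    return es
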