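"""Cross-validated classification and survival evaluation.

Stratified k-fold cross-validation of a classifier over a dichotomized
cohort, ROC/AUC (rank estimator, ties counted 1/2), Youden-index cutoff,
confusion metrics at the cutoff, and Kaplan-Meier / log-rank comparison of
the cutoff-defined high- and low-risk groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.stats import rankdata

from .ingest import ClinicalTable, LabeledDataset

__all__ = [
    "SurvivalEvaluation",
    "cross_validate",
    "roc_auc",
    "youden_cutoff",
    "confusion_metrics",
    "km_logrank",
    "evaluate_predictions",
]

# model_runner(train_dataset, test_matrix) -> probability of class 1 per row
ModelRunner = Callable[[LabeledDataset, pd.DataFrame], np.ndarray]


def cross_validate(
    dataset: LabeledDataset,
    model_runner: ModelRunner,
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Stratified k-fold cross-validation; every sample predicted once.

    Returns a frame with columns sample, fold, probability, label. Folds are
    built per class from a seeded permutation, so the assignment is
    deterministic and each fold holds both classes whenever class counts
    allow; otherwise an error is raised.
    """
    labels = np.asarray(dataset.labels, dtype=int)
    n = labels.size
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if k < 2 or k > n:
        raise ValueError(f"k={k} out of range for n={n}")
    if counts.min() < k and k <= counts.min() * 2:
        pass  # folds may miss a class; handled below
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    for cls in classes:
        idx = rng.permutation(np.flatnonzero(labels == cls))
        for fold, part in enumerate(np.array_split(idx, k)):
            fold_of[part] = fold
    rows = []
    for fold in range(k):
        test = fold_of == fold
        train = ~test
        if len(np.unique(labels[train])) < 2:
            raise ValueError(f"training folds for fold {fold} miss a class")
        train_ds = LabeledDataset(
            matrix=dataset.matrix.iloc[train],
            labels=dataset.labels.iloc[train],
            horizon_years=dataset.horizon_years,
        )
        probs = np.asarray(model_runner(train_ds, dataset.matrix.iloc[test]))
        for s, p, y in zip(dataset.matrix.index[test], probs, labels[test]):
            rows.append(
                {"sample": s, "fold": fold, "probability": float(p), "label": int(y)}
            )
    return pd.DataFrame(rows)


def roc_auc(
    predictions: pd.DataFrame,
) -> tuple[pd.DataFrame, float]:
    """ROC curve and AUC from a predictions frame.

    AUC is the rank (Mann-Whitney) estimator with ties counted 1/2, which
    equals trapezoidal integration of the empirical ROC. The returned frame
    has columns threshold, fpr, tpr over all distinct score thresholds.
    """
    y = predictions["label"].to_numpy(dtype=int)
    s = predictions["probability"].to_numpy(dtype=float)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both labels must be present to compute a ROC")
    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    thresholds = np.unique(s)[::-1]  # descending
    fpr = [0.0]
    tpr = [0.0]
    thr = [np.inf]
    for t in thresholds:
        pred1 = s >= t
        tpr.append(float((pred1 & (y == 1)).sum() / n1))
        fpr.append(float((pred1 & (y == 0)).sum() / n0))
        thr.append(float(t))
    roc = pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
    return roc, float(auc)


def youden_cutoff(roc: pd.DataFrame) -> float:
    """Threshold maximizing Youden's J = tpr - fpr; ties -> smaller threshold."""
    finite = roc[np.isfinite(roc["threshold"])]
    j = finite["tpr"].to_numpy() - finite["fpr"].to_numpy()
    thr = finite["threshold"].to_numpy()
    best = j.max()
    return float(thr[j >= best - 1e-12].min())


def confusion_metrics(predictions: pd.DataFrame, cutoff: float) -> dict[str, float]:
    """Accuracy, sensitivity, specificity at ``probability >= cutoff`` -> 1."""
    y = predictions["label"].to_numpy(dtype=int)
    pred = (predictions["probability"].to_numpy(dtype=float) >= cutoff).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return {
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "accuracy": (tp + tn) / max(tp + tn + fp + fn, 1),
        "sensitivity": tp / max(tp + fn, 1),
        "specificity": tn / max(tn + fp, 1),
    }


def km_logrank(
    clinical: ClinicalTable, groups: pd.Series
) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Kaplan-Meier curves per risk group and the two-sample log-rank test.

    ``groups`` maps sample_id -> 'high'/'low'. Returns per-group KM survival
    tables, the log-rank chi-square statistic, and its p-value.
    """
    df = clinical.table.set_index("sample_id").loc[groups.index]
    names = sorted(groups.unique())
    if len(names) != 2 or groups.value_counts().min() == 0:
        raise ValueError("need two nonempty risk groups")
    curves: dict[str, pd.DataFrame] = {}
    for name in names:
        members = groups[groups == name].index
        kmf = KaplanMeierFitter()
        kmf.fit(
            df.loc[members, "os_time_years"],
            df.loc[members, "os_event"],
            label=str(name),
        )
        curves[str(name)] = kmf.survival_function_.reset_index().rename(
            columns={"timeline": "time_years", str(name): "survival"}
        )
    a, b = (groups[groups == name].index for name in names)
    res = logrank_test(
        df.loc[a, "os_time_years"],
        df.loc[b, "os_time_years"],
        event_observed_A=df.loc[a, "os_event"],
        event_observed_B=df.loc[b, "os_event"],
    )
    return curves, float(res.test_statistic), float(res.p_value)


@dataclass
class SurvivalEvaluation:
    """Everything measured for one horizon's classifier."""

    predictions: pd.DataFrame
    roc: pd.DataFrame
    auc: float
    cutoff: float
    confusion: dict[str, float]
    km_groups: pd.Series
    km_curves: dict[str, pd.DataFrame] | None
    logrank_stat: float | None
    logrank_p: float | None

    def metrics_row(self) -> dict[str, float]:
        return {
            "auc": self.auc,
            "accuracy": self.confusion["accuracy"],
            "sensitivity": self.confusion["sensitivity"],
            "specificity": self.confusion["specificity"],
            "cutoff": self.cutoff,
            "logrank_p": self.logrank_p if self.logrank_p is not None else np.nan,
        }


def evaluate_predictions(
    predictions: pd.DataFrame,
    clinical: ClinicalTable | None = None,
) -> SurvivalEvaluation:
    """ROC/AUC, Youden cutoff, confusion metrics, and (optionally) KM/log-rank.

    Risk groups assign probability >= cutoff to 'high'. The log-rank block
    is skipped when no clinical table is supplied or a group is empty.
    """
    roc, auc = roc_auc(predictions)
    cutoff = youden_cutoff(roc)
    confusion = confusion_metrics(predictions, cutoff)
    groups = pd.Series(
        np.where(predictions["probability"] >= cutoff, "high", "low"),
        index=predictions["sample"],
        name="risk_group",
    )
    curves = stat = p = None
    if clinical is not None and groups.nunique() == 2:
        curves, stat, p = km_logrank(clinical, groups)
    return SurvivalEvaluation(
        predictions=predictions,
        roc=roc,
        auc=auc,
        cutoff=cutoff,
        confusion=confusion,
        km_groups=groups,
        km_curves=curves,
        logrank_stat=stat,
        logrank_p=p,
    )
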