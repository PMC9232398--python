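"""ROC/AUC arithmetic, Youden cutoff, confusion metrics, KM/log-rank."""

import numpy as np
import pandas as pd
import pytest

from diffomics.evaluate import (
    confusion_metrics,
    cross_validate,
    km_logrank,
    roc_auc,
    youden_cutoff,
)
from diffomics.ingest import ClinicalTable, LabeledDataset


def preds_frame(scores, labels):
    return pd.DataFrame(
        {
            "sample": [f"S{k}" for k in range(len(scores))],
            "fold": 0,
            "probability": scores,
            "label": labels,
        }
    )


def auc_bruteforce(scores, labels):
    """Exhaustive concordance enumeration with ties counted 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def youden_bruteforce(scores, labels):
    """Enumerate all candidate thresholds; max J, ties to smaller threshold."""
    best_j, best_t = -np.inf, None
    for t in sorted(set(scores)):
        tpr = sum(1 for s, y in zip(scores, labels) if y == 1 and s >= t) / sum(labels)
        fpr = sum(1 for s, y in zip(scores, labels) if y == 0 and s >= t) / (
            len(labels) - sum(labels)
        )
        j = tpr - fpr
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return best_t


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc(preds_frame([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]))
        assert auc == 1.0

    def test_all_equal_scores_give_half(self):
        _, auc = roc_auc(preds_frame([0.5] * 6, [0, 1, 0, 1, 0, 1]))
        assert auc == 0.5

    def test_four_score_example_matches_enumeration(self):
        scores, labels = [0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]
        _, auc = roc_auc(preds_frame(scores, labels))
        assert auc == pytest.approx(auc_bruteforce(scores, labels), abs=1e-12)

    def test_random_instances_match_enumeration(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 30))
            scores = rng.integers(0, 6, n) / 5.0  # force ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            _, auc = roc_auc(preds_frame(scores, labels))
            assert auc == pytest.approx(auc_bruteforce(scores, labels), abs=1e-12)

    def test_rank_auc_equals_trapezoid(self, rng):
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[0], labels[1] = 0, 1
        roc, auc = roc_auc(preds_frame(scores, labels))
        trapezoid = np.trapezoid(roc["tpr"], roc["fpr"])
        assert auc == pytest.approx(trapezoid, abs=1e-10)

    def test_score_negation_complements(self, rng):
        scores = rng.permutation(np.arange(20) / 20.0)  # tie-free
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        _, a1 = roc_auc(preds_frame(scores, labels))
        _, a2 = roc_auc(preds_frame(-scores, labels))
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(preds_frame([0.1, 0.9], [1, 1]))


class TestYouden:
    def test_perfect_separation_smallest_maximizer(self):
        roc, _ = roc_auc(preds_frame([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]))
        assert youden_cutoff(roc) == 0.8

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            scores = (rng.integers(0, 8, 15) / 7.0).tolist()
            labels = rng.integers(0, 2, 15).tolist()
            if min(labels) == max(labels):
                labels[0] = 1 - labels[0]
            roc, _ = roc_auc(preds_frame(scores, labels))
            assert youden_cutoff(roc) == pytest.approx(
                youden_bruteforce(scores, labels), abs=1e-12
            )

    def test_degenerate_all_equal(self):
        roc, _ = roc_auc(preds_frame([0.3] * 4, [0, 1, 0, 1]))
        assert youden_cutoff(roc) == 0.3


class TestConfusion:
    def test_perfect(self):
        m = confusion_metrics(preds_frame([0.1, 0.9], [0, 1]), 0.5)
        assert m["accuracy"] == m["sensitivity"] == m["specificity"] == 1.0

    def test_all_negative_predictions(self):
        m = confusion_metrics(preds_frame([0.1, 0.2], [0, 1]), 0.9)
        assert m["specificity"] == 1.0 and m["sensitivity"] == 0.0

    def test_counts_arithmetic(self):
        # tp=3 fp=1 tn=4 fn=2 -> acc 0.7, sens 0.6, spec 0.8
        scores = [0.9] * 3 + [0.9] + [0.1] * 4 + [0.1] * 2
        labels = [1] * 3 + [0] + [0] * 4 + [1] * 2
        m = confusion_metrics(preds_frame(scores, labels), 0.5)
        assert (m["tp"], m["fp"], m["tn"], m["fn"]) == (3, 1, 4, 2)
        assert m["accuracy"] == pytest.approx(0.7)
        assert m["sensitivity"] == pytest.approx(0.6)
        assert m["specificity"] == pytest.approx(0.8)


class TestKmLogrank:
    @staticmethod
    def clinical(ids, times, events):
        return ClinicalTable(
            pd.DataFrame(
                {"sample_id": ids, "os_time_years": times, "os_event": events}
            )
        )

    def test_identical_groups_give_null_statistic(self):
        ids = [f"S{k}" for k in range(8)]
        clin = self.clinical(ids, [1, 2, 3, 4] * 2, [1, 1, 0, 1] * 2)
        groups = pd.Series(["high"] * 4 + ["low"] * 4, index=ids)
        # identical time/event data in both groups
        _, stat, p = km_logrank(clin, groups)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_hand_worked_logrank_table(self):
        # groups (1,2,3) vs (4,5,6), all events. Hand table:
        # O_A = 3, E_A = 3/6 + 2/5 + 1/4 = 1.15, V = 0.25 + 0.24 + 0.1875
        # chi2 = (3 - 1.15)^2 / 0.6775 = 5.05166...
        ids = list("ABCDEF")
        clin = self.clinical(ids, [1, 2, 3, 4, 5, 6], [1] * 6)
        groups = pd.Series(["high"] * 3 + ["low"] * 3, index=ids)
        _, stat, p = km_logrank(clin, groups)
        assert stat == pytest.approx((3 - 1.15) ** 2 / 0.6775, rel=1e-6)
        assert p < 0.05

    def test_km_step_height_without_censoring(self):
        ids = list("ABCD")
        clin = self.clinical(ids, [1, 2, 3, 10], [1, 1, 1, 0])
        groups = pd.Series(["high", "high", "low", "low"], index=ids)
        curves, _, _ = km_logrank(clin, groups)
        high = curves["high"].set_index("time_years")["survival"]
        assert high.loc[2.0] == pytest.approx(0.0)  # both events by t=2

    def test_empty_group_rejected(self):
        ids = list("AB")
        clin = self.clinical(ids, [1, 2], [1, 1])
        with pytest.raises(ValueError):
            km_logrank(clin, pd.Series(["high", "high"], index=ids))


class TestCrossValidate:
    @staticmethod
    def dataset(n=100):
        rng = np.random.default_rng(0)
        matrix = pd.DataFrame(
            rng.normal(size=(n, 3)),
            columns=list("abc"),
            index=[f"S{k}" for k in range(n)],
        )
        labels = pd.Series(
            np.r_[np.ones(n // 2, int), np.zeros(n - n // 2, int)],
            index=matrix.index,
        )
        return LabeledDataset(matrix, labels, 5.0)

    @staticmethod
    def prevalence_runner(train, test_matrix):
        return np.full(len(test_matrix), float(np.mean(train.labels)))

    def test_stratification_arithmetic(self):
        ds = self.dataset(100)
        preds = cross_validate(ds, self.prevalence_runner, k=5, seed=0)
        assert len(preds) == 100
        per_fold = preds.groupby("fold")["label"].agg(["count", "sum"])
        assert (per_fold["count"] == 20).all()
        assert (per_fold["sum"] == 10).all()
        assert preds["sample"].is_unique

    def test_seed_determinism(self):
        ds = self.dataset(60)
        p1 = cross_validate(ds, self.prevalence_runner, k=5, seed=3)
        p2 = cross_validate(ds, self.prevalence_runner, k=5, seed=3)
        pd.testing.assert_frame_equal(p1, p2)

    def test_leave_one_out_boundary(self):
        ds = self.dataset(10)
        preds = cross_validate(ds, self.prevalence_runner, k=10, seed=1)
        assert len(preds) == 10
        assert preds["sample"].is_unique  # every sample predicted exactly once
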