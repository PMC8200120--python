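import itertools

import numpy as np
import pytest

from thyrocad.evaluate import (
    confusion_counts,
    loocv,
    metrics,
    report_from_probs,
    roc_auc,
)
from thyrocad.io import ValidationError
from thyrocad.network import NetworkConfig


def concordance_auc(probs, labels):
    """O(n^2) pairwise Mann–Whitney oracle with ties counted 1/2."""
    probs, labels = np.asarray(probs), np.asarray(labels)
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusionCounts:
    def test_simple(self):
        assert confusion_counts([0.9, 0.1], [1, 0]) == (1, 0, 1, 0)

    def test_tie_rule_predicts_positive(self):
        # prob == threshold counts as a positive call
        assert confusion_counts([0.5, 0.5], [1, 0], threshold=0.5) == (1, 1, 0, 0)

    def test_exhaustive_n2(self):
        probs_grid = (0.2, 0.8)
        for labels in itertools.product((0, 1), repeat=2):
            for probs in itertools.product(probs_grid, repeat=2):
                tp, fp, tn, fn = confusion_counts(probs, labels)
                exp = [0, 0, 0, 0]
                for p, y in zip(probs, labels):
                    pred = p >= 0.5
                    if pred and y == 1:
                        exp[0] += 1
                    elif pred and y == 0:
                        exp[1] += 1
                    elif not pred and y == 0:
                        exp[2] += 1
                    else:
                        exp[3] += 1
                assert (tp, fp, tn, fn) == tuple(exp)


class TestMetrics:
    def test_worked_confusion_table(self):
        # TP=11, FN=5, FP=1, TN=31 — matches 0.875/0.6875/0.96875/0.7857
        m = metrics((11, 1, 31, 5))
        assert m["accuracy"] == pytest.approx(0.875)
        assert m["sensitivity"] == pytest.approx(0.6875)
        assert m["specificity"] == pytest.approx(0.96875)
        assert m["dice"] == pytest.approx(0.7857, abs=5e-5)
        assert m["recall"] == m["sensitivity"]

    def test_all_correct(self):
        m = metrics((3, 0, 5, 0))
        for key in ("accuracy", "sensitivity", "specificity", "precision", "dice"):
            assert m[key] == 1.0

    def test_degenerate_absent_not_zero(self):
        m = metrics((0, 0, 4, 0))
        assert m["dice"] is None
        assert m["sensitivity"] is None
        assert m["specificity"] == 1.0

    def test_identities_on_random_tables(self, rng):
        for _ in range(2000):
            tp, fp, tn, fn = rng.integers(0, 40, 4)
            if tp + fp + tn + fn == 0:
                continue
            m = metrics((tp, fp, tn, fn))
            n = tp + fp + tn + fn
            assert m["accuracy"] == pytest.approx((tp + tn) / n)
            if tp + fn:
                assert m["sensitivity"] == pytest.approx(tp / (tp + fn))
            if tn + fp:
                assert m["specificity"] == pytest.approx(tn / (tn + fp))
            if 2 * tp + fp + fn:
                assert m["dice"] == pytest.approx(2 * tp / (2 * tp + fp + fn))
            for v in m.values():
                assert v is None or 0.0 <= v <= 1.0


class TestROC:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_uninformative_scores(self):
        _, auc = roc_auc([0.5] * 6, [1, 0, 1, 0, 0, 0])
        assert auc == pytest.approx(0.5)

    def test_matches_concordance_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 20))
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            probs = np.round(rng.random(n), 2)  # induce ties
            _, auc = roc_auc(probs, labels)
            assert auc == pytest.approx(concordance_auc(probs, labels), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        labels = rng.integers(0, 2, 15)
        labels[0], labels[1] = 0, 1
        probs = rng.random(15)
        _, a1 = roc_auc(probs, labels)
        _, a2 = roc_auc(1 / (1 + np.exp(-(5 * probs - 2))), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([0.2, 0.4], [1, 1])

    def test_curve_endpoints(self, rng):
        points, _ = roc_auc(rng.random(10), [0, 1] * 5)
        assert tuple(points[0]) == (0.0, 0.0)
        assert tuple(points[-1]) == (1.0, 1.0)


class TestLOOCVBookkeeping:
    def test_folds_and_pooling(self, tiny_cohort, tiny_samples, monkeypatch):
        import thyrocad.evaluate as ev

        seen_weights = []
        real_cw = ev.class_weights

        def spy(labels, convention="inverse-frequency"):
            cw = real_cw(labels, convention)
            seen_weights.append((tuple(sorted(labels)), cw.ratio))
            return cw

        monkeypatch.setattr(ev, "class_weights", spy)
        cfg = NetworkConfig(conv_filters=2, compress_filters=2, hidden_units=3,
                            epochs=1, batch_size=8, validation_fraction=0.0)
        report = ev.loocv(tiny_cohort, cfg, seed=0, samples=tiny_samples)
        assert len(report.folds) == len(tiny_cohort)
        assert sorted(f.patient_id for f in report.folds) == sorted(
            c.patient_id for c in tiny_cohort
        )
        assert sum(report.confusion) == len(tiny_cohort)
        # class weights recomputed per fold from the remaining labels
        assert len(seen_weights) == len(tiny_cohort)
        n_mal = int(tiny_cohort.labels.sum())
        n_ben = len(tiny_cohort) - n_mal
        for labels, ratio in seen_weights:
            n_mal_f = sum(labels)
            n_ben_f = len(labels) - n_mal_f
            assert (n_mal_f, n_ben_f) in {(n_mal - 1, n_ben), (n_mal, n_ben - 1)}
            assert ratio == pytest.approx(n_ben_f / n_mal_f)

    def test_single_class_manifest_rejected(self, tiny_samples):
        from thyrocad.evaluate import loocv_probs

        only_benign = [s for s in tiny_samples if s.label == 0]
        with pytest.raises(ValidationError):
            loocv_probs(only_benign, NetworkConfig(epochs=1))


class TestReportFromProbs:
    def test_report_consistency(self, rng):
        labels = np.array([0, 0, 1, 1, 0, 1])
        probs = rng.random(6)
        ids = [f"p{i}" for i in range(6)]
        rep = report_from_probs(ids, probs, labels)
        assert sum(rep.confusion) == 6
        assert rep.auc == pytest.approx(concordance_auc(probs, labels), abs=1e-12)
        assert all(0 <= f.probability <= 1 for f in rep.folds)
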