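"""Metric computation, balancing, aggregation and the window sweep."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mindfuse import evaluation as ev
from mindfuse import models
from mindfuse.io_formats import Session
from mindfuse.preprocessing import CleanedSession, Segment


class TestMetrics:
    def test_perfect_classifier(self):
        rep = ev.compute_metrics(ev.ConfusionCounts(50, 0, 50, 0))
        for name in ev.METRIC_NAMES:
            assert getattr(rep, name) == pytest.approx(100.0)

    def test_degenerate_all_negative_predictions(self):
        rep = ev.compute_metrics(ev.ConfusionCounts(tp=0, fp=0, tn=10,
                                                    fn=10))
        assert rep.sensitivity == 0.0
        assert rep.specificity == 100.0
        assert rep.balanced_accuracy == 50.0
        assert rep.geometric_mean == 0.0

    def test_undefined_sensitivity_reported_missing(self):
        rep = ev.compute_metrics(ev.ConfusionCounts(tp=0, fp=3, tn=7, fn=0))
        assert math.isnan(rep.sensitivity)
        assert math.isnan(rep.balanced_accuracy)
        assert math.isnan(rep.geometric_mean)
        assert rep.specificity == pytest.approx(70.0)

    @given(tp=st.integers(0, 500), fp=st.integers(0, 500),
           tn=st.integers(0, 500), fn=st.integers(0, 500))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_identities_hold(self, tp, fp, tn, fn):
        counts = ev.ConfusionCounts(tp, fp, tn, fn)
        if counts.total == 0:
            return
        rep = ev.compute_metrics(counts)
        assert rep.accuracy == pytest.approx(
            100.0 * (tp + tn) / counts.total, abs=1e-12)
        if tp + fn > 0 and fp + tn > 0:
            assert rep.balanced_accuracy == pytest.approx(
                (rep.sensitivity + rep.specificity) / 2, abs=1e-9)
            assert rep.geometric_mean <= rep.balanced_accuracy + 1e-9

    def test_prevalence_invariance_of_ba_and_gm(self):
        base = ev.ConfusionCounts(tp=40, fp=20, tn=30, fn=10)
        doubled = ev.ConfusionCounts(tp=80, fp=20, tn=30, fn=20)
        a, b = ev.compute_metrics(base), ev.compute_metrics(doubled)
        assert a.sensitivity == pytest.approx(b.sensitivity)
        assert a.specificity == pytest.approx(b.specificity)
        assert a.balanced_accuracy == pytest.approx(b.balanced_accuracy)
        assert a.geometric_mean == pytest.approx(b.geometric_mean)

    def test_percent_matrix_normalization(self):
        counts = ev.ConfusionCounts(tp=40, fp=20, tn=30, fn=10)
        m = counts.percent_matrix()
        assert m.sum() == pytest.approx(100.0)
        np.testing.assert_allclose(m[0], [40.0, 10.0])


def _segments(rng, labels, subject="s"):
    out = []
    for lab in labels:
        sess = Session.MANUAL1 if lab == 0 else Session.ADAS
        out.append(Segment(data=rng.standard_normal((100, 8)), label=lab,
                           subject_id=subject, session=sess))
    return out


class TestBalancing:
    def test_majority_undersampled_to_minority(self, rng):
        segs = _segments(rng, [0] * 120 + [1] * 80)
        balanced = ev.balance_training_set(segs, seed=0)
        labels = np.array([s.label for s in balanced])
        assert (labels == 0).sum() == 80
        assert (labels == 1).sum() == 80

    def test_already_balanced_is_permutation(self, rng):
        segs = _segments(rng, [0] * 30 + [1] * 30)
        balanced = ev.balance_training_set(segs, seed=1)
        assert sorted(map(id, balanced)) == sorted(map(id, segs))

    def test_seeded_determinism(self, rng):
        segs = _segments(rng, [0] * 50 + [1] * 20)
        a = ev.balance_training_set(segs, seed=7)
        b = ev.balance_training_set(segs, seed=7)
        assert [id(s) for s in a] == [id(s) for s in b]
        c = ev.balance_training_set(segs, seed=8)
        assert [id(s) for s in a] != [id(s) for s in c]

    def test_single_class_rejected(self, rng):
        with pytest.raises(ev.BalanceError):
            ev.balance_training_set(_segments(rng, [0] * 10), seed=0)


class TestCohortSummary:
    def _summary(self):
        folds = []
        for sid, (tp, fp, tn, fn) in (("a", (40, 20, 30, 10)),
                                      ("b", (50, 0, 50, 0)),
                                      ("c", (0, 0, 10, 10))):
            counts = ev.ConfusionCounts(tp, fp, tn, fn)
            folds.append(ev.FoldResult(
                subject_id=sid, counts=counts,
                report=ev.compute_metrics(counts, sid)))
        return ev.CohortSummary(folds=folds)

    def test_mean_std_recomputable_from_reports(self):
        s = self._summary()
        accs = [f.report.accuracy for f in s.folds]
        assert s.mean("accuracy") == pytest.approx(np.mean(accs))
        assert s.std("accuracy") == pytest.approx(np.std(accs, ddof=1))

    def test_json_round_trip_keeps_audit_trail(self, tmp_path):
        import json

        s = self._summary()
        path = tmp_path / "results.json"
        s.write_json(path)
        loaded = json.loads(path.read_text())
        assert len(loaded["folds"]) == 3
        for fold, orig in zip(loaded["folds"], s.folds):
            assert fold["counts"]["tp"] == orig.counts.tp
            total = sum(sum(row) for row in fold["confusion_percent"])
            assert total == pytest.approx(100.0)
        assert loaded["summary"]["accuracy"]["mean"] == pytest.approx(
            s.mean("accuracy"))


class TestLoso:
    def test_requires_two_subjects(self, rng):
        with pytest.raises(ValueError):
            ev.loso_evaluate(_segments(rng, [0, 1]),
                             models.ModelSpec(window_samples=100))

    def test_one_fold_per_subject(self, rng):
        segs = []
        for subj in ("a", "b", "c"):
            segs += _segments(rng, [0] * 12 + [1] * 12, subject=subj)
        spec = models.ModelSpec(arch="data_fusion", window_samples=100,
                                max_epochs=1, early_stopping_patience=1)
        summary = ev.loso_evaluate(segs, spec, seed=0)
        assert [f.subject_id for f in summary.folds] == ["a", "b", "c"]
        for f in summary.folds:
            assert f.counts.total == 24


class TestWindowSweep:
    def test_sweep_reports_per_length_and_flags_short_windows(self, rng):
        fs = 200.0
        cleaned = [
            CleanedSession(subject_id=s, session=sess, fs=fs,
                           data=rng.standard_normal((int(20 * fs), 8)),
                           ecg_lead=0)
            for s in ("a", "b")
            for sess in (Session.MANUAL1, Session.ADAS)
        ]
        spec = models.ModelSpec(arch="data_fusion", max_epochs=1,
                                early_stopping_patience=1)
        results = ev.window_length_sweep(cleaned, spec,
                                         lengths_s=[0.1, 0.5], seed=0)
        assert "error" in results[0.1]    # 20 samples < minimal valid input
        assert 0.0 <= results[0.5]["mean_accuracy"] <= 100.0
        again = ev.window_length_sweep(cleaned, spec, lengths_s=[0.5],
                                       seed=0)
        assert again[0.5]["mean_accuracy"] == results[0.5]["mean_accuracy"]
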