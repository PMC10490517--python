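"""Leave-one-subject-out evaluation with training-set balancing and the
five confusion-matrix metrics (accuracy, sensitivity, specificity,
balanced accuracy, geometric mean), each reported in percent.

The positive class defaults to label 0 (high engagement / manual driving).
Training folds are balanced by seeded random undersampling of the majority
class; test folds are never balanced.  Cohort results are aggregated as
mean +/- sample standard deviation over subjects; a fold whose sensitivity
or specificity is undefined (no positives / no negatives in the test set)
is excluded from that metric's aggregate and logged.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math

import numpy as np

from . import models
from .preprocessing import CleanedSession, Segment

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "sensitivity", "specificity",
                "balanced_accuracy", "geometric_mean")


class BalanceError(ValueError):
    """Training set cannot be balanced (a class is absent)."""


@dataclasses.dataclass
class ConfusionCounts:
    """Binary confusion counts for one test subject."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def percent_matrix(self) -> np.ndarray:
        """2x2 matrix [[TP, FN], [FP, TN]] (rows = actual positive/negative,
        columns = predicted) as percent of total."""
        m = np.array([[self.tp, self.fn], [self.fp, self.tn]], dtype=float)
        return 100.0 * m / self.total


@dataclasses.dataclass
class MetricsReport:
    """The five metrics in percent; undefined values are NaN."""

    subject_id: str
    accuracy: float
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    geometric_mean: float

    def as_dict(self) -> dict:
        return {"subject_id": self.subject_id,
                **{m: getattr(self, m) for m in METRIC_NAMES}}


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                               positive_label: int = 0) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t, pos_p = y_true == positive_label, y_pred == positive_label
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def compute_metrics(counts: ConfusionCounts,
                    subject_id: str = "") -> MetricsReport:
    """Accuracy, sensitivity, specificity, BA and GM in percent.

    BA = (sensitivity + specificity) / 2 and GM = sqrt(sens x spec) on the
    fractional scale; both are NaN when either constituent is undefined.
    """
    if counts.total <= 0:
        raise ValueError("empty confusion table")
    acc = 100.0 * (counts.tp + counts.tn) / counts.total
    sens = (100.0 * counts.tp / (counts.tp + counts.fn)
            if counts.tp + counts.fn > 0 else math.nan)
    spec = (100.0 * counts.tn / (counts.fp + counts.tn)
            if counts.fp + counts.tn > 0 else math.nan)
    ba = (sens + spec) / 2.0
    gm = 100.0 * math.sqrt((sens / 100.0) * (spec / 100.0)) \
        if not (math.isnan(sens) or math.isnan(spec)) else math.nan
    return MetricsReport(subject_id=subject_id, accuracy=acc,
                         sensitivity=sens, specificity=spec,
                         balanced_accuracy=ba, geometric_mean=gm)


def balance_training_set(segments: list[Segment],
                         seed: int) -> list[Segment]:
    """Seeded random undersampling of the majority class (without
    replacement) to the minority count.  Test sets are never balanced."""
    labels = np.array([s.label for s in segments])
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise BalanceError("both classes must be present to balance")
    n_min = counts.min()
    rng = np.random.default_rng(seed)
    keep = []
    for cls in classes:
        members = np.flatnonzero(labels == cls)
        keep.append(rng.choice(members, size=n_min, replace=False))
    keep = np.sort(np.concatenate(keep))
    return [segments[i] for i in keep]


@dataclasses.dataclass
class FoldResult:
    subject_id: str
    counts: ConfusionCounts
    report: MetricsReport


@dataclasses.dataclass
class CohortSummary:
    """Per-subject results plus mean +/- std aggregation.

    ``mean``/``std`` are computed over the folds where the metric is
    defined (sample std, ddof=1).  Per-subject confusion matrices are kept
    in percent-of-total normalization.
    """

    folds: list[FoldResult]
    positive_label: int = 0

    @property
    def reports(self) -> list[MetricsReport]:
        return [f.report for f in self.folds]

    def metric_values(self, name: str) -> np.ndarray:
        return np.array([getattr(r, name) for r in self.reports])

    def mean(self, name: str) -> float:
        vals = self.metric_values(name)
        defined = vals[~np.isnan(vals)]
        if len(defined) < len(vals):
            logger.info("%s undefined for %d fold(s); excluded from mean",
                        name, int(np.isnan(vals).sum()))
        return float(defined.mean()) if defined.size else math.nan

    def std(self, name: str) -> float:
        vals = self.metric_values(name)
        defined = vals[~np.isnan(vals)]
        if defined.size < 2:
            return math.nan
        return float(defined.std(ddof=1))

    def summary_table(self) -> dict:
        return {name: {"mean": self.mean(name), "std": self.std(name)}
                for name in METRIC_NAMES}

    def to_json(self) -> dict:
        return {
            "positive_label": self.positive_label,
            "folds": [
                {
                    "subject_id": f.subject_id,
                    "counts": dataclasses.asdict(f.counts),
                    "metrics": f.report.as_dict(),
                    "confusion_percent": f.counts.percent_matrix().tolist(),
                }
                for f in self.folds
            ],
            "summary": self.summary_table(),
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=2)

    def write_csv(self, path) -> None:
        import pandas as pd

        rows = [f.report.as_dict() for f in self.folds]
        pd.DataFrame(rows).to_csv(path, index=False)


def loso_evaluate(segments: list[Segment], spec: models.ModelSpec,
                  seed: int = 0, positive_label: int = 0) -> CohortSummary:
    """Leave-one-subject-out cross-validation.

    Each fold trains on the balanced union of all other subjects' segments
    and tests on every segment of the held-out subject (unbalanced).
    Subject disjointness between train and test is asserted per fold.
    """
    subjects = sorted({s.subject_id for s in segments})
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    folds = []
    for k, held_out in enumerate(subjects):
        test = [s for s in segments if s.subject_id == held_out]
        if not test:
            logger.warning("subject %s has no segments; fold skipped",
                           held_out)
            continue
        train_pool = [s for s in segments if s.subject_id != held_out]
        assert not {s.subject_id for s in train_pool} & {held_out}
        fold_seed = (seed * 1009 + k) % (2 ** 31)
        train_set = balance_training_set(train_pool, seed=fold_seed)
        fold_spec = dataclasses.replace(spec, seed=fold_seed)
        handle = models.build(fold_spec)
        models.train(handle, train_set, fold_spec)
        y_pred, _ = models.predict(handle, test)
        y_true = np.array([s.label for s in test])
        counts = confusion_from_predictions(y_true, y_pred, positive_label)
        folds.append(FoldResult(subject_id=held_out, counts=counts,
                                report=compute_metrics(counts, held_out)))
    return CohortSummary(folds=folds, positive_label=positive_label)


def window_length_sweep(cleaned: list[CleanedSession],
                        spec: models.ModelSpec, lengths_s: list[float],
                        seed: int = 0) -> dict[float, dict]:
    """Re-segment the cleaned recordings at each window length, rebuild the
    network for the new flatten width, and report LOSO mean accuracy.

    A length below the architecture's minimal valid input is reported as an
    error for that length instead of aborting the sweep.
    """
    results: dict[float, dict] = {}
    fs = cleaned[0].fs
    for length in lengths_s:
        window_samples = int(round(length * fs))
        try:
            models.time_after_blocks(window_samples)
        except Exception as err:
            results[length] = {"error": str(err)}
            continue
        segs = [s for cs in cleaned for s in cs.segments(window_s=length)]
        sweep_spec = dataclasses.replace(spec, window_samples=window_samples)
        summary = loso_evaluate(segs, sweep_spec, seed=seed)
        results[length] = {"mean_accuracy": summary.mean("accuracy"),
                           "std_accuracy": summary.std("accuracy"),
                           "n_segments": len(segs)}
    return results
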