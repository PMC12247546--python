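"""Model evaluation: nested cross-validation, LOSO, and chance levels.

Performance is estimated with a nested 9-fold scheme: trials are split into
10 stratified folds, one fold is fixed as the holdout test set, and each of
the remaining nine folds serves once as the validation set (used for early
stopping and for the reported cross-validation accuracy) while the other
eight are used for training. Chance levels come in three flavors: the
theoretical 1/K level, the binomial threshold accounting for the finite
trial count, and the empirical (de-facto) level obtained by decoding a
control session that carries no task-related signal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import EpochSet

__all__ = [
    "FoldPlan",
    "EvalReport",
    "DegenerateTestError",
    "make_fold_plan",
    "nested_cv",
    "aggregate_confusion",
    "loso_cv",
    "binomial_chance_threshold",
    "empirical_chance",
    "paired_accuracy_test",
]


class DegenerateTestError(ValueError):
    """Paired test on differences with zero variance is undefined."""


@dataclass
class FoldPlan:
    """Stratified 10-fold split: 9 rotating validation folds + fixed holdout.

    ``folds`` holds the nine candidate validation folds; ``test_idx`` is the
    fixed holdout fold reused across all nine rotations. Within any rotation
    the train/validation/test sets are pairwise disjoint and their union is
    the full trial index range.
    """

    folds: list[np.ndarray]
    test_idx: np.ndarray
    seed: int
    stratified: bool = True
    holdout: str = "fixed"   # "fixed": one test fold reused; "rotating":
    #                          the test fold rotates alongside validation

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def split(self, i: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(train, validation, test) indices for rotation ``i``."""
        if self.holdout == "fixed":
            val = self.folds[i]
            test = self.test_idx
            train = np.concatenate(
                [f for j, f in enumerate(self.folds) if j != i])
        else:
            parts = self.folds + [self.test_idx]
            val = parts[i]
            test = parts[(i + 1) % len(parts)]
            train = np.concatenate(
                [f for j, f in enumerate(parts)
                 if j != i and j != (i + 1) % len(parts)])
        return np.sort(train), np.sort(val), np.sort(test)


def make_fold_plan(
    n_trials: int,
    labels: np.ndarray,
    seed: int,
    n_folds: int = 10,
    holdout: str = "fixed",
) -> FoldPlan:
    """Random stratified partition into ``n_folds`` label-balanced folds.

    With ``holdout="fixed"`` (default) the last fold is the holdout test
    set reused across all rotations and the others rotate as validation;
    ``"rotating"`` rotates the test fold alongside the validation fold. If
    any class has fewer trials than ``n_folds`` the split falls back to an
    unstratified partition with a warning.
    """
    if holdout not in ("fixed", "rotating"):
        raise ValueError("holdout must be 'fixed' or 'rotating'")
    if n_trials < n_folds:
        raise ValueError(f"need at least {n_folds} trials")
    labels = np.asarray(labels)
    stratified = True
    counts = np.bincount(labels)
    if counts.min() < n_folds:
        warnings.warn("a class has fewer trials than folds; "
                      "falling back to unstratified folds", stacklevel=2)
        stratified = False
    if stratified:
        from sklearn.model_selection import StratifiedKFold
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                   random_state=seed)
    else:
        from sklearn.model_selection import KFold
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    parts = [test for _, test in splitter.split(np.zeros(n_trials), labels)]
    return FoldPlan(folds=parts[:-1], test_idx=parts[-1], seed=seed,
                    stratified=stratified, holdout=holdout)


@dataclass
class EvalReport:
    """Aggregated nested-CV results plus chance-level context."""

    fold_val_accuracy: list[float] = field(default_factory=list)
    fold_test_accuracy: list[float] = field(default_factory=list)
    confusion_counts: np.ndarray | None = None
    confusion_normalized: np.ndarray | None = None
    chance: dict = field(default_factory=dict)
    tests: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def val_mean(self) -> float:
        return float(np.mean(self.fold_val_accuracy))

    @property
    def val_sd(self) -> float:
        return float(np.std(self.fold_val_accuracy))

    @property
    def test_mean(self) -> float:
        return float(np.mean(self.fold_test_accuracy))

    @property
    def test_sd(self) -> float:
        return float(np.std(self.fold_test_accuracy))

    def to_dict(self) -> dict:
        def _clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            if isinstance(v, dict):
                return {k: _clean(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [_clean(x) for x in v]
            return v

        return {
            "fold_val_accuracy": [float(a) for a in self.fold_val_accuracy],
            "fold_test_accuracy": [float(a) for a in self.fold_test_accuracy],
            "val_mean": self.val_mean,
            "val_sd": self.val_sd,
            "test_mean": self.test_mean,
            "test_sd": self.test_sd,
            "confusion_counts": _clean(self.confusion_counts),
            "confusion_normalized": _clean(self.confusion_normalized),
            "chance": _clean(self.chance),
            "tests": _clean(self.tests),
            "metadata": _clean(self.metadata),
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2, sort_keys=True)


def _confusion_counts(true: np.ndarray, pred: np.ndarray, k: int) -> np.ndarray:
    m = np.zeros((k, k), dtype=np.int64)
    np.add.at(m, (true, pred), 1)
    return m


def nested_cv(
    epochs: EpochSet,
    model_cfg,
    plan: FoldPlan,
    classifier_factory=None,
) -> EvalReport:
    """Run the nested cross-validation over a fold plan.

    For every rotation a fresh classifier is trained on eight folds with the
    validation fold used for early stopping; validation accuracy and
    confusion counts plus the accuracy on the fixed holdout are recorded.
    ``classifier_factory`` may supply any object with
    ``fit(train_set, val_set)`` / ``predict(data)``; by default an LFCNN
    classifier is built from ``model_cfg``.
    """
    if classifier_factory is None:
        from .lfcnn import LFCNNClassifier
        n_classes = epochs.n_classes

        def classifier_factory():
            return LFCNNClassifier(model_cfg, n_classes=n_classes)

    k = epochs.n_classes
    report = EvalReport()
    per_fold_counts = []
    for i in range(plan.n_folds):
        tr, va, te = plan.split(i)
        clf = classifier_factory()
        clf.fit(epochs.subset(tr), epochs.subset(va))
        val_pred = np.asarray(clf.predict(epochs.data[va]))
        test_pred = np.asarray(clf.predict(epochs.data[te]))
        report.fold_val_accuracy.append(
            float(np.mean(val_pred == epochs.labels[va])))
        report.fold_test_accuracy.append(
            float(np.mean(test_pred == epochs.labels[te])))
        per_fold_counts.append(_confusion_counts(epochs.labels[va], val_pred, k))
    counts, norm, zero_rows = aggregate_confusion(per_fold_counts)
    report.confusion_counts = counts
    report.confusion_normalized = norm
    report.metadata["zero_confusion_rows"] = zero_rows
    report.metadata["n_folds"] = plan.n_folds
    report.metadata["stratified"] = plan.stratified
    report.chance["theoretical_pct"] = 100.0 / k
    report.chance["binomial_alpha_0.001_pct"] = binomial_chance_threshold(
        epochs.n_trials, k, 0.001)
    return report


def aggregate_confusion(
    per_fold_counts: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Sum per-fold confusion counts and row-normalize by true-class totals.

    Returns the summed counts, the row-normalized matrix (each row divided
    by its total; rows with zero total are left as zeros and flagged), and
    the list of flagged empty-class rows.
    """
    mats = [np.asarray(m) for m in per_fold_counts]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("confusion matrices must share a shape")
    counts = np.sum(mats, axis=0)
    totals = counts.sum(axis=1, keepdims=True).astype(float)
    zero_rows = [int(i) for i in np.flatnonzero(totals[:, 0] == 0)]
    safe = np.where(totals == 0, 1.0, totals)
    norm = counts / safe
    return counts, norm, zero_rows


def loso_cv(
    sessions: list[EpochSet],
    model_cfg,
    seed: int = 0,
    classifier_factory=None,
    val_fraction: float = 0.1,
) -> dict:
    """Leave-one-subject-out evaluation over per-subject sessions.

    For each subject the model is trained on the pooled trials of all other
    subjects, with ``val_fraction`` of the pooled data held out (stratified)
    for early stopping; accuracy is reported both on that pooled validation
    set and on the entire left-out subject.
    """
    from sklearn.model_selection import train_test_split

    if len(sessions) < 3:
        raise ValueError("LOSO needs at least 3 sessions")
    n_ch = sessions[0].n_channels
    if any(s.n_channels != n_ch for s in sessions):
        raise ValueError("sessions have inconsistent channel counts")
    if classifier_factory is None:
        from .lfcnn import LFCNNClassifier
        n_classes = max(s.n_classes for s in sessions)

        def classifier_factory():
            return LFCNNClassifier(model_cfg, n_classes=n_classes)

    held_out_acc, pooled_val_acc = [], []
    for hold in range(len(sessions)):
        rest = [s for j, s in enumerate(sessions) if j != hold]
        data = np.concatenate([s.data for s in rest])
        labels = np.concatenate([s.labels for s in rest])
        idx = np.arange(len(labels))
        tr, va = train_test_split(idx, test_size=val_fraction,
                                  stratify=labels, random_state=seed + hold)
        ref = rest[0]
        pooled = EpochSet(data=data, labels=labels, sfreq=ref.sfreq,
                          window=ref.window, class_names=list(ref.class_names))
        clf = classifier_factory()
        clf.fit(pooled.subset(tr), pooled.subset(va))
        val_pred = np.asarray(clf.predict(data[va]))
        test = sessions[hold]
        test_pred = np.asarray(clf.predict(test.data))
        pooled_val_acc.append(float(np.mean(val_pred == labels[va])))
        held_out_acc.append(float(np.mean(test_pred == test.labels)))
    return {
        "held_out_accuracy": held_out_acc,
        "pooled_val_accuracy": pooled_val_acc,
        "held_out_mean": float(np.mean(held_out_acc)),
        "pooled_val_mean": float(np.mean(pooled_val_acc)),
    }


def binomial_chance_threshold(n_trials: int, n_classes: int,
                              alpha: float) -> float:
    """Accuracy (percent) above which a classifier beats guessing at level alpha.

    The smallest trial count ``k`` with ``P(X >= k) < alpha`` (strict) for
    ``X ~ Binomial(n_trials, 1/n_classes)``, returned as ``100 k / n``. As
    ``n`` grows the threshold approaches the theoretical ``100 / K``. When
    even a perfect score is not significant at ``alpha`` (tiny ``n``), the
    returned value exceeds 100%, signaling that significance is
    unattainable at this sample size.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    if n_trials < 1:
        raise ValueError("n_trials must be positive")
    p = 1.0 / n_classes
    ks = np.arange(n_trials + 2)
    sf = stats.binom.sf(ks - 1, n_trials, p)  # P(X >= k)
    k = int(ks[np.argmax(sf < alpha)])
    return 100.0 * k / n_trials


def empirical_chance(control_report: EvalReport) -> float:
    """De-facto chance level: mean CV accuracy of a control decode, percent."""
    return round(100.0 * float(np.mean(control_report.fold_val_accuracy)), 1)


def paired_accuracy_test(acc_a, acc_b) -> tuple[float, float]:
    """Two-sided paired Student's t-test on per-subject accuracy differences."""
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length paired samples of size >= 2")
    d = a - b
    if np.std(d) == 0.0:
        raise DegenerateTestError("zero-variance differences: t undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
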