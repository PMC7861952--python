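"""Cross-validation planning and subject-averaged accuracy reporting.

The evaluation protocol is threefold cross-validation stratified within each
(subject, class) group by repetition index, so all analysis windows of one
trial stay on the same side of the split, and accuracy is averaged per subject
with an unweighted mean across subjects (each subject counts equally no matter
how many trials they contributed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import LabeledSignalSet

__all__ = ["CvPlan", "AccuracyReport", "make_cv_folds", "subject_average"]

log = logging.getLogger(__name__)


@dataclass
class CvPlan:
    """Fold assignment over trial ids; folds partition the trial set."""

    folds: list[tuple[np.ndarray, np.ndarray]]  # (train_ids, test_ids)
    n_folds: int = 3

    def validate_partition(self, all_ids: np.ndarray) -> None:
        all_ids = np.asarray(sorted(all_ids))
        test_union = np.sort(np.concatenate([t for _, t in self.folds]))
        if test_union.shape != all_ids.shape or np.any(test_union != all_ids):
            raise ValueError("test folds do not partition the trial set")
        for train, test in self.folds:
            if np.intersect1d(train, test).size:
                raise ValueError("train/test overlap within a fold")


@dataclass
class AccuracyReport:
    """Per-subject, per-class and subject-averaged overall accuracy."""

    per_subject_accuracy: dict[int, float]
    overall_accuracy: float
    per_class_accuracy: dict[int, float]
    split_name: str = "test"
    n_trials: int = 0

    def to_dict(self) -> dict:
        return {
            "split": self.split_name,
            "overall_accuracy": self.overall_accuracy,
            "per_subject_accuracy": {str(k): v for k, v in self.per_subject_accuracy.items()},
            "per_class_accuracy": {str(k): v for k, v in self.per_class_accuracy.items()},
            "n_trials": self.n_trials,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def make_cv_folds(dataset: LabeledSignalSet, n_folds: int = 3, seed: int = 0) -> CvPlan:
    """Build a CV plan stratified by repetition within each (subject, class).

    With 6 repetitions and 3 folds every fold's test set holds exactly 2
    repetitions of every (subject, class) group, reproducing a 2/3 train,
    1/3 test split per group.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)

    groups: dict[tuple[int, int], list[int]] = {}
    for t in dataset:
        groups.setdefault((t.subject_id, t.class_label), []).append(t.trial_id)

    fold_test: list[list[int]] = [[] for _ in range(n_folds)]
    for (subj, cls), ids in sorted(groups.items()):
        if len(ids) < n_folds:
            raise ValueError(
                f"group (subject={subj}, class={cls}) has {len(ids)} trials, "
                f"fewer than n_folds={n_folds}"
            )
        ids = np.array(sorted(ids))
        perm = rng.permutation(len(ids))
        for pos, idx in enumerate(perm):
            fold_test[pos % n_folds].append(int(ids[idx]))

    all_ids = np.array(sorted(t.trial_id for t in dataset))
    folds = []
    for k in range(n_folds):
        test = np.array(sorted(fold_test[k]))
        train = np.setdiff1d(all_ids, test)
        folds.append((train, test))
    plan = CvPlan(folds=folds, n_folds=n_folds)
    plan.validate_partition(all_ids)
    return plan


def subject_average(
    subject_ids: np.ndarray,
    y_true: np.ndarray,
    y_pred: np.ndarray,
    split_name: str = "test",
) -> AccuracyReport:
    """Accuracy per subject, then the unweighted mean across subjects.

    Subjects contribute equally to the overall figure regardless of their
    trial counts.  Per-class accuracy (recall of each class) is pooled over
    all trials; a subject with zero trials is excluded with a warning.
    """
    subject_ids = np.asarray(subject_ids)
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if not (subject_ids.shape == y_true.shape == y_pred.shape):
        raise ValueError("subject_ids, y_true, y_pred must have equal length")

    per_subject: dict[int, float] = {}
    for s in np.unique(subject_ids):
        mask = subject_ids == s
        if not mask.any():  # pragma: no cover - unique() precludes this
            log.warning("subject %s has no trials; excluded from the average", s)
            continue
        per_subject[int(s)] = float(np.mean(y_true[mask] == y_pred[mask]))

    per_class: dict[int, float] = {}
    for c in np.unique(y_true):
        mask = y_true == c
        per_class[int(c)] = float(np.mean(y_pred[mask] == c))

    overall = float(np.mean(list(per_subject.values()))) if per_subject else float("nan")
    return AccuracyReport(
        per_subject_accuracy=per_subject,
        overall_accuracy=overall,
        per_class_accuracy=per_class,
        split_name=split_name,
        n_trials=int(y_true.shape[0]),
    )
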