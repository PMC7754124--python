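"""Fragment-level SVM/RF classification under patient-grouped 10-fold CV,
the confusion taxonomy, and the >= 5-of-10 majority-vote sample judgement.

Folds are assigned at *patient* level so that all fragments of a patient
(and hence of a sample) share one fold: without this grouping, fragments
of the same acquisition would leak between training and test sets and
inflate accuracy.  Assignment is stratified by the patient's sample-label
profile so each fold's class mix approximates the global one.

The error taxonomy follows the clinical reading: *false positive* — true
non-tumour predicted as any tumour class; *false negative* — true tumour
predicted non-tumour; *misclassified* — one tumour histotype predicted as
the other (only possible in the 3-class task); *concordant* — exact match
with the pathology label.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .model import (
    TUMOUR_LABELS,
    FeatureMatrix,
    PipelineConfig,
    SampleRecord,
    ValidationError,
)

__all__ = [
    "TASKS",
    "assign_folds",
    "train_classifier",
    "crossval",
    "fragment_confusion",
    "majority_vote",
    "sample_confusion",
    "ConfusionSummary",
    "SampleJudgement",
]

#: task name -> (cohort filter or None for all rows)
TASKS = {
    "hcc-vs-nt": "HCC_cohort",
    "mfccc-vs-nt": "MFCCC_cohort",
    "three-class": None,
}

#: task name -> admissible label space
TASK_LABELS = {
    "hcc-vs-nt": frozenset({"HCC", "NONTUMOUR"}),
    "mfccc-vs-nt": frozenset({"MFCCC", "NONTUMOUR"}),
    "three-class": frozenset({"HCC", "MFCCC", "NONTUMOUR"}),
}

INDETERMINATE = "INDETERMINATE"


# ------------------------------------------------------------------ folds

def assign_folds(manifest: list[SampleRecord], k: int, seed: int) -> dict[str, int]:
    """Map each patient_id to a fold in [0, k), stratified and seeded.

    Patients are stratified by the multiset of tissue labels they
    contribute (e.g. tumour+paired-non-tumour vs tumour-only, per cohort),
    shuffled within stratum, and dealt round-robin, so fold sizes within a
    stratum differ by at most one patient.
    """
    by_patient: dict[str, list[SampleRecord]] = {}
    for rec in manifest:
        by_patient.setdefault(rec.patient_id, []).append(rec)
    if k > len(by_patient):
        raise ValidationError(
            f"k={k} folds requested but only {len(by_patient)} patients available"
        )
    strata: dict[tuple, list[str]] = {}
    for pid, recs in by_patient.items():
        key = (recs[0].cohort, tuple(sorted(r.tissue_label for r in recs)))
        strata.setdefault(key, []).append(pid)
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    offset = 0
    for key in sorted(strata):
        pids = sorted(strata[key])
        rng.shuffle(pids)
        for i, pid in enumerate(pids):
            assignment[pid] = (offset + i) % k
        offset += len(pids)  # stagger strata so fold totals stay balanced
    return assignment


# ------------------------------------------------------------- classifier

def train_classifier(X: np.ndarray, y: np.ndarray, algo: str, config: PipelineConfig | None = None):
    """Fit an SVM (RBF on standardized features) or a 500-tree random forest.

    Standardization parameters are learned inside the returned pipeline,
    i.e. on the training rows only when used under cross-validation.
    """
    cfg = config or PipelineConfig()
    if len(set(np.asarray(y).tolist())) < 2:
        raise ValidationError("training fold contains a single class")
    if algo == "svm":
        model = Pipeline(
            [
                ("scale", StandardScaler()),
                ("svc", SVC(kernel="rbf", C=cfg.svm_c, gamma=cfg.svm_gamma)),
            ]
        )
    elif algo == "rf":
        model = RandomForestClassifier(
            n_estimators=cfg.rf_n_trees,
            max_features="sqrt",
            random_state=cfg.seed,
            n_jobs=1,
        )
    else:
        raise ValidationError(f"unknown algorithm {algo!r}; expected 'svm' or 'rf'")
    model.fit(X, y)
    return model


# --------------------------------------------------------------- crossval

def _task_rows(fm: FeatureMatrix, task: str) -> np.ndarray:
    if task not in TASKS:
        raise ValidationError(f"unknown task {task!r}; expected one of {sorted(TASKS)}")
    cohort = TASKS[task]
    if cohort is None:
        return np.ones(fm.n_rows, dtype=bool)
    return (fm.row_meta["cohort"] == cohort).to_numpy()


def crossval(
    fm: FeatureMatrix,
    folds: dict[str, int],
    algo: str,
    task: str,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Patient-grouped K-fold cross-validation on one classification task.

    Returns the fragment-level predictions table with columns
    ``sample_id, patient_id, fragment_index, true_label, predicted_label,
    fold``; every selected row is predicted exactly once, by a model that
    never saw any fragment of the same patient.
    """
    cfg = config or PipelineConfig()
    sel = _task_rows(fm, task)
    sub = fm.select(sel)
    meta = sub.row_meta
    fold_of_row = meta["patient_id"].map(folds)
    if fold_of_row.isna().any():
        missing = meta.loc[fold_of_row.isna(), "patient_id"].iloc[0]
        raise ValidationError(f"patient {missing!r} has no fold assignment")
    fold_of_row = fold_of_row.to_numpy(dtype=int)
    y = meta["tissue_label"].to_numpy()
    preds = np.empty(sub.n_rows, dtype=object)
    for f in sorted(set(fold_of_row.tolist())):
        test = fold_of_row == f
        train = ~test
        if not test.any():
            raise ValidationError(f"fold {f} has an empty test set")
        # leakage guard: train/test patient sets must be disjoint
        train_p = set(meta.loc[train, "patient_id"])
        test_p = set(meta.loc[test, "patient_id"])
        if train_p & test_p:
            raise ValidationError(f"patient leakage across fold {f}: {train_p & test_p}")
        try:
            model = train_classifier(sub.X[train], y[train], algo, cfg)
        except ValidationError as exc:
            raise ValidationError(f"fold {f}: {exc}") from exc
        preds[test] = model.predict(sub.X[test])
    return pd.DataFrame(
        {
            "sample_id": meta["sample_id"],
            "patient_id": meta["patient_id"],
            "fragment_index": meta["fragment_index"],
            "true_label": y,
            "predicted_label": preds.astype(str),
            "fold": fold_of_row,
        }
    ).reset_index(drop=True)


# -------------------------------------------------------------- confusion

@dataclass
class ConfusionSummary:
    """Counts and derived metrics of one task's predictions.

    ``n_concordant + n_false_positive + n_false_negative + n_misclassified
    == n_total`` always holds; binary tasks have ``n_misclassified == 0``.
    Sensitivity counts concordant tumour items over all tumour items,
    specificity concordant non-tumour over all non-tumour.
    """

    task: str
    n_total: int
    n_concordant: int
    n_false_positive: int
    n_false_negative: int
    n_misclassified: int
    n_tumour: int
    n_nontumour: int
    n_concordant_tumour: int
    n_concordant_nontumour: int
    per_class_recall: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        parts = (
            self.n_concordant + self.n_false_positive
            + self.n_false_negative + self.n_misclassified
        )
        if parts != self.n_total:
            raise ValidationError(
                f"confusion counts sum to {parts}, expected n_total={self.n_total}"
            )
        if min(self.n_concordant, self.n_false_positive, self.n_false_negative,
               self.n_misclassified) < 0:
            raise ValidationError("confusion counts must be >= 0")

    @property
    def accuracy(self) -> float:
        return self.n_concordant / self.n_total if self.n_total else math.nan

    @property
    def sensitivity(self) -> float:
        return self.n_concordant_tumour / self.n_tumour if self.n_tumour else math.nan

    @property
    def specificity(self) -> float:
        return (
            self.n_concordant_nontumour / self.n_nontumour if self.n_nontumour else math.nan
        )

    def as_dict(self) -> dict:
        return {
            "task": self.task,
            "n_total": self.n_total,
            "n_concordant": self.n_concordant,
            "n_false_positive": self.n_false_positive,
            "n_false_negative": self.n_false_negative,
            "n_misclassified": self.n_misclassified,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "per_class_recall": self.per_class_recall,
        }


def _categorize(true_label: str, pred_label: str) -> str:
    if true_label == pred_label:
        return "concordant"
    true_tum = true_label in TUMOUR_LABELS
    pred_tum = pred_label in TUMOUR_LABELS
    if not true_tum and pred_tum:
        return "false_positive"
    if true_tum and not pred_tum:
        return "false_negative"
    return "misclassified"  # HCC <-> MFCCC


def _summarize(task: str, true: np.ndarray, pred: np.ndarray) -> ConfusionSummary:
    labels_in_task = set(true.tolist())
    cats = Counter(_categorize(t, p) for t, p in zip(true, pred))
    is_tum = np.asarray([t in TUMOUR_LABELS for t in true])
    correct = true == pred
    recall = {}
    for c in sorted(labels_in_task):
        m = true == c
        recall[c] = float(correct[m].mean()) if m.any() else math.nan
    return ConfusionSummary(
        task=task,
        n_total=int(true.size),
        n_concordant=cats.get("concordant", 0),
        n_false_positive=cats.get("false_positive", 0),
        n_false_negative=cats.get("false_negative", 0),
        n_misclassified=cats.get("misclassified", 0),
        n_tumour=int(is_tum.sum()),
        n_nontumour=int((~is_tum).sum()),
        n_concordant_tumour=int(correct[is_tum].sum()),
        n_concordant_nontumour=int(correct[~is_tum].sum()),
        per_class_recall=recall,
    )


def fragment_confusion(preds: pd.DataFrame, task: str) -> ConfusionSummary:
    """Fragment-level confusion summary of a predictions table."""
    true = preds["true_label"].to_numpy()
    pred = preds["predicted_label"].to_numpy()
    space = TASK_LABELS.get(task, set(true.tolist()))
    for p in set(pred.tolist()) | set(true.tolist()):
        if p not in space:
            raise ValidationError(
                f"label {p!r} outside task label space {sorted(space)}"
            )
    return _summarize(task, true, pred)


# ---------------------------------------------------------- majority vote

@dataclass(frozen=True)
class SampleJudgement:
    """Majority-vote verdict of one sample from its fragment predictions."""

    sample_id: str
    n_fragments: int
    n_correct: int
    verdict: str  # "concordant" | "non_concordant"
    predicted_sample_label: str
    tie_flag: bool


def majority_vote(preds: pd.DataFrame) -> list[SampleJudgement]:
    """Aggregate fragment predictions into per-sample verdicts.

    A sample is *concordant* iff at least ``ceil(n/2)`` of its fragments
    match the pathology label (>= 5 of 10).  The predicted sample label is
    the modal fragment prediction; a modal tie is flagged and the label
    set to ``INDETERMINATE``.
    """
    out = []
    for sid, grp in preds.groupby("sample_id", sort=True):
        n = len(grp)
        n_correct = int((grp["true_label"] == grp["predicted_label"]).sum())
        counts = Counter(grp["predicted_label"])
        top = counts.most_common()
        tie = len(top) > 1 and top[0][1] == top[1][1]
        label = INDETERMINATE if tie else top[0][0]
        out.append(
            SampleJudgement(
                sample_id=str(sid),
                n_fragments=n,
                n_correct=n_correct,
                verdict="concordant" if n_correct >= math.ceil(n / 2) else "non_concordant",
                predicted_sample_label=label,
                tie_flag=tie,
            )
        )
    return out


def sample_confusion(judgements: list[SampleJudgement], preds: pd.DataFrame, task: str = "") -> ConfusionSummary:
    """Sample-level confusion from modal predicted labels.

    An ``INDETERMINATE`` modal label counts as an error on the side of the
    true label (tumour sample -> false negative, non-tumour -> false
    positive); this is conservative, and only arises on even vote splits.
    """
    true_of_sample = preds.groupby("sample_id", sort=True)["true_label"].first()
    true = np.asarray([true_of_sample[j.sample_id] for j in judgements])
    pred = []
    for j, t in zip(judgements, true):
        if j.predicted_sample_label == INDETERMINATE:
            pred.append("NONTUMOUR" if t in TUMOUR_LABELS else "HCC")
        else:
            pred.append(j.predicted_sample_label)
    return _summarize(task or "sample-level", true, np.asarray(pred))
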