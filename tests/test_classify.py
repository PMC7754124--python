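import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pesiml.classify import (
    assign_folds,
    crossval,
    fragment_confusion,
    majority_vote,
    sample_confusion,
    train_classifier,
)
from pesiml.model import PipelineConfig, SampleRecord, ValidationError


def _manifest(n_patients, cohort="HCC_cohort", tumour="HCC", paired=True):
    recs = []
    for i in range(n_patients):
        pid = f"P{i:03d}"
        recs.append(SampleRecord(f"{pid}T", pid, tumour, cohort))
        if paired:
            recs.append(SampleRecord(f"{pid}N", pid, "NONTUMOUR", cohort))
    return recs


class TestAssignFolds:
    def test_ten_patients_ten_folds_one_each(self):
        folds = assign_folds(_manifest(10), k=10, seed=0)
        assert sorted(folds.values()) == list(range(10))

    def test_no_patient_in_two_folds(self):
        folds = assign_folds(_manifest(25), k=10, seed=1)
        assert len(folds) == 25  # dict: one fold per patient by construction
        sizes = np.bincount(list(folds.values()), minlength=10)
        assert sizes.max() - sizes.min() <= 1

    def test_all_fragments_of_a_sample_share_fold(self, fast_cohort):
        manifest, fm = fast_cohort
        folds = assign_folds(manifest, k=5, seed=0)
        fold_col = fm.row_meta["patient_id"].map(folds)
        per_sample = fm.row_meta.assign(fold=fold_col).groupby("sample_id")["fold"].nunique()
        assert (per_sample == 1).all()

    def test_more_folds_than_patients_rejected(self):
        with pytest.raises(ValidationError, match="patients"):
            assign_folds(_manifest(5), k=10, seed=0)


class TestTrainClassifier:
    def _toy(self, rng, n=10):
        X = np.vstack([rng.normal(0, 0.3, (n, 2)), rng.normal(5, 0.3, (n, 2))])
        y = np.array(["HCC"] * n + ["NONTUMOUR"] * n)
        return X, y

    @pytest.mark.parametrize("algo", ["svm", "rf"])
    def test_separable_toy_training_accuracy_one(self, algo):
        X, y = self._toy(np.random.default_rng(0))
        model = train_classifier(X, y, algo)
        assert (model.predict(X) == y).all()

    def test_rf_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 5))
        y = np.array(["HCC", "NONTUMOUR"] * 20)
        cfg = PipelineConfig(seed=7, rf_n_trees=50)
        p1 = train_classifier(X, y, "rf", cfg).predict(X)
        p2 = train_classifier(X, y, "rf", cfg).predict(X)
        assert (p1 == p2).all()

    def test_single_class_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValidationError, match="single class"):
            train_classifier(X, np.array(["HCC"] * 5), "svm")

    def test_unknown_algo_rejected(self):
        X, y = self._toy(np.random.default_rng(0))
        with pytest.raises(ValidationError, match="unknown algorithm"):
            train_classifier(X, y, "xgboost")

    def test_shuffled_labels_give_chance_holdout_accuracy(self):
        """Null calibration: random labels -> held-out accuracy at chance."""
        rng = np.random.default_rng(2)
        accs = []
        for _ in range(5):
            X = rng.normal(size=(120, 6))
            y = np.array(["HCC", "NONTUMOUR"] * 60)
            rng.shuffle(y)
            model = train_classifier(X[:80], y[:80], "svm")
            accs.append((model.predict(X[80:]) == y[80:]).mean())
        n = 5 * 40
        half_width = stats.norm.ppf(0.995) * 0.5 / np.sqrt(n)
        assert abs(np.mean(accs) - 0.5) <= half_width


def _preds_from_counts(n_tumour, n_nontumour, fn, fp, tumour="HCC", frag_per_sample=10):
    """Construct a fragment predictions table with exact error counts."""
    rows = []
    idx = 0
    for true, n, errors, wrong in (
        (tumour, n_tumour, fn, "NONTUMOUR"),
        ("NONTUMOUR", n_nontumour, fp, tumour),
    ):
        for i in range(n):
            sid = f"{true}{i // frag_per_sample}"
            pred = wrong if i < errors else true
            rows.append((sid, f"p_{sid}", i % frag_per_sample, true, pred, 0))
            idx += 1
    return pd.DataFrame(
        rows,
        columns=["sample_id", "patient_id", "fragment_index", "true_label",
                 "predicted_label", "fold"],
    )


class TestFragmentConfusion:
    def test_counts_sum_and_all_correct(self):
        preds = _preds_from_counts(50, 50, 0, 0)
        c = fragment_confusion(preds, "hcc-vs-nt")
        assert c.accuracy == 1.0
        assert (c.n_false_positive, c.n_false_negative, c.n_misclassified) == (0, 0, 0)

    def test_binary_task_has_no_misclassified(self):
        preds = _preds_from_counts(100, 100, 7, 11)
        c = fragment_confusion(preds, "hcc-vs-nt")
        assert c.n_misclassified == 0
        assert c.n_concordant + c.n_false_positive + c.n_false_negative == c.n_total

    def test_three_class_misclassified_detected(self):
        preds = _preds_from_counts(50, 50, 0, 0)
        preds.loc[preds.index[:5], "predicted_label"] = "MFCCC"  # HCC -> MFCCC
        c = fragment_confusion(preds, "three-class")
        assert c.n_misclassified == 5

    def test_label_outside_task_space_rejected(self):
        preds = _preds_from_counts(10, 10, 0, 0)
        preds.loc[preds.index[0], "predicted_label"] = "MFCCC"
        with pytest.raises(ValidationError, match="MFCCC"):
            fragment_confusion(preds, "hcc-vs-nt")


class TestMajorityVote:
    def test_five_of_ten_is_concordant(self):
        preds = _preds_from_counts(10, 0, 5, 0)  # one sample, 5 wrong fragments
        (j,) = majority_vote(preds)
        assert j.n_correct == 5
        assert j.verdict == "concordant"
        assert j.tie_flag  # 5-5 split in a binary task is a modal tie

    def test_four_of_ten_is_non_concordant(self):
        preds = _preds_from_counts(10, 0, 6, 0)
        (j,) = majority_vote(preds)
        assert j.n_correct == 4
        assert j.verdict == "non_concordant"

    def test_modal_label_and_no_tie_on_clear_majority(self):
        preds = _preds_from_counts(10, 0, 2, 0)
        (j,) = majority_vote(preds)
        assert j.predicted_sample_label == "HCC"
        assert not j.tie_flag

    def test_concordance_matches_binomial_tail(self):
        """Fraction of concordant samples over many i.i.d. samples matches
        P(Bin(10, 1-p) >= 5) within 3 standard errors."""
        rng = np.random.default_rng(0)
        p_err, n_samples, n_frag = 0.3, 10_000, 10
        correct = rng.random((n_samples, n_frag)) >= p_err
        rows = []
        for s in range(n_samples):
            for f in range(n_frag):
                rows.append(
                    (f"S{s:05d}", f"P{s:05d}", f, "HCC",
                     "HCC" if correct[s, f] else "NONTUMOUR", 0)
                )
        preds = pd.DataFrame(
            rows, columns=["sample_id", "patient_id", "fragment_index",
                           "true_label", "predicted_label", "fold"]
        )
        judgements = majority_vote(preds)
        frac = np.mean([j.verdict == "concordant" for j in judgements])
        expected = stats.binom.sf(4, n_frag, 1 - p_err)  # P(X >= 5)
        se = np.sqrt(expected * (1 - expected) / n_samples)
        assert abs(frac - expected) <= 3 * se


class TestSampleConfusion:
    def test_reported_sample_concordance_arithmetic(self):
        # 222 samples, 25 with >5 wrong fragments -> concordance 88.7%
        preds = _preds_from_counts(1170, 1050, 250, 0)
        assert preds["sample_id"].nunique() == 222
        judgements = majority_vote(preds)
        c = sample_confusion(judgements, preds)
        assert round(100 * c.accuracy, 1) == 88.7
        assert c.n_false_negative == 25

    def test_one_false_negative_of_96(self):
        preds = _preds_from_counts(500, 460, 10, 0, tumour="MFCCC")
        judgements = majority_vote(preds)
        c = sample_confusion(judgements, preds)
        assert c.n_total == 96
        assert round(100 * c.accuracy, 1) == 99.0

    def test_all_concordant(self):
        preds = _preds_from_counts(100, 100, 0, 0)
        judgements = majority_vote(preds)
        c = sample_confusion(judgements, preds)
        assert c.accuracy == 1.0


class TestCrossval:
    def test_every_row_predicted_once_and_leakage_free(self, fast_cohort):
        manifest, fm = fast_cohort
        folds = assign_folds(manifest, k=3, seed=0)
        preds = crossval(fm, folds, "svm", "three-class", PipelineConfig(seed=0))
        assert len(preds) == fm.n_rows
        merged = preds.merge(
            pd.DataFrame({"patient_id": list(folds), "fold_assigned": list(folds.values())}),
            on="patient_id",
        )
        assert (merged["fold"] == merged["fold_assigned"]).all()

    def test_task_row_selection(self, fast_cohort):
        manifest, fm = fast_cohort
        folds = assign_folds(manifest, k=3, seed=0)
        cfg = PipelineConfig(seed=0, rf_n_trees=50)
        n_hcc_arm = int((fm.row_meta["cohort"] == "HCC_cohort").sum())
        preds = crossval(fm, folds, "rf", "hcc-vs-nt", cfg)
        assert len(preds) == n_hcc_arm
        assert set(preds["true_label"]) == {"HCC", "NONTUMOUR"}

    def test_deterministic_repeat(self, fast_cohort):
        manifest, fm = fast_cohort
        folds = assign_folds(manifest, k=3, seed=1)
        cfg = PipelineConfig(seed=1, rf_n_trees=50)
        p1 = crossval(fm, folds, "rf", "hcc-vs-nt", cfg)
        p2 = crossval(fm, folds, "rf", "hcc-vs-nt", cfg)
        pd.testing.assert_frame_equal(p1, p2)

    def test_missing_fold_assignment_rejected(self, fast_cohort):
        _, fm = fast_cohort
        with pytest.raises(ValidationError, match="fold"):
            crossval(fm, {"nobody": 0}, "svm", "three-class")
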