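import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilspec.dataset import SpectraSet
from soilspec.pls import PLS2Regression
from soilspec.plsda import (
    ConfusionMatrix,
    PLSDAClassifier,
    accuracy_curve,
    assign_class,
    confusion,
    decode_indicator,
    encode_indicator,
    loo_cv,
    overall_accuracy,
    per_class_accuracy,
    train_confusion,
)
from soilspec.reference import CLASS_TOTALS, reported_confusions


class TestIndicator:
    def test_explicit_example(self):
        Y = encode_indicator(["A", "B", "A"], ["A", "B"])
        assert Y.tolist() == [[1, 0], [0, 1], [1, 0]]
        assert decode_indicator(Y, ["A", "B"]) == ["A", "B", "A"]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="'C'"):
            encode_indicator(["C"], ["A", "B"])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.sampled_from(["A", "B", "C"]), min_size=1, max_size=30))
    def test_round_trip_and_row_sums(self, labels):
        Y = encode_indicator(labels, ["A", "B", "C"])
        assert np.all(Y.sum(axis=1) == 1)
        assert decode_indicator(Y, ["A", "B", "C"]) == labels

    def test_study_training_column_sums(self):
        """153 training labels at the study's class counts -> (24,48,19,30,32)."""
        train_counts = (24, 48, 19, 30, 32)
        classes = list(CLASS_TOTALS)
        labels = [c for c, n in zip(classes, train_counts) for _ in range(n)]
        Y = encode_indicator(labels, classes)
        assert tuple(Y.sum(axis=0).astype(int)) == train_counts


class TestAssignClass:
    def test_largest_value_wins(self):
        row = [[0.1, 0.7, 0.05, 0.1, 0.05]]
        assert assign_class(row, ["c1", "c2", "c3", "c4", "c5"]) == ["c2"]

    def test_tie_goes_to_earliest_class(self):
        assert assign_class([[0.5, 0.5, 0, 0, 0]], list("abcde")) == ["a"]

    def test_nonfinite_row_identified(self):
        with pytest.raises(ValueError, match="row 1"):
            assign_class([[0.1, 0.2], [np.nan, 0.3]], ["A", "B"])

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(0)
        P = rng.normal(size=(50, 4))
        classes = ["w", "x", "y", "z"]
        got = assign_class(P, classes)
        for i, row in enumerate(P):
            best, best_v = None, -np.inf
            for j, c in enumerate(classes):
                if row[j] > best_v:
                    best, best_v = c, row[j]
            assert got[i] == best

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_row_shift_invariance(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(6, 3))
        shift = rng.normal(size=(6, 1))
        assert assign_class(P, ["A", "B", "C"]) == assign_class(P + shift, ["A", "B", "C"])


class TestConfusionAndAccuracy:
    def test_perfect_prediction_is_diagonal(self):
        cm = confusion(["A", "B", "B"], ["A", "B", "B"], ["A", "B"])
        assert cm.counts.tolist() == [[1, 0], [0, 2]]
        assert overall_accuracy(cm) == 100.0

    def test_total_count_conserved_under_prediction_permutation(self):
        rng = np.random.default_rng(1)
        true = list(rng.choice(["A", "B", "C"], size=30))
        pred = list(rng.permutation(true))
        cm = confusion(true, pred, ["A", "B", "C"])
        assert cm.total == 30
        assert cm.counts.sum(axis=1).tolist() == [true.count(c) for c in "ABC"]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="2 true vs 1"):
            confusion(["A", "A"], ["A"], ["A"])

    def test_reported_loo_matrix_accuracies(self):
        """All-feature model, LOO block: rows sum to the training counts and
        the overall accuracy recomputes to the published 88.89%."""
        cm = reported_confusions("plsda")["loo"]
        assert cm.counts.sum(axis=1).tolist() == [24, 48, 19, 30, 32]
        assert round(overall_accuracy(cm), 2) == 88.89
        acc = per_class_accuracy(cm)
        assert round(acc[2], 2) == 63.16  # Chernozems row (1,3,12,0,3)

    def test_empty_class_row_is_nan_not_zero(self):
        cm = ConfusionMatrix(np.array([[2, 0], [0, 0]]), ("A", "B"))
        acc = per_class_accuracy(cm)
        assert acc[0] == 100.0 and np.isnan(acc[1])

    def test_all_off_diagonal_row_is_zero(self):
        cm = ConfusionMatrix(np.array([[0, 3], [1, 1]]), ("A", "B"))
        assert per_class_accuracy(cm)[0] == 0.0


class TestLOO:
    def test_matches_bruteforce_refit_loop(self, tiny_spectra):
        a = 2
        cm = loo_cv(tiny_spectra, a)
        # literal loop: one independent fit/predict per held-out sample
        preds = []
        X = tiny_spectra.absorbance
        for i in range(tiny_spectra.n_samples):
            keep = [j for j in range(tiny_spectra.n_samples) if j != i]
            Y = encode_indicator(
                [tiny_spectra.labels[j] for j in keep], tiny_spectra.class_order
            )
            m = PLS2Regression(a).fit(X[keep], Y)
            preds.append(
                assign_class(m.predict(X[i : i + 1]), tiny_spectra.class_order)[0]
            )
        ref = confusion(tiny_spectra.labels, preds, tiny_spectra.class_order)
        assert np.array_equal(cm.counts, ref.counts)

    def test_separable_two_class_single_feature(self):
        wn = np.array([5000.0])
        X = np.array([[0.0], [0.1], [0.2], [1.0], [1.1], [1.2]])
        s = SpectraSet(wn, X, [f"s{i}" for i in range(6)],
                       ["A", "A", "A", "B", "B", "B"], ("A", "B"))
        assert overall_accuracy(loo_cv(s, 1)) == 100.0

    def test_infeasible_components_rejected(self, tiny_spectra):
        with pytest.raises(ValueError, match="infeasible"):
            loo_cv(tiny_spectra, tiny_spectra.n_samples - 1)


class TestClassifier:
    def test_predict_uses_class_order_for_ties_and_output_labels(self, tiny_spectra):
        clf = PLSDAClassifier(n_components=2, class_order=tiny_spectra.class_order)
        clf.fit(tiny_spectra.absorbance, tiny_spectra.labels)
        pred = clf.predict(tiny_spectra.absorbance)
        assert set(pred) <= set(tiny_spectra.class_order)
        assert clf.score(tiny_spectra.absorbance, tiny_spectra.labels) >= 0.8

    def test_sklearn_protocol(self, tiny_spectra):
        from sklearn.base import clone

        clf = PLSDAClassifier(n_components=3, class_order=("A", "B", "C"))
        params = clf.get_params()
        assert params["n_components"] == 3
        clone(clf)  # must be re-constructible from get_params


class TestAccuracyCurve:
    def test_curve_shape_and_consistency(self, small_spectra):
        from soilspec.dataset import stratified_split

        train, test = stratified_split(small_spectra, seed=3)
        table = accuracy_curve(train, test, max_components=6)
        assert len(table) == 6
        assert list(table["n_components"]) == list(range(1, 7))
        for a in (1, 4, 6):
            expected = overall_accuracy(train_confusion(train, a))
            got = float(table.loc[table["n_components"] == a, "calibration"].iloc[0])
            assert got == pytest.approx(expected)
        # strong-signal data: calibration accuracy non-decreasing to saturation
        cal = table["calibration"].to_numpy()
        assert np.all(np.diff(cal) >= -1e-9)
        loo_at_4 = overall_accuracy(loo_cv(train, 4))
        assert float(table.loc[table["n_components"] == 4, "loo"].iloc[0]) == pytest.approx(loo_at_4)
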