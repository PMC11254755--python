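"""Task definitions, Phi scoring, standardisation, CV protocol, baselines."""

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st
from sklearn.metrics import matthews_corrcoef

from chemres.classification import (
    TASKS,
    ClassificationError,
    ContingencyCounts,
    ELMClassifier,
    baseline_suite,
    cross_validate,
    phi_accuracy,
    phi_score,
    standardize,
    task_label,
    train_linear_svc,
)


class TestTasks:
    @pytest.mark.parametrize(
        "task,point,label",
        [
            ("xor", (0.25, 0.25), 0),
            ("xor", (0.25, 0.75), 1),
            ("xor", (0.75, 0.25), 1),
            ("and", (1.0, 1.0), 1),
            ("and", (0.25, 0.75), 0),
            ("or", (0.25, 0.75), 1),
            ("linear", (0.2, 0.8), 1),
            ("circle", (0.5, 0.5), 1),
            ("circle", (0.05, 0.05), 0),
            ("triangle", (0.5, 0.5), 1),
            ("rings", (0.5, 0.75), 1),
            ("dots", (0.25, 0.25), 1),
            ("dots", (0.5, 0.25), 0),
        ],
    )
    def test_canonical_boundaries(self, task, point, label):
        assert task_label(task, point) == label

    def test_all_tasks_have_both_classes_on_fixture_grid(self):
        from chemres.input_profiles import sample_classification_grid

        grid = sample_classification_grid(n=132, seed=0)
        for name in TASKS:
            labels = task_label(name, grid.normalized)
            assert 0 < labels.sum() < 132, name

    def test_point_outside_unit_square_rejected(self):
        with pytest.raises(ClassificationError):
            task_label("xor", (1.5, 0.2))


class TestPhiScore:
    def test_perfect_and_inverted_predictions(self):
        assert phi_score(ContingencyCounts(5, 5, 0, 0)) == pytest.approx(1.0)
        assert phi_score(ContingencyCounts(0, 0, 5, 5)) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert phi_score(ContingencyCounts(3, 2, 1, 1)) == pytest.approx(5 / 12)

    def test_degenerate_margin_returns_zero(self):
        assert phi_score(ContingencyCounts(5, 0, 0, 0)) == 0.0

    @hsettings(max_examples=100, derandomize=True)
    @given(st.tuples(*[st.integers(0, 20)] * 4))
    def test_matches_reference_mcc(self, counts):
        tp, tn, fp, fn = counts
        y_true = [1] * tp + [0] * tn + [0] * fp + [1] * fn
        y_pred = [1] * tp + [0] * tn + [1] * fp + [0] * fn
        if len(set(y_true)) < 2 or len(set(y_pred)) < 2:
            expected = 0.0
        else:
            expected = matthews_corrcoef(y_true, y_pred)
        assert phi_score(ContingencyCounts(tp, tn, fp, fn)) == pytest.approx(
            expected, abs=1e-12
        )

    @hsettings(max_examples=100, derandomize=True)
    @given(st.tuples(*[st.integers(0, 20)] * 4))
    def test_symmetric_under_class_swap(self, counts):
        tp, tn, fp, fn = counts
        a = phi_score(ContingencyCounts(tp, tn, fp, fn))
        b = phi_score(ContingencyCounts(tn, tp, fn, fp))
        assert a == pytest.approx(b)

    @pytest.mark.parametrize("phi,expected", [(1.0, 1.0), (-1.0, 0.0), (0.0, 0.5)])
    def test_phi_accuracy_map(self, phi, expected):
        assert phi_accuracy(phi) == expected

    def test_phi_accuracy_rejects_out_of_range(self):
        with pytest.raises(ClassificationError):
            phi_accuracy(1.5)


class TestStandardize:
    def test_hand_computed_two_point_column(self):
        Z, params = standardize(np.array([[1.0], [3.0]]))
        np.testing.assert_allclose(Z, [[-1.0], [1.0]])

    def test_idempotent_on_standardized_data(self, rng):
        X = rng.normal(size=(50, 4))
        Z, _ = standardize(X)
        Z2, _ = standardize(Z)
        np.testing.assert_allclose(Z, Z2, atol=1e-12)

    def test_constant_column_scale_one_with_warning(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            Z, params = standardize(X)
        np.testing.assert_allclose(Z[:, 0], 0.0)
        assert params.scale[0] == 1.0


class TestLinearSVC:
    def test_separable_clusters_fit_perfectly(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (20, 3)), rng.normal(5, 0.1, (20, 3))])
        y = np.repeat([0, 1], 20)
        model = train_linear_svc(X, y)
        assert (model.predict(X) == y).all()

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ClassificationError):
            train_linear_svc(X, np.zeros(10))

    def test_duplicated_feature_column_keeps_decision_function(self, rng):
        # duplicating a column halves its effective L2 penalty, so the fit
        # is equivalent only up to a small perturbation of the margin
        X = rng.normal(size=(60, 5))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        base = train_linear_svc(X, y)
        dup = train_linear_svc(np.hstack([X, X[:, [0]]]), y)
        Xt = rng.normal(size=(200, 5))
        d_base = base.decision_function(Xt)
        d_dup = dup.decision_function(np.hstack([Xt, Xt[:, [0]]]))
        assert np.corrcoef(d_base, d_dup)[0, 1] > 0.995
        agree = (base.predict(Xt) == dup.predict(np.hstack([Xt, Xt[:, [0]]]))).mean()
        assert agree >= 0.98


class TestCrossValidation:
    def test_evaluation_count_matches_protocol(self, rng):
        X = rng.normal(size=(132, 4))
        y = (X[:, 0] > 0).astype(int)
        cv = cross_validate(X, y, repeats=2, splits=26, test_size=5, seed=0)
        assert cv.n_evaluations == 52
        # 132 - 130: two train-only inputs per repeat
        counts = cv.records["test_indices"].apply(len)
        assert (counts == 5).all()

    def test_separable_fixture_scores_one(self, rng):
        X = np.vstack([rng.normal(0, 0.05, (70, 2)), rng.normal(4, 0.05, (70, 2))])
        y = np.repeat([0, 1], 70)
        cv = cross_validate(X, y, repeats=2, splits=26, test_size=5, seed=1)
        assert cv.mean_phi_accuracy == pytest.approx(1.0)
        np.testing.assert_allclose(cv.per_input_accuracy[~np.isnan(cv.per_input_accuracy)], 1.0)

    def test_permuted_labels_score_near_chance(self, rng):
        X = rng.normal(size=(132, 6))
        y = rng.integers(0, 2, size=132)
        cv = cross_validate(X, y, repeats=5, splits=26, test_size=5, seed=2)
        assert abs(cv.mean_phi_accuracy - 0.5) < 0.08

    def test_holdout_bookkeeping(self, rng):
        X = rng.normal(size=(60, 3))
        y = (X[:, 0] > 0).astype(int)
        repeats, splits, test_size = 4, 10, 5
        cv = cross_validate(X, y, repeats=repeats, splits=splits,
                            test_size=test_size, seed=3)
        held = np.zeros(60)
        for idx in cv.records["test_indices"]:
            for i in idx:
                held[i] += 1
        assert held.mean() == pytest.approx(repeats * splits * test_size / 60)

    def test_too_few_inputs_rejected(self, rng):
        X = rng.normal(size=(20, 2))
        y = (X[:, 0] > 0).astype(int)
        with pytest.raises(ClassificationError):
            cross_validate(X, y, repeats=1, splits=26, test_size=5, seed=0)


@pytest.fixture(scope="module")
def grid():
    from chemres.input_profiles import sample_classification_grid

    return sample_classification_grid(n=132, seed=0)


class TestBaselines:
    def test_linear_task_is_linearly_separable(self, grid):
        y = task_label("linear", grid.normalized)
        res = baseline_suite(grid.normalized, y, repeats=2, seed=0,
                             algorithms=("lsvc",))
        assert res["lsvc"].mean_phi_accuracy > 0.9

    def test_xor_defeats_linear_classifier(self, grid):
        y = task_label("xor", grid.normalized)
        res = baseline_suite(grid.normalized, y, repeats=2, seed=0,
                             algorithms=("lsvc",))
        assert abs(res["lsvc"].mean_phi_accuracy - 0.5) < 0.2

    def test_nonlinear_baselines_solve_xor(self, grid):
        y = task_label("xor", grid.normalized)
        res = baseline_suite(grid.normalized, y, repeats=1, seed=0,
                             algorithms=("svc_rbf", "elm"))
        assert res["svc_rbf"].mean_phi_accuracy > 0.8
        assert res["elm"].mean_phi_accuracy > 0.8

    def test_elm_without_hidden_units_equals_lsvc(self, grid):
        y = task_label("linear", grid.normalized)
        X = grid.normalized
        elm = ELMClassifier(n_hidden=0).fit(X, y)
        lsvc = train_linear_svc(X, y)
        np.testing.assert_array_equal(elm.predict(X), lsvc.predict(X))
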