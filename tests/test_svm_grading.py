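import numpy as np
import pytest

from idcgrade.exceptions import ValidationError
from idcgrade.gabor_features import FeatureMatrix
from idcgrade.svm_grading import (
    DEFAULT_C_GRID,
    EvalReport,
    KernelSpec,
    cross_validate,
    decision_function,
    default_kernel_grid,
    grid_search,
    kernel_eval,
    kernel_matrix,
    predict,
    train_svm,
)

LINEAR = KernelSpec("linear")
GAUSS = KernelSpec("gaussian", sigma2=1.6)


def make_matrix(values, labels):
    values = np.asarray(values, dtype=float)
    names = [f"f{i}" for i in range(values.shape[1])]
    ids = [f"p{i}" for i in range(values.shape[0])]
    return FeatureMatrix.from_rows(ids, values, labels, names)


def separable_cohort(n_per_class=9, dim=4, gap=6.0, seed=0):
    r = np.random.default_rng(seed)
    lo = r.normal(0.0, 1.0, (n_per_class, dim))
    hi = r.normal(gap, 1.0, (n_per_class, dim))
    values = np.vstack([lo, hi])
    labels = ["II"] * n_per_class + ["III"] * n_per_class
    return make_matrix(values, labels)


class TestKernels:
    def test_gaussian_identity(self):
        x = np.array([1.0, -2.0, 0.5])
        assert kernel_eval(GAUSS, x, x) == pytest.approx(1.0)

    def test_linear_dot_product(self):
        assert kernel_eval(LINEAR, [1.0, 2.0], [3.0, 4.0]) == pytest.approx(11.0)

    def test_polynomial_direct_evaluation(self):
        spec = KernelSpec("polynomial", degree=2, alpha=0.5, offset=0.0)
        assert kernel_eval(spec, [2.0, 0.0], [2.0, 0.0]) == pytest.approx(4.0)

    def test_gaussian_matches_explicit_formula(self, rng):
        x, y = rng.normal(size=3), rng.normal(size=3)
        expected = np.exp(-np.sum((x - y) ** 2) / (2 * 1.6))
        assert kernel_eval(GAUSS, x, y) == pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValidationError):
            kernel_eval(LINEAR, [1.0], [1.0, 2.0])

    def test_spec_validation(self):
        with pytest.raises(ValidationError):
            KernelSpec("gaussian", sigma2=-1.0)
        with pytest.raises(ValidationError):
            KernelSpec("polynomial", degree=2)  # missing alpha/offset
        with pytest.raises(ValidationError):
            KernelSpec("sigmoid")


class TestTraining:
    def test_separable_1d_boundary(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        labels = np.array(["II", "II", "III", "III"])
        model = train_svm(X, labels, LINEAR, C=1000.0)
        assert list(predict(model, X)) == list(labels)
        # boundary between the inner points: their decision values straddle 0
        assert decision_function(model, [[-1.0]])[0] < 0 < decision_function(model, [[1.0]])[0]
        assert predict(model, [[5.0]])[0] == "III"

    @pytest.mark.parametrize("spec", [LINEAR, GAUSS,
                                      KernelSpec("polynomial", degree=3, alpha=0.5, offset=1.0)])
    @pytest.mark.parametrize("C", [0.5, 8.0])
    def test_kkt_constraints_hold(self, rng, spec, C):
        X = rng.normal(size=(14, 3))
        labels = np.array(["II"] * 7 + ["III"] * 7)
        X[7:] += 1.0
        model = train_svm(X, labels, spec, C)
        assert np.all(model.alpha >= -1e-9)
        assert np.all(model.alpha <= C + 1e-9)
        assert abs(model.alpha @ model.y) < 1e-6

    def test_free_support_vectors_sit_on_margin(self, rng):
        matrix = separable_cohort(seed=3)
        model = train_svm(matrix.values, matrix.labels, GAUSS, C=8.0)
        eps = 1e-6 * model.C
        free = (model.alpha > eps) & (model.alpha < model.C - eps)
        if free.any():
            g = kernel_matrix(model.spec, model.X) @ (model.alpha * model.y) + model.bias
            assert np.allclose(model.y[free] * g[free], 1.0, atol=1e-3)

    def test_duplicated_training_set_same_decision(self, rng):
        # with a wide margin and large C no multiplier sits at its bound,
        # so duplicating every point leaves the hard-margin solution intact
        X = rng.normal(size=(10, 2))
        labels = np.array(["II"] * 5 + ["III"] * 5)
        X[5:, 0] += 6.0
        m1 = train_svm(X, labels, GAUSS, C=100.0)
        m2 = train_svm(np.vstack([X, X]), np.concatenate([labels, labels]), GAUSS, C=100.0)
        probes = rng.normal(size=(20, 2))
        assert np.allclose(
            decision_function(m1, probes), decision_function(m2, probes), atol=1e-2
        )

    def test_free_sv_predictions_match_their_labels(self, rng):
        matrix = separable_cohort(n_per_class=8, gap=4.0, seed=5)
        model = train_svm(matrix.values, matrix.labels, LINEAR, C=2.0)
        eps = 1e-6 * model.C
        free = (model.alpha > eps) & (model.alpha < model.C - eps)
        g = kernel_matrix(model.spec, model.X) @ (model.alpha * model.y) + model.bias
        assert np.all(np.sign(g[free]) == model.y[free])

    def test_mirror_symmetry_flips_label(self):
        X = np.array([[-3.0], [-2.0], [-1.0], [1.0], [2.0], [3.0]])
        labels = np.array(["II"] * 3 + ["III"] * 3)
        model = train_svm(X, labels, LINEAR, C=10.0)
        d_pos = decision_function(model, [[1.7]])[0]
        d_neg = decision_function(model, [[-1.7]])[0]
        assert d_pos == pytest.approx(-d_neg, abs=1e-6)
        assert predict(model, [[1.7]])[0] == "III"
        assert predict(model, [[-1.7]])[0] == "II"

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValidationError):
            train_svm(rng.normal(size=(5, 2)), ["II"] * 5, LINEAR, C=1.0)

    def test_agrees_with_sklearn_dual(self, rng):
        """Independent QP oracle: sklearn's SMO on the same scaled data."""
        from sklearn.svm import SVC

        for seed in range(6):
            r = np.random.default_rng(seed)
            n = int(r.integers(6, 13))
            X = r.normal(size=(n, 2))
            y = np.where(r.random(n) > 0.5, 1.0, -1.0)
            if np.all(y > 0) or np.all(y < 0):
                y[0] = -y[0]
            labels = np.where(y > 0, "III", "II")
            for spec, C in [(LINEAR, 2.0), (GAUSS, 8.0)]:
                model = train_svm(X, labels, spec, C)
                K = kernel_matrix(spec, model.X)
                ref = SVC(C=C, kernel="precomputed").fit(K, y)
                # dual objective agreement
                def objective(alpha):
                    Q = (y[:, None] * y[None, :]) * K
                    return 0.5 * alpha @ Q @ alpha - alpha.sum()
                ref_alpha = np.zeros(n)
                ref_alpha[ref.support_] = np.abs(ref.dual_coef_[0])
                assert objective(model.alpha) == pytest.approx(
                    objective(ref_alpha), abs=1e-4
                )
                # identical predictions on a probe grid
                probes = np.stack(
                    np.meshgrid(np.linspace(-2, 2, 5), np.linspace(-2, 2, 5)), -1
                ).reshape(-1, 2)
                Kp = kernel_matrix(spec, model.scaler.transform(probes), model.X)
                ours = decision_function(model, probes)
                theirs = ref.decision_function(Kp)
                assert np.all(np.sign(ours) == np.sign(theirs))


class TestEvalReport:
    def test_constructed_confusion_metrics(self):
        report = EvalReport(tp=5, fn=1, tn=4, fp=2, n_folds=3)
        assert report.accuracy == pytest.approx(0.75)
        assert report.sensitivity == pytest.approx(5 / 6)
        assert report.specificity == pytest.approx(4 / 6)
        assert report.P == 6 and report.N == 6

    def test_identities_on_random_counts(self, rng):
        for _ in range(20):
            tp, fn, tn, fp = rng.integers(0, 30, size=4)
            if tp + fn == 0 or tn + fp == 0:
                continue
            rep = EvalReport(tp=int(tp), fn=int(fn), tn=int(tn), fp=int(fp), n_folds=3)
            assert rep.tp + rep.fn == rep.P
            assert rep.tn + rep.fp == rep.N
            assert rep.accuracy == pytest.approx((tp + tn) / (tp + tn + fp + fn))


class TestCrossValidation:
    def test_perfect_separation_all_folds(self):
        matrix = separable_cohort(n_per_class=9, gap=8.0)
        subset = np.arange(matrix.n_features)
        for folds in (3, 4, 5):
            report = cross_validate(matrix, subset, GAUSS, C=8.0, n_folds=folds, seed=1)
            assert report.accuracy == 1.0
            assert report.sensitivity == 1.0
            assert report.specificity == 1.0
            assert report.P + report.N == len(matrix)

    def test_same_seed_same_report(self):
        matrix = separable_cohort(gap=2.0, seed=9)
        subset = np.arange(matrix.n_features)
        r1 = cross_validate(matrix, subset, GAUSS, 2.0, 3, seed=5)
        r2 = cross_validate(matrix, subset, GAUSS, 2.0, 3, seed=5)
        assert r1.to_dict() == r2.to_dict()

    def test_pooled_counts_cover_every_patient(self):
        matrix = separable_cohort(gap=1.0, seed=2)
        report = cross_validate(matrix, np.arange(4), LINEAR, 1.0, 4, seed=0)
        assert report.P + report.N == len(matrix)
        assert len(report.per_fold) == 4


class TestGridSearch:
    def test_singleton_grid_returned(self):
        matrix = separable_cohort(gap=6.0)
        (spec, C, report), table = grid_search(
            matrix, np.arange(4), [GAUSS], [8.0], n_folds=3, seed=0
        )
        assert spec == GAUSS and C == 8.0
        assert table.shape == (1, 1)

    def test_default_grid_shape(self):
        matrix = separable_cohort(gap=6.0)
        (_, _, _), table = grid_search(matrix, np.arange(4), n_folds=3, seed=0)
        assert table.shape == (12, 5)  # 1 linear + 7 polynomial + 4 gaussian rows
        assert list(table.columns) == [f"C={c:g}" for c in DEFAULT_C_GRID]
        assert np.isfinite(table.to_numpy(dtype=float)).all()

    def test_separable_cohort_best_at_smallest_c(self):
        matrix = separable_cohort(gap=8.0)
        (spec, C, report), table = grid_search(
            matrix, np.arange(4), [GAUSS], [1.0, 2.0, 8.0], n_folds=3, seed=0
        )
        assert report.accuracy == 1.0
        smallest_perfect = min(
            c for c in (1.0, 2.0, 8.0) if table.loc[spec.label, f"C={c:g}"] == 100.0
        )
        assert C == smallest_perfect

    def test_kernel_grid_families(self):
        grid = default_kernel_grid()
        families = [s.family for s in grid]
        assert families.count("linear") == 1
        assert families.count("polynomial") == 7
        assert families.count("gaussian") == 4
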