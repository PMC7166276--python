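"""Kernel SVM grading: dual training, prediction, K-fold CV and grid search.

The two-class grader solves the soft-margin SVM dual

    min_a  (1/2) sum_ij y_i y_j a_i a_j K(x_i, x_j) - sum_j a_j
    s.t.   sum_i y_i a_i = 0,   0 <= a_i <= C,

with grade III encoded as +1 and grade II as -1, and classifies by

    f(x) = sgn( sum_i a_i* y_i K(x, x_i) + b* ),

the bias b* taken from the free support vectors (0 < a* < C), averaged
over all of them for stability. Features are standardized with
training-set statistics before any kernel evaluation. The dual is a small
box/equality-constrained convex QP, solved here with SLSQP; the contract
is the decision function (KKT residuals below 1e-6), not a particular
optimizer.

Evaluation uses stratified K folds fixed by a seed; confusion counts are
pooled (micro-averaged) across folds, with grade III the positive class:
accuracy = (TP+TN)/(P+N), sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.model_selection import StratifiedKFold

from .dataset_io import GRADES, POSITIVE_GRADE
from .exceptions import ValidationError
from .gabor_features import FeatureMatrix

DEFAULT_C_GRID = (1.0, 2.0, 8.0, 16.0, 32.0)


@dataclass(frozen=True)
class KernelSpec:
    """One kernel parameterization: linear, polynomial or gaussian.

    linear:      k(x, y) = x.y
    polynomial:  k(x, y) = (alpha x.y + offset)^degree
    gaussian:    k(x, y) = exp(-||x - y||^2 / (2 sigma2))
    """

    family: str
    degree: int | None = None
    alpha: float | None = None
    offset: float | None = None
    sigma2: float | None = None

    def __post_init__(self):
        if self.family == "linear":
            if any(v is not None for v in (self.degree, self.alpha, self.offset, self.sigma2)):
                raise ValidationError("linear kernel takes no parameters")
        elif self.family == "polynomial":
            if self.degree is None or self.alpha is None or self.offset is None:
                raise ValidationError("polynomial kernel needs degree, alpha, offset")
            if self.sigma2 is not None:
                raise ValidationError("polynomial kernel does not take sigma2")
            if self.degree < 1:
                raise ValidationError(f"degree must be >= 1, got {self.degree}")
        elif self.family == "gaussian":
            if self.sigma2 is None or self.sigma2 <= 0:
                raise ValidationError("gaussian kernel needs sigma2 > 0")
            if any(v is not None for v in (self.degree, self.alpha, self.offset)):
                raise ValidationError("gaussian kernel only takes sigma2")
        else:
            raise ValidationError(f"unknown kernel family {self.family!r}")

    @property
    def label(self) -> str:
        if self.family == "linear":
            return "linear"
        if self.family == "polynomial":
            return f"poly d={self.degree} a={self.alpha:g} r={self.offset:g}"
        return f"gaussian s2={self.sigma2:g}"


def kernel_matrix(spec: KernelSpec, X: np.ndarray, Y: np.ndarray | None = None) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    Y = X if Y is None else np.atleast_2d(np.asarray(Y, dtype=np.float64))
    if X.shape[1] != Y.shape[1]:
        raise ValidationError(f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]}")
    if spec.family == "linear":
        return X @ Y.T
    if spec.family == "polynomial":
        return (spec.alpha * (X @ Y.T) + spec.offset) ** spec.degree
    d2 = (
        (X ** 2).sum(axis=1)[:, None]
        + (Y ** 2).sum(axis=1)[None, :]
        - 2.0 * X @ Y.T
    )
    return np.exp(-np.maximum(d2, 0.0) / (2.0 * spec.sigma2))


def kernel_eval(spec: KernelSpec, x, y) -> float:
    """Scalar kernel value between two feature vectors."""
    x = np.atleast_1d(np.asarray(x, dtype=np.float64))
    y = np.atleast_1d(np.asarray(y, dtype=np.float64))
    if x.shape != y.shape:
        raise ValidationError(f"dimension mismatch: {x.shape} vs {y.shape}")
    return float(kernel_matrix(spec, x[None, :], y[None, :])[0, 0])


@dataclass
class Scaler:
    """Per-feature standardization fit on training data."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Scaler":
        X = np.asarray(X, dtype=np.float64)
        sd = X.std(axis=0)
        return cls(mean=X.mean(axis=0), std=np.where(sd > 0, sd, 1.0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=np.float64) - self.mean) / self.std


@dataclass
class SvmModel:
    """Trained grader: dual multipliers, bias and scaled training data."""

    spec: KernelSpec
    C: float
    alpha: np.ndarray        # all training multipliers, in [0, C]
    bias: float
    X: np.ndarray            # scaled training features
    y: np.ndarray            # +1 (grade III) / -1 (grade II)
    scaler: Scaler
    bias_fallback: bool = False
    dual_objective: float = field(default=np.nan)

    @property
    def support_mask(self) -> np.ndarray:
        return self.alpha > 1e-8

    @property
    def support_vectors(self) -> np.ndarray:
        return self.X[self.support_mask]


def encode_labels(labels) -> np.ndarray:
    """Grade III -> +1, grade II -> -1."""
    labels = np.asarray(labels)
    bad = set(labels.tolist()) - set(GRADES)
    if bad:
        raise ValidationError(f"unknown grade labels: {sorted(bad)}")
    return np.where(labels == POSITIVE_GRADE, 1.0, -1.0)


def decode_labels(signs) -> np.ndarray:
    return np.where(np.asarray(signs) > 0, POSITIVE_GRADE, "II")


def _solve_dual(Q: np.ndarray, y: np.ndarray, C: float) -> tuple[np.ndarray, float]:
    n = y.size

    def f(a):
        return 0.5 * a @ Q @ a - a.sum()

    def jac(a):
        return Q @ a - 1.0

    cons = {"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}
    res = minimize(
        f,
        x0=np.zeros(n),
        jac=jac,
        bounds=[(0.0, C)] * n,
        constraints=[cons],
        method="SLSQP",
        options={"maxiter": 1000, "ftol": 1e-12},
    )
    a = np.clip(res.x, 0.0, C)
    # Re-project the equality constraint onto the free coordinates.
    viol = a @ y
    free = (a > 1e-9) & (a < C - 1e-9)
    if abs(viol) > 0 and free.any():
        a[free] -= viol * y[free] / free.sum()
        a = np.clip(a, 0.0, C)
    return a, float(f(a))


def train_svm(X, labels, spec: KernelSpec, C: float) -> SvmModel:
    """Fit the dual SVM on (already subset) feature rows.

    ``labels`` may be grade strings or +/-1. Standardization is fit here,
    on the training rows only, so CV folds never leak test statistics.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    labels = np.asarray(labels)
    y = labels.astype(np.float64) if labels.dtype.kind in "if" else encode_labels(labels)
    if not ((y > 0).any() and (y < 0).any()):
        raise ValidationError("training data must contain both classes")
    if C <= 0:
        raise ValidationError(f"C must be positive, got {C}")
    scaler = Scaler.fit(X)
    Xs = scaler.transform(X)
    K = kernel_matrix(spec, Xs)
    Q = (y[:, None] * y[None, :]) * K
    alpha, obj = _solve_dual(Q, y, C)

    g = K @ (alpha * y)  # decision values without bias, on training points
    eps = 1e-6 * C
    free = (alpha > eps) & (alpha < C - eps)
    if free.any():
        bias = float(np.mean(y[free] - g[free]))
        fallback = False
    else:
        # No free support vector: place the boundary midway between the
        # closest functional margins of the two classes.
        bias = -0.5 * (g[y > 0].min() + g[y < 0].max())
        fallback = True
    return SvmModel(
        spec=spec, C=float(C), alpha=alpha, bias=bias, X=Xs, y=y,
        scaler=scaler, bias_fallback=fallback, dual_objective=obj,
    )


def decision_function(model: SvmModel, X) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.X.shape[1]:
        raise ValidationError(
            f"expected {model.X.shape[1]} features, got {X.shape[1]}"
        )
    Xs = model.scaler.transform(X)
    K = kernel_matrix(model.spec, Xs, model.X)
    return K @ (model.alpha * model.y) + model.bias


def predict(model: SvmModel, X) -> np.ndarray:
    """Predicted grades; a decision value of exactly 0 maps to grade II."""
    return decode_labels(decision_function(model, X))


@dataclass
class EvalReport:
    """Pooled confusion counts and derived metrics for one CV run."""

    tp: int
    tn: int
    fp: int
    fn: int
    n_folds: int
    per_fold: list = field(default_factory=list)
    config: dict = field(default_factory=dict)

    @property
    def P(self) -> int:
        return self.tp + self.fn

    @property
    def N(self) -> int:
        return self.tn + self.fp

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.P + self.N)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    def to_dict(self) -> dict:
        return {
            "TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
            "P": self.P, "N": self.N,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n_folds": self.n_folds,
            "per_fold": self.per_fold,
            "config": self.config,
        }


def confusion_counts(true_labels, pred_labels) -> dict:
    true = np.asarray(true_labels)
    pred = np.asarray(pred_labels)
    pos = true == POSITIVE_GRADE
    ppred = pred == POSITIVE_GRADE
    return {
        "tp": int(np.sum(pos & ppred)),
        "fn": int(np.sum(pos & ~ppred)),
        "tn": int(np.sum(~pos & ~ppred)),
        "fp": int(np.sum(~pos & ppred)),
    }


def stratified_folds(labels, n_folds: int, seed: int):
    """Seeded stratified fold indices; every fold must hold both classes."""
    labels = np.asarray(labels)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(labels.size), labels))
    for _, test_idx in folds:
        if len(set(labels[test_idx])) < 2:
            raise ValidationError(
                f"a fold contains a single class; use fewer than {n_folds} folds"
            )
    return folds


def cross_validate(
    matrix: FeatureMatrix,
    feature_subset,
    spec: KernelSpec,
    C: float,
    n_folds: int = 3,
    seed: int = 0,
) -> EvalReport:
    """Stratified K-fold CV over a fixed feature subset, pooled confusion.

    Standardization (and everything else data-dependent inside
    :func:`train_svm`) is fit on each training fold only.
    """
    subset = np.asarray(feature_subset, dtype=int)
    X = matrix.values[:, subset]
    labels = matrix.labels
    folds = stratified_folds(labels, n_folds, seed)
    totals = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
    per_fold = []
    for train_idx, test_idx in folds:
        model = train_svm(X[train_idx], labels[train_idx], spec, C)
        pred = predict(model, X[test_idx])
        counts = confusion_counts(labels[test_idx], pred)
        per_fold.append(counts)
        for k in totals:
            totals[k] += counts[k]
    return EvalReport(
        **totals,
        n_folds=n_folds,
        per_fold=per_fold,
        config={
            "kernel": spec.label, "C": C, "n_features": int(subset.size),
            "seed": seed,
        },
    )


def default_kernel_grid() -> list[KernelSpec]:
    """The evaluated kernel parameterizations: linear, 7 polynomial rows,
    4 gaussian bandwidths."""
    grid = [KernelSpec("linear")]
    for d, a, r in [(2, 0.5, 0.0), (3, 0.5, 0.0), (4, 1 / 3, 0.0), (2, 0.25, 0.0),
                    (3, 2.0, 2.0), (4, 2.0, 4.0), (6, 1 / 6, 6.0)]:
        grid.append(KernelSpec("polynomial", degree=d, alpha=a, offset=r))
    for s2 in (0.125, 0.06, 5.0, 1.6):
        grid.append(KernelSpec("gaussian", sigma2=s2))
    return grid


def gaussian_kernel_grid() -> list[KernelSpec]:
    return [s for s in default_kernel_grid() if s.family == "gaussian"]


def grid_search(
    matrix: FeatureMatrix,
    feature_subset,
    kernel_grid=None,
    C_grid=DEFAULT_C_GRID,
    n_folds: int = 3,
    seed: int = 0,
):
    """Evaluate every (kernel, C) pair by CV; return the best and the table.

    The best configuration maximizes pooled accuracy; ties resolve to the
    smaller C, then to kernel-grid order. The table has one row per
    kernel parameterization and one accuracy column (in %) per C.
    """
    kernel_grid = list(kernel_grid) if kernel_grid is not None else default_kernel_grid()
    C_grid = list(C_grid)
    if not kernel_grid or not C_grid:
        raise ValidationError("kernel and C grids must be non-empty")
    table = pd.DataFrame(
        index=pd.Index([s.label for s in kernel_grid], name="kernel"),
        columns=[f"C={c:g}" for c in C_grid],
        dtype=float,
    )
    best = None  # (accuracy, -C rank handled via ordering, spec, C, report)
    for spec in kernel_grid:
        for C in C_grid:
            report = cross_validate(matrix, feature_subset, spec, C, n_folds, seed)
            table.loc[spec.label, f"C={C:g}"] = 100.0 * report.accuracy
            key = (report.accuracy, -C)
            if best is None or key > best[0]:
                best = (key, spec, C, report)
    _, spec, C, report = best
    return (spec, C, report), table
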