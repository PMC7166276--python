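"""High-level grading model in the Model/Results style.

:class:`TextureGradingModel` wraps the full decision pipeline — feature
ranking, top-k subset selection, kernel/C grid search and stratified
K-fold evaluation — behind a statsmodels-like interface: build the model
from a feature matrix (or straight from a cohort manifest, which runs
segmentation and Gabor extraction), call :meth:`~TextureGradingModel.fit`
with a seed, and receive a :class:`TextureGradingResults` carrying the
selected features, the cross-validated confusion metrics, the full grid
table and a fitted final grader for new patients.

By default the feature ranking is recomputed inside every training fold
(``rank_within_folds=True``); ranking on the full cohort before CV lets
the test patients influence which features are evaluated, which inflates
small-cohort accuracy estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .feature_selection import FeatureRanking, score_features, select_subset
from .gabor_features import FeatureMatrix, build_bank, extract_cohort_features
from .svm_grading import (
    DEFAULT_C_GRID,
    EvalReport,
    KernelSpec,
    SvmModel,
    confusion_counts,
    cross_validate,
    gaussian_kernel_grid,
    predict,
    stratified_folds,
    train_svm,
)


class TextureGradingModel:
    """Texture-based tumor grader over a patients-by-features matrix.

    Parameters
    ----------
    matrix : FeatureMatrix
        Patients x features table with grade labels.
    k_features : int
        Size of the ranked feature subset fed to the SVM (default 8).
    kernel_grid, C_grid
        Kernel parameterizations and box penalties searched by CV
        accuracy; defaults are the four gaussian bandwidths and
        C in {1, 2, 8, 16, 32}.
    n_folds : int
        Stratified CV folds (default 3).
    beta : float or "auto"
        Scale of the separability score (auto = median raw distance).
    rank_within_folds : bool
        Re-rank features on each training fold (default True).
    """

    def __init__(
        self,
        matrix: FeatureMatrix,
        k_features: int = 8,
        kernel_grid=None,
        C_grid=DEFAULT_C_GRID,
        n_folds: int = 3,
        beta="auto",
        rank_within_folds: bool = True,
    ):
        if not 1 <= k_features <= matrix.n_features:
            raise ValidationError(
                f"k_features must be in [1, {matrix.n_features}], got {k_features}"
            )
        self.matrix = matrix
        self.k_features = int(k_features)
        self.kernel_grid = list(kernel_grid) if kernel_grid is not None else gaussian_kernel_grid()
        self.C_grid = list(C_grid)
        self.n_folds = int(n_folds)
        self.beta = beta
        self.rank_within_folds = bool(rank_within_folds)

    @classmethod
    def from_manifest(cls, manifest_path, seg_config, bank=None, **kwargs) -> "TextureGradingModel":
        """Build the model straight from a cohort on disk.

        Loads the manifest, segments every slice and extracts the Gabor
        feature matrix before constructing the model.
        """
        from .dataset_io import load_manifest

        manifest = load_manifest(manifest_path)
        matrix = extract_cohort_features(manifest, seg_config, bank=bank or build_bank())
        return cls(matrix, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "TextureGradingModel":
        """Build from a DataFrame with a ``grade`` column (index = patient)."""
        return cls(FeatureMatrix(df), **kwargs)

    # -- evaluation -----------------------------------------------------

    def _cv_one(self, spec: KernelSpec, C: float, seed: int) -> EvalReport:
        if not self.rank_within_folds:
            ranking = score_features(self.matrix, beta=self.beta)
            subset = select_subset(ranking, self.k_features)
            return cross_validate(self.matrix, subset, spec, C, self.n_folds, seed)
        labels = self.matrix.labels
        X = self.matrix.values
        folds = stratified_folds(labels, self.n_folds, seed)
        totals = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
        per_fold = []
        for train_idx, test_idx in folds:
            sub_matrix = FeatureMatrix(self.matrix.df.iloc[train_idx])
            ranking = score_features(sub_matrix, beta=self.beta)
            subset = select_subset(ranking, self.k_features)
            model = train_svm(X[np.ix_(train_idx, subset)], labels[train_idx], spec, C)
            pred = predict(model, X[np.ix_(test_idx, subset)])
            counts = confusion_counts(labels[test_idx], pred)
            per_fold.append(counts)
            for k in totals:
                totals[k] += counts[k]
        return EvalReport(
            **totals,
            n_folds=self.n_folds,
            per_fold=per_fold,
            config={"kernel": spec.label, "C": C, "n_features": self.k_features, "seed": seed},
        )

    def fit(self, seed: int = 0) -> "TextureGradingResults":
        """Grid-search the kernel/C space by CV and fit the final grader.

        Ties in CV accuracy resolve to the smaller C, then grid order.
        The final grader is refit on the full cohort with the winning
        configuration and the full-cohort top-k features.
        """
        table = pd.DataFrame(
            index=pd.Index([s.label for s in self.kernel_grid], name="kernel"),
            columns=[f"C={c:g}" for c in self.C_grid],
            dtype=float,
        )
        best = None
        for spec in self.kernel_grid:
            for C in self.C_grid:
                report = self._cv_one(spec, C, seed)
                table.loc[spec.label, f"C={C:g}"] = 100.0 * report.accuracy
                key = (report.accuracy, -C)
                if best is None or key > best[0]:
                    best = (key, spec, C, report)
        _, best_spec, best_C, best_report = best
        ranking = score_features(self.matrix, beta=self.beta)
        subset = select_subset(ranking, self.k_features)
        final = train_svm(
            self.matrix.values[:, subset], self.matrix.labels, best_spec, best_C
        )
        return TextureGradingResults(
            model=self,
            seed=seed,
            grid_table=table,
            kernel=best_spec,
            C=best_C,
            report=best_report,
            ranking=ranking,
            feature_subset=subset,
            final_svm=final,
        )


@dataclass
class TextureGradingResults:
    """Fitted grading results: CV metrics, ranking, grid table, final SVM."""

    model: TextureGradingModel
    seed: int
    grid_table: pd.DataFrame
    kernel: KernelSpec
    C: float
    report: EvalReport
    ranking: FeatureRanking
    feature_subset: np.ndarray
    final_svm: SvmModel = field(repr=False, default=None)

    @property
    def accuracy(self) -> float:
        return self.report.accuracy

    @property
    def sensitivity(self) -> float:
        return self.report.sensitivity

    @property
    def specificity(self) -> float:
        return self.report.specificity

    @property
    def selected_features(self) -> list[str]:
        return [self.model.matrix.feature_names[i] for i in self.feature_subset]

    def predict(self, features) -> np.ndarray:
        """Grade new patients from their full-length feature vectors."""
        if isinstance(features, FeatureMatrix):
            features = features.values
        features = np.atleast_2d(np.asarray(features, dtype=np.float64))
        if features.shape[1] == self.model.matrix.n_features:
            features = features[:, self.feature_subset]
        elif features.shape[1] != self.feature_subset.size:
            raise ValidationError(
                f"expected {self.model.matrix.n_features} (full) or "
                f"{self.feature_subset.size} (subset) features, got {features.shape[1]}"
            )
        return predict(self.final_svm, features)

    def summary(self) -> str:
        """Human-readable fit summary (selected config, metrics, features)."""
        r = self.report
        lines = [
            "Texture grading model (Gabor features + kernel SVM)",
            "=" * 55,
            f"patients: {len(self.model.matrix)}   features: {self.model.matrix.n_features}"
            f"   subset size: {self.model.k_features}",
            f"CV protocol: stratified {self.model.n_folds}-fold, seed {self.seed}, "
            f"fold-internal ranking: {self.model.rank_within_folds}",
            f"selected kernel: {self.kernel.label}   C = {self.C:g}",
            "",
            f"pooled confusion   TP={r.tp}  FN={r.fn}  TN={r.tn}  FP={r.fp}",
            f"accuracy    {100 * r.accuracy:6.2f}%",
            f"sensitivity {100 * r.sensitivity:6.2f}%   (grade III detection)",
            f"specificity {100 * r.specificity:6.2f}%   (grade II detection)",
            "",
            "top-ranked features (full cohort):",
        ]
        frame = self.ranking.to_frame().head(self.model.k_features)
        for _, row in frame.iterrows():
            lines.append(
                f"  {int(row['rank']):3d}. {row['feature_name']:<22s}"
                f" D={row['D']:.4f}  idx={row['idx']:.4f}"
            )
        return "\n".join(lines)

    # -- plotting -------------------------------------------------------

    def plot_ranking(self, ax=None, top_n: int = 20):
        """Bar chart of the top separability scores."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        frame = self.ranking.to_frame().head(top_n)
        ax.barh(frame["feature_name"][::-1], frame["idx"][::-1])
        ax.set_xlabel("separability idx")
        ax.set_title("Feature ranking")
        return ax

    def plot_grid(self, ax=None):
        """Heatmap of CV accuracy over the kernel/C grid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        data = self.grid_table.to_numpy(dtype=float)
        im = ax.imshow(data, aspect="auto", cmap="viridis")
        ax.set_xticks(range(data.shape[1]), self.grid_table.columns)
        ax.set_yticks(range(data.shape[0]), self.grid_table.index)
        ax.set_xlabel("penalty C")
        ax.figure.colorbar(im, ax=ax, label="CV accuracy (%)")
        ax.set_title("Kernel / C grid search")
        return ax
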