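"""Covariate construction: PLS blood-cell imputation, PCs, residualization.

The expression residuals consumed by the eQTL scan are ordinary
least-squares residuals of each transcript on age, sex, technical batch,
measured-or-imputed blood-cell components, genotype principal components
(population structure) and expression principal components (unknown
confounders), all in one joint design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .config import DataError
from .datatypes import ExpressionMatrix
from .simulate import CELL_COLUMNS

logger = logging.getLogger(__name__)


@dataclass
class PcScores:
    """Top-k principal component scores with explained-variance fractions."""

    scores: pd.DataFrame  # samples x components, columns PC1..PCk
    explained_variance_ratio: np.ndarray

    @property
    def k(self) -> int:
        return self.scores.shape[1]


class PlsCellImputer(RegressorMixin, BaseEstimator):
    """Predict blood-cell components from expression via PLS regression.

    The number of latent components is selected by k-fold
    cross-validation (default 3-fold) to maximize the mean held-out R^2
    across cell-component targets; the model is then refit on all
    measured samples.

    Parameters
    ----------
    n_folds : int
        Cross-validation folds.
    max_components : int
        Upper bound of the component search (1..max_components).
    random_state : int
        Seed for the CV fold shuffle.

    Attributes
    ----------
    n_components_ : int
        Selected number of latent components.
    cv_r2_ : pd.Series
        Held-out R^2 per target at the selected size; NaN for targets
        excluded for zero variance.
    targets_ : list[str]
        Names of the fitted (non-degenerate) targets.
    """

    def __init__(self, n_folds: int = 3, max_components: int = 10, random_state: int = 0):
        self.n_folds = n_folds
        self.max_components = max_components
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y_df = pd.DataFrame(y)
        n = X.shape[0]
        if n < 3 * self.n_folds:
            raise DataError(
                f"need at least {3 * self.n_folds} measured samples for "
                f"{self.n_folds}-fold PLS fitting, got {n}"
            )
        variances = y_df.var(axis=0, ddof=1)
        self.excluded_targets_ = list(y_df.columns[variances <= 0])
        self.targets_ = [c for c in y_df.columns if c not in self.excluded_targets_]
        if not self.targets_:
            raise DataError("all cell-component targets have zero variance")
        Y = y_df[self.targets_].to_numpy(dtype=float)

        max_k = min(self.max_components, X.shape[1], n - int(np.ceil(n / self.n_folds)) - 1)
        max_k = max(max_k, 1)
        kf = KFold(n_splits=self.n_folds, shuffle=True, random_state=self.random_state)
        folds = list(kf.split(X))

        best_k, best_mean, best_r2 = 1, -np.inf, None
        for k in range(1, max_k + 1):
            pred = np.empty_like(Y)
            for train, test in folds:
                m = PLSRegression(n_components=k, scale=True)
                m.fit(X[train], Y[train])
                pred[test] = m.predict(X[test])
            ss_res = ((Y - pred) ** 2).sum(axis=0)
            ss_tot = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
            r2 = 1.0 - ss_res / ss_tot
            if r2.mean() > best_mean:
                best_k, best_mean, best_r2 = k, r2.mean(), r2
        self.n_components_ = best_k
        cv = pd.Series(best_r2, index=self.targets_)
        for c in self.excluded_targets_:
            cv[c] = np.nan
        self.cv_r2_ = cv
        self.model_ = PLSRegression(n_components=best_k, scale=True)
        self.model_.fit(X, Y)
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        pred = self.model_.predict(np.asarray(X, dtype=float))
        return pd.DataFrame(pred, columns=self.targets_)


def fit_pls_imputer(
    expression: ExpressionMatrix,
    measured_cells: pd.DataFrame,
    n_folds: int = 3,
    max_components: int = 10,
    random_state: int = 0,
) -> tuple[PlsCellImputer, pd.Series]:
    """Fit the cell-count imputer on measured samples; return it + CV R^2."""
    common = expression.sample_ids.intersection(measured_cells.index)
    imputer = PlsCellImputer(
        n_folds=n_folds, max_components=max_components, random_state=random_state
    )
    imputer.fit(expression.values.loc[common], measured_cells.loc[common])
    return imputer, imputer.cv_r2_


def impute_cell_counts(
    imputer: PlsCellImputer,
    expression: ExpressionMatrix,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Fill unmeasured cell components with PLS predictions.

    Samples flagged ``cell_measured`` keep their observed values; the
    provenance flag column is updated to ``cell_imputed`` for the rest.
    """
    missing_samples = expression.sample_ids.difference(covariates.index)
    if len(missing_samples):
        raise DataError(f"samples missing from covariate table: {list(missing_samples[:5])}")
    out = covariates.copy()
    if "cell_measured" not in out.columns:
        out["cell_measured"] = True
    to_impute = out.index[~out["cell_measured"]]
    if len(to_impute):
        pred = imputer.predict(expression.values.loc[to_impute])
        pred.index = to_impute
        for c in imputer.targets_:
            out.loc[to_impute, c] = pred[c]
    out["cell_imputed"] = ~out["cell_measured"]
    return out


def compute_pcs(matrix, k: int, standardize: bool = False) -> PcScores:
    """Top-k principal component scores of a samples x features matrix.

    Columns are centered (and scaled to unit variance if
    ``standardize``); scores are U*S from the SVD, sign-fixed so the
    largest-magnitude loading of each component is positive. If k
    exceeds the matrix rank the result is truncated with a warning.
    """
    if isinstance(matrix, ExpressionMatrix):
        matrix = matrix.values
    df = pd.DataFrame(matrix)
    X = df.to_numpy(dtype=float)
    if k > min(X.shape):
        raise DataError(f"k={k} exceeds min(n_samples, n_features)={min(X.shape)}")
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    tol = S[0] * max(X.shape) * np.finfo(float).eps if S.size else 0.0
    rank = int((S > tol).sum())
    if k > rank:
        logger.warning("requested %d PCs but matrix rank is %d; truncating", k, rank)
        k = rank
    # deterministic sign: largest-|loading| entry of each right vector positive
    for i in range(k):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    scores = U[:, :k] * S[:k]
    evr = (S**2) / (S**2).sum()
    return PcScores(
        scores=pd.DataFrame(
            scores, index=df.index, columns=[f"PC{i + 1}" for i in range(k)]
        ),
        explained_variance_ratio=evr[:k],
    )


# cell percentage columns entering the design (basophil dropped: the five
# percentages sum to 100, so all five would be collinear with intercept)
DESIGN_CELL_PCTS = ["neutrophil_pct", "lymphocyte_pct", "monocyte_pct", "eosinophil_pct"]


def build_design(
    covariates: pd.DataFrame,
    genotype_pcs: PcScores | None = None,
    expression_pcs: PcScores | None = None,
) -> pd.DataFrame:
    """Assemble the OLS design matrix (with intercept) for residualization.

    Numeric covariates enter as-is; categoricals (sex, batch and any
    other object/category column) are one-hot encoded with the first
    level dropped. Basophil percentage is excluded to avoid
    compositional collinearity.
    """
    parts = [pd.Series(1.0, index=covariates.index, name="intercept")]
    numeric_cols = [c for c in ["age", "wbc_count", "platelet_count"] if c in covariates]
    numeric_cols += [c for c in DESIGN_CELL_PCTS if c in covariates]
    for c in numeric_cols:
        parts.append(covariates[c].astype(float))
    skip = set(numeric_cols) | {"basophil_pct", "cell_measured", "cell_imputed", "sample_id"}
    for c in covariates.columns:
        if c in skip:
            continue
        col = covariates[c]
        if col.dtype.kind in "biufc":
            parts.append(col.astype(float))
        else:
            dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            parts.extend(dummies[d] for d in dummies)
    design = pd.concat(parts, axis=1)
    for pcs, prefix in ((genotype_pcs, "geno"), (expression_pcs, "expr")):
        if pcs is not None:
            block = pcs.scores.add_prefix(f"{prefix}_")
            design = design.join(block)
    return design


def _drop_collinear(X: pd.DataFrame) -> pd.DataFrame:
    """Remove columns that are linearly dependent on earlier ones (QR pivot)."""
    A = X.to_numpy(dtype=float)
    _, R, piv = linalg.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(A.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = np.sort(piv[:rank])
    dropped = [X.columns[i] for i in piv[rank:]]
    if dropped:
        logger.warning("dropping collinear design columns: %s", dropped)
    return X.iloc[:, keep]


@dataclass
class CovariateResidualizer:
    """OLS residualization of expression on a fixed covariate design.

    ``fit`` stores the (full-rank) design; ``transform`` returns, per
    transcript, the least-squares residuals — orthogonal to every design
    column and mean-zero (the design includes an intercept).
    """

    design_: pd.DataFrame = field(default=None, repr=False)
    n_dropped_columns_: int = 0

    def fit(self, design: pd.DataFrame) -> "CovariateResidualizer":
        if design.isna().any().any():
            raise DataError("design matrix contains missing values")
        full = _drop_collinear(design)
        self.n_dropped_columns_ = design.shape[1] - full.shape[1]
        if full.shape[1] <= 1 and design.shape[1] > 1:
            raise DataError("design collapsed to intercept only after dropping collinear columns")
        self.design_ = full
        return self

    def transform(self, expression: ExpressionMatrix) -> ExpressionMatrix:
        if self.design_ is None:
            raise DataError("residualizer not fitted")
        if not expression.sample_ids.equals(self.design_.index):
            raise DataError("expression and design sample sets differ")
        X = self.design_.to_numpy(dtype=float)
        Y = expression.values.to_numpy(dtype=float)
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ coef
        return ExpressionMatrix(
            pd.DataFrame(resid, index=expression.sample_ids, columns=expression.gene_ids)
        )


def residualize_expression(
    expression: ExpressionMatrix,
    covariates: pd.DataFrame,
    genotype_pcs: PcScores | None = None,
    expression_pcs: PcScores | None = None,
) -> ExpressionMatrix:
    """One-call covariate + PC residualization (joint single-pass OLS)."""
    design = build_design(
        covariates.loc[expression.sample_ids], genotype_pcs, expression_pcs
    )
    return CovariateResidualizer().fit(design).transform(expression)


def prepare_residuals(
    expression: ExpressionMatrix,
    covariates: pd.DataFrame,
    genotypes=None,
    n_genotype_pcs: int = 5,
    n_expression_pcs: int = 15,
    pls_folds: int = 3,
    pls_max_components: int = 10,
    random_state: int = 0,
    precomputed_residuals: ExpressionMatrix | None = None,
):
    """Full preprocessing stage: impute cells, PCs, residualize.

    ``precomputed_residuals`` is an escape hatch for cohorts whose
    expression was already adjusted externally (e.g. kinship-corrected):
    when given, it is returned unchanged and no fitting happens.

    Returns (residuals, filled_covariates, cv_r2, genotype_pcs,
    expression_pcs).
    """
    if precomputed_residuals is not None:
        return precomputed_residuals, covariates, None, None, None
    measured = covariates[covariates.get("cell_measured", pd.Series(True, covariates.index))]
    imputer, cv_r2 = fit_pls_imputer(
        expression,
        measured[[c for c in CELL_COLUMNS if c in measured.columns]],
        n_folds=pls_folds,
        max_components=pls_max_components,
        random_state=random_state,
    )
    filled = impute_cell_counts(imputer, expression, covariates)
    genotype_pcs = None
    if genotypes is not None:
        k = min(n_genotype_pcs, genotypes.n_samples, genotypes.n_variants)
        genotype_pcs = compute_pcs(genotypes.dosages, k=k, standardize=True)
    k_e = min(n_expression_pcs, expression.n_samples, expression.n_genes)
    expression_pcs = compute_pcs(expression, k=k_e, standardize=False)
    residuals = residualize_expression(expression, filled, genotype_pcs, expression_pcs)
    return residuals, filled, cv_r2, genotype_pcs, expression_pcs
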