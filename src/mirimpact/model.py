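"""The linear perturbation model and its validation machinery.

Irradiation is modelled as perturbing the strength of each miRNA's
negative regulation of its targets.  For transcript j the predicted log2
fold change is

    fc_j = sum_i dk_i * c'_ji * miRNA_i + b0

where ``c'_ji`` is the weighted binding-site count, ``miRNA_i`` the log2
miRNA abundance, ``dk_i`` the per-miRNA perturbation coefficient
(positive dk: repression weakens, targets rise) and ``b0`` a shared
miRNA-independent offset.  In matrix form ``fc = A dk + b0`` with
``A = C' diag(miRNA)``.  The system is overdetermined (many more
transcripts than miRNAs) and inconsistent, so (dk, b0) are estimated by
least squares; on rank-deficient designs the minimum-norm solution is
returned.  Fit quality is scored by the Spearman correlation between
predicted and observed fold changes, and validated by random
training/validation splits and by randomized-matrix null controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import DataError, InvalidArgumentError, ShapeError
from .expression import FoldChangeVector
from .interaction import RANDOMIZATION_SCHEMES, WeightedTargetMatrix, randomize_matrix


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks.

    Ties receive average ranks.  If either vector is constant the
    correlation is undefined; NaN is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ShapeError("spearman expects two equal-length vectors")
    if x.size < 2:
        raise InvalidArgumentError("need at least two observations")
    rx = rankdata(x)
    ry = rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        warnings.warn("constant input: Spearman correlation undefined", stacklevel=2)
        return float("nan")
    rho = ((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy)
    return float(np.clip(rho, -1.0, 1.0))


@dataclass
class ModelDesign:
    """Design matrix A = C' diag(miRNA) with its identifier bookkeeping."""

    A: np.ndarray
    mirna_expr: np.ndarray
    transcript_ids: list[str]
    mirna_ids: list[str]
    intercept_included: bool = True

    @property
    def shape(self) -> tuple[int, int]:
        return self.A.shape

    def column_subset(self, subset) -> np.ndarray:
        """Indices of the requested miRNA ids, preserving design order."""
        wanted = set(subset)
        unknown = wanted - set(self.mirna_ids)
        if unknown:
            raise InvalidArgumentError(f"unknown miRNA ids {sorted(unknown)}")
        return np.array([i for i, m in enumerate(self.mirna_ids) if m in wanted], dtype=int)


def build_design(
    C_prime: WeightedTargetMatrix,
    mirna_expr,
    mirna_ids: list[str] | None = None,
) -> ModelDesign:
    """Scale each C' column by the matching miRNA log2 abundance.

    ``mirna_expr`` may be a mapping/Series keyed by miRNA id or a plain
    vector aligned with the C' columns.  miRNAs missing from the expression
    data are dropped with a warning; an empty intersection is an error.
    """
    if hasattr(mirna_expr, "keys"):
        available = [m for m in C_prime.mirna_ids if m in mirna_expr]
        if not available:
            raise DataError("no miRNA of C' has an expression value")
        if len(available) < len(C_prime.mirna_ids):
            dropped = sorted(set(C_prime.mirna_ids) - set(available))
            warnings.warn(
                f"dropping {len(dropped)} miRNAs without expression values",
                stacklevel=2,
            )
        cols = [C_prime.mirna_ids.index(m) for m in available]
        expr = np.array([float(mirna_expr[m]) for m in available])
        values = C_prime.values[:, cols]
        ids = available
    else:
        expr = np.asarray(mirna_expr, dtype=float)
        if expr.shape[0] != len(C_prime.mirna_ids):
            raise ShapeError(
                f"expression length {expr.shape[0]} != {len(C_prime.mirna_ids)} miRNAs"
            )
        values = C_prime.values
        ids = list(C_prime.mirna_ids)
    if mirna_ids is not None:
        ids = list(mirna_ids)
    return ModelDesign(values * expr, expr, list(C_prime.transcript_ids), ids)


class MiRNAPerturbationModel(RegressorMixin, BaseEstimator):
    """Least-squares estimator of per-miRNA perturbation coefficients.

    scikit-learn style regressor: ``fit(A, fc)`` where A is the design
    matrix (transcripts x miRNAs) and fc the observed log2 fold changes.
    The intercept b0 is estimated jointly by augmenting the design with a
    constant column; rank-deficient designs yield the minimum-norm
    solution (fitted values are unaffected by the degeneracy).

    Attributes
    ----------
    coef_ : ndarray, the estimated dk vector
    intercept_ : float, the estimated b0
    rank_ : effective rank of the augmented design
    rho_train_ : Spearman correlation of fitted vs observed fold changes
    residuals_ : observed minus fitted fold changes
    """

    def __init__(self, fit_intercept: bool = True):
        self.fit_intercept = fit_intercept

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
            raise ShapeError(f"non-conformable design {X.shape} and response {y.shape}")
        if X.shape[0] < 2:
            raise InvalidArgumentError("need at least two transcripts")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise DataError("design and response must be finite")
        if self.fit_intercept:
            augmented = np.hstack([X, np.ones((X.shape[0], 1))])
        else:
            augmented = X
        # singular values below eps*max(M,N) (relative) are rank-deficiency
        # noise, e.g. an exactly duplicated target column; truncate them so
        # the minimum-norm solution is returned
        cutoff = np.finfo(float).eps * max(augmented.shape)
        solution, _, rank, _ = linalg.lstsq(augmented, y, cond=cutoff)
        if self.fit_intercept:
            self.coef_ = solution[:-1]
            self.intercept_ = float(solution[-1])
        else:
            self.coef_ = solution
            self.intercept_ = 0.0
        self.rank_ = int(rank)
        self.n_features_in_ = X.shape[1]
        fitted = X @ self.coef_ + self.intercept_
        self.fitted_values_ = fitted
        self.residuals_ = y - fitted
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.rho_train_ = spearman(fitted, y)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_


@dataclass
class FittedModel:
    """Estimated perturbation coefficients with diagnostics."""

    dk: np.ndarray
    b0: float
    mirna_ids: list[str]
    rho_train: float
    residuals: np.ndarray = field(repr=False, default=None)
    rank_of_design: int = 0

    def dk_series(self):
        import pandas as pd

        return pd.Series(self.dk, index=self.mirna_ids)


def fit_least_squares(design: ModelDesign, fc_observed) -> FittedModel:
    """Estimate (dk, b0) for a design by ordinary least squares."""
    fc = fc_observed.fc if isinstance(fc_observed, FoldChangeVector) else np.asarray(fc_observed, dtype=float)
    est = MiRNAPerturbationModel().fit(design.A, fc)
    return FittedModel(
        dk=est.coef_,
        b0=est.intercept_,
        mirna_ids=list(design.mirna_ids),
        rho_train=est.rho_train_,
        residuals=est.residuals_,
        rank_of_design=est.rank_,
    )


def predict_fold_change(
    model: FittedModel, design: ModelDesign, subset=None
) -> FoldChangeVector:
    """Predict fold changes, optionally from a subset of miRNAs.

    The subset masks design columns and the matching dk entries; b0 is
    always included.
    """
    if subset is None:
        pred = design.A @ model.dk + model.b0
    else:
        idx = design.column_subset(subset)
        pred = design.A[:, idx] @ model.dk[idx] + model.b0
    return FoldChangeVector(pred, list(design.transcript_ids))


@dataclass
class SplitValidationResult:
    """Spearman correlations over random training/validation splits."""

    n_splits: int
    rho_train_dist: np.ndarray
    rho_valid_dist: np.ndarray
    split_fraction: float
    seed: int | None


def split_validate(
    C_prime: WeightedTargetMatrix,
    mirna_expr,
    fc_observed,
    split_fraction: float = 0.5,
    n_splits: int = 10000,
    seed: int | None = None,
) -> SplitValidationResult:
    """Random-split validation of the perturbation model.

    For each split the transcripts are partitioned into a training part
    (fraction ``split_fraction``) and a validation part; (dk, b0) are
    estimated on the training rows and applied unchanged to predict the
    validation rows.  Both Spearman correlations are recorded.
    """
    if not (0 < split_fraction < 1):
        raise InvalidArgumentError("split_fraction must lie in (0, 1)")
    design = build_design(C_prime, mirna_expr)
    fc = fc_observed.fc if isinstance(fc_observed, FoldChangeVector) else np.asarray(fc_observed, dtype=float)
    n_m = design.A.shape[0]
    n_train = int(round(split_fraction * n_m))
    n_mi = design.A.shape[1]
    if min(n_train, n_m - n_train) < n_mi + 2:
        raise InvalidArgumentError(
            f"split sizes ({n_train}, {n_m - n_train}) too small for "
            f"{n_mi} miRNAs"
        )
    rng = np.random.default_rng(seed)
    rho_train = np.empty(n_splits)
    rho_valid = np.empty(n_splits)
    est = MiRNAPerturbationModel()
    for s in range(n_splits):
        perm = rng.permutation(n_m)
        train, valid = perm[:n_train], perm[n_train:]
        est.fit(design.A[train], fc[train])
        rho_train[s] = est.rho_train_
        rho_valid[s] = spearman(est.predict(design.A[valid]), fc[valid])
    return SplitValidationResult(n_splits, rho_train, rho_valid, split_fraction, seed)


@dataclass
class RandomizationResult:
    """Null distribution of model correlations under a randomization scheme."""

    scheme: str
    n_reps: int
    rho_dist: np.ndarray


def randomization_control(
    C_prime: WeightedTargetMatrix,
    mirna_expr,
    fc_observed,
    scheme: str,
    n_reps: int = 1000,
    seed: int | None = None,
) -> RandomizationResult:
    """Assess how much of the model fit survives destroying C'.

    ``uniform`` and ``permute`` re-fit the model with a randomized matrix
    and record the training correlation; ``permute_after_fit`` keeps the
    coefficients estimated on the original C' and predicts through a
    freshly permuted matrix each repetition — the strongest null, since
    real parameters meet a structureless target matrix.
    """
    if scheme not in RANDOMIZATION_SCHEMES:
        raise InvalidArgumentError(
            f"unknown scheme {scheme!r}; expected one of {RANDOMIZATION_SCHEMES}"
        )
    fc = fc_observed.fc if isinstance(fc_observed, FoldChangeVector) else np.asarray(fc_observed, dtype=float)
    rng = np.random.default_rng(seed)
    rho = np.empty(n_reps)
    if scheme == "permute_after_fit":
        design = build_design(C_prime, mirna_expr)
        model = fit_least_squares(design, fc)
        for r in range(n_reps):
            shuffled = randomize_matrix(C_prime, "permute", rng)
            pred = build_design(shuffled, mirna_expr).A @ model.dk + model.b0
            rho[r] = spearman(pred, fc)
    else:
        for r in range(n_reps):
            random_C = randomize_matrix(C_prime, scheme, rng)
            design = build_design(random_C, mirna_expr)
            rho[r] = fit_least_squares(design, fc).rho_train
    return RandomizationResult(scheme, n_reps, rho)
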