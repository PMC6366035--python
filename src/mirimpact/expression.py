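"""Expression matrices, Gaussian-mixture noise filtering, fold changes.

Microarray expression summaries on the log2 scale are bimodal: a low
component of features at the noise floor and one or more components of
genuinely expressed features.  The filter fits Gaussian mixtures with
2..8 components (EM, 100 random starts, tolerance 1e-2, at most 5000
iterations), selects the number of components by BIC, and removes the
low-expression component(s).  Two removal rules are provided and agree on
well-separated mixtures:

``top_three``
    Order components by mean and keep the top ``min(3, k - 1)`` (high /
    medium / low expression); everything below is the noise floor.  The
    threshold is the decision boundary where the posterior probability of
    the kept components reaches one half.
``kmeans``
    Cluster the component means into keep/remove groups with 1-D 2-means
    and threshold at the same posterior boundary.

Duplicate probes of one gene are collapsed to the most-expressed probe,
and fold changes are differences of mean log2 expression between sample
groups (treated minus control).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .exceptions import ConfigurationError, DataError, InvalidArgumentError

REMOVAL_RULES = ("top_three", "kmeans")


@dataclass
class ExpressionMatrix:
    """Feature x sample log2 expression values with sample metadata.

    ``sample_meta`` is indexed by sample id with columns ``condition``
    (e.g. control / irradiated) and ``time_h``; ``gene_map`` optionally
    maps feature ids to gene ids for duplicate collapsing.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    gene_map: pd.Series | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise DataError("expression values must be finite")
        if self.values.index.has_duplicates:
            raise DataError("feature ids must be unique")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise DataError(f"samples without metadata: {sorted(missing)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    def summary(self) -> pd.Series:
        """Per-feature mean log2 expression across all samples."""
        return self.values.mean(axis=1)

    def select_samples(self, selector) -> list[str]:
        """Resolve a selector to a list of sample ids.

        A selector is a list of sample ids, or a dict matched against the
        metadata columns (e.g. ``{"condition": "control", "time_h": 1}``).
        """
        if isinstance(selector, dict):
            mask = pd.Series(True, index=self.sample_meta.index)
            for key, value in selector.items():
                if key not in self.sample_meta.columns:
                    raise ConfigurationError(f"unknown metadata column {key!r}")
                mask &= self.sample_meta[key] == value
            ids = [s for s in self.values.columns if mask.get(s, False)]
        else:
            unknown = set(selector) - set(self.values.columns)
            if unknown:
                raise DataError(f"unknown sample ids {sorted(unknown)}")
            ids = list(selector)
        return ids


@dataclass
class NoiseFilterResult:
    """Outcome of the mixture-based noise filtering of one feature set."""

    n_components: int
    component_weights: np.ndarray
    component_means: np.ndarray
    component_sds: np.ndarray
    threshold: float
    kept_ids: list[str]
    removed_ids: list[str]
    rule: str
    summary: pd.Series = field(repr=False, default=None)


class NoiseFilter(BaseEstimator):
    """Gaussian-mixture noise-floor estimator for expression summaries.

    Parameters follow the conventional mixture-filtering settings: the
    number of components is selected by BIC over ``k_min..k_max``, each
    candidate fitted by EM with ``n_starts`` random initialisations,
    convergence tolerance ``tol`` and at most ``max_iter`` iterations.

    Attributes (after :meth:`fit`)
    ------------------------------
    n_components_ : selected number of components
    weights_, means_, sds_ : mixture parameters, sorted by mean
    threshold_ : log2 expression level below which features are noise
    kept_components_ : indices (into the sorted components) retained
    """

    def __init__(
        self,
        k_min: int = 2,
        k_max: int = 8,
        n_starts: int = 100,
        tol: float = 1e-2,
        max_iter: int = 5000,
        rule: str = "top_three",
        random_state: int = 0,
    ):
        self.k_min = k_min
        self.k_max = k_max
        self.n_starts = n_starts
        self.tol = tol
        self.max_iter = max_iter
        self.rule = rule
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.rule not in REMOVAL_RULES:
            raise ConfigurationError(f"unknown removal rule {self.rule!r}")
        if self.k_min < 1 or self.k_max < self.k_min:
            raise InvalidArgumentError("need 1 <= k_min <= k_max")
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:  # feature x sample matrix -> per-feature mean
            x = x.mean(axis=1)
        if x.ndim != 1:
            raise InvalidArgumentError("expected a vector or feature x sample matrix")
        if x.size < 3 * self.k_max:
            raise InvalidArgumentError(
                f"need at least {3 * self.k_max} features to fit up to "
                f"{self.k_max} components"
            )
        data = x.reshape(-1, 1)
        best = None
        for k in range(self.k_min, self.k_max + 1):
            gmm = GaussianMixture(
                n_components=k,
                covariance_type="full",
                n_init=self.n_starts,
                tol=self.tol,
                max_iter=self.max_iter,
                random_state=self.random_state,
            ).fit(data)
            bic = gmm.bic(data)
            if best is None or bic < best[0]:
                best = (bic, gmm)
        self.bic_, gmm = best
        order = np.argsort(gmm.means_.ravel())
        self.n_components_ = gmm.n_components
        self.weights_ = gmm.weights_[order]
        self.means_ = gmm.means_.ravel()[order]
        self.sds_ = np.sqrt(gmm.covariances_.reshape(-1)[order])
        self.kept_components_ = self._kept_components()
        self.threshold_ = self._threshold(x)
        return self

    def _kept_components(self) -> np.ndarray:
        k = self.n_components_
        if k == 1:
            return np.array([0])
        if self.rule == "top_three":
            n_keep = min(3, k - 1)
            return np.arange(k - n_keep, k)
        # kmeans rule: split the component means into low/high groups
        km = KMeans(n_clusters=2, n_init=10, random_state=self.random_state).fit(
            self.means_.reshape(-1, 1)
        )
        high_cluster = np.argmax(km.cluster_centers_.ravel())
        kept = np.nonzero(km.labels_ == high_cluster)[0]
        return kept

    def _threshold(self, x: np.ndarray) -> float:
        kept = self.kept_components_
        removed = np.setdiff1d(np.arange(self.n_components_), kept)
        if removed.size == 0:
            return float(x.min() - 1.0)  # nothing removed

        def posterior_margin(v: float) -> float:
            dens = self.weights_ * norm.pdf(v, self.means_, self.sds_)
            return dens[kept].sum() - dens[removed].sum()

        lo = float(self.means_[removed].max())
        hi = float(self.means_[kept].min())
        if lo >= hi:
            return float((lo + hi) / 2.0)
        try:
            return float(brentq(posterior_margin, lo, hi))
        except ValueError:
            # no sign change between the bracketing means: pick the lowest
            # crossing on a fine grid over the data range
            grid = np.linspace(x.min(), x.max(), 4096)
            margins = np.array([posterior_margin(v) for v in grid])
            crossing = np.nonzero(np.diff(np.sign(margins)) > 0)[0]
            if crossing.size:
                return float(grid[crossing[0] + 1])
            return float((lo + hi) / 2.0)


def fit_noise_model(
    expr_summary,
    k_min: int = 2,
    k_max: int = 8,
    n_starts: int = 100,
    tol: float = 1e-2,
    max_iter: int = 5000,
    rule: str = "top_three",
    random_state: int = 0,
    threshold_override: float | None = None,
) -> NoiseFilterResult:
    """Fit the mixture noise model to a per-feature expression summary.

    ``expr_summary`` is a pandas Series (feature id -> mean log2 level) or a
    plain vector.  ``threshold_override`` skips the rule and imposes a manual
    threshold, for sensitivity sweeps.
    """
    series = (
        expr_summary
        if isinstance(expr_summary, pd.Series)
        else pd.Series(np.asarray(expr_summary, dtype=float))
    )
    nf = NoiseFilter(k_min, k_max, n_starts, tol, max_iter, rule, random_state)
    nf.fit(series.to_numpy(dtype=float))
    threshold = nf.threshold_ if threshold_override is None else float(threshold_override)
    kept = series.index[series >= threshold]
    removed = series.index[series < threshold]
    return NoiseFilterResult(
        n_components=nf.n_components_,
        component_weights=nf.weights_,
        component_means=nf.means_,
        component_sds=nf.sds_,
        threshold=threshold,
        kept_ids=list(kept),
        removed_ids=list(removed),
        rule=rule,
        summary=series,
    )


def apply_noise_filter(expr: ExpressionMatrix, result: NoiseFilterResult) -> ExpressionMatrix:
    """Restrict an expression matrix to the features kept by the filter."""
    all_ids = set(result.kept_ids) | set(result.removed_ids)
    if all_ids != set(expr.feature_ids):
        raise DataError("noise-filter result computed on a different feature set")
    keep = [f for f in expr.feature_ids if f in set(result.kept_ids)]
    if not keep:
        warnings.warn("noise filter removed every feature", stacklevel=2)
    return ExpressionMatrix(
        expr.values.loc[keep], expr.sample_meta,
        expr.gene_map.loc[keep] if expr.gene_map is not None else None,
    )


def collapse_duplicates(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Keep one probe per gene: highest mean expression, ties to the
    lexicographically smallest feature id.

    Multiple probes of one gene have strongly correlated levels and would
    otherwise inflate correlation estimates downstream.
    """
    if expr.gene_map is None:
        raise ConfigurationError("collapse_duplicates requires a feature -> gene map")
    means = expr.summary()
    choice = (
        pd.DataFrame({"gene": expr.gene_map, "mean": means})
        .rename_axis("feature")
        .reset_index()
        .sort_values(["gene", "mean", "feature"], ascending=[True, False, True])
        .groupby("gene", sort=False)
        .head(1)["feature"]
    )
    keep = [f for f in expr.feature_ids if f in set(choice)]
    return ExpressionMatrix(expr.values.loc[keep], expr.sample_meta, expr.gene_map.loc[keep])


@dataclass
class FoldChangeVector:
    """Per-transcript log2 fold changes with the sample sets used."""

    fc: np.ndarray
    transcript_ids: list[str]
    pre_samples: list[str] = field(default_factory=list)
    post_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.fc = np.asarray(self.fc, dtype=float)
        if self.fc.shape[0] != len(self.transcript_ids):
            raise DataError("fold-change length does not match transcript ids")

    def to_series(self) -> pd.Series:
        return pd.Series(self.fc, index=self.transcript_ids)


def compute_fold_change(expr: ExpressionMatrix, pre_selector, post_selector) -> FoldChangeVector:
    """Log2 fold change per feature: mean(post samples) - mean(pre samples)."""
    pre = expr.select_samples(pre_selector)
    post = expr.select_samples(post_selector)
    if not pre or not post:
        raise InvalidArgumentError("pre and post selections must be non-empty")
    fc = expr.values[post].mean(axis=1) - expr.values[pre].mean(axis=1)
    return FoldChangeVector(fc.to_numpy(), expr.feature_ids, pre, post)
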