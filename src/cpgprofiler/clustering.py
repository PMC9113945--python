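"""Three-way gene clustering from the 1-D CG-likelihood distribution.

The CG-likelihood distribution of a full gene set is roughly trimodal:
housekeeping-like genes pile up near 0, tissue-specific-like genes near 1,
and an intermediate group in between. A univariate Gaussian mixture fitted
by EM turns this into cluster labels 1..k, ordered by ascending component
mean so that cluster 1 always has the lowest likelihoods (sharp, CpG-rich
promoters) and cluster k the highest (flat, CpG-poor promoters).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_is_fitted

__all__ = ["LikelihoodMixture", "fit_gmm_1d", "assign_clusters", "cluster_composition",
           "logit_transform"]


def logit_transform(p, eps: float = 1e-7):
    """Log-odds of a probability vector, clipped to (eps, 1−eps).

    A well-trained classifier saturates its probabilities near 0 and 1, which
    violates the Gaussian-component assumption of the mixture model and
    collapses distinct low-likelihood groups onto the boundary. Clustering on
    the log-odds scale restores the separation while leaving cluster order
    (ascending mean) intact, since the transform is strictly monotone.
    """
    arr = np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)
    out = np.log(arr / (1.0 - arr))
    if isinstance(p, pd.Series):
        return pd.Series(out, index=p.index, name=p.name)
    return out


class LikelihoodMixture(BaseEstimator, ClusterMixin):
    """Univariate Gaussian mixture over CG likelihoods with ordered labels.

    Thin estimator around EM mixture fitting that (a) orders components by
    ascending mean, so ``predict`` returns clusters 1..n_components with
    cluster 1 at the low-likelihood end, and (b) floors component variances
    to keep near-discrete likelihood distributions from collapsing a
    component.

    Attributes (after ``fit``): ``means_``, ``variances_``, ``weights_``
    (each sorted by mean) and ``gmm_`` (the underlying fitted mixture).
    """

    def __init__(self, n_components: int = 3, n_init: int = 5, tol: float = 1e-6,
                 max_iter: int = 500, var_floor: float = 1e-6, random_state: int = 0):
        self.n_components = n_components
        self.n_init = n_init
        self.tol = tol
        self.max_iter = max_iter
        self.var_floor = var_floor
        self.random_state = random_state

    @staticmethod
    def _column(x) -> np.ndarray:
        x = np.asarray(x, dtype=float).reshape(-1, 1)
        if not np.all(np.isfinite(x)):
            raise ValueError("likelihoods contain NaN or infinite values")
        return x

    def fit(self, X, y=None):
        x = self._column(X)
        if len(x) < 10 * self.n_components:
            raise ValueError(
                f"need at least {10 * self.n_components} points to fit "
                f"{self.n_components} components, got {len(x)}"
            )
        gmm = GaussianMixture(
            n_components=self.n_components,
            covariance_type="full",
            n_init=self.n_init,
            tol=self.tol,
            max_iter=self.max_iter,
            reg_covar=self.var_floor,
            random_state=self.random_state,
        ).fit(x)
        var = gmm.covariances_.reshape(-1)
        if np.any(var <= self.var_floor * (1 + 1e-9)):
            warnings.warn("degenerate mixture component: variance at floor", stacklevel=2)
        self._order = np.argsort(gmm.means_.reshape(-1), kind="stable")
        self.gmm_ = gmm
        self.means_ = gmm.means_.reshape(-1)[self._order]
        self.variances_ = var[self._order]
        self.weights_ = gmm.weights_[self._order]
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Posterior responsibilities, columns ordered by ascending component mean."""
        check_is_fitted(self, "gmm_")
        return self.gmm_.predict_proba(self._column(X))[:, self._order]

    def predict(self, X) -> np.ndarray:
        """Cluster labels 1..n_components by maximum responsibility.

        Exact responsibility ties resolve to the smaller-mean cluster
        (argmax takes the first maximum over the mean-ordered columns).
        """
        return np.argmax(self.predict_proba(X), axis=1) + 1

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).predict(X)


def fit_gmm_1d(likelihoods, k: int = 3, seed: int = 0, n_init: int = 5,
               tol: float = 1e-6) -> LikelihoodMixture:
    """Fit a k-component univariate mixture to CG likelihoods (best of n_init)."""
    return LikelihoodMixture(n_components=k, n_init=n_init, tol=tol, random_state=seed).fit(
        np.asarray(likelihoods, dtype=float)
    )


def assign_clusters(likelihoods: pd.Series | np.ndarray, mixture: LikelihoodMixture) -> pd.DataFrame:
    """Hard cluster assignment plus responsibilities for each gene.

    Returns a DataFrame indexed like ``likelihoods`` with a ``cluster`` column
    (1..k, ascending component mean) and one ``resp_<c>`` column per cluster.
    """
    values = likelihoods.to_numpy() if isinstance(likelihoods, pd.Series) else np.asarray(likelihoods)
    index = likelihoods.index if isinstance(likelihoods, pd.Series) else pd.RangeIndex(len(values))
    resp = mixture.predict_proba(values)
    out = pd.DataFrame({"cluster": np.argmax(resp, axis=1) + 1}, index=index)
    for c in range(resp.shape[1]):
        out[f"resp_{c + 1}"] = resp[:, c]
    return out


def cluster_composition(
    assignment: pd.DataFrame, annotations: dict[str, set[str] | list[str]]
) -> pd.DataFrame:
    """Cross-tabulate cluster membership against annotation gene sets.

    ``annotations`` maps a set name (e.g. "housekeeping") to gene ids.
    Returns one row per (annotation, cluster) with the member count, the
    proportion of the annotation's matched genes in that cluster, and the
    number of annotation ids absent from the assignment (reported once per
    annotation as ``n_unmatched``).
    """
    rows = []
    clusters = np.sort(assignment["cluster"].unique())
    for name, genes in annotations.items():
        genes = set(genes)
        if not genes:
            raise ValueError(f"annotation set {name!r} is empty")
        matched = assignment.loc[assignment.index.isin(genes), "cluster"]
        n_unmatched = len(genes) - len(matched)
        for c in clusters:
            n = int((matched == c).sum())
            rows.append(
                {"annotation": name, "cluster": int(c), "count": n,
                 "proportion": n / len(matched) if len(matched) else np.nan,
                 "n_matched": len(matched), "n_unmatched": n_unmatched}
            )
    return pd.DataFrame(rows)
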