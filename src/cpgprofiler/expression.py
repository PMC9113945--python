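"""Tissue-specificity scoring and window-wise Spearman correlation.

The tissue specificity of gene i in tissue t is
``s_it = (eps_it - mu_i) / mu_i`` where ``eps_it`` is the gene's mean
expression in tissue t and ``mu_i`` its mean over all tissues; s_it is 0 for
uniformly expressed genes and approaches its lower bound −1 in tissues where
the gene is silent. The window-wise correlation engine computes one Spearman
coefficient per 40-bp window column of a genes × windows matrix against a
per-gene response (expression) — or against the matching column of a second
matrix — yielding a 1 × n_windows correlation profile.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "tissue_specificity",
    "max_tissue_specificity",
    "windowed_spearman",
    "windowed_spearman_paired",
    "select_high_expressed",
]


def tissue_specificity(expr: pd.DataFrame, tissue_of: pd.Series | None = None) -> pd.DataFrame:
    """Per-(gene, tissue) specificity s_it = (eps_it − mu_i) / mu_i.

    ``expr`` is genes × samples, nonnegative. If ``tissue_of`` maps sample
    names to tissue names, eps_it is the mean over a tissue's replicate
    samples; otherwise each column is its own tissue. mu_i is the unweighted
    mean of eps_it over tissues; genes with mu_i = 0 get all-NaN rows.
    """
    values = expr.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("expression values must be nonnegative")
    if tissue_of is not None:
        eps = expr.T.groupby(tissue_of).mean().T
    else:
        eps = expr
    mu = eps.mean(axis=1)
    s = eps.sub(mu, axis=0).div(mu, axis=0)
    s[mu == 0] = np.nan
    return s


def max_tissue_specificity(ts: pd.DataFrame, exclude: list[str] | None = None) -> pd.Series:
    """Per-gene maximum s_it over retained tissues (e.g. excluding testis)."""
    exclude = list(exclude or [])
    unknown = set(exclude) - set(ts.columns)
    if unknown:
        raise ValueError(f"excluded tissues not present: {sorted(unknown)}")
    kept = ts.drop(columns=exclude)
    if kept.shape[1] == 0:
        raise ValueError("all tissues excluded")
    return kept.max(axis=1).rename("max_tissue_specificity")


def _spearman_one(a: np.ndarray, b: np.ndarray, min_n: int) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < min_n:
        return np.nan
    ra = rankdata(a[ok])
    rb = rankdata(b[ok])
    if ra.std() == 0 or rb.std() == 0:
        return np.nan
    ra -= ra.mean()
    rb -= rb.mean()
    return float(np.dot(ra, rb) / np.sqrt(np.dot(ra, ra) * np.dot(rb, rb)))


def windowed_spearman(
    feature_matrix: pd.DataFrame, response: pd.Series | np.ndarray, min_n: int = 10
) -> pd.DataFrame:
    """Column-wise Spearman between each window column and a per-gene response.

    Ties get average ranks; per column, gene pairs with a missing value in
    either variable are dropped; columns left with fewer than ``min_n`` valid
    pairs, or with zero variance, are NaN. Returns a DataFrame indexed by
    window offset with columns ``rho`` and ``n``.
    """
    resp = response.reindex(feature_matrix.index).to_numpy(dtype=float) \
        if isinstance(response, pd.Series) else np.asarray(response, dtype=float)
    if len(resp) != len(feature_matrix):
        raise ValueError("response length does not match matrix gene count")
    X = feature_matrix.to_numpy(dtype=float)
    rho = np.empty(X.shape[1])
    n = np.empty(X.shape[1], dtype=int)
    for w in range(X.shape[1]):
        ok = np.isfinite(X[:, w]) & np.isfinite(resp)
        n[w] = int(ok.sum())
        rho[w] = _spearman_one(X[:, w], resp, min_n)
    return pd.DataFrame({"rho": rho, "n": n}, index=feature_matrix.columns)


def windowed_spearman_paired(
    matrix_a: pd.DataFrame, matrix_b: pd.DataFrame, min_n: int = 10
) -> pd.DataFrame:
    """Per-window Spearman between matching columns of two genes × windows matrices."""
    if matrix_a.shape != matrix_b.shape or not matrix_a.columns.equals(matrix_b.columns):
        raise ValueError("matrices must share genes and window grid")
    if not matrix_a.index.equals(matrix_b.index):
        matrix_b = matrix_b.reindex(matrix_a.index)
        if matrix_b.isna().all(axis=1).any():
            raise ValueError("matrices must share genes and window grid")
    A = matrix_a.to_numpy(dtype=float)
    B = matrix_b.to_numpy(dtype=float)
    rho = np.empty(A.shape[1])
    n = np.empty(A.shape[1], dtype=int)
    for w in range(A.shape[1]):
        ok = np.isfinite(A[:, w]) & np.isfinite(B[:, w])
        n[w] = int(ok.sum())
        rho[w] = _spearman_one(A[:, w], B[:, w], min_n)
    return pd.DataFrame({"rho": rho, "n": n}, index=matrix_a.columns)


def select_high_expressed(values: pd.Series, percentile: float = 75.0) -> pd.Index:
    """Genes whose expression strictly exceeds the given percentile of all genes.

    The threshold is the linear-interpolation percentile of the full value
    vector; with all values equal the subset is empty (strict inequality).
    """
    if len(values) == 0:
        raise ValueError("empty expression vector")
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    threshold = np.percentile(values.to_numpy(dtype=float), percentile)
    return values.index[values > threshold]
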