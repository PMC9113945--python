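"""Threshold partition of differential-expression tables and group profiles.

Consumes an externally produced DE table (gene, log2 fold change, p-value —
e.g. DESeq2 output) and applies the strict rule: up-expressed when
log2FC > 1 and p < 0.05; down-expressed when log2FC < −1 and p < 0.05;
everything else, including genes with missing statistics, is stable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["classify_de", "de_proportions_by_cluster", "group_profile"]

_CATEGORIES = ("up", "down", "stable")


def classify_de(table: pd.DataFrame, lfc_cut: float = 1.0, p_cut: float = 0.05,
                lfc_col: str = "log2fc", p_col: str = "pvalue") -> pd.DataFrame:
    """Partition genes into up / down / stable by strict fold-change and p cuts.

    Returns a DataFrame indexed by gene with columns ``de`` (category) and
    ``missing`` (True where lfc or p was absent; such genes are stable).
    """
    if lfc_cut <= 0 or p_cut <= 0:
        raise ValueError("cuts must be positive")
    lfc = pd.to_numeric(table[lfc_col], errors="coerce")
    p = pd.to_numeric(table[p_col], errors="coerce")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    missing = lfc.isna() | p.isna()
    de = pd.Series("stable", index=table.index, name="de")
    de[(lfc > lfc_cut) & (p < p_cut) & ~missing] = "up"
    de[(lfc < -lfc_cut) & (p < p_cut) & ~missing] = "down"
    return pd.DataFrame({"de": de, "missing": missing})


def de_proportions_by_cluster(partition: pd.DataFrame, assignment: pd.DataFrame) -> pd.DataFrame:
    """Up/down/stable proportions within each cluster (rows sum to 1).

    ``partition`` is the output of :func:`classify_de`; ``assignment`` has a
    ``cluster`` column indexed by gene. Only genes present in both are
    counted; clusters left empty get an all-NaN row with a warning.
    """
    common = partition.index.intersection(assignment.index)
    if len(common) == 0:
        raise ValueError("no genes shared between DE table and cluster assignment")
    de = partition.loc[common, "de"]
    clusters = np.sort(assignment["cluster"].unique())
    rows = {}
    for c in clusters:
        members = de[assignment.loc[common, "cluster"] == c]
        if len(members) == 0:
            warnings.warn(f"cluster {c} has no genes with DE statistics", stacklevel=2)
            rows[c] = {cat: np.nan for cat in _CATEGORIES}
        else:
            rows[c] = {cat: float((members == cat).mean()) for cat in _CATEGORIES}
    out = pd.DataFrame.from_dict(rows, orient="index")[list(_CATEGORIES)]
    out.index.name = "cluster"
    return out


def group_profile(matrix: pd.DataFrame, groups: pd.Series,
                  order_by: pd.Series | None = None) -> pd.DataFrame:
    """Mean window profile per group, ignoring missing entries.

    ``groups`` maps gene id to a label (cluster number or DE category); each
    label yields one row of per-window means. Labels for genes absent from
    the matrix raise. If ``order_by`` is given, the full per-gene matrix
    reordered by descending ``order_by`` (e.g. expression, for heatmap
    export) is attached as the ``ranked_matrix_`` attribute of the result.
    """
    unknown = groups.index.difference(matrix.index)
    if len(unknown):
        raise ValueError(f"unknown genes in grouping: {list(unknown[:3])} ...")
    profiles = {}
    for label, genes in groups.groupby(groups):
        sub = matrix.loc[genes.index]
        profiles[label] = sub.mean(axis=0, skipna=True)
    out = pd.DataFrame(profiles).T
    out.index.name = "group"
    if order_by is not None:
        ranked = matrix.loc[order_by.sort_values(ascending=False).index]
        out.attrs["ranked_matrix"] = ranked
    return out
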