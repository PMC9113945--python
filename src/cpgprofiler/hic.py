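"""Insulation score, A/B compartments and compartment index from Hi-C matrices.

Operates on normalized per-chromosome contact matrices at a fixed bin size
(40 kb by default). The insulation score of bin i contrasts the contact
density inside its two flanking blocks with the contacts crossing bin i:

    IS_i = ln(1 + a1/b + a2/b)

where a1 and a2 are the mean contact probabilities within the upstream and
downstream k-bin flanks and b is the mean over the k × k block of contacts
between them. IS is high where the two flanks interact little across the
bin, i.e. at domain (TAD) boundaries, and is invariant under global scaling
of the matrix.

Compartments are called from the leading eigenvector of the correlation
matrix of the distance-normalized (observed/expected) contact map, with the
sign oriented so the A compartment has the higher mean of a supplied
orientation track (typically per-bin CpG density). The compartment index of
bin i, CI_i = ln(C_iA / C_iB), is the log-ratio of its mean contact with A
bins versus B bins; higher CI means a more open, A-like environment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GeneRecord

__all__ = [
    "ContactMatrix",
    "insulation_score",
    "call_compartments",
    "compartment_index",
    "gene_bin_lookup",
]


@dataclass
class ContactMatrix:
    """Symmetric, nonnegative, normalized contact matrix for one chromosome."""

    chrom: str
    bin_size: int
    matrix: np.ndarray
    bins: pd.DataFrame  # columns: chrom, start, end

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("contact matrix must be symmetric")
        if np.any(m < 0):
            raise ValueError("contact matrix must be nonnegative")
        if len(self.bins) != m.shape[0]:
            raise ValueError("bin table length does not match matrix size")
        self.matrix = m

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_coo(cls, coo_path: str | Path, bins_path: str | Path,
                 bin_size: int = 40_000) -> "ContactMatrix":
        """Load from a COO triplet TSV (bin_i, bin_j, value) and a bins BED."""
        bins = pd.read_csv(bins_path, sep="\t", header=None,
                           names=["chrom", "start", "end"], usecols=[0, 1, 2])
        if bins["chrom"].nunique() != 1:
            raise ValueError("bin table must cover a single chromosome")
        n = len(bins)
        m = np.zeros((n, n))
        coo = pd.read_csv(coo_path, sep="\t", header=None, names=["i", "j", "value"])
        i = coo["i"].to_numpy(int)
        j = coo["j"].to_numpy(int)
        v = coo["value"].to_numpy(float)
        if i.max(initial=-1) >= n or j.max(initial=-1) >= n:
            raise ValueError("COO indices exceed bin table")
        m[i, j] = v
        m[j, i] = v
        return cls(str(bins["chrom"].iloc[0]), bin_size, m, bins)


def insulation_score(cm: ContactMatrix, window_bp: int = 480_000) -> pd.Series:
    """Per-bin insulation score IS = ln(1 + a1/b + a2/b), NaN near edges.

    ``window_bp`` must be a multiple of the bin size; k = window_bp / bin_size
    bins flank the central bin on each side. The central bin's row and column
    are not part of any block, and diagonal entries are excluded from the
    flank means a1 and a2. Bins without complete flanks, or with b = 0, are
    NaN.
    """
    if window_bp % cm.bin_size != 0:
        raise ValueError("window_bp must be a multiple of the bin size")
    k = window_bp // cm.bin_size
    n = cm.n_bins
    if k >= n:
        raise ValueError(f"window of {k} bins does not fit a {n}-bin matrix")
    m = cm.matrix
    offdiag = ~np.eye(k, dtype=bool)
    out = np.full(n, np.nan)
    for i in range(k, n - k):
        up = m[i - k:i, i - k:i]
        down = m[i + 1:i + k + 1, i + 1:i + k + 1]
        a1 = up[offdiag].mean()
        a2 = down[offdiag].mean()
        b = m[i - k:i, i + 1:i + k + 1].mean()
        if b > 0:
            out[i] = np.log1p(a1 / b + a2 / b)
    return pd.Series(out, name="insulation_score")


def _observed_over_expected(m: np.ndarray) -> np.ndarray:
    """Divide each diagonal by its mean; empty (all-zero) diagonals stay zero."""
    n = m.shape[0]
    oe = np.zeros_like(m)
    idx = np.arange(n)
    for d in range(n):
        i = idx[: n - d]
        vals = m[i, i + d]
        mean = vals.mean()
        if mean > 0:
            oe[i, i + d] = vals / mean
            oe[i + d, i] = oe[i, i + d]
    return oe


def call_compartments(cm: ContactMatrix, orientation_track: np.ndarray | pd.Series) -> pd.Series:
    """A/B compartment labels from the O/E correlation leading eigenvector.

    The sign of the eigenvector is oriented so the mean of
    ``orientation_track`` (per-bin CpG density, by convention higher in the
    open A compartment) is larger among A bins. Bins with no contacts are
    unlabeled (empty string). Raises if the matrix carries no compartment
    signal (constant correlation structure).
    """
    orient = np.asarray(orientation_track, dtype=float)
    if len(orient) != cm.n_bins:
        raise ValueError("orientation track length does not match bin count")
    nonempty = cm.matrix.sum(axis=1) > 0
    if nonempty.sum() < 10:
        raise ValueError("need at least 10 non-empty bins")
    sub = cm.matrix[np.ix_(nonempty, nonempty)]
    oe = _observed_over_expected(sub)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(oe)
    if not np.all(np.isfinite(corr)):
        raise ValueError("no compartment signal: degenerate correlation matrix")
    w, v = np.linalg.eigh(corr)
    lead = v[:, -1]
    if np.allclose(lead, lead[0]) or w[-1] <= 1e-10:
        raise ValueError("no compartment signal")
    labels_sub = np.where(lead >= 0, "A", "B")
    mean_a = orient[nonempty][labels_sub == "A"].mean()
    mean_b = orient[nonempty][labels_sub == "B"].mean()
    if mean_b > mean_a:
        labels_sub = np.where(labels_sub == "A", "B", "A")
    labels = np.full(cm.n_bins, "", dtype=object)
    labels[nonempty] = labels_sub
    return pd.Series(labels, name="compartment")


def compartment_index(cm: ContactMatrix, labels: pd.Series | np.ndarray) -> pd.Series:
    """Per-bin CI = ln(mean contact with A bins / mean contact with B bins).

    Self-contacts are excluded; bins whose mean contact with either
    compartment is 0, and unlabeled bins, are NaN.
    """
    labels = np.asarray(labels, dtype=object)
    a_mask = labels == "A"
    b_mask = labels == "B"
    if a_mask.sum() == 0 or b_mask.sum() == 0:
        raise ValueError("both compartments must be non-empty")
    m = cm.matrix
    n = cm.n_bins
    out = np.full(n, np.nan)
    for i in range(n):
        if not (a_mask[i] or b_mask[i]):
            continue
        row = m[i].copy()
        row[i] = np.nan  # exclude self-contact
        with np.errstate(invalid="ignore"):
            ca = np.nanmean(row[a_mask]) if a_mask.sum() - a_mask[i] > 0 else 0.0
            cb = np.nanmean(row[b_mask]) if b_mask.sum() - b_mask[i] > 0 else 0.0
        if ca > 0 and cb > 0:
            out[i] = np.log(ca / cb)
    return pd.Series(out, name="compartment_index")


def gene_bin_lookup(genes: Sequence[GeneRecord], bins: pd.DataFrame,
                    bin_size: int | None = None) -> pd.Series:
    """Index of the half-open bin containing each gene's TSS (NaN if outside)."""
    if bin_size is None:
        bin_size = int(bins["end"].iloc[0] - bins["start"].iloc[0])
    chrom = str(bins["chrom"].iloc[0])
    start = int(bins["start"].min())
    end = int(bins["end"].max())
    out = pd.Series(np.nan, index=[g.gene_id for g in genes], name="bin")
    for g in genes:
        if g.chrom == chrom and start <= g.tss < end:
            out[g.gene_id] = (g.tss - start) // bin_size
    return out
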