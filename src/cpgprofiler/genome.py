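"""TSS-anchored windowed featurization of genomic sequence and signal tracks.

Every matrix produced here is oriented in the transcriptional sense: column 0
is always 8 kb (by default) upstream of the TSS regardless of strand, so that
minus-strand genes are directly comparable with plus-strand genes.

Coordinates are 0-based half-open throughout, matching BED conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneRecord",
    "WindowGrid",
    "read_tss_bed",
    "extract_window_sequence",
    "dinucleotide_density_matrix",
    "read_bedgraph",
    "signal_window_matrix",
    "methylation_window_matrix",
    "tss_signed_distance",
    "peak_overlap_proportion",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneRecord:
    """A gene anchored at its TSS.

    ``tss`` is a 0-based genomic coordinate; ``strand`` is '+' or '-'.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"{self.gene_id}: tss must be >= 0, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class WindowGrid:
    """Nonoverlapping windows tiling [tss - flank, tss + flank).

    Defaults give the 400-window, 40-bp grid over 16 kb centred on the TSS.
    """

    flank: int = 8000
    window: int = 40

    def __post_init__(self) -> None:
        if self.window <= 1:
            raise ValueError("window must be > 1")
        if (2 * self.flank) % self.window != 0:
            raise ValueError("2*flank must be a multiple of window")

    @property
    def n_windows(self) -> int:
        return (2 * self.flank) // self.window

    @property
    def span(self) -> int:
        return 2 * self.flank

    def offsets(self) -> np.ndarray:
        """Window start offsets relative to the TSS (−flank … +flank−window)."""
        return np.arange(-self.flank, self.flank, self.window)


def read_tss_bed(path: str | Path) -> list[GeneRecord]:
    """Read a BED6 file of TSS anchors (chrom, start, end, name, score, strand).

    The TSS is taken as the interval start (intervals are expected to be
    1-bp anchors; wider intervals use their start).
    """
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: BED6 requires 6 columns, got {len(parts)}")
            chrom, start, _end, name, _score, strand = parts[:6]
            if name in seen:
                raise ValueError(f"{path}:{ln}: duplicate gene id {name!r}")
            seen.add(name)
            genes.append(GeneRecord(name, chrom, int(start), strand))
    return genes


def _chrom_sequence(genome, chrom: str) -> str:
    """Fetch a full chromosome as an uppercase string from a Fasta or mapping."""
    try:
        rec = genome[chrom]
    except KeyError as exc:
        raise KeyError(f"chromosome {chrom!r} not found in genome") from exc
    return str(rec[:]) if not isinstance(rec, str) else rec


def extract_window_sequence(genome, gene: GeneRecord, grid: WindowGrid = WindowGrid()) -> str:
    """Extract the 2*flank sequence around the TSS, oriented 5'→3'.

    For minus-strand genes the reverse complement of the plus-strand slice is
    returned, so index 0 is always ``flank`` bp upstream in the transcriptional
    sense. Slices running off a chromosome end are padded with N (a warning is
    emitted). Unknown chromosomes raise ``KeyError``.
    """
    try:
        rec = genome[gene.chrom]
    except KeyError as exc:
        raise KeyError(f"chromosome {gene.chrom!r} not found in genome") from exc
    length = len(rec)
    start, end = gene.tss - grid.flank, gene.tss + grid.flank
    lo, hi = max(start, 0), min(end, length)
    if lo >= hi:
        core = ""
    else:
        sliced = rec[lo:hi]
        core = sliced if isinstance(sliced, str) else str(sliced)
    left_pad, right_pad = lo - start, end - hi
    if left_pad or right_pad:
        warnings.warn(
            f"{gene.gene_id}: window off chromosome end; padding "
            f"{left_pad} bp left / {right_pad} bp right with N",
            stacklevel=2,
        )
    seq = "N" * left_pad + core.upper() + "N" * right_pad
    if gene.strand == "-":
        seq = reverse_complement(seq)
    return seq


def _count_windows(seq: str, dinucleotide: str, grid: WindowGrid) -> np.ndarray:
    """Overlapping-scan dinucleotide counts per window, first-base attribution."""
    b = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    d0, d1 = (ord(c) for c in dinucleotide)
    match = (b[:-1] == d0) & (b[1:] == d1)
    starts = np.arange(0, grid.span, grid.window)
    return np.add.reduceat(match.astype(np.int64), starts)


def dinucleotide_density_matrix(
    genome,
    genes: Sequence[GeneRecord],
    grid: WindowGrid = WindowGrid(),
    dinucleotide: str = "CG",
) -> pd.DataFrame:
    """Per-gene windowed dinucleotide counts: genes × n_windows integer matrix.

    ``dinucleotide`` names the pair on the gene's sense strand (so "TG" for a
    minus-strand gene counts reference-strand "CA"). Occurrences are found by
    an overlapping scan of the reference-strand slice and attributed to the
    half-open 40-bp window containing their leftmost reference base; for
    minus-strand genes the window order is then reversed so column 0 is
    always the upstream end in the transcriptional sense. Anchoring the
    boundary-straddler attribution on the reference strand makes the
    palindromic-dinucleotide strand symmetry exact: a minus-strand CG vector
    equals the reversed plus-strand vector. Occurrences touching N count 0.
    Columns are labelled by window start offsets relative to the TSS.
    """
    if len(genes) == 0:
        raise ValueError("empty gene list")
    dinucleotide = dinucleotide.upper()
    if len(dinucleotide) != 2:
        raise ValueError("dinucleotide must be length 2")
    rows = np.empty((len(genes), grid.n_windows), dtype=np.int64)
    for i, gene in enumerate(genes):
        plus = GeneRecord(gene.gene_id, gene.chrom, gene.tss, "+")
        with warnings.catch_warnings():
            if gene.strand == "-":
                warnings.simplefilter("ignore")  # padding warned once via plus
            slice_seq = extract_window_sequence(genome, plus, grid)
        target = dinucleotide if gene.strand == "+" else reverse_complement(dinucleotide)
        counts = _count_windows(slice_seq, target, grid)
        rows[i] = counts if gene.strand == "+" else counts[::-1]
    return pd.DataFrame(rows, index=[g.gene_id for g in genes], columns=grid.offsets())


# ---------------------------------------------------------------------------
# signal tracks


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph into a (chrom, start, end, value) DataFrame."""
    chroms, starts, ends, vals = [], [], [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{ln}: bedGraph requires 4 columns, got {len(parts)}")
            try:
                s, e, v = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed bedGraph line: {line!r}") from exc
            if e <= s:
                raise ValueError(f"{path}:{ln}: empty or inverted interval")
            chroms.append(parts[0])
            starts.append(s)
            ends.append(e)
            vals.append(v)
    return pd.DataFrame({"chrom": chroms, "start": starts, "end": ends, "value": vals})


def _track_index(track: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, int]]:
    """Per-chromosome (starts, ends, values, max_len), sorted by start."""
    index = {}
    for chrom, sub in track.groupby("chrom", sort=False):
        sub = sub.sort_values("start", kind="mergesort")
        s = sub["start"].to_numpy(np.int64)
        e = sub["end"].to_numpy(np.int64)
        v = sub["value"].to_numpy(float)
        index[chrom] = (s, e, v, int((e - s).max()))
    return index


def _locus_profile(
    index, chrom: str, a: int, b: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-base (value_sum, cover_count) over [a, b); overlaps are averaged."""
    n = b - a
    total = np.zeros(n)
    cover = np.zeros(n)
    if chrom not in index:
        return total, cover
    s, e, v, max_len = index[chrom]
    lo = np.searchsorted(s, a - max_len, side="left")
    hi = np.searchsorted(s, b, side="left")
    for i in range(lo, hi):
        if e[i] <= a:
            continue
        ca, cb = max(s[i], a) - a, min(e[i], b) - a
        total[ca:cb] += v[i]
        cover[ca:cb] += 1.0
    return total, cover


def signal_window_matrix(
    track: pd.DataFrame | str | Path,
    genes: Sequence[GeneRecord],
    grid: WindowGrid = WindowGrid(),
) -> pd.DataFrame:
    """Windowed mean signal per gene from a bedGraph-style track.

    Entries are base-pair-weighted means of the track over each window's
    genomic footprint (overlapping track intervals are averaged per base),
    after strand orientation: minus-strand genes have their window order
    reversed. Windows with zero covered bases are NaN, never silently zero.
    """
    if len(genes) == 0:
        raise ValueError("empty gene list")
    if not isinstance(track, pd.DataFrame):
        track = read_bedgraph(track)
    index = _track_index(track)
    out = np.full((len(genes), grid.n_windows), np.nan)
    starts = np.arange(0, grid.span, grid.window)
    for gi, gene in enumerate(genes):
        a, b = gene.tss - grid.flank, gene.tss + grid.flank
        total, cover = _locus_profile(index, gene.chrom, max(a, 0), b)
        if a < 0:  # off-chromosome left flank: uncovered
            pad = np.zeros(-a)
            total, cover = np.concatenate([pad, total]), np.concatenate([pad, cover])
        per_base = np.divide(total, cover, out=np.zeros_like(total), where=cover > 0)
        if gene.strand == "-":
            per_base, cover = per_base[::-1], cover[::-1]
        wcov = np.add.reduceat((cover > 0).astype(float), starts)
        out[gi] = np.divide(
            np.add.reduceat(per_base, starts), wcov,
            out=np.full(grid.n_windows, np.nan), where=wcov > 0,
        )
    return pd.DataFrame(out, index=[g.gene_id for g in genes], columns=grid.offsets())


def methylation_window_matrix(
    cpg_betas: pd.DataFrame,
    genes: Sequence[GeneRecord],
    grid: WindowGrid = WindowGrid(),
) -> pd.DataFrame:
    """Windowed mean methylation beta per gene.

    ``cpg_betas`` has columns (chrom, pos, beta) with 0 ≤ beta ≤ 1; entry
    (g, w) is the unweighted mean beta over CpG sites whose coordinate falls
    in window w of the oriented grid; windows with no site are NaN.
    """
    if len(genes) == 0:
        raise ValueError("empty gene list")
    beta = cpg_betas["beta"].to_numpy(float)
    if np.any((beta < 0) | (beta > 1)):
        raise ValueError("beta values must lie in [0, 1]")
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in cpg_betas.groupby("chrom", sort=False):
        sub = sub.sort_values("pos", kind="mergesort")
        per_chrom[chrom] = (sub["pos"].to_numpy(np.int64), sub["beta"].to_numpy(float))
    out = np.full((len(genes), grid.n_windows), np.nan)
    for gi, gene in enumerate(genes):
        if gene.chrom not in per_chrom:
            continue
        pos, b = per_chrom[gene.chrom]
        a, bnd = gene.tss - grid.flank, gene.tss + grid.flank
        lo, hi = np.searchsorted(pos, a), np.searchsorted(pos, bnd)
        if lo == hi:
            continue
        off = pos[lo:hi] - a
        if gene.strand == "-":
            off = grid.span - 1 - off
        w = off // grid.window
        sums = np.bincount(w, weights=b[lo:hi], minlength=grid.n_windows)
        cnts = np.bincount(w, minlength=grid.n_windows)
        row = out[gi]
        np.divide(sums, cnts, out=row, where=cnts > 0)
    return pd.DataFrame(out, index=[g.gene_id for g in genes], columns=grid.offsets())


# ---------------------------------------------------------------------------
# peak geometry


def tss_signed_distance(
    peaks: pd.DataFrame, genes: Sequence[GeneRecord]
) -> pd.Series:
    """Signed distance from each TSS to the nearest peak midpoint.

    Positive values mean the peak lies downstream of transcription (for a
    minus-strand gene that is a smaller genomic coordinate). Genes whose
    chromosome carries no peak get NaN. Equidistant ties resolve to the
    peak with the smaller genomic coordinate.
    """
    mids: dict[str, np.ndarray] = {}
    for chrom, sub in peaks.groupby("chrom", sort=False):
        m = ((sub["start"].to_numpy(np.int64) + sub["end"].to_numpy(np.int64)) // 2)
        mids[chrom] = np.sort(m)
    out = pd.Series(np.nan, index=[g.gene_id for g in genes], name="signed_distance")
    for gene in genes:
        m = mids.get(gene.chrom)
        if m is None or len(m) == 0:
            continue
        i = np.searchsorted(m, gene.tss)
        cands = m[max(i - 1, 0): i + 1]
        nearest = cands[np.argmin(np.abs(cands - gene.tss))]
        d = int(nearest) - gene.tss
        out[gene.gene_id] = d if gene.strand == "+" else -d
    return out


def peak_overlap_proportion(
    peaks: pd.DataFrame, genes: Sequence[GeneRecord], promoter_window: int
) -> float:
    """Fraction of genes with ≥1 peak overlapping [tss−w, tss+w), strand-agnostic."""
    if len(genes) == 0:
        raise ValueError("empty gene set")
    if promoter_window <= 0:
        raise ValueError("promoter_window must be > 0")
    idx: dict[str, tuple[np.ndarray, np.ndarray, int]] = {}
    for chrom, sub in peaks.groupby("chrom", sort=False):
        sub = sub.sort_values("start", kind="mergesort")
        s = sub["start"].to_numpy(np.int64)
        e = sub["end"].to_numpy(np.int64)
        idx[chrom] = (s, e, int((e - s).max()) if len(s) else 0)
    n_hit = 0
    for gene in genes:
        if gene.chrom not in idx:
            continue
        s, e, max_len = idx[gene.chrom]
        a, b = gene.tss - promoter_window, gene.tss + promoter_window
        lo = np.searchsorted(s, a - max_len)
        hi = np.searchsorted(s, b)
        if np.any(e[lo:hi] > a):
            n_hit += 1
    return n_hit / len(genes)
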