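"""Self-contained synthetic inputs with the structure the analysis assumes.

The generator plants three promoter archetypes that mirror the three CpG
profile classes seen in real gene sets:

1. sharp, high CpG peak at the TSS (housekeeping-like; label 0),
2. broad CpG peak of moderate intensity (unlabeled),
3. flat, CpG-poor profile (tissue-specific-like; label 1).

The expected CG count of window w is ``baseline + h_k * exp(-(w-200)^2 /
(2 sigma_k^2))`` and is realized by placing non-overlapping CG dinucleotides
on a CpG-free background, so realized counts match the target in
expectation and never exceed the per-window maximum. Expression is coupled
to the realized TSS-proximal CpG density with archetype-dependent strength
(strongest for the flat archetype), with housekeeping-like genes broadly
expressed and archetype-3 genes confined to few tissues. Epigenetic tracks
couple a repressive broad/confined mark to low expression, an active mark
and nucleosome depletion to high expression, and methylation anticorrelated
with expression near the TSS. Hi-C matrices carry planted domain blocks and
a checkerboard compartment term with multiplicative lognormal noise.

Every generator is a pure function of ``SimulationConfig``: all randomness
flows from the single seed through spawned child streams.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome import GeneRecord, WindowGrid, reverse_complement
from .hic import ContactMatrix

__all__ = [
    "SimulationConfig",
    "gen_sequences",
    "gen_expression",
    "gen_marks",
    "gen_contact_matrix",
    "gen_de_table",
    "simulate_all",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study; defaults are the shipped conditions."""

    # gene set: genes per archetype (sharp / broad / flat)
    n_genes: tuple[int, int, int] = (600, 600, 600)
    flank: int = 8000
    window: int = 40
    baseline_rate: float = 0.5          # CG per window away from the peak
    peak_height: tuple[float, float, float] = (12.0, 5.0, 0.0)
    peak_sigma: tuple[float, float, float] = (3.0, 15.0, 1.0)  # in windows
    spacer: int = 200                   # bp between loci
    n_chroms: int = 2
    # expression model (log2 scale)
    n_tissues: int = 12
    expr_alpha: tuple[float, float, float] = (3.0, 2.0, 1.5)
    expr_beta: tuple[float, float, float] = (0.15, 0.6, 1.2)
    gene_noise_sd: float = 0.5          # CpG-independent per-gene variability
    tissue_noise_sd: float = 0.3        # per-(gene, tissue) noise
    # epigenetic marks
    k27_amp: tuple[float, float, float] = (0.8, 2.0, 0.0)
    mark_noise_sd: float = 0.3
    meth_noise_sd: float = 0.05
    # Hi-C
    hic_n_bins: int = 120
    hic_bin_size: int = 40_000
    tad_boundaries: tuple[int, ...] = (60,)
    hic_within: float = 1.0
    hic_between: float = 0.1
    comp_block: int = 10                # bins per compartment block
    comp_strength: float = 0.4
    hic_noise_sd: float = 0.1
    # DE table
    lfc_sd: tuple[float, float, float] = (0.4, 0.8, 1.5)
    de_p_scale: float = 0.4
    seed: int = 0

    @property
    def grid(self) -> WindowGrid:
        return WindowGrid(self.flank, self.window)

    @classmethod
    def classifier_benchmark(cls, seed: int = 0) -> "SimulationConfig":
        """Gene counts sized for an 800+800 labelled train split, 500+500
        held-out labelled genes, and 2000 unlabelled genes."""
        return cls(n_genes=(1300, 1000, 1300), seed=seed)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key, val in raw.items():
            if isinstance(val, list):
                raw[key] = tuple(val)
        return cls(**raw)


def _streams(config: SimulationConfig) -> dict[str, np.random.Generator]:
    names = ("sequence", "expression", "marks", "hic", "de")
    children = np.random.SeedSequence(config.seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# sequences


def _cpg_free_background(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform ACGT sequence with CpG dinucleotides removed (deamination-like)."""
    seq = _BASES[rng.integers(0, 4, size=n)].copy()
    for _ in range(16):
        cg = np.flatnonzero((seq[:-1] == ord("C")) & (seq[1:] == ord("G")))
        if len(cg) == 0:
            break
        repl = np.frombuffer(b"ACT", dtype=np.uint8)[rng.integers(0, 3, size=len(cg))]
        seq[cg + 1] = repl
    return seq


def _place_cg(seq: np.ndarray, rates: np.ndarray, window: int, rng: np.random.Generator) -> np.ndarray:
    """Plant CG dinucleotides with per-window expected counts ``rates``.

    Placements whose first base sits on the last position of a window are
    skipped so every planted CG lies wholly inside one window and window
    counts are unambiguous. Over the remaining window−1 eligible positions,
    acceptance probability p = lambda/(window − 1 − lambda) together with the
    skip-one-position-after-placement rule gives an expected count of
    ``lambda`` per window. Returns realized counts per window.
    """
    n = len(seq)
    lam = np.clip(rates, 0.0, window - 3.0)
    p = lam / (window - 1 - lam)
    p_pos = np.repeat(p, window)[: n - 1]
    p_pos[window - 1::window] = 0.0  # no boundary-straddling placements
    drawn = np.flatnonzero(rng.random(n - 1) < p_pos)
    kept = []
    last = -2
    for pos in drawn:
        if pos > last + 1:
            kept.append(pos)
            last = pos
    kept = np.asarray(kept, dtype=np.int64)
    if len(kept):
        seq[kept] = ord("C")
        seq[kept + 1] = ord("G")
    counts = np.bincount(kept // window, minlength=len(rates))[: len(rates)]
    return counts


def archetype_rates(config: SimulationConfig, archetype: int) -> np.ndarray:
    """Expected CG count per window for an archetype (1-based)."""
    w = np.arange(config.grid.n_windows, dtype=float)
    center = config.grid.n_windows / 2
    h = config.peak_height[archetype - 1]
    sigma = config.peak_sigma[archetype - 1]
    return config.baseline_rate + h * np.exp(-((w - center) ** 2) / (2 * sigma**2))


def gen_sequences(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[GeneRecord], pd.DataFrame]:
    """Synthesize a genome of 16-kb gene loci plus TSS records and truth table.

    The truth table records the planted archetype, the semi-supervised label
    (0 housekeeping-like, 1 tissue-specific-like, −1 unlabeled) and the
    realized CG count in the central windows (used by the expression model).
    """
    rng = rng or _streams(config)["sequence"]
    grid = config.grid
    span = grid.span
    center = grid.n_windows // 2
    central = slice(center - 6, center + 7)  # 13 windows around the TSS

    total = sum(config.n_genes)
    archetypes = np.repeat([1, 2, 3], config.n_genes)
    order = rng.permutation(total)
    archetypes = archetypes[order]
    strands = np.where(rng.random(total) < 0.5, "+", "-")

    rates = {k: archetype_rates(config, k) for k in (1, 2, 3)}
    chrom_parts: dict[str, list[str]] = {f"chrS{c + 1}": [] for c in range(config.n_chroms)}
    chrom_len = {name: 0 for name in chrom_parts}
    genes: list[GeneRecord] = []
    rows = []
    for i in range(total):
        k = int(archetypes[i])
        seq = _cpg_free_background(span, rng)
        counts = _place_cg(seq, rates[k], grid.window, rng)
        oriented = seq.tobytes().decode("ascii")
        chrom = f"chrS{(i % config.n_chroms) + 1}"
        locus_start = chrom_len[chrom]
        tss = locus_start + grid.flank
        placed = oriented if strands[i] == "+" else reverse_complement(oriented)
        spacer = _BASES[rng.integers(0, 4, size=config.spacer)].tobytes().decode("ascii")
        chrom_parts[chrom].extend([placed, spacer])
        chrom_len[chrom] += span + config.spacer
        gid = f"g{i:05d}"
        genes.append(GeneRecord(gid, chrom, tss, strands[i]))
        rows.append(
            {"gene_id": gid, "archetype": k,
             "label": {1: 0, 2: -1, 3: 1}[k],
             "strand": strands[i], "chrom": chrom, "tss": tss,
             "central_cg": int(counts[central].sum()),
             "total_cg": int(counts.sum())}
        )
    genome = {name: "".join(parts) for name, parts in chrom_parts.items()}
    truth = pd.DataFrame(rows).set_index("gene_id")
    return genome, genes, truth


# ---------------------------------------------------------------------------
# expression


def gen_expression(
    truth: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Genes × tissues TPM-like expression coupled to TSS-proximal CpG density.

    log2 expression = alpha_k + beta_k * z(central CG count, within archetype)
    + gene effect + tissue effect + noise. Archetype-1 genes get small dense
    tissue effects (broad expression); archetype-3 genes are high in one
    "home" tissue and low elsewhere; archetype 2 is intermediate.
    """
    rng = rng or _streams(config)["expression"]
    tissues = [f"t{j + 1:02d}" for j in range(config.n_tissues)]
    n = len(truth)
    log2e = np.zeros((n, config.n_tissues))
    arch = truth["archetype"].to_numpy()
    central = truth["central_cg"].to_numpy(float)
    gene_eff = rng.normal(0.0, config.gene_noise_sd, size=n)
    for k in (1, 2, 3):
        mask = arch == k
        if not mask.any():
            continue
        z = central[mask]
        z = (z - z.mean()) / max(z.std(), 1e-8)
        base = config.expr_alpha[k - 1] + config.expr_beta[k - 1] * z + gene_eff[mask]
        nk = mask.sum()
        tau = np.zeros((nk, config.n_tissues))
        if k == 1:
            tau = rng.normal(0.0, 0.2, size=(nk, config.n_tissues))
        elif k == 2:
            for r in range(nk):
                home = rng.choice(config.n_tissues, size=3, replace=False)
                tau[r] = -1.0
                tau[r, home] = 1.5
        else:
            for r in range(nk):
                home = rng.integers(config.n_tissues)
                tau[r] = -2.0
                tau[r, home] = 3.0
        noise = rng.normal(0.0, config.tissue_noise_sd, size=(nk, config.n_tissues))
        log2e[mask] = base[:, None] + tau + noise
    expr = pd.DataFrame(2.0 ** log2e, index=truth.index, columns=tissues)
    return expr


# ---------------------------------------------------------------------------
# epigenetic marks


def _window_intervals(gene: GeneRecord, grid: WindowGrid) -> tuple[np.ndarray, np.ndarray]:
    """Chromosome-coordinate (start, end) of each oriented window, in window order."""
    w = np.arange(grid.n_windows)
    if gene.strand == "+":
        starts = gene.tss - grid.flank + w * grid.window
    else:
        starts = gene.tss + grid.flank - (w + 1) * grid.window
    return starts, starts + grid.window


def gen_marks(
    genes: list[GeneRecord],
    truth: pd.DataFrame,
    expression: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Synthetic mark tracks (bedGraph frames) and per-CpG methylation table.

    The repressive (H3K27me3-like) track scales with a within-archetype
    repression rank — TSS-confined for archetype 1, a broad plateau for
    archetype 2, absent (decoupled from expression) for archetype 3. The
    active (H3K4me3-like) track and the nucleosome-depletion (MNase-like) dip
    scale with expression rank in every archetype. Methylation beta values
    sit at realized CpG positions and drop near active TSSs.
    """
    rng = rng or _streams(config)["marks"]
    grid = config.grid
    nw = grid.n_windows
    w = np.arange(nw, dtype=float)
    center = nw / 2
    confined = np.exp(-((w - center) ** 2) / (2 * 5.0**2))
    plateau = ((w >= nw * 0.25) & (w < nw * 0.75)).astype(float)
    active_tpl = np.exp(-((w - center) ** 2) / (2 * 4.0**2))
    dip_tpl = np.exp(-((w - center) ** 2) / (2 * 3.0**2))
    meth_tpl = np.exp(-((w - center) ** 2) / (2 * 10.0**2))

    expr_mean = expression.mean(axis=1)
    arch = truth["archetype"]
    act_rank = pd.Series(index=truth.index, dtype=float)
    for k in (1, 2, 3):
        sub = expr_mean[arch == k]
        if len(sub):
            act_rank[sub.index] = sub.rank(method="average") / len(sub)
    rep_rank = 1.0 - act_rank

    track_rows: dict[str, list[pd.DataFrame]] = {"h3k27me3": [], "h3k4me3": [], "mnase": []}
    meth_rows = []
    for gene in genes:
        k = int(arch[gene.gene_id])
        r, a = rep_rank[gene.gene_id], act_rank[gene.gene_id]
        k27_tpl = confined if k == 1 else plateau if k == 2 else np.zeros(nw)
        signals = {
            "h3k27me3": np.maximum(
                config.k27_amp[k - 1] * r * k27_tpl + rng.normal(0, config.mark_noise_sd, nw), 0.0),
            "h3k4me3": np.maximum(3.0 * a * active_tpl + rng.normal(0, config.mark_noise_sd, nw), 0.0),
            "mnase": np.maximum(1.0 - 0.8 * a * dip_tpl + rng.normal(0, config.mark_noise_sd, nw), 0.0),
        }
        starts, ends = _window_intervals(gene, grid)
        for name, sig in signals.items():
            track_rows[name].append(pd.DataFrame(
                {"chrom": gene.chrom, "start": starts, "end": ends,
                 "value": np.round(sig, 4)}))
        # methylation sites at window centres, beta anticorrelated with activity
        beta = np.clip(0.9 - 0.7 * a * meth_tpl + rng.normal(0, config.meth_noise_sd, nw), 0.0, 1.0)
        site_pos = (starts + ends) // 2
        meth_rows.append(pd.DataFrame({"chrom": gene.chrom, "pos": site_pos,
                                       "beta": np.round(beta, 4)}))
    tracks = {name: pd.concat(parts, ignore_index=True).sort_values(["chrom", "start"],
              kind="mergesort", ignore_index=True) for name, parts in track_rows.items()}
    methylation = pd.concat(meth_rows, ignore_index=True).sort_values(
        ["chrom", "pos"], kind="mergesort", ignore_index=True)
    return tracks, methylation


# ---------------------------------------------------------------------------
# Hi-C


def gen_contact_matrix(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[ContactMatrix, dict]:
    """Planted-TAD, planted-compartment contact matrix plus truth.

    ``C_ij = base_ij * (1 + gamma * v_i * v_j) * lognormal noise`` where
    ``base`` is the within/between-TAD block intensity and v the planted
    compartment vector (+1 A-like blocks, −1 B-like). Truth carries the
    boundary positions, v, and the per-bin CpG orientation track.
    """
    rng = rng or _streams(config)["hic"]
    n = config.hic_n_bins
    bounds = sorted(config.tad_boundaries)
    if config.hic_within <= config.hic_between or config.hic_between <= 0:
        raise ValueError("require within > between > 0")
    tad_of = np.zeros(n, dtype=int)
    for b in bounds:
        tad_of[b:] += 1
    base = np.where(tad_of[:, None] == tad_of[None, :], config.hic_within, config.hic_between)

    n_blocks = int(np.ceil(n / config.comp_block))
    signs = rng.choice([-1.0, 1.0], size=n_blocks)
    if np.all(signs == signs[0]):
        signs[-1] = -signs[0]
    v = np.repeat(signs, config.comp_block)[:n]
    m = base * (1.0 + config.comp_strength * np.outer(v, v))
    if config.hic_noise_sd > 0:
        noise = rng.lognormal(0.0, config.hic_noise_sd, size=(n, n))
        noise = np.sqrt(noise * noise.T)  # symmetric multiplicative noise
        m = m * noise
    m = (m + m.T) / 2.0
    bins = pd.DataFrame({"chrom": "chrH", "start": np.arange(n) * config.hic_bin_size,
                         "end": (np.arange(n) + 1) * config.hic_bin_size})
    cm = ContactMatrix("chrH", config.hic_bin_size, m, bins)
    orientation = 2.0 + v + rng.normal(0.0, 0.1, size=n)
    truth = {"boundaries": bounds, "compartments": v, "orientation": orientation}
    return cm, truth


# ---------------------------------------------------------------------------
# DE table


def gen_de_table(
    truth: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Synthetic DE statistics: broader fold-change draws for flat-promoter genes.

    log2 fold changes are N(0, lfc_sd[k]) per archetype; p-values are two-sided
    normal tails of |lfc|/p_scale with multiplicative jitter, so large fold
    changes are significant and the planted archetype 3 has the highest DE
    proportion.
    """
    from scipy.stats import norm

    rng = rng or _streams(config)["de"]
    arch = truth["archetype"].to_numpy()
    sd = np.array(config.lfc_sd)[arch - 1]
    lfc = rng.normal(0.0, sd)
    p = 2.0 * norm.sf(np.abs(lfc) / config.de_p_scale)
    p = np.clip(p * rng.uniform(0.5, 1.5, size=len(p)), 1e-300, 1.0)
    return pd.DataFrame({"log2fc": lfc, "pvalue": p}, index=truth.index)


# ---------------------------------------------------------------------------
# orchestration


def _write_fasta(genome: dict[str, str], path: Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _write_bedgraph(track: pd.DataFrame, path: Path) -> None:
    track.to_csv(path, sep="\t", header=False, index=False)


def simulate_all(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write every synthetic input; returns the file map."""
    out = Path(out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    rngs = _streams(config)

    genome, genes, truth = gen_sequences(config, rngs["sequence"])
    expression = gen_expression(truth, config, rngs["expression"])
    tracks, methylation = gen_marks(genes, truth, expression, config, rngs["marks"])
    cm, hic_truth = gen_contact_matrix(config, rngs["hic"])
    de_table = gen_de_table(truth, config, rngs["de"])

    paths: dict[str, Path] = {}
    paths["fasta"] = out / "genome.fa"
    _write_fasta(genome, paths["fasta"])
    paths["tss_bed"] = out / "tss.bed"
    with open(paths["tss_bed"], "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.tss}\t{g.tss + 1}\t{g.gene_id}\t0\t{g.strand}\n")
    paths["truth"] = out / "truth" / "genes.tsv"
    truth.to_csv(paths["truth"], sep="\t")
    paths["expression"] = out / "expression.tsv"
    expression.to_csv(paths["expression"], sep="\t")
    for name, track in tracks.items():
        paths[name] = out / f"{name}.bedgraph"
        _write_bedgraph(track, paths[name])
    paths["methylation"] = out / "methylation.tsv"
    methylation.to_csv(paths["methylation"], sep="\t", index=False)
    paths["hic_coo"] = out / "hic_coo.tsv"
    iu = np.triu_indices(cm.n_bins)
    pd.DataFrame({"i": iu[0], "j": iu[1], "value": cm.matrix[iu]}).to_csv(
        paths["hic_coo"], sep="\t", header=False, index=False)
    paths["hic_bins"] = out / "hic_bins.bed"
    cm.bins.to_csv(paths["hic_bins"], sep="\t", header=False, index=False)
    paths["hic_truth"] = out / "truth" / "hic.tsv"
    pd.DataFrame({"bin": np.arange(cm.n_bins),
                  "compartment": hic_truth["compartments"],
                  "orientation": hic_truth["orientation"],
                  "boundary": np.isin(np.arange(cm.n_bins), hic_truth["boundaries"]).astype(int)}
                 ).to_csv(paths["hic_truth"], sep="\t", index=False)
    paths["de_table"] = out / "de_table.tsv"
    de_table.to_csv(paths["de_table"], sep="\t")
    paths["config"] = out / "config.yaml"
    config.to_yaml(paths["config"])
    return paths
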