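"""End-to-end orchestration: simulate → featurize → train → score → cluster → correlate.

``run_pipeline`` exercises every stage of the analysis on a synthetic study
and returns the quantities a real run would report: held-out AUC, CG
likelihoods, cluster assignment and its agreement with the planted
archetypes, and the window-wise correlation profiles of expression against
CpG density and against the repressive mark.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .classifier import ProfileGRUClassifier, evaluate_auc
from .clustering import LikelihoodMixture, assign_clusters, logit_transform
from .expression import windowed_spearman
from .genome import dinucleotide_density_matrix, read_tss_bed, signal_window_matrix
from .simulate import SimulationConfig, gen_expression, gen_marks, gen_sequences, simulate_all

__all__ = ["split_labels", "run_pipeline"]


def split_labels(
    truth: pd.DataFrame, train_per_class: int | None, seed: int
) -> tuple[pd.Series, pd.Index]:
    """Semi-supervised label vector and held-out labelled gene index.

    Per class, ``train_per_class`` genes (default: 75% of the class) keep
    their label; every other gene — the held-out labelled genes and the
    genuinely unlabeled ones — gets −1 and enters training only through the
    consistency term.
    """
    rng = np.random.default_rng(seed)
    y = pd.Series(-1, index=truth.index, dtype=int)
    held_out = []
    for cls in (0, 1):
        ids = truth.index[truth["label"] == cls]
        n_train = train_per_class if train_per_class is not None else int(round(0.75 * len(ids)))
        if n_train >= len(ids):
            raise ValueError(f"train_per_class={n_train} leaves no held-out genes for class {cls}")
        perm = rng.permutation(len(ids))
        y[ids[perm[:n_train]]] = cls
        held_out.append(ids[perm[n_train:]])
    return y, held_out[0].append(held_out[1])


def run_pipeline(
    config: SimulationConfig,
    out_dir: str | Path | None = None,
    train_per_class: int | None = None,
    with_marks: bool = True,
    classifier_params: dict[str, Any] | None = None,
) -> dict[str, Any]:
    """Run the full analysis on one synthetic study.

    When ``out_dir`` is given, all synthetic inputs are written to disk and
    the FASTA/BED are read back for featurization, exercising the file
    interfaces; otherwise everything stays in memory.
    """
    if out_dir is not None:
        paths = simulate_all(config, out_dir)
        import pyfaidx

        genome = pyfaidx.Fasta(str(paths["fasta"]))
        genes = read_tss_bed(paths["tss_bed"])
        truth = pd.read_csv(paths["truth"], sep="\t", index_col=0)
        expression = pd.read_csv(paths["expression"], sep="\t", index_col=0)
        k27_track: Any = paths["h3k27me3"]
    else:
        genome, genes, truth = gen_sequences(config)
        expression = gen_expression(truth, config)
        if with_marks:
            tracks, _ = gen_marks(genes, truth, expression, config)
            k27_track = tracks["h3k27me3"]

    grid = config.grid
    density = dinucleotide_density_matrix(genome, genes, grid, "CG")

    y, held_out = split_labels(truth, train_per_class, config.seed)
    params = {"random_state": config.seed}
    params.update(classifier_params or {})
    clf = ProfileGRUClassifier(**params).fit(density, y)
    likelihood = pd.Series(clf.score_cg_likelihood(density), index=density.index,
                           name="cg_likelihood")
    auc = evaluate_auc(likelihood[held_out].to_numpy(),
                       truth.loc[held_out, "label"].to_numpy())

    log_odds = logit_transform(likelihood)
    mixture = LikelihoodMixture(n_components=3, random_state=config.seed).fit(log_odds)
    assignment = assign_clusters(log_odds, mixture)
    ari = adjusted_rand_score(truth["archetype"], assignment["cluster"])

    expr_mean = expression.mean(axis=1)
    rho_cpg = {}
    rho_k27 = {}
    nw = grid.n_windows
    central = slice(nw // 2 - 6, nw // 2 + 7)
    for k in (1, 2, 3):
        ids = truth.index[truth["archetype"] == k]
        rho_cpg[k] = windowed_spearman(density.loc[ids], expr_mean[ids])
        if with_marks:
            k27 = signal_window_matrix(k27_track, [g for g in genes if g.gene_id in set(ids)], grid)
            rho_k27[k] = windowed_spearman(k27, expr_mean[ids])

    results: dict[str, Any] = {
        "density": density, "truth": truth, "likelihood": likelihood,
        "classifier": clf, "mixture": mixture, "assignment": assignment,
        "auc": auc, "ari": ari,
        "central_rho_cpg": {k: float(np.nanmean(rho_cpg[k]["rho"].to_numpy()[central]))
                            for k in rho_cpg},
        "rho_cpg": rho_cpg,
    }
    if with_marks:
        results["rho_k27"] = rho_k27
        results["mean_abs_rho_k27"] = {
            k: float(np.nanmean(np.abs(rho_k27[k]["rho"]))) for k in rho_k27
        }
    return results
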