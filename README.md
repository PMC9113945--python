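# cpgprofiler

Classify genes by the CpG dinucleotide distribution around their
transcription start site (TSS), and relate the resulting classes to
expression, chromatin marks, and 3-D genome structure.

Promoters fall into recognizable CpG archetypes: housekeeping-like genes
carry a sharp, high CpG peak at the TSS; many tissue-specific genes have
flat, CpG-poor promoters; a third group sits in between with broad,
moderate CpG enrichment. `cpgprofiler` turns each gene into a 400-window
CpG density vector, scores it with a semi-supervised recurrent classifier,
clusters the scores into three groups, and provides the downstream
statistics used to characterize those groups: tissue specificity,
window-wise expression correlation profiles, Hi-C insulation and
compartment metrics, and a differential-expression partition. A
self-contained synthetic data generator with planted ground truth makes the
whole chain testable end to end without any external downloads.

## What is in the box

| Module | Contents |
| --- | --- |
| `cpgprofiler.genome` | TSS-anchored, strand-oriented featurization: 16-kb window, 40-bp bins → genes × 400 dinucleotide count matrices; bedGraph/methylation window matrices; peak geometry helpers |
| `cpgprofiler.classifier` | `ProfileGRUClassifier` — bidirectional GRU over the 400-window profile, trained semi-supervised with a consistency (UDA-style) loss; outputs a per-gene **CG likelihood** |
| `cpgprofiler.clustering` | `LikelihoodMixture` — ordered 1-D Gaussian mixture over (log-odds of) CG likelihoods; cluster composition tables |
| `cpgprofiler.expression` | Tissue specificity `s_it = (eps_it − mu_i)/mu_i`; window-wise Spearman correlation engine |
| `cpgprofiler.hic` | Insulation score `IS = ln(1 + a1/b + a2/b)` (480-kb window), A/B compartment calls, compartment index `CI = ln(C_iA/C_iB)` |
| `cpgprofiler.de` | Strict `|log2FC| > 1, p < 0.05` up/down/stable partition and per-cluster proportions |
| `cpgprofiler.simulate` | Synthetic genome/expression/marks/Hi-C/DE generator with three planted promoter archetypes |
| `cpgprofiler.pipeline` | `run_pipeline` — simulate → featurize → train → score → cluster → correlate |

Estimators follow scikit-learn conventions (`fit`/`predict`/`predict_proba`,
trailing-underscore attributes, `-1` marks unlabeled rows as in sklearn's
semi-supervised API); everything else is plain functions on pandas frames.

## Quickstart (library)

```python
from cpgprofiler import SimulationConfig, run_pipeline

results = run_pipeline(SimulationConfig(seed=0))
print(round(results["auc"], 3), round(results["ari"], 3))
```

On the default synthetic study (600 genes per archetype, seed 0) this
trains on 450 labeled genes per class, scores everything, and reports a
held-out AUC of **0.996** and an archetype-recovery adjusted Rand index of
**0.865**, in about 70 s on one CPU. The returned dict also carries the
density matrix, the fitted classifier and mixture, per-gene likelihoods and
cluster assignments, and per-archetype expression–CpG correlation profiles.

Scoring real data follows the same shape: build a density matrix from a
FASTA + TSS BED, fit `ProfileGRUClassifier` with labels 0 (housekeeping),
1 (tissue-specific), −1 (unlabeled), then cluster the likelihoods:

```python
import pyfaidx
from cpgprofiler import (dinucleotide_density_matrix, read_tss_bed,
                         ProfileGRUClassifier, LikelihoodMixture,
                         logit_transform, assign_clusters)

genes = read_tss_bed("tss.bed")
density = dinucleotide_density_matrix(pyfaidx.Fasta("genome.fa"), genes)
clf = ProfileGRUClassifier().fit(density, y)      # y in {0, 1, -1}
likelihood = clf.score_cg_likelihood(density)
mix = LikelihoodMixture().fit(logit_transform(likelihood))
clusters = assign_clusters(logit_transform(likelihood), mix)
```

## Quickstart (CLI)

Every stage is exposed as a subcommand of the `cpgprofiler` executable:

```bash
cpgprofiler simulate all --seed 0 --out-dir study/
cpgprofiler featurize --fasta study/genome.fa --tss-bed study/tss.bed --out density.tsv
cpgprofiler train --density density.tsv --hk-list hk.txt --ts-list ts.txt --out-dir model/
cpgprofiler score --model model/model.pkl --density density.tsv --out likelihood.tsv
cpgprofiler cluster --likelihood likelihood.tsv --out-dir clusters/
cpgprofiler correlate --matrix density.tsv --response expr_mean.tsv \
    --clusters clusters/clusters.tsv --out rho.tsv
cpgprofiler insulation --matrix study/hic_coo.tsv --bins study/hic_bins.bed --out is.bedgraph
cpgprofiler compartments --matrix study/hic_coo.tsv --bins study/hic_bins.bed \
    --orientation cpg_per_bin.tsv --out compartments.tsv
cpgprofiler de-partition --table study/de_table.tsv --clusters clusters/clusters.tsv \
    --out-dir de/
```

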