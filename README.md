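# setkit

Analysis toolkit for joint single-cell epigenome + transcriptome assays of
asymmetric stem-cell division.

## The problem

Mouse embryonic stem cells dividing next to a localized Wnt3a signal (a
Wnt3a-coated bead) split asymmetrically: the bead-proximal daughter keeps
high Nanog and pluripotency, the distal daughter differentiates, and a
minority of pairs divide symmetrically or with reversed orientation. Assays
that tagment chromatin around a chosen histone mark *and* capture the
transcriptome of the same cell (SET-seq-style protocols) make it possible to
ask how a repressive mark such as H3K27me3 — versus an active mark such as
H3K4me3 — tracks the expression changes of this decision.

`setkit` implements the downstream analysis of such an experiment as a
tested, reusable library plus a CLI, driven by a synthetic-data generator
with known ground truth so every stage is verifiable without any sequencing
download:

- **`genome_io`** — BED/TSV/MatrixMarket readers and writers for gene
  models, peaks, per-cell fragments and count matrices (0-based half-open
  coordinates throughout).
- **`synthetic`** — a generative model of the experiment: paired daughter
  cells with division-mode probabilities, three latent states
  (Proxi/Dista/Mix), negative-binomial expression with cluster markers,
  per-cell fragments whose allocation to gene-linked peaks follows
  `exp(ρ·z)` coupling to expression (ρ < 0: H3K27me3-like anti-coupling;
  ρ = 0: H3K4me3-like decoupling), and a lognormal Nanog-reporter intensity.
- **`demux_qc`** — i5/i7 combinatorial barcode demultiplexing, the
  detected-gene window filter (keep 1,000–5,000 genes), the mapping-ratio
  filter (> 10 %), and nested-subsampling saturation curves.
- **`signal`** — binned coverage normalised by `1e7 / mapped reads`, a
  deterministic Poisson-threshold peak caller (broad/narrow modes standing in
  for MACS2), FRiP, peak-length-normalised per-gene signal scores, and 1 kb
  window replicate correlation.
- **`annotate`** — promoter windows (3 kb downstream to 0.5 kb upstream of
  the TSS), hierarchical peak→gene assignment (within 3 kb of a TSS, else
  nearest within 500 kb), and the promoter-recovery ROC/AUC quality metric.
- **`expression`** — RPKM, log-normalisation, one-vs-rest Wilcoxon marker
  statistics, and the differential-gene filter (p < 0.05, |log2FC| > 2).
- **`clustering`** — PCA → shared-nearest-neighbour graph → seeded Louvain
  clustering with resolution bisection to exactly three communities, cluster
  naming from bead-position composition, and the joint row-Z-scored
  expression/signal gene embedding.
- **`comodule`** — weighted-correlation gene modules (adjacency `|r|^β`),
  module eigengenes and kME, cross-modality eigengene correlation with BH
  adjustment, and per-cell marker-gene signal load.
- **`concordance`** — epigenome-vs-expression cluster projection with a
  chi-square test against the expression-marginal control, daughter-pair
  typing (Proxi–Dista / toMix / withinCluster), and reporter-intensity
  division-mode classification (symmetric iff `|log2(I_p/I_d)| ≤ τ`).

## Worked example

```python
import numpy as np, pandas as pd, warnings
from setkit import (SimulationConfig, simulate_experiment, classify_division,
                    gene_signal_scores, log_normalize, detect_modules,
                    module_correlation, frip)

cfg = SimulationConfig(seed=42, n_pairs=150, n_genes=300,
                       n_marker_genes_per_cluster=30,
                       genome=(("chr1", 3_000_000), ("chr2", 3_000_000)),
                       frag_depth_mean=3000)
ds = simulate_experiment(cfg)
print(f"simulated {ds.n_cells} cells in {cfg.n_pairs} daughter-cell pairs")

meta = ds.cell_meta
prox = meta[meta.position == "proximal"].set_index("pair_id")
dist = meta[meta.position == "distal"].set_index("pair_id")
pairs = pd.DataFrame({"pair_id": prox.index,
                      "proximal_intensity": prox.nanog_intensity,
                      "distal_intensity": dist.loc[prox.index, "nanog_intensity"]})
for mode, pct in classify_division(pairs, tau=0.5).percentages.items():
    print(f"{mode:>10}: {pct:5.1f} %")

mapping = {g: g for g in ds.peak_gene_ids}
for mark in sorted(ds.counts):
    cm = ds.counts[mark]
    print(f"{mark}: FRiP = {frip(ds.fragments[mark], ds.truth_peaks):.3f}")
    scores = gene_signal_scores(ds.fragments[mark], ds.truth_peaks, mapping,
                                cell_ids=cm.cell_ids).scores
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mc = module_correlation(detect_modules(np.log1p(scores)),
                                detect_modules(log_normalize(cm)))
    print(f"{mark}: significantly correlated module pairs = "
          f"{100 * mc.ratio_significant:.1f} %")
```

prints

```
simulated 300 cells in 150 daughter-cell pairs
asymmetric:  64.0 %
 symmetric:  24.7 %
   reverse:  11.3 %
H3K27me3: FRiP = 0.904
H3K27me3: significantly correlated module pairs = 100.0 %
H3K4me3: FRiP = 0.905
H3K4me3: significantly correlated module pairs = 0.0 %
```

The division percentages recover the generator's wild-type rates
(62.2 / 24.5 / 13.3 %) within sampling error at 150 pairs. The module
contrast is the assay's central readout: gene modules built from the
anti-coupled H3K27me3-like signal correlate with the expression modules of
the same cells, while the decoupled H3K4me3-like signal yields none.

The same analysis runs from the shell:

```sh
setkit all --seed 7 --out run/          # simulate + every stage
setkit simulate --seed 7 --out run/     # or stage by stage
setkit signal   --seed 7 --out run/
```

Each stage writes its tables plus a `manifest.json` with parameters, seeds
and SHA-256 hashes of all inputs and outputs; a rerun with the same seed is
hash-identical.

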