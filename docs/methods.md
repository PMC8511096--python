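# Methods

## The experiment being modelled

A joint single-cell assay profiles, in each cell, (a) fragments from
antibody-guided tagmentation around one histone mark and (b) the
transcriptome. Cells are picked as daughter pairs after division next to a
Wnt3a bead, each daughter labelled proximal or distal, and each pair is
processed in one mark cohort (H3K27me3-like or H3K4me3-like). The analysis
asks whether the mark's per-gene signal tracks expression across the three
cell states of the division — Proxi (proximal-enriched), Dista
(distal-enriched) and Mix (symmetric-like).

## Generative model

One simulated experiment (`setkit.synthetic.simulate_experiment`) draws:

1. **Pairs and states.** Each of `n_pairs` pairs gets a division mode from
   `division_probs = (asymmetric, symmetric, reverse)`, default
   (0.622, 0.245, 0.133) — the wild-type rates of the modelled system.
   Asymmetric: proximal daughter → Proxi, distal → Dista. Symmetric: both →
   Mix. Reverse: proximal → Dista, distal → Proxi. Pairs alternate between
   mark cohorts so both daughters share a cohort, as they share a physical
   experiment.
2. **Genome and genes.** `n_genes` single-interval genes (alternating
   strand) laid out evenly on the configured chromosomes; an infeasible
   layout raises. Gene length is the annotated interval — no exon model, so
   RPKM uses interval length (a documented simplification).
3. **Expression.** Counts are negative binomial with per-gene base means
   drawn lognormally around `expr_mean` (default 3.0, lognormal sigma 1.0)
   and variance `μ + μ²/dispersion` (`expr_dispersion` = 2.0, a typical
   single-cell size parameter). Each state has
   `n_marker_genes_per_cluster` marker genes (default 50) whose mean is
   multiplied by `2^marker_log2fc` (default 3.0) in cells of that state.
   With the default 2,000 genes these choices put per-cell detected-gene
   numbers (~1,300–1,450) inside the 1,000–5,000 QC window, as in the real
   assay.
4. **Peaks and fragments.** Every marker gene, and a fraction
   `peak_gene_frac` (default 0.7) of the remaining genes, carries one truth
   peak: a `peak_width_bp` (1,000 bp) window centred on its TSS. Genes
   without peaks exist deliberately — they provide the standard negatives
   without which the promoter-ROC is undefined. Each cell draws
   Poisson(`frag_depth_mean`, default 2,000) fragments of `frag_length_bp`
   (100 bp). A fraction `background_frac` (0.1) lands uniformly on the
   genome; the rest pick a peak-bearing gene with probability
   `∝ exp(ρ_mark · z_g(c))`, where `z_g(c)` is the gene's standardised
   log1p expression in that cell, and land uniformly inside its peak.
   `ρ = −0.8` (H3K27me3-like) makes highly expressed genes fragment-poor;
   `ρ = 0` (H3K4me3-like) decouples signal from expression. Coupling on the
   standardised scale keeps ρ comparable across genes of different depth.
5. **Reporter intensity.** Per cell, lognormal with state-dependent mean
   (Proxi 4.0, Dista 1.0, Mix 2.0 — free parameters; no quantitative
   reporter distributions are available to calibrate against) and
   coefficient of variation `intensity_cv` (default 0.1).
6. **Cell metadata.** i5/i7 barcodes (8-mers), batch labels in plates of 96
   per cohort, and a simulated mapping ratio (Beta(8,4), with a
   `low_quality_frac` = 0.02 tail at Beta(2,30)) since no aligner runs here.
   Batch labels carry no batch effect by default; cross-batch integration is
   out of scope.

Everything is drawn from one `numpy` generator seeded by `config.seed`;
identical configs produce byte-identical emitted files.

### What the generator does *not* emulate

Read-level errors, UMIs (the modelled libraries have none), doublets,
ambient RNA, exon structure, batch effects, chromatin domains broader than
one peak per gene, and mark co-occupancy (each cohort sees one mark). Tests
passing on this generator therefore validate the *analysis logic* — score
definitions, statistics, recovery of planted structure — not robustness to
artefacts absent from the model.

## Analysis pipeline choices

- **Peak caller.** A deterministic surrogate for MACS2: bin counts are
  tested against Poisson(genome-wide mean λ); bins with upper-tail
  p < 1e-5 are merged (broad: gaps ≤ 1,000 bp, min width 500 bp; narrow: no
  gap, min 100 bp); score = mean enrichment over λ. Externally called peaks
  can be imported as BED instead. The Poisson-against-global-λ test ignores
  local background variation — acceptable on simulated data, crude on real
  genomes.
- **Promoter window.** Taken literally as 3,000 bp downstream (into the
  gene body) to 500 bp upstream of the TSS, mirrored on the minus strand;
  an `upstream_heavy` flag swaps the extents for users who prefer the
  common upstream-dominated convention.
- **Peak→gene distance** is measured to the TSS point (0 if the peak spans
  it), with exact ties broken toward the lexicographically smaller gene id.
- **ROC sweep.** Thresholds default to the log-spaced Poisson p grid
  1e-1…1e-10; AUC is the trapezoid over (FPR, TPR) anchored at (0,0) and
  (1,1).
- **Replicate correlation** aggregates both tracks to non-overlapping 1 kb
  windows (a tiling rather than a sliding window, which keeps the Pearson
  estimate well-defined on non-overlapping observations).
- **Marker test.** One-vs-rest Wilcoxon rank-sum on log-normalised
  expression (log1p of counts per 10,000); exact p for small tie-free
  groups, otherwise the tie-corrected normal approximation. log2FC compares
  de-logged cluster means with pseudocount 1. The differential filter
  applies raw p < 0.05 and |log2FC| > 2 literally; a BH-adjusted column is
  reported alongside.
- **Demultiplexing** defaults to zero mismatches; with `max_mismatch = 1`
  a read is assigned only when exactly one whitelist pair is within
  distance on both barcodes.
- **Saturation subsampling is nested** (prefixes of one seeded
  permutation), which guarantees a monotone curve.
- **Clustering.** PCA (20 components, full SVD for determinism) →
  k = 20 nearest neighbours → SNN edge weights by Jaccard of neighbour sets
  (pruned below 1/15) → Louvain with a fixed seed. When three communities
  are requested, the resolution is searched on a 25-point geometric grid in
  [0.05, 5] and refined by bisection; failure raises with advice. Graph
  nodes and edges are inserted in canonical cell-id order, making the
  result equivariant under permutation of the input rows. Epigenome cells
  are clustered the same way on log1p signal scores of the most variable
  genes (variance ranking stands in for a p-value ranking of differential
  signature genes).
- **Cluster naming.** Proxi = highest proximal fraction; Dista = highest
  distal fraction among the rest; Mix = remainder; exact ties break toward
  the smaller cluster index; a composition in which one cluster strictly
  maximises both fractions raises with the composition table.
- **Modules.** Adjacency `|r|^β` with β = 6 (the conventional soft
  threshold); average linkage on 1 − adjacency; **static cut at height
  0.99**. A cut at 0.25 — sometimes quoted because it is the eigengene
  *merging* height in weighted-correlation workflows — cannot form modules
  on this dissimilarity scale: genes correlated at r = 0.9 already sit at
  1 − 0.9⁶ ≈ 0.47. The gene-tree cut belongs near 0.99, and the planted
  two-block recovery test pins this behaviour. Topological-overlap
  smoothing and dynamic tree cutting are intentionally omitted for
  determinism. Eigengene = first principal component of the module's
  standardised rows, sign-fixed so member kME is positive on average.
- **Module correlation.** Pearson between all epigenome × expression
  eigengene pairs over shared cells; p from the correlation t statistic; BH
  across pairs at α = 0.05; summarised by the ratio of significant pairs.
  (The underlying study summarised cross-modality module agreement with an
  unspecified chi-square construction; this correlation t-test + BH ratio
  is the package's explicit, reproducible stand-in.) A modality with no
  modules yields ratio 0 with a warning.
- **Concordance.** For each epigenome cluster, a goodness-of-fit chi-square
  of its distribution over expression clusters against the expression
  marginal ("percentage classified by corresponding expression" control),
  df = k − 1, plus an omnibus sum. Per-cluster tests mirror the per-cluster
  bars such analyses report; both are returned.
- **Pair typing** is exhaustive and exclusive: same cluster →
  withinCluster; exactly one Mix → toMix; otherwise Proxi–Dista. The
  "paired within Mix" share is counted at the cell level (a Mix cell whose
  sibling is also Mix), then re-expressed over all labelled cells; pairs
  with an unlabelled daughter are excluded and counted.
- **Division classification.** Symmetric iff |log2(I_p/I_d)| ≤ τ, default
  τ = 0.5 (a 1.4-fold band; the source analyses never quantify "similar
  amounts", so τ is exposed as a config key and CLI flag). Non-positive
  intensities exclude the pair. Condition comparisons use the Pearson
  chi-square of independence on the 2 × 3 mode table.

## Problem sizes in the test suite

Unit and property tests run the generator at reduced scale (60–150 pairs,
90–300 genes, 2–6 Mb genomes, 100–6,000 fragments per cell), chosen so each
check has adequate statistical power while the whole suite stays
desk-scale. The stochastic acceptance checks use: 233 pairs × 5–20 seeds
for division-mode recovery; 20 seeds of single-mark experiments (150 pairs,
120 genes, 6,000 fragments/cell) for the module-ratio ordering — one mark
per run so all cells feed one cohort, which is what powers module
formation; one 150-pair, 300-gene run for the cluster-concordance contrast;
20 seeds of 100-pair runs for the marker-load contrast. The acceptance
script simulates 233 pairs at full default size for 20 seeds.

## Known limitations

- RPKM uses annotated interval length, not exonic length.
- The Poisson peak caller has no local background model and no fragment
  model; it is adequate for the simulated data and for testing, not a
  replacement for a production caller on real libraries.
- Louvain community count is not strictly monotone in resolution, so the
  bisection to three clusters is heuristic (grid + bisection); on
  structure-free data the three communities it returns are arbitrary noise
  partitions, which is exactly what the uncoupled-mark concordance control
  relies on.
- Cross-batch (CCA-style) integration is not implemented; simulated batches
  are effect-free. A per-batch gene-standardisation fallback would be the
  natural extension point.
- `module_correlation` treats eigengenes as fixed covariates; uncertainty
  from module detection itself is not propagated.
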