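"""Simulated asymmetric-division joint epigenome+transcriptome experiment.

The generator emulates the structure of a Wnt3a-bead asymmetric mESC division
experiment assayed with a paired single-cell epigenome+transcriptome method:

* daughter-cell *pairs* drawn with division-mode probabilities — an
  asymmetric pair puts the bead-proximal daughter in the Proxi state and the
  distal daughter in the Dista state; a symmetric pair puts both daughters in
  the Mix state; a reverse pair swaps Proxi/Dista;
* negative-binomial expression counts with cluster marker genes up-shifted by
  ``marker_log2fc`` in their own cluster;
* per-cell genomic fragments whose allocation across gene-linked peak windows
  is coupled to expression through ``exp(rho * z)``, where ``z`` is the
  gene's standardised log1p expression in that cell — ``rho < 0`` gives
  H3K27me3-like anti-coupling, ``rho = 0`` H3K4me3-like decoupling;
* a lognormal Nanog-reporter intensity per cell with state-dependent mean
  (Proxi high, Dista low, Mix intermediate).

Each pair is assigned to one histone-mark cohort (its two daughters are
processed in the same physical experiment), so the dataset carries one count
matrix and one fragment set per mark. Everything is deterministic under a
fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import (
    CountMatrix,
    FragmentSet,
    GeneModel,
    GeneSet,
    Peak,
    PeakSet,
    write_count_matrix,
    write_fragments,
    write_gene_bed,
    write_peaks_bed,
)

STATES = ("Proxi", "Dista", "Mix")
DIVISION_MODES = ("asymmetric", "symmetric", "reverse")

#: wild-type division-mode rates (asymmetric, symmetric, reverse)
WT_DIVISION_PROBS = (0.622, 0.245, 0.133)


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of the simulated experiment.

    Defaults describe a desk-scale version of the real study: 233 analysed
    daughter-cell pairs at the wild-type division-mode rates, ~2,000 genes so
    that per-cell detected-gene numbers fall inside the 1,000-5,000 QC window,
    an anti-coupled H3K27me3-like mark and an uncoupled H3K4me3-like mark.
    """

    seed: int = 0
    n_pairs: int = 233
    division_probs: tuple[float, float, float] = WT_DIVISION_PROBS
    n_genes: int = 2000
    n_marker_genes_per_cluster: int = 50
    genome: tuple[tuple[str, int], ...] = (("chr1", 10_000_000), ("chr2", 10_000_000))
    expr_mean: float = 3.0
    expr_dispersion: float = 2.0
    expr_mean_sigma: float = 1.0  # lognormal spread of per-gene base means
    marker_log2fc: float = 3.0
    frag_depth_mean: int = 2000
    peak_width_bp: int = 1000
    frag_length_bp: int = 100
    coupling: dict[str, float] = field(
        default_factory=lambda: {"H3K27me3": -0.8, "H3K4me3": 0.0}
    )
    background_frac: float = 0.1
    peak_gene_frac: float = 0.7  # fraction of non-marker genes carrying a peak
    intensity_cv: float = 0.1
    intensity_means: dict[str, float] = field(
        default_factory=lambda: {"Proxi": 4.0, "Dista": 1.0, "Mix": 2.0}
    )
    low_quality_frac: float = 0.02  # cells simulated with poor mapping ratio
    cells_per_batch: int = 96

    def validate(self) -> None:
        if abs(sum(self.division_probs) - 1.0) > 1e-9:
            raise SimulationError("division_probs must sum to 1")
        if any(p < 0 for p in self.division_probs):
            raise SimulationError("division_probs must be non-negative")
        if self.n_genes < 3 * self.n_marker_genes_per_cluster:
            raise SimulationError(
                "n_genes must be >= 3 * n_marker_genes_per_cluster"
            )
        for mark, rho in self.coupling.items():
            if not -1.0 <= rho <= 1.0:
                raise SimulationError(f"coupling rho for {mark} outside [-1, 1]")
        if not 0.0 <= self.background_frac <= 1.0:
            raise SimulationError("background_frac must lie in [0, 1]")
        if not 0.0 <= self.peak_gene_frac <= 1.0:
            raise SimulationError("peak_gene_frac must lie in [0, 1]")
        if self.peak_width_bp <= self.frag_length_bp:
            raise SimulationError("peak_width_bp must exceed frag_length_bp")


@dataclass
class SimulatedDataset:
    """A complete simulated experiment with known truth."""

    config: SimulationConfig
    genes: GeneSet
    truth_peaks: PeakSet  # one TSS-centred window per peak-bearing gene
    peak_gene_ids: list[str]  # genes that carry a truth peak
    marker_genes: dict[str, list[str]]  # state -> marker gene ids
    counts: dict[str, CountMatrix]  # mark -> expression counts of its cohort
    fragments: dict[str, FragmentSet]  # mark -> per-cell fragments
    cell_meta: pd.DataFrame  # cell_id, i5, i7, position, pair_id, mark, batch,
    #                          mapping_ratio
    truth: pd.DataFrame  # cell_id, true_cluster, position, pair_id,
    #                      division_mode, nanog_intensity

    @property
    def n_cells(self) -> int:
        return len(self.cell_meta)


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

def _lay_out_genes(config: SimulationConfig) -> GeneSet:
    """Place single-interval genes evenly along the configured chromosomes.

    Genes alternate strand; each gene is 2 kb (or half the spacing if the
    genome is tight). Raises if the genome cannot hold ``n_genes`` genes with
    room for a TSS-centred peak window.
    """
    total = sum(length for _, length in config.genome)
    spacing = total // config.n_genes
    min_spacing = max(config.peak_width_bp * 2, 2 * config.frag_length_bp + 2)
    if spacing < min_spacing:
        raise SimulationError(
            f"genome of {total} bp cannot hold {config.n_genes} genes "
            f"(need >= {min_spacing} bp per gene)"
        )
    gene_len = min(2000, spacing // 2)
    genes: list[GeneModel] = []
    i = 0
    for chrom, length in config.genome:
        n_here = round(config.n_genes * length / total)
        n_here = min(n_here, config.n_genes - i)
        if i + n_here < config.n_genes and chrom == config.genome[-1][0]:
            n_here = config.n_genes - i
        offset = config.peak_width_bp  # keep peak windows inside the chromosome
        for j in range(n_here):
            start = offset + j * spacing
            end = start + gene_len
            if end + config.peak_width_bp > length:
                raise SimulationError(f"genes overflow chromosome {chrom}")
            strand = "+" if (i % 2 == 0) else "-"
            genes.append(GeneModel(f"g{i:04d}", chrom, start, end, strand))
            i += 1
    return GeneSet(genes)


def _truth_peaks(
    genes: GeneSet, peak_gene_ids: list[str], width: int
) -> PeakSet:
    peaks = []
    for gid in peak_gene_ids:
        g = genes[gid]
        half = width // 2
        peaks.append(
            Peak(g.chrom, g.tss - half, g.tss - half + width, 1.0, "narrow", gid)
        )
    return PeakSet(peaks)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _barcode(idx: int, alphabet: str = "ACGT", length: int = 8) -> str:
    chars = []
    for _ in range(length):
        chars.append(alphabet[idx % 4])
        idx //= 4
    return "".join(reversed(chars))


def _negative_binomial(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB with variance mean + mean^2 / dispersion (size = dispersion)."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate_experiment(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generative model under ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = _lay_out_genes(config)
    gene_ids = genes.gene_ids
    n_genes = len(gene_ids)

    # marker genes: disjoint blocks, one per state
    m = config.n_marker_genes_per_cluster
    marker_idx = rng.choice(n_genes, size=3 * m, replace=False)
    marker_genes = {
        state: sorted(gene_ids[i] for i in marker_idx[k * m : (k + 1) * m])
        for k, state in enumerate(STATES)
    }
    marker_of = np.full(n_genes, -1)
    for k, state in enumerate(STATES):
        for gid in marker_genes[state]:
            marker_of[gene_ids.index(gid)] = k

    # peak-bearing genes: all markers plus a fraction of the rest
    non_marker = np.flatnonzero(marker_of < 0)
    n_extra = int(round(config.peak_gene_frac * len(non_marker)))
    extra = rng.choice(non_marker, size=n_extra, replace=False) if n_extra else []
    peak_idx = np.sort(np.concatenate([marker_idx, np.asarray(extra, dtype=int)]))
    peak_gene_ids = [gene_ids[i] for i in peak_idx]
    truth_peaks = _truth_peaks(genes, peak_gene_ids, config.peak_width_bp)

    # pairs: division mode, states, mark cohort
    modes = rng.choice(3, size=config.n_pairs, p=list(config.division_probs))
    marks = sorted(config.coupling)
    pair_mark = [marks[i % len(marks)] for i in range(config.n_pairs)]

    state_of_pos = {
        0: {"proximal": "Proxi", "distal": "Dista"},  # asymmetric
        1: {"proximal": "Mix", "distal": "Mix"},  # symmetric
        2: {"proximal": "Dista", "distal": "Proxi"},  # reverse
    }

    cells: list[dict] = []
    for p in range(config.n_pairs):
        for pos in ("proximal", "distal"):
            cells.append(
                {
                    "cell_id": f"c{p:04d}_{pos[:4]}",
                    "pair_id": f"p{p:04d}",
                    "position": pos,
                    "true_cluster": state_of_pos[modes[p]][pos],
                    "division_mode": DIVISION_MODES[modes[p]],
                    "mark": pair_mark[p],
                }
            )
    meta = pd.DataFrame(cells)
    meta["i5"] = [_barcode(i) for i in range(len(meta))]
    meta["i7"] = [_barcode(i + 1_000_000) for i in range(len(meta))]
    # batches of cells_per_batch within each mark cohort, mirroring plate runs
    meta["batch"] = ""
    for mark in marks:
        sel = meta.index[meta["mark"] == mark]
        for rank, idx in enumerate(sel):
            meta.loc[idx, "batch"] = f"{mark}_b{rank // config.cells_per_batch:02d}"

    # mapping ratio: mostly good cells, a small low-quality tail
    good = rng.beta(8, 4, size=len(meta))
    bad = rng.beta(2, 30, size=len(meta))
    is_bad = rng.random(len(meta)) < config.low_quality_frac
    meta["mapping_ratio"] = np.where(is_bad, bad, good)

    # Nanog reporter intensity: lognormal, state-dependent mean, CV fixed
    sigma = math.sqrt(math.log(1.0 + config.intensity_cv**2))
    state_mean = meta["true_cluster"].map(config.intensity_means).to_numpy(float)
    mu = np.log(state_mean) - sigma**2 / 2.0
    meta["nanog_intensity"] = rng.lognormal(mu, sigma)

    # expression: per-gene base means, marker up-shift in own cluster
    base_mu = rng.lognormal(
        math.log(config.expr_mean) - config.expr_mean_sigma**2 / 2.0,
        config.expr_mean_sigma,
        size=n_genes,
    )
    state_index = meta["true_cluster"].map({s: k for k, s in enumerate(STATES)})
    counts_by_mark: dict[str, CountMatrix] = {}
    frags_by_mark: dict[str, FragmentSet] = {}
    chrom_names = [c for c, _ in config.genome]
    chrom_lengths = np.array([l for _, l in config.genome], dtype=float)
    chrom_p = chrom_lengths / chrom_lengths.sum()
    peak_starts = np.array([p.start for p in truth_peaks.peaks])
    peak_chrom = np.array([p.chrom for p in truth_peaks.peaks])
    peak_name = [p.name for p in truth_peaks.peaks]
    # truth peaks are sorted by (chrom, start); map gene -> its peak row
    peak_row_of_gene = {name: i for i, name in enumerate(peak_name)}
    peak_rows = np.array([peak_row_of_gene[g] for g in peak_gene_ids])

    for mark in marks:
        cohort = meta[meta["mark"] == mark]
        cohort_cells = cohort["cell_id"].tolist()
        n_c = len(cohort_cells)
        shift = np.zeros((n_genes, n_c))
        cohort_state = state_index[cohort.index].to_numpy()
        for k in range(3):
            gene_mask = marker_of == k
            cell_mask = cohort_state == k
            shift[np.ix_(gene_mask, cell_mask)] = config.marker_log2fc
        mean = base_mu[:, None] * np.power(2.0, shift)
        counts = _negative_binomial(rng, mean, config.expr_dispersion)
        counts_by_mark[mark] = CountMatrix(list(gene_ids), cohort_cells, counts)

        # coupling weights: z-scored log1p expression, per gene across cohort
        logx = np.log1p(counts)
        sd = logx.std(axis=1)
        mu_g = logx.mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd[:, None] > 0, (logx - mu_g[:, None]) / sd[:, None], 0.0)
        rho = config.coupling[mark]
        weights = np.exp(rho * z[peak_idx, :])  # peak-bearing genes only
        weights /= weights.sum(axis=0, keepdims=True)

        frames = []
        flen = config.frag_length_bp
        for ci, cell in enumerate(cohort_cells):
            n_frag = rng.poisson(config.frag_depth_mean)
            n_bg = rng.binomial(n_frag, config.background_frac)
            n_sig = n_frag - n_bg
            # background: uniform on the genome
            bg_chrom_i = rng.choice(len(chrom_names), size=n_bg, p=chrom_p)
            bg_start = (
                rng.random(n_bg) * (chrom_lengths[bg_chrom_i] - flen)
            ).astype(np.int64)
            # signal: pick a peak-bearing gene per fragment, land in its window
            sig_gene = rng.choice(len(peak_rows), size=n_sig, p=weights[:, ci])
            sig_rows = peak_rows[sig_gene]
            offs = rng.integers(0, config.peak_width_bp - flen, size=n_sig)
            sig_start = peak_starts[sig_rows] + offs
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": np.concatenate(
                            [
                                np.array(chrom_names, dtype=object)[bg_chrom_i],
                                peak_chrom[sig_rows],
                            ]
                        ),
                        "start": np.concatenate([bg_start, sig_start]),
                        "end": np.concatenate([bg_start, sig_start]) + flen,
                        "cell_id": cell,
                    }
                )
            )
        frags_by_mark[mark] = FragmentSet(
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=FragmentSet.COLUMNS)
        )

    truth = meta[
        [
            "cell_id",
            "true_cluster",
            "position",
            "pair_id",
            "division_mode",
            "nanog_intensity",
        ]
    ].copy()
    # the reporter intensity is an observable (imaging channel), so it lives
    # in the metadata as well as in the truth table
    cell_meta = meta[
        [
            "cell_id",
            "i5",
            "i7",
            "position",
            "pair_id",
            "mark",
            "batch",
            "mapping_ratio",
            "nanog_intensity",
        ]
    ].copy()

    return SimulatedDataset(
        config=config,
        genes=genes,
        truth_peaks=truth_peaks,
        peak_gene_ids=peak_gene_ids,
        marker_genes=marker_genes,
        counts=counts_by_mark,
        fragments=frags_by_mark,
        cell_meta=cell_meta,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# emission
# ---------------------------------------------------------------------------

def emit_dataset(
    dataset: SimulatedDataset, out_dir: str | Path, overwrite: bool = False
) -> dict[str, Path]:
    """Write the dataset in the standard plain-text formats.

    Produces ``genes.bed``, ``truth_peaks.bed``, per-mark
    ``fragments_<mark>.bed`` and ``counts_<mark>.tsv``, ``cell_meta.tsv`` and
    ``truth.json``. Refuses a non-empty directory unless ``overwrite``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} is not empty (pass overwrite=True)")

    paths: dict[str, Path] = {}
    paths["genes"] = out / "genes.bed"
    write_gene_bed(dataset.genes, paths["genes"])
    paths["truth_peaks"] = out / "truth_peaks.bed"
    write_peaks_bed(dataset.truth_peaks, paths["truth_peaks"])
    for mark in sorted(dataset.counts):
        paths[f"fragments_{mark}"] = out / f"fragments_{mark}.bed"
        write_fragments(dataset.fragments[mark], paths[f"fragments_{mark}"])
        paths[f"counts_{mark}"] = out / f"counts_{mark}.tsv"
        write_count_matrix(dataset.counts[mark], paths[f"counts_{mark}"])
    paths["cell_meta"] = out / "cell_meta.tsv"
    dataset.cell_meta.to_csv(paths["cell_meta"], sep="\t", index=False)

    truth_obj = {
        "n_pairs": dataset.config.n_pairs,
        "division_probs": list(dataset.config.division_probs),
        "coupling": dataset.config.coupling,
        "marker_genes": dataset.marker_genes,
        "peak_gene_ids": dataset.peak_gene_ids,
        "cells": dataset.truth.to_dict(orient="records"),
    }
    paths["truth"] = out / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(truth_obj, fh, indent=1, sort_keys=True)
    return paths
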