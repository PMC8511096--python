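"""Promoter geometry, peak-to-gene assignment and the promoter-ROC metric.

The promoter of a gene spans 3,000 bp downstream (into the gene body) to
500 bp upstream of its TSS — 3,500 bp in total — mirrored on the minus
strand. An ``upstream_heavy`` flag swaps the two extents for users preferring
the common upstream-dominated convention.

Peaks are assigned to genes hierarchically: first to a gene whose TSS lies
within 3 kb of the peak, otherwise to the closest gene within 500 kb,
otherwise left unassigned.

The promoter-ROC classifies promoters as recovered or missed against a
reference peak set while sweeping the peak-calling p-value threshold, and
summarises the sweep by the trapezoid AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import GeneModel, GeneSet, PeakSet
from .signal import CoverageTrack, call_peaks

PROMOTER_DOWNSTREAM_BP = 3000
PROMOTER_UPSTREAM_BP = 500

#: default log-spaced Poisson p-value sweep for the ROC
DEFAULT_ROC_THRESHOLDS = tuple(10.0 ** -k for k in range(1, 11))

UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class PromoterRegion:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    clipped: bool = False


@dataclass
class RocResult:
    thresholds: list[float]
    table: pd.DataFrame  # threshold, TP, FP, FN, TN, TPR, FPR
    auc: float
    n_positives: int
    n_negatives: int


def promoter(
    gene: GeneModel,
    chrom_length: int | None = None,
    downstream_bp: int = PROMOTER_DOWNSTREAM_BP,
    upstream_bp: int = PROMOTER_UPSTREAM_BP,
    upstream_heavy: bool = False,
) -> PromoterRegion:
    """TSS-anchored promoter window (default 3 kb downstream / 0.5 kb upstream).

    ``upstream_heavy`` swaps the extents. The window is clipped at chromosome
    bounds, with the clip recorded in the ``clipped`` flag.
    """
    if upstream_heavy:
        downstream_bp, upstream_bp = upstream_bp, downstream_bp
    t = gene.tss
    if gene.strand == "+":
        start, end = t - upstream_bp, t + downstream_bp
    else:
        # downstream runs toward smaller coordinates on the minus strand
        start, end = t - downstream_bp + 1, t + upstream_bp + 1
    clipped = False
    if start < 0:
        start, clipped = 0, True
    if chrom_length is not None and end > chrom_length:
        end, clipped = chrom_length, True
    return PromoterRegion(gene.gene_id, gene.chrom, start, end, gene.strand, clipped)


def assign_peaks_to_genes(
    peaks: PeakSet,
    genes: GeneSet,
    near_bp: int = 3000,
    far_bp: int = 500_000,
) -> pd.DataFrame:
    """Assign each peak to a gene by TSS distance.

    Distance is from the closest base of the peak to the TSS point (0 when
    the peak spans the TSS). Preference goes to the nearest gene within
    ``near_bp``; failing that, the nearest gene within ``far_bp``; failing
    that, UNASSIGNED. Exact distance ties break to the lexicographically
    smaller gene id. Returns a table (chrom, start, end, peak_name, gene_id,
    distance, rule).
    """
    gene_list = sorted(genes, key=lambda g: g.gene_id)
    by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    for chrom in {g.chrom for g in gene_list}:
        here = [g for g in gene_list if g.chrom == chrom]
        by_chrom[chrom] = (np.array([g.tss for g in here]), [g.gene_id for g in here])
    rows = []
    for p in peaks:
        best_gene, best_dist = None, None
        if p.chrom in by_chrom:
            tss, ids = by_chrom[p.chrom]
            d = np.where(
                (p.start <= tss) & (tss < p.end),
                0,
                np.where(tss < p.start, p.start - tss, tss - (p.end - 1)),
            )
            # genes are sorted by id, so argmin already breaks ties
            # toward the lexicographically smaller gene id
            best = int(np.argmin(d))
            best_gene, best_dist = ids[best], int(d[best])
        if best_dist is None or best_dist > far_bp:
            gene_id, rule, dist = UNASSIGNED, "none", np.nan
        else:
            gene_id = best_gene
            dist = best_dist
            rule = "near" if best_dist <= near_bp else "far"
        rows.append(
            {
                "chrom": p.chrom,
                "start": p.start,
                "end": p.end,
                "peak_name": p.name,
                "gene_id": gene_id,
                "distance": dist,
                "rule": rule,
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "peak_name", "gene_id", "distance", "rule"]
    )


def assignment_to_mapping(table: pd.DataFrame) -> dict[tuple[str, int, int], str]:
    """Convert an assignment table to a peak-key -> gene mapping."""
    return {
        (r.chrom, int(r.start), int(r.end)): r.gene_id
        for r in table.itertuples()
        if r.gene_id != UNASSIGNED
    }


def _recovered(promoters: list[PromoterRegion], peaks: PeakSet) -> np.ndarray:
    if len(peaks) == 0:
        return np.zeros(len(promoters), dtype=bool)
    return peaks.overlaps(
        np.array([pr.chrom for pr in promoters]),
        np.array([pr.start for pr in promoters]),
        np.array([pr.end for pr in promoters]),
    )


def promoter_roc(
    peaks_by_threshold: dict[float, PeakSet] | None,
    reference_peaks: PeakSet,
    genes: GeneSet,
    tracks: dict[str, CoverageTrack] | None = None,
    thresholds: tuple[float, ...] = DEFAULT_ROC_THRESHOLDS,
    mode: str = "narrow",
    chrom_lengths: dict[str, int] | None = None,
) -> RocResult:
    """Promoter-recovery ROC against a reference peak set.

    Standard positives are promoters overlapping >= 1 reference peak;
    standard negatives are the remaining promoters. At each threshold a
    promoter counts as recovered iff it overlaps >= 1 called peak; TP/FP are
    recovered positives/negatives. Either pass pre-called
    ``peaks_by_threshold`` or coverage ``tracks`` to be thresholded here.
    AUC is the trapezoid over (FPR, TPR) sorted by FPR, anchored at (0,0)
    and (1,1).
    """
    if len(reference_peaks) == 0:
        raise ValueError("reference peak set is empty")
    if peaks_by_threshold is None:
        if tracks is None:
            raise ValueError("need either peaks_by_threshold or tracks")
        peaks_by_threshold = {
            t: call_peaks(tracks, mode=mode, p_threshold=t) for t in thresholds
        }

    promoters = [
        promoter(g, chrom_lengths.get(g.chrom) if chrom_lengths else None)
        for g in genes
    ]
    positive = _recovered(promoters, reference_peaks)
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"ROC undefined: {n_pos} standard positives, {n_neg} negatives"
        )

    rows = []
    for t in sorted(peaks_by_threshold, reverse=True):
        rec = _recovered(promoters, peaks_by_threshold[t])
        tp = int((rec & positive).sum())
        fp = int((rec & ~positive).sum())
        rows.append(
            {
                "threshold": t,
                "TP": tp,
                "FP": fp,
                "FN": n_pos - tp,
                "TN": n_neg - fp,
                "TPR": tp / n_pos,
                "FPR": fp / n_neg,
            }
        )
    table = pd.DataFrame(rows)
    fpr = np.concatenate([[0.0], np.sort(table["FPR"].to_numpy()), [1.0]])
    tpr = np.concatenate(
        [[0.0], table.sort_values(["FPR", "TPR"])["TPR"].to_numpy(), [1.0]]
    )
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(sorted(peaks_by_threshold, reverse=True), table, auc, n_pos, n_neg)
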