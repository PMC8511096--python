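"""Coverage, peak calling, FRiP, per-gene signal scores, replicate correlation.

Coverage is binned (default 50 bp) and depth-normalised with the scale factor
``1e7 / mapped_reads``, so a library of exactly ten million mapped fragments
has scale 1. The peak caller is a deterministic Poisson-threshold surrogate
for MACS2: bins whose count clears a Poisson upper-tail test against the
genome-wide mean rate are merged into peaks, with the broad/narrow modes
differing only in merge gap and minimum width. Externally called peaks can be
imported through :func:`setkit.genome_io.read_peaks_bed` instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import FragmentSet, Peak, PeakSet, ValidationError

SCALE_NUMERATOR = 10_000_000  # scaleFactor = 1e7 / mapped reads

#: per-mode peak-caller defaults: (merge_gap_bp, min_width_bp)
PEAK_MODE_DEFAULTS = {"broad": (1000, 500), "narrow": (0, 100)}


@dataclass
class CoverageTrack:
    """Normalised binned coverage of one chromosome."""

    chrom: str
    bin_size_bp: int
    values: np.ndarray  # normalised depth per bin
    scale: float = 1.0  # values = raw bin counts * scale

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValidationError("coverage values must be >= 0")

    @property
    def counts(self) -> np.ndarray:
        return self.values / self.scale

    @property
    def n_bins(self) -> int:
        return len(self.values)


@dataclass
class SignalMatrix:
    """Per-gene, per-cell mark signal, peak-length normalised."""

    scores: pd.DataFrame  # genes x cells
    flagged_cells: list[str]  # cells with zero fragments

    @property
    def gene_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.scores.columns)


def binned_coverage(
    fragments: FragmentSet,
    genome: dict[str, int],
    bin_size: int = 50,
    total_mapped: int | None = None,
) -> dict[str, CoverageTrack]:
    """Binned, depth-normalised coverage per chromosome.

    A fragment contributes once to every bin it overlaps. ``total_mapped``
    defaults to the number of fragments in the set.
    """
    if total_mapped is None:
        total_mapped = len(fragments)
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    scale = SCALE_NUMERATOR / total_mapped

    tracks: dict[str, CoverageTrack] = {}
    df = fragments.df
    for chrom, length in genome.items():
        n_bins = -(-length // bin_size)  # ceil
        counts = np.zeros(n_bins, dtype=np.int64)
        sub = df[df["chrom"] == chrom]
        if len(sub):
            start = sub["start"].to_numpy()
            end = sub["end"].to_numpy()
            first = start // bin_size
            last = (end - 1) // bin_size  # inclusive (half-open fragment end)
            span = int((last - first).max()) + 1
            for off in range(span):
                b = first + off
                sel = b <= last
                np.add.at(counts, np.clip(b[sel], 0, n_bins - 1), 1)
        tracks[chrom] = CoverageTrack(chrom, bin_size, counts * scale, scale)
    return tracks


def call_peaks(
    tracks: dict[str, CoverageTrack],
    mode: str = "narrow",
    p_threshold: float = 1e-5,
    merge_gap_bp: int | None = None,
    min_width_bp: int | None = None,
) -> PeakSet:
    """Poisson-threshold peak calling on binned coverage.

    Bins with Poisson upper-tail p-value below ``p_threshold`` against the
    genome-wide mean bin count are enriched; enriched runs separated by at
    most ``merge_gap_bp`` are merged; peaks shorter than ``min_width_bp`` are
    dropped. Peak score is the mean enrichment ratio over the genome-wide
    rate. Broad mode merges across 1 kb gaps and requires 500 bp; narrow mode
    merges nothing and requires 100 bp.
    """
    if mode not in PEAK_MODE_DEFAULTS:
        raise ValueError(f"mode must be one of {sorted(PEAK_MODE_DEFAULTS)}")
    default_gap, default_min = PEAK_MODE_DEFAULTS[mode]
    merge_gap_bp = default_gap if merge_gap_bp is None else merge_gap_bp
    min_width_bp = default_min if min_width_bp is None else min_width_bp
    if not tracks:
        raise ValueError("no coverage tracks given")

    all_counts = np.concatenate([t.counts for t in tracks.values()])
    lam = all_counts.mean()
    if lam == 0:
        return PeakSet([])

    peaks: list[Peak] = []
    for chrom, track in tracks.items():
        counts = np.round(track.counts).astype(np.int64)
        # upper tail P(X >= k) under Poisson(lam)
        pvals = stats.poisson.sf(counts - 1, lam)
        enriched = pvals < p_threshold
        if not enriched.any():
            continue
        bs = track.bin_size_bp
        idx = np.flatnonzero(enriched)
        # group enriched bins into runs, merging gaps <= merge_gap_bp
        gap_bins = merge_gap_bp // bs
        breaks = np.flatnonzero(np.diff(idx) > gap_bins + 1)
        run_starts = np.concatenate([[0], breaks + 1])
        run_ends = np.concatenate([breaks, [len(idx) - 1]])
        for rs, re in zip(run_starts, run_ends):
            start = int(idx[rs]) * bs
            end = (int(idx[re]) + 1) * bs
            if end - start < min_width_bp:
                continue
            segment = counts[idx[rs] : idx[re] + 1]
            score = float(segment.mean() / lam)
            peaks.append(Peak(chrom, start, end, score, mode))
    return PeakSet(peaks)


def frip(fragments: FragmentSet, peaks: PeakSet) -> float:
    """Fraction of fragments overlapping any peak by >= 1 bp."""
    if len(fragments) == 0:
        warnings.warn("FRiP undefined: zero fragments")
        return float("nan")
    df = fragments.df
    hit = peaks.overlaps(
        df["chrom"].to_numpy(), df["start"].to_numpy(), df["end"].to_numpy()
    )
    return float(hit.mean())


def frip_per_cell(fragments: FragmentSet, peaks: PeakSet) -> pd.Series:
    """FRiP computed per cell barcode."""
    df = fragments.df
    hit = peaks.overlaps(
        df["chrom"].to_numpy(), df["start"].to_numpy(), df["end"].to_numpy()
    )
    return pd.Series(hit).groupby(df["cell_id"].to_numpy()).mean().sort_index()


def gene_signal_scores(
    fragments: FragmentSet,
    peaks: PeakSet,
    assignment: dict | pd.Series,
    cell_ids: list[str] | None = None,
) -> SignalMatrix:
    """Depth- and peak-length-normalised per-gene, per-cell signal.

    ``assignment`` maps a peak key ``(chrom, start, end)`` (or a peak name)
    to a gene id; unassigned peaks are skipped and genes with no assigned
    peak are absent from the result.

    score(g, c) = sum over assigned peaks of (fragments of c in peak)
    * 1e7 / total fragments of c, divided by the summed width of the gene's
    assigned peaks.
    """
    if isinstance(assignment, pd.Series):
        assignment = assignment.to_dict()
    # resolve assignment keys -> peak objects
    gene_peaks: dict[str, list[Peak]] = {}
    for p in peaks:
        key = (p.chrom, p.start, p.end)
        gene = assignment.get(key, assignment.get(p.name))
        if gene is None or gene == "UNASSIGNED":
            continue
        gene_peaks.setdefault(str(gene), []).append(p)
    genes = sorted(gene_peaks)

    df = fragments.df
    if cell_ids is None:
        cell_ids = fragments.cell_ids
    cell_index = {c: i for i, c in enumerate(cell_ids)}
    df = df[df["cell_id"].isin(cell_index)]
    totals = df["cell_id"].map(cell_index).to_numpy(dtype=np.int64)
    per_cell_total = np.bincount(totals, minlength=len(cell_ids)).astype(float)

    flagged = [c for c, t in zip(cell_ids, per_cell_total) if t == 0]
    if flagged:
        warnings.warn(f"{len(flagged)} cells have zero fragments; rows set to 0")

    raw = np.zeros((len(genes), len(cell_ids)))
    # overlap counts per (gene, cell); assigned peaks are disjoint, and a
    # fragment is credited to the single peak it overlaps
    gene_of = {g: i for i, g in enumerate(genes)}
    assigned = sorted(
        ((p, gene_of[g]) for g, ps in gene_peaks.items() for p in ps),
        key=lambda t: (t[0].chrom, t[0].start),
    )
    frag_chrom = df["chrom"].to_numpy()
    frag_start = df["start"].to_numpy()
    frag_end = df["end"].to_numpy()
    for chrom in np.unique(frag_chrom):
        here = [(p, gi) for p, gi in assigned if p.chrom == chrom]
        if not here:
            continue
        pstarts = np.array([p.start for p, _ in here])
        pends = np.array([p.end for p, _ in here])
        pgene = np.array([gi for _, gi in here])
        mask = frag_chrom == chrom
        fs, fe = frag_start[mask], frag_end[mask]
        idx = np.searchsorted(pends, fs, side="right")
        ok = idx < len(pstarts)
        hit = np.zeros(len(fs), dtype=bool)
        hit[ok] = pstarts[idx[ok]] < fe[ok]
        np.add.at(raw, (pgene[idx[hit]], totals[mask][hit]), 1)

    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(per_cell_total > 0, SCALE_NUMERATOR / per_cell_total, 0.0)
    widths = np.array([sum(p.width for p in gene_peaks[g]) for g in genes], float)
    scores = raw * norm[None, :] / widths[:, None]
    return SignalMatrix(
        pd.DataFrame(scores, index=genes, columns=cell_ids), flagged
    )


def window_correlation(
    tracks_a: dict[str, CoverageTrack],
    tracks_b: dict[str, CoverageTrack],
    window_bp: int = 1000,
) -> float:
    """Pearson correlation of two coverage profiles over tiled windows.

    Both track sets are aggregated (summed) to non-overlapping windows of
    ``window_bp`` across the shared chromosomes; returns NaN with a warning
    for constant profiles.
    """
    shared = sorted(set(tracks_a) & set(tracks_b))
    if not shared:
        raise ValueError("no shared chromosomes between tracks")
    xs, ys = [], []
    for chrom in shared:
        ta, tb = tracks_a[chrom], tracks_b[chrom]
        if ta.bin_size_bp != tb.bin_size_bp or ta.n_bins != tb.n_bins:
            raise ValueError(f"{chrom}: track binning differs")
        per = max(1, window_bp // ta.bin_size_bp)
        n_win = ta.n_bins // per
        if n_win == 0:
            continue
        xs.append(ta.values[: n_win * per].reshape(n_win, per).sum(axis=1))
        ys.append(tb.values[: n_win * per].reshape(n_win, per).sum(axis=1))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.std() == 0 or y.std() == 0:
        warnings.warn("window correlation undefined for a constant track")
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def export_bedgraph(tracks: dict[str, CoverageTrack], path) -> None:
    """Write coverage as bedGraph (one line per non-zero bin)."""
    with open(path, "w") as fh:
        for chrom in sorted(tracks):
            t = tracks[chrom]
            nz = np.flatnonzero(t.values)
            for b in nz:
                fh.write(
                    f"{chrom}\t{b * t.bin_size_bp}\t{(b + 1) * t.bin_size_bp}"
                    f"\t{t.values[b]:g}\n"
                )
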