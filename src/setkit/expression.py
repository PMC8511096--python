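"""RPKM normalisation and one-vs-rest marker-gene statistics.

Marker detection follows the Seurat-style recipe: counts are log-normalised
(log1p of counts scaled to 10,000 per cell), each cluster is tested one
versus rest with the Wilcoxon rank-sum test, and the log2 fold change
compares cluster and rest means of the de-logged expression with a
pseudocount of 1. Differential genes pass p < 0.05 and |log2FC| > 2; raw
p-values are thresholded (the selection rule is literal), with a
Benjamini-Hochberg column reported alongside.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import CountMatrix


def rpkm(counts: CountMatrix, gene_lengths_bp: dict[str, int] | pd.Series) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads.

    RPKM(g, c) = counts(g, c) / (length_kb(g) * total(c) / 1e6).
    """
    lengths = pd.Series(gene_lengths_bp).reindex(counts.gene_ids)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()[:3]
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    mat = counts.to_frame().astype(float)
    totals = mat.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()[:3]
        raise ValueError(f"cells with zero total counts (QC them out first): {bad}")
    length_kb = lengths.to_numpy() / 1000.0
    return mat.div(totals / 1e6, axis=1).div(length_kb, axis=0)


def log_normalize(counts: CountMatrix, scale: float = 1e4) -> pd.DataFrame:
    """log1p of counts scaled to ``scale`` per cell."""
    mat = counts.to_frame().astype(float)
    totals = mat.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("cells with zero total counts")
    return np.log1p(mat.div(totals, axis=1) * scale)


def rank_sum_markers(
    expr: pd.DataFrame, labels: pd.Series | dict, min_cells: int = 3
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum marker statistics per (gene, cluster).

    ``expr`` is a log-normalised genes x cells matrix; ``labels`` maps cell to
    cluster. Returns a table with columns gene_id, cluster, log2fc, p_value,
    p_adj (BH across the whole table), pct_expressing_in, pct_expressing_out.
    Small tie-free group pairs are tested exactly; larger ones use the normal
    approximation with tie correction. Clusters with fewer than ``min_cells``
    cells are excluded with a warning.
    """
    labels = pd.Series(labels).reindex(expr.columns)
    if labels.isna().any():
        raise ValueError("every cell must have a cluster label")
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters for marker testing")

    usable = []
    for cl in clusters:
        if (labels == cl).sum() < min_cells:
            warnings.warn(f"cluster {cl!r} has < {min_cells} cells; excluded")
        else:
            usable.append(cl)
    if len(usable) < 2:
        raise ValueError("fewer than 2 clusters with enough cells")

    values = expr.to_numpy()
    linear = np.expm1(values)  # back to normalised-count scale
    rows = []
    for cl in usable:
        in_mask = (labels == cl).to_numpy()
        out_mask = ~in_mask & labels.isin(usable).to_numpy()
        x = values[:, in_mask]
        y = values[:, out_mask]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant rows yield p = 1
            res = stats.mannwhitneyu(x, y, axis=1, alternative="two-sided", method="auto")
        pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        mean_in = linear[:, in_mask].mean(axis=1)
        mean_out = linear[:, out_mask].mean(axis=1)
        log2fc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": expr.index,
                    "cluster": cl,
                    "log2fc": log2fc,
                    "p_value": np.clip(pvals, np.nextafter(0, 1), 1.0),
                    "pct_expressing_in": (x > 0).mean(axis=1),
                    "pct_expressing_out": (y > 0).mean(axis=1),
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    table["p_adj"] = stats.false_discovery_control(table["p_value"], method="bh")
    return table


def select_features(
    markers: pd.DataFrame, p_max: float = 0.05, min_abs_log2fc: float = 2.0
) -> list[str]:
    """Differential genes: p < p_max and |log2FC| > min_abs_log2fc in >= 1 cluster."""
    hit = markers[
        (markers["p_value"] < p_max) & (markers["log2fc"].abs() > min_abs_log2fc)
    ]
    return sorted(hit["gene_id"].unique())


def top_markers(
    markers: pd.DataFrame,
    n: int,
    p_max: float = 0.05,
    min_abs_log2fc: float = 2.0,
) -> dict[str, list[str]]:
    """Per cluster, the ``n`` qualifying genes with largest log2FC.

    Ties break by gene id; clusters with fewer than ``n`` qualifying genes
    return all of them with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out: dict[str, list[str]] = {}
    qual = markers[
        (markers["p_value"] < p_max) & (markers["log2fc"].abs() > min_abs_log2fc)
    ]
    for cl, sub in qual.groupby("cluster"):
        ordered = sub.sort_values(
            ["log2fc", "gene_id"], ascending=[False, True]
        )["gene_id"].tolist()
        if len(ordered) < n:
            warnings.warn(
                f"cluster {cl!r}: only {len(ordered)} qualifying markers (< {n})"
            )
        out[cl] = ordered[:n]
    return out
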