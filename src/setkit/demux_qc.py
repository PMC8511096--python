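"""Barcode demultiplexing, cell-level quality filters and saturation analysis.

Cells are identified by the combination of an i5 and an i7 barcode. A read is
assigned to a cell iff exactly one whitelist pair lies within the allowed
Hamming distance on *both* barcodes; ambiguous reads stay unassigned.

Quality filters follow the study's rules: expression cells are kept when the
number of detected genes lies in [min_genes, max_genes] (cells with *less
than* 1,000 or *more than* 5,000 detected genes are removed, so the bounds
are inclusive); epigenome cells are kept when their mapping ratio is strictly
greater than 10%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import CountMatrix

UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class BarcodeAssignment:
    read_id: str
    i5: str
    i7: str
    cell_id: str  # whitelist cell id or UNASSIGNED


@dataclass(frozen=True)
class CellQCStats:
    cell_id: str
    n_genes_detected: int = 0
    n_fragments: int = 0
    mapping_ratio: float = 0.0
    passed: bool = False


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    records: Iterable[tuple[str, str, str]],
    whitelist: Mapping[tuple[str, str], str],
    max_mismatch: int = 0,
) -> list[BarcodeAssignment]:
    """Assign reads to cells by their (i5, i7) barcode combination.

    ``records`` are (read_id, observed_i5, observed_i7) tuples. A record is
    assigned iff exactly one whitelist pair is within Hamming distance
    ``max_mismatch`` on both barcodes; ties or no match yield UNASSIGNED.
    """
    pairs = list(whitelist)
    if len(set(pairs)) != len(pairs):
        raise ValueError("whitelist barcode pairs must be unique")
    if pairs:
        len5 = {len(i5) for i5, _ in pairs}
        len7 = {len(i7) for _, i7 in pairs}
        if len(len5) != 1 or len(len7) != 1:
            raise ValueError("whitelist barcodes must all have equal length")
        (n5,) = len5
        (n7,) = len7

    out: list[BarcodeAssignment] = []
    for read_id, i5, i7 in records:
        if pairs and (len(i5) != n5 or len(i7) != n7):
            raise ValueError(
                f"read {read_id}: barcode length differs from whitelist"
            )
        hits = [
            cell
            for (w5, w7), cell in whitelist.items()
            if _hamming(i5, w5) <= max_mismatch and _hamming(i7, w7) <= max_mismatch
        ]
        cell = hits[0] if len(hits) == 1 else UNASSIGNED
        out.append(BarcodeAssignment(read_id, i5, i7, cell))
    return out


def qc_filter_expression(
    matrix: CountMatrix, min_genes: int = 1000, max_genes: int = 5000
) -> tuple[list[str], list[CellQCStats]]:
    """Keep cells whose detected-gene number lies in [min_genes, max_genes]."""
    detected = matrix.detected_per_cell()
    stats = [
        CellQCStats(
            cell_id=c,
            n_genes_detected=int(d),
            passed=bool(min_genes <= d <= max_genes),
        )
        for c, d in detected.items()
    ]
    kept = [s.cell_id for s in stats if s.passed]
    return kept, stats


def qc_filter_epigenome(
    stats: Sequence[CellQCStats] | pd.DataFrame, min_mapping_ratio: float = 0.10
) -> list[str]:
    """Keep cells with mapping ratio strictly greater than the threshold."""
    if isinstance(stats, pd.DataFrame):
        ratios = stats.set_index("cell_id")["mapping_ratio"]
    else:
        ratios = pd.Series({s.cell_id: s.mapping_ratio for s in stats})
    if ((ratios < 0) | (ratios > 1)).any():
        raise ValueError("mapping ratios must lie in [0, 1]")
    return [c for c, r in ratios.items() if r > min_mapping_ratio]


def saturation_curve(
    gene_labels: Sequence[str], depths: Sequence[int], seed: int = 0
) -> pd.DataFrame:
    """Detected-gene saturation under nested random subsampling.

    ``gene_labels`` is the per-read gene assignment of the full library. All
    requested depths are prefixes of a single seeded permutation, so the curve
    is monotone non-decreasing by construction.
    """
    labels = np.asarray(gene_labels, dtype=object)
    total = len(labels)
    for d in depths:
        if d > total:
            raise ValueError(f"depth {d} exceeds total reads {total}")
        if d < 0:
            raise ValueError("depths must be non-negative")
    order = np.random.default_rng(seed).permutation(total)
    rows = []
    for d in depths:
        rows.append({"depth": int(d), "n_genes_detected": len(set(labels[order[:d]]))})
    return pd.DataFrame(rows)


def read_whitelist(path) -> dict[tuple[str, str], str]:
    """Read a barcode whitelist TSV with columns i5, i7, cell_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"i5", "i7", "cell_id"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: whitelist missing columns {sorted(missing)}")
    wl = {(r.i5, r.i7): r.cell_id for r in df.itertuples()}
    if len(wl) != len(df):
        warnings.warn("duplicate (i5, i7) pairs collapsed in whitelist")
    return wl
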