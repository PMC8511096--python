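"""Genomic data model and plain-text readers/writers.

All interval types use 0-based, half-open coordinates (the BED convention);
the TSS of a minus-strand gene is therefore ``end - 1``. Formats handled here
are deliberately simple: BED6 gene tables, 4-column fragment BED files
(chrom, start, end, cell barcode), peak BED files with the enrichment score
in column 5 and the calling mode (broad/narrow) in column 7, and count
matrices as either TSV (header row of cell ids, first column gene ids) or
MatrixMarket triplets with two sidecar id files.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class GenomicParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Parsed content violates an invariant (coordinates, uniqueness, ...)."""


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A single-interval gene with strand and TSS semantics."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        """Transcription start site: ``start`` on +, ``end - 1`` on -."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length_bp(self) -> int:
        return self.end - self.start


class GeneSet:
    """An ordered collection of :class:`GeneModel` with unique ids."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: list[GeneModel] = list(genes)
        self._by_id: dict[str, GeneModel] = {}
        for g in self.genes:
            if g.gene_id in self._by_id:
                raise ValidationError(f"duplicate gene_id {g.gene_id!r}")
            self._by_id[g.gene_id] = g

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [g.chrom for g in self.genes],
                "start": [g.start for g in self.genes],
                "end": [g.end for g in self.genes],
                "gene_id": self.gene_ids,
                "strand": [g.strand for g in self.genes],
                "tss": [g.tss for g in self.genes],
            }
        )


def read_gene_bed(path: str | Path) -> GeneSet:
    """Read a 6-column BED gene table (chrom, start, end, gene_id, score, strand)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise GenomicParseError(
                    f"{path}: line {lineno}: expected 6 BED columns, got {len(fields)}"
                )
            chrom, start_s, end_s, gene_id, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GenomicParseError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            try:
                genes.append(GeneModel(gene_id, chrom, start, end, strand))
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
    return GeneSet(genes)


def write_gene_bed(genes: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Peak:
    """An enriched genomic interval with a score and a calling mode."""

    chrom: str
    start: int
    end: int
    score: float = 0.0
    mode: str = "narrow"
    name: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"peak [{self.start}, {self.end}): start >= end")
        if self.score < 0:
            raise ValidationError("peak score must be >= 0")

    @property
    def width(self) -> int:
        return self.end - self.start


class PeakSet:
    """Peaks kept sorted by (chrom, start); supports fast overlap queries."""

    def __init__(self, peaks: Iterable[Peak]):
        self.peaks: list[Peak] = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in {p.chrom for p in self.peaks}:
            starts = np.array([p.start for p in self.peaks if p.chrom == chrom])
            ends = np.array([p.end for p in self.peaks if p.chrom == chrom])
            self._by_chrom[chrom] = (starts, ends)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def overlaps(self, chrom: np.ndarray, start: np.ndarray, end: np.ndarray) -> np.ndarray:
        """Vectorised >=1 bp overlap test for intervals against this peak set.

        Assumes peaks on each chromosome are non-overlapping (true for called
        or simulated peaks); for a query interval the candidate peak is the
        first one ending after the query start.
        """
        chrom = np.asarray(chrom)
        start = np.asarray(start)
        end = np.asarray(end)
        out = np.zeros(len(start), dtype=bool)
        for c, (pstarts, pends) in self._by_chrom.items():
            mask = chrom == c
            if not mask.any():
                continue
            idx = np.searchsorted(pends, start[mask], side="right")
            valid = idx < len(pstarts)
            hit = np.zeros(mask.sum(), dtype=bool)
            hit[valid] = pstarts[idx[valid]] < end[mask][valid]
            out[mask] = hit
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [p.chrom for p in self.peaks],
                "start": [p.start for p in self.peaks],
                "end": [p.end for p in self.peaks],
                "name": [p.name for p in self.peaks],
                "score": [p.score for p in self.peaks],
                "mode": [p.mode for p in self.peaks],
            }
        )


def read_peaks_bed(path: str | Path) -> PeakSet:
    """Read peaks from BED: score in column 5, mode in column 7 (optional)."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GenomicParseError(f"{path}: line {lineno}: expected >=3 columns")
            chrom, start_s, end_s = fields[:3]
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 else 0.0
            mode = fields[6] if len(fields) > 6 else "narrow"
            try:
                peaks.append(Peak(chrom, int(start_s), int(end_s), score, mode, name))
            except (ValueError, ValidationError) as exc:
                raise GenomicParseError(f"{path}: line {lineno}: {exc}") from exc
    return PeakSet(peaks)


def write_peaks_bed(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:g}\t.\t{p.mode}\n"
            )


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FragmentRecord:
    cell_id: str
    chrom: str
    start: int
    end: int


class FragmentSet:
    """Per-cell genomic fragments, stored columnar for speed.

    Backed by a DataFrame with columns chrom, start, end, cell_id in file
    order; grouping by cell happens on demand.
    """

    COLUMNS = ["chrom", "start", "end", "cell_id"]

    def __init__(self, df: pd.DataFrame):
        df = df.reset_index(drop=True)[self.COLUMNS]
        if len(df):
            if (df["start"] < 0).any():
                raise ValidationError("fragment with negative coordinate")
            if (df["start"] >= df["end"]).any():
                raise ValidationError("fragment with start >= end")
            if (df["cell_id"].astype(str) == "").any():
                raise ValidationError("fragment with empty cell_id")
        self.df = df

    @classmethod
    def from_records(cls, records: Iterable[FragmentRecord]) -> "FragmentSet":
        recs = list(records)
        return cls(
            pd.DataFrame(
                {
                    "chrom": [r.chrom for r in recs],
                    "start": [r.start for r in recs],
                    "end": [r.end for r in recs],
                    "cell_id": [r.cell_id for r in recs],
                },
                columns=cls.COLUMNS,
            )
        )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def cell_ids(self) -> list[str]:
        return sorted(self.df["cell_id"].unique())

    def per_cell_counts(self) -> pd.Series:
        return self.df["cell_id"].value_counts().sort_index()

    def subset_cells(self, cells: Iterable[str]) -> "FragmentSet":
        keep = set(cells)
        return FragmentSet(self.df[self.df["cell_id"].isin(keep)])


def read_fragments(path: str | Path) -> FragmentSet:
    """Read a fragments BED-like file (chrom, start, end, cell_id)."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 1, 2, 3],
            names=FragmentSet.COLUMNS,
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "cell_id": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=FragmentSet.COLUMNS).astype(
            {"start": np.int64, "end": np.int64}
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise GenomicParseError(f"{path}: {exc}") from exc
    return FragmentSet(df)


def write_fragments(frags: FragmentSet, path: str | Path) -> None:
    frags.df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Integer gene x cell count matrix with ordered id lists."""

    gene_ids: list[str]
    cell_ids: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids in count matrix")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids in count matrix")
        if len(self.counts) and (self.counts < 0).any():
            raise ValidationError("negative counts")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.cell_ids)

    def detected_per_cell(self) -> pd.Series:
        """Number of genes with count > 0, per cell."""
        return pd.Series((self.counts > 0).sum(axis=0), index=self.cell_ids)

    def subset_cells(self, cells: list[str]) -> "CountMatrix":
        idx = [self.cell_ids.index(c) for c in cells]
        return CountMatrix(list(self.gene_ids), list(cells), self.counts[:, idx])


def _mtx_sidecars(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(f"{stem}.genes.txt"), Path(f"{stem}.cells.txt")


def read_count_matrix(
    path: str | Path,
    format: Literal["tsv", "mtx"] = "tsv",
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> CountMatrix:
    """Read counts from TSV or a MatrixMarket triplet with id sidecar files.

    The two formats yield identical matrices for identical content. For
    ``mtx``, sidecar files default to ``<stem>.genes.txt`` / ``<stem>.cells.txt``.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return CountMatrix(
            [str(g) for g in df.index],
            [str(c) for c in df.columns],
            df.to_numpy(dtype=np.int64),
        )
    if format == "mtx":
        g_default, c_default = _mtx_sidecars(path)
        genes_path = Path(genes_path) if genes_path else g_default
        cells_path = Path(cells_path) if cells_path else c_default
        mat = scipy.io.mmread(path)
        genes = [ln.strip() for ln in open(genes_path) if ln.strip()]
        cells = [ln.strip() for ln in open(cells_path) if ln.strip()]
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        if dense.shape != (len(genes), len(cells)):
            raise ValidationError(
                f"{path}: matrix is {dense.shape} but sidecars list "
                f"{len(genes)} genes and {len(cells)} cells"
            )
        return CountMatrix(genes, cells, dense.astype(np.int64))
    raise ValueError(f"unknown count matrix format {format!r}")


def write_count_matrix(
    matrix: CountMatrix, path: str | Path, format: Literal["tsv", "mtx"] = "tsv"
) -> None:
    path = Path(path)
    if format == "tsv":
        matrix.to_frame().to_csv(path, sep="\t")
    elif format == "mtx":
        g_path, c_path = _mtx_sidecars(path)
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(matrix.counts))
        g_path.write_text("".join(f"{g}\n" for g in matrix.gene_ids))
        c_path.write_text("".join(f"{c}\n" for c in matrix.cell_ids))
    else:
        raise ValueError(f"unknown count matrix format {format!r}")
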