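"""Gene co-expression/co-signal modules, eigengenes, kME and cross-modality
module correlation.

Module detection is a deterministic weighted-correlation-network surrogate:
the adjacency between two genes is |Pearson r|^beta (soft threshold, default
beta = 6), genes are clustered by average linkage on 1 - adjacency with a
static tree cut (default height 0.99, the conventional gene-dendrogram cut), and clusters below the minimum size
stay unassigned. Each module's eigengene is the first principal component of
its standardised gene rows, with the sign fixed so that member genes
correlate positively with it; kME is the gene-eigengene Pearson correlation.

Cross-modality correlation pairs every epigenome module eigengene with every
expression module eigengene over the shared cells, tests each Pearson r with
the usual t statistic, adjusts across pairs by Benjamini-Hochberg, and
summarises by the ratio of significantly correlated module pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

UNASSIGNED = "UNASSIGNED"


@dataclass
class ModuleSet:
    membership: pd.Series  # gene -> module id ("M1", ...) or UNASSIGNED
    eigengenes: pd.DataFrame  # modules x cells
    kme: pd.DataFrame  # genes x modules

    @property
    def module_ids(self) -> list[str]:
        return list(self.eigengenes.index)

    def genes_of(self, module_id: str) -> list[str]:
        return sorted(self.membership.index[self.membership == module_id])


@dataclass
class ModuleCorrelation:
    r: pd.DataFrame  # epi modules x expr modules
    p: pd.DataFrame
    p_adj: pd.DataFrame
    significant: pd.DataFrame  # boolean, after BH at alpha
    ratio_significant: float
    n_cells: int


def detect_modules(
    matrix: pd.DataFrame,
    beta: float = 6.0,
    min_module_size: int = 10,
    cut_height: float = 0.99,
) -> ModuleSet:
    """Detect co-varying gene modules in a genes x cells matrix."""
    if matrix.shape[1] < 3:
        raise ValueError("need >= 3 cells to detect modules")
    sd = matrix.std(axis=1, ddof=0)
    usable = matrix.loc[sd > 0]
    if len(usable) < len(matrix):
        warnings.warn(
            f"dropping {len(matrix) - len(usable)} constant genes from "
            "module detection"
        )
    if len(usable) < min_module_size:
        warnings.warn("not enough variable genes; no modules detected")
        return ModuleSet(
            membership=pd.Series(UNASSIGNED, index=matrix.index),
            eigengenes=pd.DataFrame(columns=matrix.columns),
            kme=pd.DataFrame(index=matrix.index),
        )

    corr = np.corrcoef(usable.to_numpy())
    adjacency = np.abs(corr) ** beta
    diss = 1.0 - adjacency
    np.fill_diagonal(diss, 0.0)
    diss = (diss + diss.T) / 2.0  # exact symmetry for squareform
    link = hierarchy.linkage(squareform(diss, checks=False), method="average")
    raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")

    membership = pd.Series(UNASSIGNED, index=matrix.index, dtype=object)
    modules: list[list[str]] = []
    for lab in np.unique(raw):
        genes = list(usable.index[raw == lab])
        if len(genes) >= min_module_size:
            modules.append(genes)
    # deterministic module ids: by size desc, then first gene id
    modules.sort(key=lambda gs: (-len(gs), sorted(gs)[0]))
    for mi, genes in enumerate(modules, start=1):
        membership.loc[genes] = f"M{mi}"

    eigengenes = {}
    for mi, genes in enumerate(modules, start=1):
        sub = usable.loc[genes].to_numpy()
        zs = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, keepdims=True)
        # first right-singular vector = PC1 over cells
        _, _, vt = np.linalg.svd(zs, full_matrices=False)
        eig = vt[0]
        mean_kme = np.mean([np.corrcoef(row, eig)[0, 1] for row in zs])
        if mean_kme < 0:
            eig = -eig
        eigengenes[f"M{mi}"] = eig
    eig_df = pd.DataFrame(eigengenes, index=matrix.columns).T

    # kME for every (variable) gene against every eigengene
    uz = usable.to_numpy()
    uz = (uz - uz.mean(axis=1, keepdims=True)) / uz.std(axis=1, keepdims=True)
    ez = eig_df.to_numpy()
    ez = (ez - ez.mean(axis=1, keepdims=True)) / ez.std(axis=1, keepdims=True)
    kme_vals = uz @ ez.T / uz.shape[1]
    kme = pd.DataFrame(kme_vals, index=usable.index, columns=eig_df.index).reindex(
        matrix.index
    )
    return ModuleSet(membership=membership, eigengenes=eig_df, kme=kme)


def _pearson_p(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def module_correlation(
    epi_modules: ModuleSet, expr_modules: ModuleSet, alpha: float = 0.05
) -> ModuleCorrelation:
    """Pearson correlation of all epigenome x expression eigengene pairs.

    Cells are intersected between the two modality eigengene matrices; each
    pair's p-value comes from the correlation t-test and significance is
    called after Benjamini-Hochberg adjustment across all pairs at ``alpha``.
    """
    shared = [c for c in epi_modules.eigengenes.columns
              if c in set(expr_modules.eigengenes.columns)]
    n = len(shared)
    if n <= 3:
        raise ValueError(f"only {n} shared cells; need > 3")
    if len(epi_modules.eigengenes) == 0 or len(expr_modules.eigengenes) == 0:
        warnings.warn("a modality has no modules; ratio_significant = 0")
        empty = pd.DataFrame(
            index=epi_modules.eigengenes.index, columns=expr_modules.eigengenes.index
        )
        return ModuleCorrelation(empty, empty, empty, empty.astype(bool), 0.0, n)
    e = epi_modules.eigengenes[shared]
    x = expr_modules.eigengenes[shared]
    r = pd.DataFrame(
        np.corrcoef(e.to_numpy(), x.to_numpy())[: len(e), len(e):],
        index=e.index,
        columns=x.index,
    )
    p = r.map(lambda v: _pearson_p(v, n))
    flat_adj = stats.false_discovery_control(p.to_numpy().ravel(), method="bh")
    p_adj = pd.DataFrame(
        flat_adj.reshape(p.shape), index=p.index, columns=p.columns
    )
    significant = p_adj < alpha
    ratio = float(significant.to_numpy().mean())
    return ModuleCorrelation(r, p, p_adj, significant, ratio, n)


def signal_load_per_cell(signal: pd.DataFrame, gene_set: list[str]) -> pd.Series:
    """Per-cell summed signal over a gene set (e.g. cluster marker genes)."""
    if not gene_set:
        raise ValueError("gene_set is empty")
    missing = [g for g in gene_set if g not in signal.index]
    if missing:
        raise ValueError(f"genes absent from signal matrix, e.g. {missing[:3]}")
    return signal.loc[list(gene_set)].sum(axis=0)


def load_group_tests(load: pd.Series, labels: pd.Series | dict) -> pd.DataFrame:
    """Two-sided Welch t-tests of per-cell load between every cluster pair."""
    labels = pd.Series(labels).reindex(load.index)
    if labels.isna().any():
        raise ValueError("every cell needs a cluster label")
    groups = sorted(labels.unique())
    rows = []
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            xa = load[labels == a]
            xb = load[labels == b]
            res = stats.ttest_ind(xa, xb, equal_var=False)
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "mean_a": float(xa.mean()),
                    "mean_b": float(xb.mean()),
                    "t": float(res.statistic),
                    "p_value": float(res.pvalue),
                }
            )
    return pd.DataFrame(rows)
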