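"""SNN-graph cell clustering, cluster naming, and the joint gene embedding.

Cells are reduced by PCA, connected through a shared-nearest-neighbour (SNN)
graph whose edge weights are Jaccard similarities of k-neighbour sets, and
partitioned by seeded Louvain modularity optimisation. When exactly three
communities are requested (the Proxi/Dista/Mix setting of the study), the
resolution is searched by bisection. Clusters are then named from the
bead-position composition: the cluster with the highest proximal fraction is
Proxi, the highest distal fraction among the rest is Dista, the remainder is
Mix.

The joint embedding intersects genes detected in both modalities, row-scales
each modality to Z-scores and orders genes by average-linkage hierarchical
clustering of the signal Z-rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

CLUSTER_NAMES = ("Proxi", "Dista", "Mix")


class ClusteringError(RuntimeError):
    pass


@dataclass
class ClusterAssignment:
    labels: pd.Series  # cell_id -> cluster index
    naming: dict[int, str] = field(default_factory=dict)  # index -> name
    composition: pd.DataFrame | None = None  # per-cluster proximal/distal counts

    @property
    def n_clusters(self) -> int:
        return self.labels.nunique()

    def named_labels(self) -> pd.Series:
        if not self.naming:
            raise ValueError("clusters have not been named yet")
        return self.labels.map(self.naming)


def _snn_graph(pcs: np.ndarray, cell_ids: list[str], k: int, prune: float) -> nx.Graph:
    n = len(cell_ids)
    k_eff = min(k, n)
    nn = NearestNeighbors(n_neighbors=k_eff).fit(pcs)
    _, idx = nn.kneighbors(pcs)  # includes self as its own nearest neighbour
    member = np.zeros((n, n), dtype=bool)
    member[np.repeat(np.arange(n), k_eff), idx.ravel()] = True
    inter = member.astype(np.int32) @ member.T.astype(np.int32)
    union = 2 * k_eff - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        jac = inter / union
    # canonical node and edge insertion order, so the result is invariant
    # to the order cells arrive in
    order = np.argsort(np.asarray(cell_ids, dtype=object))
    g = nx.Graph()
    g.add_nodes_from(np.asarray(cell_ids, dtype=object)[order])
    ii, jj = np.where(np.triu(jac, 1) >= prune)
    edges = sorted(
        (tuple(sorted((cell_ids[i], cell_ids[j]))), float(jac[i, j]))
        for i, j in zip(ii, jj)
    )
    g.add_weighted_edges_from((u, v, w) for (u, v), w in edges)
    return g


def _louvain(g: nx.Graph, resolution: float, seed: int) -> list[set]:
    return nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )


def snn_cluster(
    features: pd.DataFrame,
    n_pcs: int = 20,
    k: int = 20,
    resolution: float = 1.0,
    target_k: int | None = None,
    seed: int = 0,
    prune: float = 1.0 / 15.0,
) -> ClusterAssignment:
    """Cluster cells (rows of ``features``) on an SNN graph.

    With ``target_k`` set, the Louvain resolution is searched on a coarse
    grid and refined by bisection within [0.05, 5] until the community count
    equals the target; failure raises :class:`ClusteringError`. Results are
    deterministic under a fixed seed and equivariant under permutation of the
    cell rows (the graph and the community sweep use a canonical cell-id
    order).
    """
    if not np.isfinite(features.to_numpy()).all():
        raise ValueError("features must be finite")
    cell_ids = [str(c) for c in features.index]
    n = len(cell_ids)
    if target_k is not None and n < 2 * k:
        warnings.warn(f"only {n} cells for k={k} neighbours")

    x = features.to_numpy(dtype=float)
    n_comp = min(n_pcs, n - 1, x.shape[1])
    if n_comp >= 1 and x.std(axis=0).sum() > 0:
        pcs = PCA(n_components=n_comp, svd_solver="full").fit_transform(x)
    else:
        pcs = x  # degenerate input: no reduction possible
    g = _snn_graph(pcs, cell_ids, k, prune)

    def communities_at(res: float) -> list[set]:
        return _louvain(g, res, seed)

    if target_k is None:
        comms = communities_at(resolution)
    else:
        lo, hi = 0.05, 5.0
        comms = None
        grid = np.geomspace(lo, hi, 25)
        counts = []
        for r in grid:
            c = communities_at(float(r))
            counts.append(len(c))
            if len(c) == target_k:
                comms = c
                break
        if comms is None:
            # bisect between the closest bracketing resolutions
            below = [g_ for g_, c_ in zip(grid, counts) if c_ < target_k]
            above = [g_ for g_, c_ in zip(grid, counts) if c_ > target_k]
            if not below or not above:
                raise ClusteringError(
                    f"cannot reach {target_k} communities for resolution in "
                    f"[{lo}, {hi}]; adjust k or resolution bounds"
                )
            a, b = max(below), min(above)
            for _ in range(50):
                mid = (a + b) / 2.0
                c = communities_at(float(mid))
                if len(c) == target_k:
                    comms = c
                    break
                if len(c) < target_k:
                    a = mid
                else:
                    b = mid
            if comms is None:
                raise ClusteringError(
                    f"bisection failed to reach {target_k} communities; "
                    "adjust k or resolution bounds"
                )

    # canonical community indices: by size (desc), then smallest member id
    ordered = sorted(comms, key=lambda c: (-len(c), min(c)))
    labels = pd.Series(index=pd.Index(cell_ids, name="cell_id"), dtype=int)
    for ci, comm in enumerate(ordered):
        labels.loc[sorted(comm)] = ci
    return ClusterAssignment(labels=labels)


def name_clusters(
    assignment: ClusterAssignment, positions: pd.Series | dict
) -> ClusterAssignment:
    """Name three clusters Proxi/Dista/Mix from bead-position composition.

    Proxi is the cluster with the highest proximal fraction; Dista the
    highest distal fraction among the remaining two; the last is Mix. Exact
    ties break deterministically toward the smaller cluster index.
    """
    if assignment.n_clusters != 3:
        raise ValueError(
            f"naming requires exactly 3 clusters, got {assignment.n_clusters}"
        )
    positions = pd.Series(positions).reindex(assignment.labels.index)
    if positions.isna().any():
        raise ValueError("every clustered cell needs a proximal/distal position")

    comp = (
        pd.crosstab(assignment.labels, positions)
        .reindex(columns=["proximal", "distal"], fill_value=0)
        .sort_index()
    )
    frac_prox = comp["proximal"] / comp.sum(axis=1)
    frac_dist = comp["distal"] / comp.sum(axis=1)
    proxi = int(frac_prox.idxmax())  # idxmax: first occurrence wins ties
    dista_global = int(frac_dist.idxmax())
    if dista_global == proxi and (frac_dist.drop(proxi) < frac_dist[proxi]).all():
        raise ValueError(
            "degenerate composition: one cluster maximises both proximal and "
            f"distal fractions\n{comp}"
        )
    rest = frac_dist.drop(proxi)
    dista = int(rest.idxmax())
    (mix,) = [i for i in comp.index if i not in (proxi, dista)]
    naming = {proxi: "Proxi", dista: "Dista", int(mix): "Mix"}
    return ClusterAssignment(
        labels=assignment.labels, naming=naming, composition=comp
    )


@dataclass
class JointMatrix:
    """Row-scaled joint view of expression and mark signal over shared genes."""

    expr_z: pd.DataFrame  # genes x samples, row Z-scores
    signal_z: pd.DataFrame  # genes x samples, row Z-scores
    row_order: list[str]  # dendrogram leaf order of the signal Z-rows
    gene_clusters: pd.Series  # 3-way cut of the signal dendrogram
    linkage: np.ndarray

    def to_newick(self) -> str:
        """Dendrogram of the signal rows as a Newick string."""
        tree = hierarchy.to_tree(self.linkage)
        genes = list(self.expr_z.index)

        def rec(node) -> str:
            if node.is_leaf():
                return genes[node.id]
            return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

        return rec(tree) + ";"


def _row_zscore(df: pd.DataFrame) -> pd.DataFrame:
    mu = df.mean(axis=1)
    sd = df.std(axis=1, ddof=0)
    return df.sub(mu, axis=0).div(sd, axis=0)


def joint_zscore(
    expr: pd.DataFrame, signal: pd.DataFrame, n_row_clusters: int = 3
) -> JointMatrix:
    """Merge both modalities over shared detected genes and order rows.

    Genes must be detected (non-constant) in both modalities; constant rows
    are dropped with a warning. Rows are Z-scored per modality; average-
    linkage hierarchical clustering (Euclidean) of the *signal* Z-rows gives
    the row order and the ``n_row_clusters``-way gene grouping.
    """
    shared_cols = [c for c in expr.columns if c in signal.columns]
    if not shared_cols:
        raise ValueError("no shared samples between modalities")
    shared = sorted(set(expr.index) & set(signal.index))
    e = expr.loc[shared, shared_cols]
    s = signal.loc[shared, shared_cols]
    const = (e.std(axis=1, ddof=0) == 0) | (s.std(axis=1, ddof=0) == 0)
    if const.any():
        warnings.warn(f"dropping {int(const.sum())} constant gene rows")
        e, s = e.loc[~const], s.loc[~const]
    if len(e) < 2:
        raise ValueError("fewer than 2 shared non-constant genes")
    ez, sz = _row_zscore(e), _row_zscore(s)
    link = hierarchy.linkage(pdist(sz.to_numpy()), method="average")
    order = [sz.index[i] for i in hierarchy.leaves_list(link)]
    cut = hierarchy.fcluster(link, t=n_row_clusters, criterion="maxclust")
    return JointMatrix(
        expr_z=ez,
        signal_z=sz,
        row_order=order,
        gene_clusters=pd.Series(cut, index=sz.index, name="gene_cluster"),
        linkage=link,
    )
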