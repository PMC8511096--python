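"""Cluster concordance across modalities, daughter-cell pairing statistics and
Nanog-reporter division-mode classification.

Concordance projects the epigenome-derived cell clusters onto the
expression-derived clusters: for each epigenome cluster the observed
distribution over expression clusters is tested (goodness-of-fit chi-square)
against the expression cluster marginal — the "percentage of cells classified
by corresponding gene expression" negative control.

Pairs of daughter cells are typed from their cluster names: Proxi-Dista when
one daughter sits in each lineage cluster, toMix when exactly one daughter is
in Mix, withinCluster when both share a cluster. Division modes come from the
Nanog reporter intensities of the bead-proximal (I_p) and distal (I_d)
daughters: symmetric when |log2(I_p / I_d)| <= tau, otherwise asymmetric
(proximal brighter) or reverse (distal brighter).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DIVISION_MODES = ("asymmetric", "symmetric", "reverse")
PAIR_TYPES = ("Proxi-Dista", "toMix", "withinCluster")


@dataclass
class ConcordanceTable:
    contingency: pd.DataFrame  # epi clusters x expr clusters, counts
    expr_marginal_props: pd.Series
    expected: pd.DataFrame
    enrichment: pd.DataFrame  # observed / expected
    per_cluster_chi2: pd.DataFrame  # epi cluster, statistic, df, p_value
    omnibus_chi2: float
    omnibus_p: float


def project_clusters(
    epi_labels: pd.Series | dict, expr_labels: pd.Series | dict
) -> ConcordanceTable:
    """Contingency of epigenome vs expression clusters with chi-square tests.

    Expected counts for epigenome cluster i are its size times the expression
    cluster marginal proportions; each epigenome cluster gets a
    goodness-of-fit chi-square with df = (#expression clusters - 1), and an
    omnibus statistic sums them.
    """
    epi = pd.Series(epi_labels)
    expr = pd.Series(expr_labels)
    shared = epi.index.intersection(expr.index)
    if len(shared) == 0:
        raise ValueError("no shared cells between the two labelings")
    epi, expr = epi[shared], expr[shared]

    contingency = pd.crosstab(epi, expr)
    contingency.index.name = "epi_cluster"
    contingency.columns.name = "expr_cluster"
    props = expr.value_counts(normalize=True).reindex(contingency.columns)
    sizes = contingency.sum(axis=1)
    expected = pd.DataFrame(
        np.outer(sizes, props), index=contingency.index, columns=contingency.columns
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        enrichment = contingency / expected

    df = len(contingency.columns) - 1
    rows = []
    total_stat = 0.0
    for cl in contingency.index:
        obs = contingency.loc[cl].to_numpy(dtype=float)
        exp = expected.loc[cl].to_numpy()
        stat = float(((obs - exp) ** 2 / exp).sum())
        total_stat += stat
        rows.append(
            {
                "epi_cluster": cl,
                "statistic": stat,
                "df": df,
                "p_value": float(stats.chi2.sf(stat, df)) if df > 0 else 1.0,
            }
        )
    omnibus_df = df * len(contingency.index)
    omnibus_p = float(stats.chi2.sf(total_stat, omnibus_df)) if omnibus_df else 1.0
    return ConcordanceTable(
        contingency=contingency,
        expr_marginal_props=props,
        expected=expected,
        enrichment=enrichment,
        per_cluster_chi2=pd.DataFrame(rows),
        omnibus_chi2=total_stat,
        omnibus_p=omnibus_p,
    )


@dataclass
class PairSummary:
    records: pd.DataFrame  # pair_id, proximal_cell, distal_cell, pair_type
    fractions: pd.Series  # pair type -> fraction of classified pairs
    mix_paired_of_mix_cells: float  # Mix cells whose sibling is also Mix / Mix cells
    mix_paired_of_all_cells: float  # same numerator over all labelled cells
    n_pairs_classified: int
    n_pairs_excluded: int


def pair_types(pairs: pd.DataFrame, named_labels: pd.Series | dict) -> PairSummary:
    """Type daughter-cell pairs from the two daughters' cluster names.

    ``pairs`` needs columns pair_id, proximal_cell, distal_cell. Pairs with an
    unlabelled daughter are excluded and counted. Also reports the fraction
    of Mix-cluster cells whose sibling is in Mix, and that quantity as a
    fraction of all labelled cells.
    """
    labels = pd.Series(named_labels)
    rows = []
    excluded = 0
    for rec in pairs.itertuples():
        lp = labels.get(rec.proximal_cell)
        ld = labels.get(rec.distal_cell)
        if lp is None or ld is None or pd.isna(lp) or pd.isna(ld):
            excluded += 1
            continue
        both = {lp, ld}
        if lp == ld:
            ptype = "withinCluster"
        elif "Mix" in both:
            ptype = "toMix"
        elif both == {"Proxi", "Dista"}:
            ptype = "Proxi-Dista"
        else:  # two distinct non-Mix clusters other than the canonical pair
            ptype = "Proxi-Dista"
        rows.append(
            {
                "pair_id": rec.pair_id,
                "proximal_cell": rec.proximal_cell,
                "distal_cell": rec.distal_cell,
                "proximal_cluster": lp,
                "distal_cluster": ld,
                "pair_type": ptype,
            }
        )
    records = pd.DataFrame(
        rows,
        columns=[
            "pair_id",
            "proximal_cell",
            "distal_cell",
            "proximal_cluster",
            "distal_cluster",
            "pair_type",
        ],
    )
    if len(records):
        fractions = (
            records["pair_type"].value_counts(normalize=True).reindex(
                PAIR_TYPES, fill_value=0.0
            )
        )
    else:
        fractions = pd.Series(0.0, index=list(PAIR_TYPES))

    n_mix_cells = int((labels == "Mix").sum())
    within_mix = records[
        (records["pair_type"] == "withinCluster")
        & (records["proximal_cluster"] == "Mix")
    ]
    mix_paired_cells = 2 * len(within_mix)
    of_mix = mix_paired_cells / n_mix_cells if n_mix_cells else float("nan")
    n_all = int(labels.notna().sum())
    of_all = mix_paired_cells / n_all if n_all else float("nan")
    return PairSummary(
        records=records,
        fractions=fractions,
        mix_paired_of_mix_cells=of_mix,
        mix_paired_of_all_cells=of_all,
        n_pairs_classified=len(records),
        n_pairs_excluded=excluded,
    )


@dataclass
class DivisionResult:
    modes: pd.Series  # pair_id -> division mode
    percentages: pd.Series  # mode -> percent of classified pairs
    counts: pd.Series
    n_excluded: int


def classify_division(
    pairs: pd.DataFrame, tau: float = 0.5, intensity_cols: tuple[str, str] = (
        "proximal_intensity", "distal_intensity"
    )
) -> DivisionResult:
    """Classify division mode of each pair from reporter intensities.

    symmetric iff |log2(I_p / I_d)| <= tau; otherwise asymmetric when the
    proximal daughter is brighter, reverse when the distal one is. Pairs with
    a non-positive intensity are excluded and counted.
    """
    col_p, col_d = intensity_cols
    ip = pairs[col_p].to_numpy(dtype=float)
    id_ = pairs[col_d].to_numpy(dtype=float)
    ok = (ip > 0) & (id_ > 0)
    n_excluded = int((~ok).sum())
    ratio = np.log2(ip[ok] / id_[ok])
    mode = np.where(
        np.abs(ratio) <= tau,
        "symmetric",
        np.where(ratio > 0, "asymmetric", "reverse"),
    )
    if "pair_id" in pairs.columns:
        idx = pd.Index(pairs.loc[ok, "pair_id"], name="pair_id")
    else:
        idx = pairs.index[ok]
    modes = pd.Series(mode, index=idx)
    counts = modes.value_counts().reindex(DIVISION_MODES, fill_value=0)
    pct = 100.0 * counts / counts.sum() if counts.sum() else counts.astype(float)
    return DivisionResult(modes=modes, percentages=pct, counts=counts,
                          n_excluded=n_excluded)


def division_mode_test(
    counts_a: pd.Series | dict, counts_b: pd.Series | dict
) -> tuple[float, int, float]:
    """Pearson chi-square of independence between two division-mode tallies.

    Returns (statistic, df, p). Both conditions must have a positive total;
    cells under 5 trigger a small-count warning.
    """
    a = pd.Series(counts_a).reindex(DIVISION_MODES, fill_value=0).astype(float)
    b = pd.Series(counts_b).reindex(DIVISION_MODES, fill_value=0).astype(float)
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("each condition needs a positive total count")
    table = np.vstack([a.to_numpy(), b.to_numpy()])
    keep = table.sum(axis=0) > 0  # drop empty categories to keep df honest
    table = table[:, keep]
    if (table < 5).any():
        warnings.warn("contingency cells below 5; chi-square may be unreliable")
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)
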