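"""Persistent-core-taxon detection and summaries.

A core OTU is one whose sample occurrence (fraction of samples with at
least one read) meets a kingdom-specific threshold in *every* experiment:
>= 0.95 for fungi and oomycetes, >= 0.98 for bacteria (the higher
bacterial cutoff reflects their higher average occurrence).  Core taxa
are summarised by their summed relative abundance within each kingdom per
month, and related taxonomically by UPGMA clustering on Gower distances
over the ranked taxonomy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

from .otu_io import RANKS, OtuTable

logger = logging.getLogger("phyllodyn")

#: occurrence thresholds per kingdom
DEFAULT_THRESHOLDS = {"bacteria": 0.98, "fungi": 0.95, "oomycetes": 0.95}


@dataclass
class OccurrenceTable:
    """Per-OTU, per-experiment fraction of samples with presence."""

    fractions: pd.DataFrame  # taxa x experiments (or single 'all' column)
    kingdom: pd.Series  # per-taxon kingdom label

    @property
    def experiments(self) -> list[str]:
        return list(self.fractions.columns)


@dataclass
class CoreSet:
    """Cross-experiment core OTUs and the thresholds that defined them."""

    otu_ids: tuple[str, ...]
    thresholds: dict
    occurrence: pd.DataFrame  # core taxa x experiments
    kingdom: pd.Series

    def __contains__(self, otu: str) -> bool:
        return otu in set(self.otu_ids)

    def __len__(self) -> int:
        return len(self.otu_ids)


def occurrence(table: OtuTable, by_experiment: bool = True) -> OccurrenceTable:
    """Fraction of samples in which each OTU has >= 1 read, per experiment
    (columns) or over all samples (single column ``all``)."""
    present = table.counts > 0
    if by_experiment:
        frac = present.T.groupby(table.samples["experiment"], observed=True).mean().T
    else:
        frac = present.mean(axis=1).to_frame("all")
    return OccurrenceTable(fractions=frac, kingdom=table.kingdom.copy())


def call_core(
    occ: OccurrenceTable, thresholds: dict | None = None
) -> CoreSet:
    """Core iff occurrence >= the kingdom threshold in every experiment."""
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    for k, v in thresholds.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"threshold for {k!r} must be in [0,1]")
    thr = occ.kingdom.map(thresholds)
    if thr.isna().any():
        missing = sorted(occ.kingdom[thr.isna()].unique())
        raise ValueError(f"no threshold given for kingdom(s): {missing}")
    is_core = (occ.fractions.ge(thr, axis=0)).all(axis=1)
    ids = tuple(occ.fractions.index[is_core])
    return CoreSet(
        otu_ids=ids,
        thresholds=thresholds,
        occurrence=occ.fractions.loc[list(ids)].copy(),
        kingdom=occ.kingdom.loc[list(ids)].copy(),
    )


def core_fraction_by_month(table: OtuTable, core: CoreSet) -> pd.DataFrame:
    """Summed relative abundance of core OTUs within each kingdom, averaged
    over the samples of each month (kingdom x month, fractions in [0,1])."""
    unknown = set(core.otu_ids) - set(table.taxa)
    if unknown:
        raise ValueError(f"core OTUs absent from table: {sorted(unknown)[:5]}")
    months = list(table.month_order)
    rows = {}
    for kingdom, sub in table.split_by_kingdom().items():
        depths = sub.counts.sum(axis=0)
        core_here = [t for t in core.otu_ids if t in set(sub.taxa)]
        core_sum = sub.counts.loc[core_here].sum(axis=0) if core_here else \
            pd.Series(0.0, index=sub.sample_ids)
        frac = core_sum / depths.replace(0, 1)
        rows[kingdom] = frac.groupby(table.samples["month"], observed=False).mean()
    out = pd.DataFrame(rows).T
    return out.reindex(columns=months)


def gower_taxonomy_distance(taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Gower dissimilarity over the categorical rank columns: the fraction
    of ranks at which two OTUs differ.  A missing rank is its own category
    (two missing entries at the same rank match)."""
    ranks = [r for r in RANKS if r in taxonomy.columns]
    if not ranks:
        raise ValueError("taxonomy has no recognised rank columns")
    lab = taxonomy[ranks].fillna("__missing__").astype(str).to_numpy()
    n = lab.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        d[i] = (lab != lab[i]).mean(axis=1)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=taxonomy.index, columns=taxonomy.index)


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    from scipy.cluster.hierarchy import to_tree

    tree = to_tree(Z)

    def rec(node, parent_dist):
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6f}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6f}"

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});" \
        if not tree.is_leaf() else f"({labels[tree.id]}:0.0);"


def taxonomy_dendrogram(
    core: CoreSet, taxonomy: pd.DataFrame
) -> tuple[str, np.ndarray, pd.DataFrame]:
    """UPGMA dendrogram of core OTUs on taxonomic Gower distances.

    Returns (newick string, scipy linkage matrix, distance matrix).
    """
    ids = list(core.otu_ids)
    missing = [t for t in ids if t not in taxonomy.index]
    if missing:
        raise ValueError(f"taxonomy missing for core OTUs: {missing[:5]}")
    if len(ids) < 2:
        raise ValueError("need at least two core OTUs to build a dendrogram")
    dist = gower_taxonomy_distance(taxonomy.loc[ids])
    Z = average(squareform(dist.to_numpy(), checks=False))
    return _linkage_to_newick(Z, ids), Z, dist
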