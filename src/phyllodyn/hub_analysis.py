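"""Hub detection by dual centrality cutoffs.

A *hub* is a node simultaneously in the top 5% of betweenness centrality
(fraction of all shortest paths passing through the node) and of
closeness centrality (inverse average shortest distance to all other
nodes), per month network.  Graphs are treated as unweighted and
sign-blind for shortest paths; closeness uses the Wasserman-Faust
component rescaling so fragmented month networks are handled.  The
product betweenness x closeness summarises monthly connectivity of
individual (e.g. core) taxa.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .core_taxa import CoreSet
from .network_inference import MonthNetwork, NetworkSeries

logger = logging.getLogger("phyllodyn")


@dataclass
class CentralityTable:
    """Per-node centralities and hub/core flags for one month network."""

    month: str
    table: pd.DataFrame  # degree, betweenness, closeness, connectivity, hub, core
    hub_quantile: float | None = None

    @property
    def hubs(self) -> tuple[str, ...]:
        if "hub" not in self.table:
            return ()
        return tuple(self.table.index[self.table["hub"]])


def centralities(net: MonthNetwork, core: CoreSet | None = None) -> CentralityTable:
    """Degree, normalized betweenness, component-rescaled closeness and
    their product for every node of one month network."""
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError(f"network for month {net.month} is empty")
    bet = nx.betweenness_centrality(g, normalized=True)
    clo = nx.closeness_centrality(g, wf_improved=True)
    deg = dict(g.degree())
    df = pd.DataFrame({
        "degree": pd.Series(deg, dtype=int),
        "betweenness": pd.Series(bet, dtype=float),
        "closeness": pd.Series(clo, dtype=float),
    }).sort_index()
    df["connectivity"] = df["betweenness"] * df["closeness"]
    df["core"] = [t in core for t in df.index] if core is not None else False
    return CentralityTable(month=net.month, table=df)


def call_hubs(ct: CentralityTable, q: float = 0.05) -> tuple[str, ...]:
    """Joint top-``q`` cutoff: a node is a hub iff it reaches the top
    ceil(q*n) values of *both* betweenness and closeness (all ties with
    the cutoff value included).  Adds ``hub`` flags to the table."""
    if not 0 < q < 1:
        raise ValueError("q must be in (0,1)")
    df = ct.table
    n = len(df)
    if n < 20:
        logger.warning("call_hubs: only %d nodes; a %d%% cutoff is coarse",
                       n, int(q * 100))
    k = max(1, math.ceil(q * n))
    thr_b = np.sort(df["betweenness"].to_numpy())[::-1][k - 1]
    thr_c = np.sort(df["closeness"].to_numpy())[::-1][k - 1]
    hub = (df["betweenness"] >= thr_b) & (df["closeness"] >= thr_c)
    df["hub"] = hub
    ct.hub_quantile = q
    return tuple(df.index[hub])


def centrality_series(
    series: NetworkSeries, core: CoreSet | None = None, q: float = 0.05
) -> dict:
    """Centrality tables with hub calls for every non-empty month network."""
    out = {}
    for net in series:
        if net.n_nodes == 0:
            logger.warning("centrality_series: skipping empty network %s", net.month)
            continue
        ct = centralities(net, core=core)
        call_hubs(ct, q=q)
        out[net.month] = ct
    return out


def core_connectivity(cts: dict, core: CoreSet) -> pd.DataFrame:
    """Betweenness x closeness product of each core OTU per month; a core
    OTU absent from a month's network scores 0."""
    months = list(cts)
    data = {}
    for m in months:
        tab = cts[m].table
        data[m] = [
            float(tab.loc[t, "connectivity"]) if t in tab.index else 0.0
            for t in core.otu_ids
        ]
    return pd.DataFrame(data, index=list(core.otu_ids), columns=months)


def hub_overlap(hubs_a: dict, hubs_b: dict) -> pd.DataFrame:
    """Per-month overlap between two hub sets (e.g. SparCC vs Spearman):
    |A&B|/|A|, |A&B|/|B| and Jaccard."""
    months = [m for m in hubs_a if m in hubs_b]
    if not months:
        raise ValueError("no shared months between the two hub collections")
    rows = []
    for m in months:
        A, B = set(hubs_a[m]), set(hubs_b[m])
        inter = A & B
        union = A | B
        rows.append(dict(
            month=m, n_a=len(A), n_b=len(B), n_shared=len(inter),
            frac_of_a=len(inter) / len(A) if A else 0.0,
            frac_of_b=len(inter) / len(B) if B else 0.0,
            jaccard=len(inter) / len(union) if union else 0.0,
        ))
    return pd.DataFrame(rows).set_index("month")
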