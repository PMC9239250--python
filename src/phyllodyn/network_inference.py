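"""Month-wise co-abundance network inference.

Two estimators are provided:

* **SparCC** — compositional correlation inference for sparse count
  tables.  Counts carry only relative information, so correlations on raw
  proportions are spurious; SparCC works on log-ratio variances
  ``t_ij = Var[log(x_i/x_j)]`` and, under the assumption that the true
  correlation network is sparse, solves a linear system for latent basis
  variances ``w_i`` from which correlations follow as
  ``rho_ij = (w_i + w_j - t_ij) / (2 sqrt(w_i w_j))``.  Strongly
  correlated pairs violate the sparsity assumption and are iteratively
  excluded from the system; the whole procedure is repeated over
  Dirichlet-resampled fractions and the element-wise median taken.
  Significance comes from a permutation null (pseudo-p-values).

* **Spearman** — rank correlations on log10(x+1)-transformed relative
  abundances with top/bottom quantile edge selection and Fisher-Z
  p-values, Bonferroni-corrected over the selected candidates.

Either path ends in a :class:`MonthNetwork` per month: an undirected
signed graph over OTUs whose edges passed the significance gate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .otu_io import OtuTable, to_relative

logger = logging.getLogger("phyllodyn")

#: floor for estimated basis variances
_OMEGA_MIN = 1e-6


@dataclass
class CorrelationMatrix:
    """Symmetric correlation estimates with significance companion."""

    rho: pd.DataFrame
    method: str  # "sparcc" | "spearman"
    p: pd.DataFrame | None = None
    #: spearman only: candidate pairs that survived quantile selection
    candidates: tuple = ()

    @property
    def taxa(self) -> list[str]:
        return list(self.rho.index)


@dataclass
class MonthNetwork:
    """Significant co-abundance graph for one month."""

    month: str
    graph: nx.Graph
    method: str
    params: dict = field(default_factory=dict)

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class NetworkSeries:
    """Ordered month networks (e.g. Nov -> Mar)."""

    networks: list[MonthNetwork]

    def __iter__(self):
        return iter(self.networks)

    def __len__(self) -> int:
        return len(self.networks)

    def __getitem__(self, i) -> MonthNetwork:
        return self.networks[i]

    @property
    def months(self) -> list[str]:
        return [n.month for n in self.networks]

    def consecutive_pairs(self) -> list[tuple[MonthNetwork, MonthNetwork]]:
        return list(zip(self.networks, self.networks[1:]))


# ---------------------------------------------------------------------------
# SparCC


def _counts_frame(table) -> pd.DataFrame:
    return table.counts if isinstance(table, OtuTable) else table


def _dirichlet_fractions(counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Posterior fractions per sample: Dirichlet(counts + 1)."""
    g = rng.standard_gamma(counts + 1.0)
    return g / g.sum(axis=0, keepdims=True)


def variation_matrix(log_fractions: np.ndarray) -> np.ndarray:
    """Aitchison variation matrix t_ij = Var[log(x_i / x_j)]."""
    c = np.cov(log_fractions)
    v = np.diag(c)
    return v[:, None] + v[None, :] - 2.0 * c


def _one_sparcc_pass(
    t: np.ndarray, exclusion_threshold: float, n_exclusion_rounds: int
) -> np.ndarray:
    """Basis-variance solve + iterative strong-pair exclusion for one
    variation matrix; returns the correlation estimate."""
    D = t.shape[0]
    M = np.ones((D, D)) + np.diag(np.full(D, D - 2.0))
    include = ~np.eye(D, dtype=bool)  # off-diagonal pairs still in the system
    excluded = np.zeros((D, D), dtype=bool)
    rho = np.eye(D)
    for round_no in range(n_exclusion_rounds + 1):
        T = (t * (include | np.eye(D, dtype=bool))).sum(axis=1)
        try:
            omega = np.linalg.solve(M, T)
        except np.linalg.LinAlgError:  # over-excluded system
            omega = np.linalg.lstsq(M, T, rcond=None)[0]
        if (omega <= 0).any():
            logger.warning(
                "sparcc: %d negative basis variance(s) clipped", int((omega <= 0).sum())
            )
            omega = np.clip(omega, _OMEGA_MIN, None)
        denom = 2.0 * np.sqrt(np.outer(omega, omega))
        rho = (omega[:, None] + omega[None, :] - t) / denom
        np.clip(rho, -1.0, 1.0, out=rho)
        np.fill_diagonal(rho, 1.0)
        if round_no == n_exclusion_rounds:
            break
        cand = np.abs(np.where(excluded | np.eye(D, dtype=bool), 0.0, rho))
        i, j = np.unravel_index(int(np.argmax(cand)), cand.shape)
        if cand[i, j] <= exclusion_threshold:
            break
        excluded[i, j] = excluded[j, i] = True
        include[i, j] = include[j, i] = False
        M[i, i] -= 1.0
        M[j, j] -= 1.0
        M[i, j] -= 1.0
        M[j, i] -= 1.0
    return rho


def sparcc_correlations(
    table,
    n_inner: int = 20,
    n_exclusion_rounds: int = 10,
    exclusion_threshold: float = 0.1,
    seed: int | np.random.Generator | None = None,
) -> CorrelationMatrix:
    """SparCC correlation estimates (element-wise median over ``n_inner``
    Dirichlet resamplings of the count table)."""
    counts = _counts_frame(table)
    D, n = counts.shape
    if D < 4:
        raise ValueError("SparCC needs at least 4 taxa")
    if n < 3:
        raise ValueError("SparCC needs at least 3 samples")
    if n < 25:
        logger.warning("sparcc: only %d samples; estimates will be unstable", n)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    X = counts.to_numpy(dtype=float)
    stack = np.empty((n_inner, D, D))
    for it in range(n_inner):
        frac = _dirichlet_fractions(X, rng)
        t = variation_matrix(np.log(frac))
        stack[it] = _one_sparcc_pass(t, exclusion_threshold, n_exclusion_rounds)
    rho = np.median(stack, axis=0)
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=counts.index, columns=counts.index),
        method="sparcc",
    )


def sparcc_pseudo_p(
    table,
    observed: CorrelationMatrix,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
    n_inner: int = 20,
    n_exclusion_rounds: int = 10,
    exclusion_threshold: float = 0.1,
) -> pd.DataFrame:
    """Two-sided permutation pseudo-p-values for SparCC correlations.

    Null tables shuffle each taxon's counts independently across samples,
    destroying all between-taxon association while preserving marginals;
    p = (1 + #{|rho_null| >= |rho_obs|}) / (1 + n_boot), so the smallest
    attainable p is 1/(1+n_boot).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    counts = _counts_frame(table)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    obs = np.abs(observed.rho.to_numpy())
    X = counts.to_numpy()
    D, n = X.shape
    exceed = np.zeros((D, D))
    for _ in range(n_boot):
        perm = np.empty_like(X)
        for i in range(D):
            perm[i] = X[i, rng.permutation(n)]
        null = sparcc_correlations(
            pd.DataFrame(perm, index=counts.index, columns=counts.columns),
            n_inner=n_inner,
            n_exclusion_rounds=n_exclusion_rounds,
            exclusion_threshold=exclusion_threshold,
            seed=rng,
        )
        exceed += np.abs(null.rho.to_numpy()) >= obs
    p = (1.0 + exceed) / (1.0 + n_boot)
    np.fill_diagonal(p, 1.0 / (1.0 + n_boot))
    return pd.DataFrame(p, index=counts.index, columns=counts.index)


# ---------------------------------------------------------------------------
# Spearman / quantile edge selection


def fisher_z_p(rho: float, n: int) -> float:
    """Two-sided normal p-value for a correlation via Fisher's
    z = atanh(rho) * sqrt(n - 3)."""
    if n <= 3:
        raise ValueError("Fisher Z needs n > 3")
    if abs(rho) >= 1.0:
        return 0.0
    z = math.atanh(rho) * math.sqrt(n - 3)
    return 2.0 * float(norm.sf(abs(z)))


def spearman_network(
    table,
    quantile: float = 0.05,
    alpha: float = 0.001,
    bonferroni_scope: str = "candidates",
) -> CorrelationMatrix:
    """Spearman correlations with top/bottom quantile edge selection.

    Accepts an :class:`OtuTable` (closed and log10(x+1)-transformed
    internally) or an already-transformed taxa x samples DataFrame.
    Candidate edges are the top and bottom ``quantile`` fractions of the
    pair correlation distribution (exactly round(q * n_pairs) each, ties
    broken by absolute value then lexical pair id); p-values are
    Fisher-Z, Bonferroni-corrected over the candidates (or over all
    pairs with ``bonferroni_scope="all"``); pairs with adjusted
    p <= alpha keep their p, all other entries are NaN.
    """
    if isinstance(table, OtuTable):
        X = to_relative(table, log10_plus1=True).values
    else:
        X = table
    D, n = X.shape
    if D < 3:
        raise ValueError("need at least 3 taxa")
    ids = list(X.index)
    # Spearman = Pearson on ranks; constant taxa yield NaN rows
    ranks = np.apply_along_axis(rankdata, 1, X.to_numpy())
    with np.errstate(invalid="ignore"):
        sd = ranks.std(axis=1)
        rho_mat = np.corrcoef(ranks)
    rho_mat[sd == 0, :] = np.nan
    rho_mat[:, sd == 0] = np.nan
    np.fill_diagonal(rho_mat, 1.0)
    rho = pd.DataFrame(rho_mat, index=ids, columns=ids)

    pairs = []
    n_constant = 0
    for a_i in range(D):
        for b_i in range(a_i + 1, D):
            r = rho_mat[a_i, b_i]
            if np.isnan(r):
                n_constant += 1
                continue
            pairs.append((ids[a_i], ids[b_i], float(r)))
    if n_constant:
        logger.warning("spearman_network: %d pair(s) skipped (constant taxon)",
                       n_constant)
    k = int(round(quantile * len(pairs)))
    top = sorted(pairs, key=lambda t: (-t[2], -abs(t[2]), t[0], t[1]))[:k]
    bottom = sorted(pairs, key=lambda t: (t[2], -abs(t[2]), t[0], t[1]))[:k]
    candidates = {(a, b): r for a, b, r in top}
    candidates.update({(a, b): r for a, b, r in bottom})

    n_tests = len(candidates) if bonferroni_scope == "candidates" else len(pairs)
    p = pd.DataFrame(np.nan, index=ids, columns=ids)
    kept = []
    for (a, b), r in candidates.items():
        p_adj = min(1.0, fisher_z_p(r, n) * n_tests)
        if p_adj <= alpha:
            p.loc[a, b] = p.loc[b, a] = p_adj
            kept.append((a, b))
    return CorrelationMatrix(rho=rho, method="spearman", p=p,
                             candidates=tuple(sorted(candidates)))


# ---------------------------------------------------------------------------
# graph assembly


def network_from_correlations(
    corr: CorrelationMatrix,
    month: str,
    kingdom: pd.Series | None = None,
    alpha: float = 0.001,
) -> MonthNetwork:
    """Build the significant-edge graph for one month.

    SparCC edges require pseudo-p strictly below ``alpha`` (the p < 0.001
    gate); Spearman edges carry Bonferroni-adjusted p already gated at
    selection time.  Isolated nodes are excluded.
    """
    if corr.p is None:
        raise ValueError("correlation matrix carries no significance values")
    g = nx.Graph()
    ids = corr.taxa
    rho = corr.rho.to_numpy()
    pmat = corr.p.to_numpy()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            pv = pmat[i, j]
            if np.isnan(pv):
                continue
            keep = pv < alpha if corr.method == "sparcc" else pv <= alpha
            if keep:
                g.add_edge(
                    ids[i], ids[j],
                    weight=float(rho[i, j]),
                    p=float(pv),
                    sign=1 if rho[i, j] >= 0 else -1,
                )
    if kingdom is not None:
        nx.set_node_attributes(
            g, {n: str(kingdom.get(n, "unknown")) for n in g.nodes}, "kingdom"
        )
    return MonthNetwork(month=month, graph=g, method=corr.method,
                        params={"alpha": alpha})


def build_month_networks(
    table: OtuTable,
    method: str = "sparcc",
    months: Sequence[str] | None = None,
    seed: int | None = None,
    alpha: float = 0.001,
    n_boot: int = 1000,
    quantile: float = 0.05,
    n_inner: int = 20,
    n_exclusion_rounds: int = 10,
    exclusion_threshold: float = 0.1,
) -> NetworkSeries:
    """One network per month, pooling that month's samples across all
    experiments.  ``table`` should already have passed
    :func:`phyllodyn.otu_io.filter_for_network`."""
    if method not in ("sparcc", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    months = list(months) if months is not None else list(table.month_order)
    rng = np.random.default_rng(seed)
    nets = []
    for m in months:
        sids = table.samples_of_month(m)
        if len(sids) < 10:
            logger.warning("build_month_networks: month %s has only %d samples",
                           m, len(sids))
        sub = table.subset_samples(sids)
        # drop taxa absent from this month (zero rows break the estimators)
        sub = sub.subset_taxa(sub.taxa[sub.counts.sum(axis=1) > 0])
        if method == "sparcc":
            corr = sparcc_correlations(
                sub, n_inner=n_inner, n_exclusion_rounds=n_exclusion_rounds,
                exclusion_threshold=exclusion_threshold, seed=rng,
            )
            corr.p = sparcc_pseudo_p(
                sub, corr, n_boot=n_boot, seed=rng, n_inner=n_inner,
                n_exclusion_rounds=n_exclusion_rounds,
                exclusion_threshold=exclusion_threshold,
            )
        else:
            corr = spearman_network(sub, quantile=quantile, alpha=alpha)
        nets.append(network_from_correlations(
            corr, month=m, kingdom=table.kingdom, alpha=alpha,
        ))
    return NetworkSeries(networks=nets)


def write_edge_list(net: MonthNetwork, path) -> None:
    """Edge-list TSV: otu_a, otu_b, rho, p, sign, month."""
    rows = [
        dict(otu_a=a, otu_b=b, rho=d["weight"], p=d["p"], sign=d["sign"],
             month=net.month)
        for a, b, d in sorted(net.graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["otu_a", "otu_b", "rho", "p", "sign", "month"]) \
        .to_csv(path, sep="\t", index=False)
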