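"""Community-level statistics: alpha diversity, Bray-Curtis beta
diversity, multi-factor PERMANOVA, beta-dispersion, consecutive-month
distances, Dunn post-hoc tests and order-level abundance summaries.

PERMANOVA is the sequential (Type-I) sums-of-squares partition of the
Gower-centred inner-product matrix (McArdle & Anderson), with free
permutation of sample labels; beta-dispersion embeds the dissimilarity
matrix by principal coordinates with the imaginary-axis correction for
negative eigenvalues, as in vegan's ``betadisper``.
"""

from __future__ import annotations

import itertools
import logging
import math
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm, rankdata
from skbio import DistanceMatrix

from .otu_io import RANKS, OtuTable, RelAbundTable, to_relative

logger = logging.getLogger("phyllodyn")


# ---------------------------------------------------------------------------
# alpha diversity


def shannon_index(counts) -> float:
    """Shannon's H on one abundance vector, natural log:
    H = -sum p_i ln p_i over positive proportions."""
    x = np.asarray(counts, dtype=float).ravel()
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero vector")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def shannon_by_sample(table: OtuTable) -> pd.Series:
    """Shannon's H per sample (zero-depth samples yield NaN with warning)."""
    out = {}
    for s in table.sample_ids:
        col = table.counts[s].to_numpy()
        if col.sum() == 0:
            logger.warning("shannon_by_sample: sample %s has zero depth", s)
            out[s] = np.nan
        else:
            out[s] = shannon_index(col)
    return pd.Series(out, name="shannon")


# ---------------------------------------------------------------------------
# beta diversity


def bray_curtis(rel: RelAbundTable | OtuTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between samples,
    BC(x, y) = 1 - 2 sum min(x_i, y_i) / (sum x_i + sum y_i)."""
    if isinstance(rel, OtuTable):
        rel = to_relative(rel)
    X = rel.values.to_numpy().T  # samples x taxa
    if X.shape[0] < 2:
        raise ValueError("need at least two samples")
    d = pdist(X, metric="braycurtis")
    if np.isnan(d).any():
        logger.warning(
            "bray_curtis: %d sample pair(s) with no abundance; distance set to 0",
            int(np.isnan(d).sum()),
        )
        d = np.nan_to_num(d, nan=0.0)
    return DistanceMatrix(squareform(d), ids=list(rel.values.columns))


def _gower_center(dm: DistanceMatrix) -> np.ndarray:
    A = -0.5 * dm.data.astype(float) ** 2
    n = A.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    """Sequential variance partition of a dissimilarity matrix."""

    table: pd.DataFrame  # rows: terms + Residual + Total; cols: df, SS, R2, F, p
    n_permutations: int
    term_order: tuple[str, ...]

    def r2(self, term: str) -> float:
        return float(self.table.loc[term, "R2"])

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "p"])


def _term_design(factors: pd.DataFrame, term: str) -> np.ndarray:
    """Dummy design columns for a main effect or ':'-interaction term."""
    parts = term.split(":")
    combo = factors[parts[0]].astype(str)
    for p in parts[1:]:
        combo = combo + "\x1f" + factors[p].astype(str)
    return pd.get_dummies(combo).to_numpy(dtype=float)


def _hat(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection matrix onto the column space of X and its rank."""
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s.max() * max(X.shape) * np.finfo(float).eps).sum())
    U = U[:, :rank]
    return U @ U.T, rank


def permanova(
    dm: DistanceMatrix,
    factors: pd.DataFrame,
    terms: list[str] | tuple[str, ...],
    n_perm: int = 10_000,
    seed: int | None = None,
    permutations: str = "random",
) -> PermanovaResult:
    """Multi-factor PERMANOVA with sequential (Type-I) sums of squares.

    Parameters
    ----------
    dm
        Sample dissimilarity matrix.
    factors
        Per-sample categorical factors, indexed by sample id.
    terms
        Ordered model terms; interactions as ``"a:b"``.
    permutations
        ``"random"`` (n_perm label permutations) or ``"exact"`` (all n!
        relabelings; only sensible for tiny n).
    """
    ids = list(dm.ids)
    factors = factors.loc[ids]
    n = len(ids)
    G = _gower_center(dm)
    ss_total = float(np.trace(G))

    kept_terms: list[str] = []
    hats: list[np.ndarray] = []
    ranks: list[int] = []
    X = np.ones((n, 1))
    _, rank_prev = _hat(X)
    base_rank = rank_prev
    for term in terms:
        for p in term.split(":"):
            if factors[p].nunique() < 2:
                logger.warning("permanova: factor %r has one level; term %r skipped",
                               p, term)
                break
        else:
            X = np.hstack([X, _term_design(factors, term)])
            H, rank = _hat(X)
            if rank == rank_prev:
                logger.warning("permanova: term %r adds no df; skipped", term)
                continue
            kept_terms.append(term)
            hats.append(H)
            ranks.append(rank)
            rank_prev = rank

    rank_full = ranks[-1] if ranks else base_rank
    df_res = n - rank_full

    def term_stats(Gp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        tr = np.array([float((H * Gp).sum()) for H in hats])
        prev = np.concatenate([[float((np.ones((n, n)) / n * Gp).sum())], tr[:-1]])
        ss = tr - prev
        ss_res = float(np.trace(Gp)) - (tr[-1] if len(tr) else 0.0)
        dfs = np.diff([base_rank] + ranks)
        F = (ss / dfs) / (ss_res / df_res) if df_res > 0 else np.full(len(ss), np.nan)
        return ss, F

    ss_obs, F_obs = term_stats(G)
    ss_res = ss_total - ss_obs.sum()

    if permutations == "exact":
        if n > 8:
            raise ValueError("exact permutations only supported for n <= 8")
        exceed = np.zeros(len(kept_terms))
        count = 0
        for perm in itertools.permutations(range(n)):
            idx = np.array(perm)
            _, F_p = term_stats(G[np.ix_(idx, idx)])
            exceed += F_p >= F_obs - 1e-12
            count += 1
        pvals = exceed / count
        n_used = count
    else:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(kept_terms))
        for _ in range(n_perm):
            idx = rng.permutation(n)
            _, F_p = term_stats(G[np.ix_(idx, idx)])
            # tiny slack so permutations that recreate the observed
            # grouping count as ties despite float rounding
            exceed += F_p >= F_obs - 1e-12
        pvals = (1.0 + exceed) / (1.0 + n_perm)
        n_used = n_perm

    dfs = np.diff([base_rank] + ranks)
    rows = {}
    for i, term in enumerate(kept_terms):
        rows[term] = dict(df=int(dfs[i]), SS=ss_obs[i], R2=ss_obs[i] / ss_total,
                          F=F_obs[i], p=pvals[i])
    rows["Residual"] = dict(df=int(df_res), SS=ss_res, R2=ss_res / ss_total,
                            F=np.nan, p=np.nan)
    rows["Total"] = dict(df=n - 1, SS=ss_total, R2=1.0, F=np.nan, p=np.nan)
    return PermanovaResult(
        table=pd.DataFrame.from_dict(rows, orient="index"),
        n_permutations=n_used,
        term_order=tuple(kept_terms),
    )


# ---------------------------------------------------------------------------
# beta-dispersion


@dataclass
class DispersionResult:
    """Per-sample distance to its group centroid in PCoA space."""

    distances: pd.Series  # indexed by sample id
    groups: pd.Series

    def median_by_group(self) -> pd.Series:
        return self.distances.groupby(self.groups, observed=True).median()


def beta_dispersion(dm: DistanceMatrix, groups) -> DispersionResult:
    """Distance of each sample to its group centroid, computed in the
    principal-coordinate embedding; negative eigenvalues contribute
    imaginary axes whose squared distances are subtracted (floored at 0),
    matching vegan's betadisper."""
    ids = list(dm.ids)
    groups = pd.Series(groups, index=ids) if not isinstance(groups, pd.Series) \
        else groups.loc[ids]
    G = _gower_center(dm)
    w, v = np.linalg.eigh(G)
    tol = np.abs(w).max() * 1e-10 if len(w) else 0.0
    pos, neg = w > tol, w < -tol
    Xp = v[:, pos] * np.sqrt(w[pos])
    Xn = v[:, neg] * np.sqrt(-w[neg])
    d = np.zeros(len(ids))
    for g in pd.unique(groups):
        mask = (groups == g).to_numpy()
        if mask.sum() < 2:
            logger.warning("beta_dispersion: group %r has <2 samples; distance 0", g)
            d[mask] = 0.0
            continue
        cp = Xp[mask].mean(axis=0)
        cn = Xn[mask].mean(axis=0)
        d2 = ((Xp[mask] - cp) ** 2).sum(axis=1) - ((Xn[mask] - cn) ** 2).sum(axis=1)
        d[mask] = np.sqrt(np.clip(d2, 0.0, None))
    return DispersionResult(
        distances=pd.Series(d, index=ids, name="dist_to_centroid"),
        groups=groups,
    )


def between_month_distances(
    dm: DistanceMatrix, months: pd.Series, month_order
) -> dict:
    """All cross-pair Bray-Curtis distances between samples of consecutive
    months: {(m, m_next): array of distances}."""
    ids = list(dm.ids)
    months = months.loc[ids].astype(str)
    data = dm.data
    pos = {s: i for i, s in enumerate(ids)}
    out = {}
    order = list(month_order)
    if len(order) < 2:
        raise ValueError("need at least two months")
    for m1, m2 in zip(order, order[1:]):
        s1 = [pos[s] for s in ids if months[s] == m1]
        s2 = [pos[s] for s in ids if months[s] == m2]
        if not s1 or not s2:
            logger.warning("between_month_distances: no samples for pair (%s, %s)",
                           m1, m2)
            continue
        out[(m1, m2)] = data[np.ix_(s1, s2)].ravel().copy()
    return out


# ---------------------------------------------------------------------------
# Dunn's post-hoc test


@dataclass
class DunnResult:
    """Pairwise Dunn z tests on Kruskal-Wallis ranks with Bonferroni
    correction and a compact letter display."""

    comparisons: pd.DataFrame  # group1, group2, z, p, p_adj, significant
    letters: dict
    mean_ranks: pd.Series
    alpha: float

    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.comparisons[self.comparisons["significant"]]
        return list(zip(sig["group1"], sig["group2"]))


def _letter_display(groups_ordered, sig_pairs) -> dict:
    """Insert-and-absorb compact letter display: groups sharing a letter
    are not significantly different."""
    sets: list[set] = [set(groups_ordered)]
    for a, b in sig_pairs:
        new_sets = []
        for s in sets:
            if a in s and b in s:
                new_sets.extend([s - {a}, s - {b}])
            else:
                new_sets.append(s)
        # absorb subsets
        sets = []
        for s in sorted(new_sets, key=len, reverse=True):
            if s and not any(s <= t for t in sets):
                sets.append(s)
    letters = {g: "" for g in groups_ordered}
    names = itertools.chain(string.ascii_lowercase,
                            ("".join(p) for p in itertools.product(
                                string.ascii_lowercase, repeat=2)))
    for s, letter in zip(
        sorted(sets, key=lambda s: min(groups_ordered.index(g) for g in s)), names
    ):
        for g in s:
            letters[g] += letter
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def dunn_test(values, groups, alpha: float = 0.05) -> DunnResult:
    """Dunn's test: pairwise mean-rank z statistics with tie correction,
    two-sided normal p-values, Bonferroni-adjusted over all pairs."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    for g in labels:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    N = len(values)
    ranks = rankdata(values)
    mean_ranks = pd.Series({g: ranks[groups == g].mean() for g in labels})
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float((tie_counts ** 3 - tie_counts).sum()) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    rows = []
    m = len(labels) * (len(labels) - 1) // 2
    for a, b in itertools.combinations(labels, 2):
        na, nb = (groups == a).sum(), (groups == b).sum()
        se = math.sqrt(var_base * (1.0 / na + 1.0 / nb))
        if se == 0:  # constant data
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = 2.0 * norm.sf(abs(z))
        p_adj = min(1.0, p * m)
        rows.append(dict(group1=a, group2=b, z=z, p=p, p_adj=p_adj,
                         significant=p_adj < alpha))
    comp = pd.DataFrame(rows)
    order = list(mean_ranks.sort_values(ascending=False).index)
    sig = [(r["group1"], r["group2"]) for _, r in comp.iterrows() if r["significant"]]
    letters = _letter_display(order, sig)
    return DunnResult(comparisons=comp, letters=letters,
                      mean_ranks=mean_ranks, alpha=alpha)


# ---------------------------------------------------------------------------
# order-level abundance summaries


def aggregate_by_rank(
    table: OtuTable, rank: str = "order", by: str = "month"
) -> pd.DataFrame:
    """Mean relative abundance of each taxonomic group per month, with
    per-sample closure *within kingdom* (each kingdom's groups sum to 1 in
    each sample before averaging).

    Returns a DataFrame indexed by (kingdom, group), columns = months.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown taxonomy rank {rank!r}")
    if by not in table.samples.columns:
        raise ValueError(f"unknown sample grouping {by!r}")
    months = [m for m in table.month_order] if by == "month" \
        else list(pd.unique(table.samples[by]))
    frames = []
    for kingdom, sub in table.split_by_kingdom().items():
        depths = sub.counts.sum(axis=0).replace(0, 1)
        rel = sub.counts.div(depths, axis=1)
        grouped = rel.groupby(
            sub.taxonomy[rank].fillna("unclassified"), observed=True
        ).sum()
        by_month = grouped.T.groupby(
            table.samples[by], observed=True
        ).mean().T
        by_month = by_month.reindex(columns=months)
        by_month.index = pd.MultiIndex.from_product(
            [[kingdom], by_month.index], names=["kingdom", rank]
        )
        frames.append(by_month)
    return pd.concat(frames)
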