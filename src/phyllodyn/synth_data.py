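"""Synthetic multi-kingdom, multi-experiment monthly OTU tables.

The generator emulates a season-long leaf-microbiome survey: three
independent experiments (years), five ordered months (Nov..Mar), four host
ecotypes with ~3 plant replicates each, and OTUs from three kingdoms
(bacteria / fungi / oomycetes).  Counts follow the log-normal/multinomial
scheme assumed by compositional (SparCC-type) correlation inference:

1. per sample, latent log-basis abundances are drawn from a multivariate
   normal whose correlation encodes the month's planted pair structure;
2. seasonal monotone trends shift the per-month log means;
3. within-month (plant-to-plant) log-scale spread shrinks by
   ``dispersion_decay`` each month, emulating community stabilisation;
4. core-taxon occupancy is imposed as an exact per-experiment inclusion
   mask and non-core taxa receive zero-inflation calibrated to a target
   sparsity;
5. abundances are closed to proportions and read counts drawn from a
   multinomial at the sample's depth.

Everything downstream (filters, diversity, core calling, SparCC networks,
rewiring, hubs) is testable against the returned :class:`SyntheticTruth`.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .otu_io import KINGDOMS, RANKS, OtuTable

logger = logging.getLogger("phyllodyn")

DEFAULT_MONTHS = ("Nov", "Dec", "Jan", "Feb", "Mar")
DEFAULT_ECOTYPES = ("Col-0", "Ws", "Bur-0", "Edi-0")

# small synthetic taxonomies per kingdom: (phylum, class, order, family) pools
_TAX_POOLS = {
    "bacteria": [
        ("Proteobacteria", "Alphaproteobacteria", "Sphingomonadales", "Sphingomonadaceae"),
        ("Proteobacteria", "Alphaproteobacteria", "Rhizobiales", "Methylobacteriaceae"),
        ("Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Oxalobacteraceae"),
        ("Actinobacteria", "Actinomycetia", "Propionibacteriales", "Nocardioidaceae"),
        ("Firmicutes", "Bacilli", "Bacillales", "Bacillaceae"),
        ("Bacteroidetes", "Flavobacteriia", "Flavobacteriales", "Flavobacteriaceae"),
    ],
    "fungi": [
        ("Ascomycota", "Dothideomycetes", "Capnodiales", "Cladosporiaceae"),
        ("Ascomycota", "Leotiomycetes", "Helotiales", "Helotiaceae"),
        ("Basidiomycota", "Tremellomycetes", "Tremellales", "Bulleribasidiaceae"),
        ("Basidiomycota", "Microbotryomycetes", "Sporidiobolales", "Sporidiobolaceae"),
        ("Basidiomycota", "Tremellomycetes", "Cystofilobasidiales", "Mrakiaceae"),
    ],
    "oomycetes": [
        ("Oomycota", "Peronosporea", "Peronosporales", "Peronosporaceae"),
        ("Oomycota", "Peronosporea", "Albuginales", "Albuginaceae"),
        ("Oomycota", "Peronosporea", "Pythiales", "Pythiaceae"),
    ],
}
_GENERA = {
    "bacteria": ("Sphingomonas", "Methylobacterium", "Massilia", "Variovorax",
                 "Marmoricola", "Bacillus", "Flavobacterium", "Pseudomonas"),
    "fungi": ("Cladosporium", "Dioszegia", "Itersonilia", "Sporidiobolus",
              "Udeniomyces", "Articulospora"),
    "oomycetes": ("Hyaloperonospora", "Albugo", "Pythium"),
}


class CorrSpecError(ValueError):
    """Raised when a planted correlation spec cannot yield a usable
    covariance (conflicting or out-of-range pairs)."""


@dataclass(frozen=True)
class CoreSpec:
    """One group of planted persistent taxa.

    occurrence is enforced exactly per experiment: ceil(occurrence * n)
    samples of each experiment contain the taxon.
    """

    kingdom: str
    occurrence: float
    mean_rel_abund: float
    n_taxa: int = 1

    def __post_init__(self) -> None:
        if self.kingdom not in KINGDOMS:
            raise ValueError(f"unknown kingdom {self.kingdom!r}")
        if not 0.0 <= self.occurrence <= 1.0:
            raise ValueError("occurrence must be in [0,1]")
        if not 0.0 < self.mean_rel_abund < 1.0:
            raise ValueError("mean_rel_abund must be in (0,1)")


@dataclass(frozen=True)
class TrendSpec:
    """Monotone seasonal trend for a taxon group.

    ``group`` is a kingdom name or an explicit tuple of taxon ids;
    ``direction`` is +1 (increasing over months) or -1 (decreasing);
    ``strength`` is the total log-mean shift from first to last month.
    """

    group: str | tuple[str, ...]
    direction: int
    strength: float = 1.0


@dataclass
class SimConfig:
    """Full parameterisation of one synthetic survey."""

    n_bacteria: int = 120
    n_fungi: int = 60
    n_oomycetes: int = 20
    n_experiments: int = 3
    months: tuple[str, ...] = DEFAULT_MONTHS
    n_ecotypes: int = 4
    plants_per_cell: int = 3
    depth: int = 10_000
    core_spec: tuple[CoreSpec, ...] = ()
    trend_spec: tuple[TrendSpec, ...] = ()
    #: month label -> list of ((taxon_i, taxon_j), basis correlation)
    corr_spec: dict = field(default_factory=dict)
    dispersion_decay: float = 1.0
    #: target zero-cell fraction; None disables zero-inflation
    sparsity_target: float | None = 0.53
    #: log-scale within-month standard deviation in the first month
    log_sigma: float = 1.2
    #: spread (sd) of per-taxon baseline log means
    baseline_sigma: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if len(set(self.months)) != len(self.months) or not self.months:
            raise ValueError("months must be non-empty and strictly ordered")
        if self.sparsity_target is not None and not 0 <= self.sparsity_target <= 1:
            raise ValueError("sparsity_target must be in [0,1]")
        if self.dispersion_decay <= 0:
            raise ValueError("dispersion_decay must be > 0")
        for month, pairs in self.corr_spec.items():
            if month not in self.months:
                raise ValueError(f"corr_spec month {month!r} not in months")
            for (a, b), rho in pairs:
                if a == b:
                    raise CorrSpecError(f"self-correlation planted for {a!r}")
                if not abs(rho) < 1:
                    raise CorrSpecError(
                        f"correlation magnitude must be < 1 for pair ({a}, {b})"
                    )

    @property
    def n_taxa(self) -> int:
        return self.n_bacteria + self.n_fungi + self.n_oomycetes

    @property
    def n_samples(self) -> int:
        return (self.n_experiments * len(self.months) * self.n_ecotypes
                * self.plants_per_cell)


@dataclass
class SyntheticTruth:
    """Planted ground truth for parameter-recovery tests."""

    core_taxa: tuple[str, ...]
    #: month -> full repaired basis correlation matrix (taxa x taxa)
    basis_correlation: dict
    #: taxa x months expected relative abundance (occupancy-weighted)
    expected_rel_abund: pd.DataFrame
    #: month -> log-scale within-month sd
    dispersion: dict
    #: month -> list of ((a, b), planted rho) after PSD repair
    planted_pairs: dict
    #: per planted-core-taxon target occurrence fraction
    core_occurrence: dict = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "core_taxa": list(self.core_taxa),
            "core_occurrence": {t: float(o)
                                for t, o in (self.core_occurrence or {}).items()},
            "dispersion": {m: float(s) for m, s in self.dispersion.items()},
            "planted_pairs": {
                m: [[a, b, float(r)] for (a, b), r in pairs]
                for m, pairs in self.planted_pairs.items()
            },
            "expected_rel_abund": {
                t: {m: float(v) for m, v in row.items()}
                for t, row in self.expected_rel_abund.iterrows()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# correlation-structure helpers


def nearest_psd_correlation(corr: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Repair a symmetric matrix to the nearest PSD correlation matrix by
    eigenvalue clipping, then rescale the diagonal back to 1."""
    w, v = np.linalg.eigh((corr + corr.T) / 2.0)
    if w.min() >= eps:
        return corr
    w = np.clip(w, eps, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def build_correlation_matrix(
    taxa: Sequence[str], pairs: Sequence[tuple[tuple[str, str], float]],
    max_repair_shift: float = 0.2,
) -> tuple[pd.DataFrame, list]:
    """Identity plus planted pairs, PSD-repaired.

    Returns the repaired matrix and the planted pairs with their
    post-repair values.  Raises :class:`CorrSpecError` when a planted
    value cannot survive the repair (shift > ``max_repair_shift``) or
    when conflicting duplicates are planted.
    """
    idx = {t: i for i, t in enumerate(taxa)}
    C = np.eye(len(taxa))
    seen: dict[tuple[int, int], float] = {}
    for (a, b), rho in pairs:
        if a not in idx or b not in idx:
            raise CorrSpecError(f"planted pair ({a}, {b}) references unknown taxa")
        i, j = sorted((idx[a], idx[b]))
        if (i, j) in seen and not math.isclose(seen[(i, j)], rho):
            raise CorrSpecError(f"conflicting correlations planted for ({a}, {b})")
        seen[(i, j)] = rho
        C[i, j] = C[j, i] = rho
    fixed = nearest_psd_correlation(C)
    repaired_pairs = []
    offending = []
    for (a, b), rho in pairs:
        got = fixed[idx[a], idx[b]]
        if abs(got - rho) > max_repair_shift:
            offending.append((a, b))
        repaired_pairs.append(((a, b), float(got)))
    if offending:
        raise CorrSpecError(
            f"corr_spec not PSD-repairable within tolerance; offending pairs: {offending}"
        )
    return pd.DataFrame(fixed, index=list(taxa), columns=list(taxa)), repaired_pairs


def perturb_network(
    corr_spec: Sequence[tuple[tuple[str, str], float]],
    rewiring_fraction: float,
    seed: int | np.random.Generator,
    taxa: Sequence[str] | None = None,
) -> list[tuple[tuple[str, str], float]]:
    """Rewire a planted pair list: exactly round(fraction * n_pairs) pairs
    are replaced by new random pairs (keeping their correlation values);
    the remainder is preserved.

    ``taxa`` is the universe from which new endpoints are drawn; defaults
    to the taxa already appearing in ``corr_spec``.
    """
    if not 0.0 <= rewiring_fraction <= 1.0:
        raise ValueError("rewiring_fraction must be in [0,1]")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    pairs = list(corr_spec)
    n_replace = int(round(rewiring_fraction * len(pairs)))
    if n_replace == 0:
        return pairs
    if taxa is None:
        taxa = sorted({t for (a, b), _ in pairs for t in (a, b)})
    taxa = list(taxa)
    if len(taxa) < 2:
        raise ValueError("need at least two taxa to rewire")
    replace_idx = set(rng.choice(len(pairs), size=n_replace, replace=False).tolist())
    used = {frozenset(p) for i, (p, _) in enumerate(pairs) if i not in replace_idx}
    old = {frozenset(p) for p, _ in pairs}
    out: list[tuple[tuple[str, str], float]] = []
    for i, (pair, rho) in enumerate(pairs):
        if i not in replace_idx:
            out.append((pair, rho))
            continue
        for _ in range(10_000):
            a, b = rng.choice(len(taxa), size=2, replace=False)
            cand = frozenset((taxa[a], taxa[b]))
            if cand not in used and cand not in old:
                break
        else:  # pragma: no cover - saturated universe
            raise ValueError("could not draw a fresh pair; taxa universe too small")
        used.add(cand)
        out.append(((taxa[a], taxa[b]), rho))
    return out


def make_month_corr_specs(
    base_pairs: Sequence[tuple[tuple[str, str], float]],
    months: Sequence[str],
    rewiring_fraction: float,
    seed: int,
    taxa: Sequence[str] | None = None,
) -> dict:
    """Chain month correlation specs: each month inherits the previous
    month's pairs with ``rewiring_fraction`` of them rewired."""
    rng = np.random.default_rng(seed)
    spec = {months[0]: list(base_pairs)}
    for prev, cur in zip(months, months[1:]):
        spec[cur] = perturb_network(spec[prev], rewiring_fraction, rng, taxa=taxa)
    return spec


# ---------------------------------------------------------------------------
# dataset generation


def _taxon_ids(config: SimConfig) -> tuple[list[str], list[str]]:
    ids, kingdoms = [], []
    for kingdom, n, tag in (
        ("bacteria", config.n_bacteria, "b"),
        ("fungi", config.n_fungi, "f"),
        ("oomycetes", config.n_oomycetes, "o"),
    ):
        for i in range(n):
            ids.append(f"Otu{tag}{i + 1:04d}")
            kingdoms.append(kingdom)
    return ids, kingdoms


def _make_taxonomy(ids, kingdoms, rng) -> pd.DataFrame:
    rows = {}
    for tid, kingdom in zip(ids, kingdoms):
        phylum, cls, order, family = _TAX_POOLS[kingdom][
            rng.integers(len(_TAX_POOLS[kingdom]))
        ]
        genus = _GENERA[kingdom][rng.integers(len(_GENERA[kingdom]))]
        rows[tid] = dict(zip(RANKS, (kingdom, phylum, cls, order, family, genus)))
    return pd.DataFrame.from_dict(rows, orient="index")[list(RANKS)]


def _sample_frame(config: SimConfig) -> pd.DataFrame:
    rows = []
    ecotypes = [DEFAULT_ECOTYPES[i % len(DEFAULT_ECOTYPES)] if i < len(DEFAULT_ECOTYPES)
                else f"eco{i + 1}" for i in range(config.n_ecotypes)]
    for e in range(1, config.n_experiments + 1):
        for m in config.months:
            for eco in ecotypes:
                for p in range(1, config.plants_per_cell + 1):
                    sid = f"E{e}.{m}.{eco}.p{p}"
                    rows.append((sid, f"E{e}", m, eco, f"p{p}"))
    df = pd.DataFrame(rows, columns=["sample", "experiment", "month", "ecotype", "plant"])
    return df.set_index("sample")


def _assign_core(config: SimConfig, ids, kingdoms, rng):
    """Pick core taxon ids per CoreSpec entry; returns (core ids in order,
    per-core occurrence, per-core target mean relative abundance)."""
    by_kingdom: dict[str, list[str]] = {k: [] for k in KINGDOMS}
    for tid, kd in zip(ids, kingdoms):
        by_kingdom[kd].append(tid)
    core_ids, occ, target = [], {}, {}
    cursor = {k: 0 for k in KINGDOMS}
    for cs in config.core_spec:
        pool = by_kingdom[cs.kingdom]
        for _ in range(cs.n_taxa):
            if cursor[cs.kingdom] >= len(pool):
                raise ValueError(f"core_spec requests more {cs.kingdom} taxa than exist")
            tid = pool[cursor[cs.kingdom]]
            cursor[cs.kingdom] += 1
            core_ids.append(tid)
            occ[tid] = cs.occurrence
            target[tid] = cs.mean_rel_abund
    return core_ids, occ, target


def _dropout_weights(abund: np.ndarray, noncore_mask: np.ndarray) -> np.ndarray:
    """Per-taxon dropout propensity for non-core taxa: rarer taxa are
    more transient (occurrence tracks abundance, as in field surveys),
    with a floor so that even abundant non-core taxa fluctuate and only
    planted core taxa can be systematically present."""
    mean_ab = abund[noncore_mask].mean(axis=1)
    order = np.argsort(np.argsort(mean_ab))  # ranks, 0 = rarest
    u = order / max(len(order) - 1, 1)
    return 0.2 + 0.8 * (1.0 - u) ** 2


def _calibrate_dropout(
    abund: np.ndarray, depths: np.ndarray, noncore_mask: np.ndarray,
    core_present: np.ndarray, target: float,
) -> np.ndarray:
    """Per-taxon zero-inflation probabilities for non-core taxa such that
    the expected overall zero fraction hits ``target``.

    A single scale factor on the abundance-rank weights is solved by
    bisection; the expectation accounts for structural zeros (dropout +
    absent core) and multinomial sampling zeros via a Poisson tail.
    """
    n_cells = abund.size
    core_mask = ~noncore_mask
    sum_core = (abund * core_present)[core_mask].sum(axis=0) \
        if core_mask.any() else np.zeros(abund.shape[1])
    sum_non = abund[noncore_mask].sum(axis=0)
    n_core_zero = int((core_present[core_mask] == 0).sum()) if core_mask.any() else 0
    w = _dropout_weights(abund, noncore_mask)

    def d_of(c: float) -> np.ndarray:
        return np.minimum(0.98, c * w)

    def expected_sparsity(c: float) -> float:
        d = d_of(c)[:, None]
        mean_d = d.mean()
        denom = sum_core + (1.0 - mean_d) * sum_non
        denom = np.where(denom <= 0, 1.0, denom)
        p = abund[noncore_mask] / denom
        p0 = np.exp(-depths * p)  # Poisson approx of multinomial zero prob
        non_zero = d + (1.0 - d) * p0
        return (non_zero.sum() + n_core_zero) / n_cells

    lo, hi = expected_sparsity(0.0), expected_sparsity(50.0)
    if target <= lo:
        if target < lo - 0.05:
            logger.warning(
                "sparsity_target %.2f below attainable floor %.2f; using no dropout",
                target, lo,
            )
        return np.zeros_like(w)
    if target >= hi:
        logger.warning(
            "sparsity_target %.2f above attainable ceiling %.2f", target, hi)
        return d_of(50.0)
    c = float(brentq(lambda x: expected_sparsity(x) - target, 0.0, 50.0,
                     xtol=1e-4))
    return d_of(c)


def generate_dataset(config: SimConfig) -> tuple[OtuTable, SyntheticTruth]:
    """Draw one synthetic survey; identical config+seed gives identical output."""
    rng = np.random.default_rng(config.seed)
    ids, kingdoms = _taxon_ids(config)
    taxonomy = _make_taxonomy(ids, kingdoms, rng)
    samples = _sample_frame(config)
    D, N = len(ids), len(samples)
    months = list(config.months)
    month_idx = {m: k for k, m in enumerate(months)}

    core_ids, core_occ, core_target = _assign_core(config, ids, kingdoms, rng)
    core_set = set(core_ids)
    id_pos = {t: i for i, t in enumerate(ids)}

    # baseline log means; core taxa pinned to their target relative abundance
    mu0 = rng.normal(0.0, config.baseline_sigma, size=D)
    noncore_rows = np.array([t not in core_set for t in ids])
    # expected abundance of a lognormal with sd log_sigma
    s2 = config.log_sigma ** 2 / 2.0
    S_non = float(np.exp(mu0[noncore_rows] + s2).sum())
    total_core_frac = sum(core_target.values())
    if total_core_frac >= 0.9:
        raise ValueError("core_spec mean relative abundances sum too close to 1")
    for t in core_ids:
        frac = core_target[t]
        mu0[id_pos[t]] = math.log(frac * S_non / (1.0 - total_core_frac)) - s2

    # seasonal trends: linear shift in log mean over month index
    trend_shift = np.zeros((D, len(months)))
    for ts in config.trend_spec:
        if isinstance(ts.group, str):
            members = [i for i, kd in enumerate(kingdoms) if kd == ts.group]
            if not members:
                members = [id_pos[ts.group]] if ts.group in id_pos else []
        else:
            members = [id_pos[t] for t in ts.group]
        if not members:
            raise ValueError(f"trend group {ts.group!r} matches no taxa")
        span = max(len(months) - 1, 1)
        for k in range(len(months)):
            trend_shift[members, k] += ts.direction * ts.strength * (k / span - 0.5)

    # per-month correlation structure (PSD-repaired) and cholesky factors
    basis_corr, planted_pairs, chol = {}, {}, {}
    for m in months:
        pairs = list(config.corr_spec.get(m, []))
        C, repaired = build_correlation_matrix(ids, pairs)
        basis_corr[m] = C
        planted_pairs[m] = repaired
        chol[m] = np.linalg.cholesky(C.to_numpy() + 1e-10 * np.eye(D))

    dispersion = {
        m: config.log_sigma * config.dispersion_decay ** month_idx[m] for m in months
    }

    # latent log abundances per sample
    log_ab = np.empty((D, N))
    sample_month = samples["month"].to_numpy()
    for m in months:
        cols = np.flatnonzero(sample_month == m)
        z = rng.standard_normal((D, len(cols)))
        sigma_m = dispersion[m]
        log_ab[:, cols] = (
            mu0[:, None] + trend_shift[:, [month_idx[m]]] + sigma_m * (chol[m] @ z)
        )
    abund = np.exp(log_ab)

    # core occupancy: exact inclusion counts per experiment
    core_present = np.ones((D, N))
    exp_labels = samples["experiment"].to_numpy()
    for t in core_ids:
        p_inc = core_occ[t]
        row = id_pos[t]
        for e in np.unique(exp_labels):
            cols = np.flatnonzero(exp_labels == e)
            n_inc = math.ceil(p_inc * len(cols))
            inc = rng.choice(cols, size=n_inc, replace=False)
            mask = np.zeros(len(cols), dtype=bool)
            mask[np.searchsorted(cols, inc)] = True
            core_present[row, cols[~mask]] = 0.0

    depths = rng.poisson(config.depth, size=N).astype(np.int64)
    depths = np.maximum(depths, 1)

    # zero-inflation of non-core taxa toward the sparsity target
    dropout_keep = np.ones((D, N))
    if config.sparsity_target is not None and noncore_rows.any():
        d = _calibrate_dropout(
            abund, depths, noncore_rows, core_present, config.sparsity_target
        )
        if d.any():
            keep = rng.random((int(noncore_rows.sum()), N)) >= d[:, None]
            dropout_keep[noncore_rows] = keep

    eff = abund * core_present * dropout_keep
    col_sum = eff.sum(axis=0)
    col_sum = np.where(col_sum <= 0, 1.0, col_sum)
    props = eff / col_sum

    counts = np.empty((D, N), dtype=np.int64)
    for j in range(N):
        counts[:, j] = rng.multinomial(depths[j], props[:, j])

    # a core taxon included in a sample must be observed: move one read
    # from the sample's largest count (depth conserved)
    for t in core_ids:
        row = id_pos[t]
        need = np.flatnonzero((core_present[row] > 0) & (counts[row] == 0))
        for j in need:
            donor = int(np.argmax(counts[:, j]))
            if donor != row and counts[donor, j] > 1:
                counts[donor, j] -= 1
                counts[row, j] += 1

    counts_df = pd.DataFrame(counts, index=ids, columns=samples.index)
    table = OtuTable(
        counts=counts_df, taxonomy=taxonomy, samples=samples.copy(),
        month_order=tuple(months),
    )

    # occupancy-weighted expected relative abundance per taxon per month
    exp_rel = np.empty((D, len(months)))
    occ_w = np.array([core_occ.get(t, 1.0) for t in ids])
    for m in months:
        k = month_idx[m]
        mean_ab = np.exp(mu0 + trend_shift[:, k] + dispersion[m] ** 2 / 2.0) * occ_w
        exp_rel[:, k] = mean_ab / mean_ab.sum()
    truth = SyntheticTruth(
        core_taxa=tuple(core_ids),
        basis_correlation=basis_corr,
        expected_rel_abund=pd.DataFrame(exp_rel, index=ids, columns=months),
        dispersion=dispersion,
        planted_pairs=planted_pairs,
        core_occurrence=dict(core_occ),
    )
    return table, truth
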