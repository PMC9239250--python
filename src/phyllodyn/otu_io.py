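"""OTU table container, I/O and abundance filters.

The :class:`OtuTable` is the universal input of the pipeline: a taxa x
samples count matrix with per-taxon ranked taxonomy (kingdom..genus) and
per-sample metadata (experiment, month, ecotype, plant).  Months are stored
as an *ordered* categorical so that "consecutive months" logic never
depends on string sort order.

Filters implement the two abundance gates used throughout leaf-microbiome
surveys: removal of low-abundance OTUs (< 50 total reads, the
``split.abund`` convention) and the stricter network-input filter (OTUs
with > 10 reads in at least 5 samples).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("phyllodyn")

#: ranked taxonomy columns, most to least inclusive
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

#: recognised kingdom labels
KINGDOMS = ("bacteria", "fungi", "oomycetes")

#: metadata columns every sample table must provide (plant is optional)
METADATA_COLS = ("experiment", "month", "ecotype")


class OtuTableError(ValueError):
    """Raised when an OTU table or its companion files are inconsistent."""


@dataclass
class OtuTable:
    """Count matrix (taxa x samples) plus taxonomy and sample metadata.

    Parameters
    ----------
    counts
        Non-negative integer DataFrame, rows indexed by OTU id, columns by
        sample id.
    taxonomy
        DataFrame indexed by OTU id with the columns of :data:`RANKS`
        (missing ranks allowed as empty strings / NaN).
    samples
        DataFrame indexed by sample id with at least ``experiment`` and
        ``month`` columns.
    month_order
        Ordered month labels (e.g. Nov..Mar).  If omitted, the order of
        first appearance in ``samples`` is used.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    samples: pd.DataFrame
    month_order: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            dup = self.counts.index[self.counts.index.duplicated()].tolist()
            raise OtuTableError(f"duplicate taxon ids: {dup[:5]}")
        if not self.counts.columns.is_unique:
            dup = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise OtuTableError(f"duplicate sample ids: {dup[:5]}")
        vals = self.counts.to_numpy()
        if not np.isfinite(vals).all():
            raise OtuTableError("counts contain non-finite values")
        if (vals < 0).any():
            raise OtuTableError("counts contain negative values")
        missing_meta = self.counts.columns.difference(self.samples.index)
        if len(missing_meta):
            raise OtuTableError(
                f"samples missing from metadata: {sorted(missing_meta)[:5]}"
            )
        missing_tax = self.counts.index.difference(self.taxonomy.index)
        if len(missing_tax):
            raise OtuTableError(
                f"taxa missing from taxonomy: {sorted(missing_tax)[:5]}"
            )
        for col in ("experiment", "month"):
            if col not in self.samples.columns:
                raise OtuTableError(f"sample metadata lacks required column {col!r}")
        # align companions to the count matrix
        self.samples = self.samples.loc[self.counts.columns].copy()
        self.taxonomy = self.taxonomy.loc[self.counts.index].copy()
        if not self.month_order:
            seen: list[str] = []
            for m in self.samples["month"]:
                if m not in seen:
                    seen.append(m)
            self.month_order = tuple(seen)
        self.samples["month"] = pd.Categorical(
            self.samples["month"], categories=self.month_order, ordered=True
        )
        if self.samples["month"].isna().any():
            bad = self.samples.index[self.samples["month"].isna()].tolist()
            raise OtuTableError(f"samples with month outside month_order: {bad[:5]}")

    # -- basic views ------------------------------------------------------

    @property
    def taxa(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def kingdom(self) -> pd.Series:
        """Per-taxon kingdom label."""
        return self.taxonomy["kingdom"]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_taxa(self, taxa: Sequence[str]) -> "OtuTable":
        taxa = [t for t in self.taxa if t in set(taxa)]  # keep original order
        return OtuTable(
            counts=self.counts.loc[taxa],
            taxonomy=self.taxonomy.loc[taxa],
            samples=self.samples,
            month_order=self.month_order,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        keep = [s for s in self.sample_ids if s in set(sample_ids)]
        return OtuTable(
            counts=self.counts[keep],
            taxonomy=self.taxonomy,
            samples=self.samples.loc[keep],
            month_order=self.month_order,
        )

    def split_by_kingdom(self) -> dict[str, "OtuTable"]:
        out = {}
        for k in pd.unique(self.kingdom):
            out[k] = self.subset_taxa(self.taxa[self.kingdom == k])
        return out

    def samples_of_month(self, month: str) -> list[str]:
        mask = self.samples["month"] == month
        return list(self.samples.index[mask])


@dataclass
class RelAbundTable:
    """Per-sample relative abundances, optionally log10(x+1)-transformed.

    ``values`` has the same shape/labels as the source count matrix; each
    column sums to 1 (before transform) unless the sample had zero depth,
    in which case the column is all-zero.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    log10_plus1: bool = False
    month_order: tuple[str, ...] = field(default=())


# ---------------------------------------------------------------------------
# reading / writing


def read_otu_table(
    counts_path: str | Path,
    taxonomy_path: str | Path,
    metadata_path: str | Path,
) -> OtuTable:
    """Read counts, taxonomy and sample metadata TSVs into an OtuTable.

    The counts TSV has OTU ids in the first column and sample ids as
    header; taxonomy TSV has OTU id plus ranked columns; metadata TSV has
    columns ``sample, experiment, month, ecotype[, plant]``.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col=0, dtype=str)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0, dtype=str)
    counts = counts.apply(pd.to_numeric)
    if not float(counts.to_numpy().sum()) == float(
        counts.round().to_numpy().sum()
    ):
        raise OtuTableError("counts file contains non-integer values")
    counts = counts.astype(np.int64)
    counts.index.name = None
    counts.columns.name = None
    taxonomy.index.name = None
    meta.index.name = None
    return OtuTable(counts=counts, taxonomy=taxonomy, samples=meta)


def write_otu_table(table: OtuTable, out_dir: str | Path, prefix: str = "otu") -> dict:
    """Write counts / taxonomy / metadata TSVs; returns the path map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out_dir / f"{prefix}_counts.tsv",
        "taxonomy": out_dir / f"{prefix}_taxonomy.tsv",
        "metadata": out_dir / f"{prefix}_metadata.tsv",
    }
    table.counts.to_csv(paths["counts"], sep="\t", index_label="otu_id")
    table.taxonomy.to_csv(paths["taxonomy"], sep="\t", index_label="otu_id")
    meta = table.samples.copy()
    meta["month"] = meta["month"].astype(str)
    meta.to_csv(paths["metadata"], sep="\t", index_label="sample")
    return {k: str(v) for k, v in paths.items()}


def to_biom(table: OtuTable):
    """Export counts+taxonomy as a biom-format Table (optional dependency)."""
    try:
        from biom.table import Table as BiomTable
    except ImportError as exc:  # pragma: no cover - env without biom
        raise ImportError("biom-format is not installed") from exc
    tax_meta = [
        {"taxonomy": [str(table.taxonomy.loc[t, r]) for r in RANKS if r in table.taxonomy]}
        for t in table.taxa
    ]
    return BiomTable(
        table.counts.to_numpy(),
        observation_ids=list(table.taxa),
        sample_ids=list(table.sample_ids),
        observation_metadata=tax_meta,
    )


def from_biom(biom_table, samples: pd.DataFrame, month_order=()) -> OtuTable:
    """Re-import a biom Table (with taxonomy metadata) plus sample metadata."""
    counts = pd.DataFrame(
        biom_table.matrix_data.toarray().astype(np.int64),
        index=list(biom_table.ids("observation")),
        columns=list(biom_table.ids("sample")),
    )
    tax_rows = {}
    for tid in counts.index:
        md = biom_table.metadata(tid, "observation") or {}
        levels = list(md.get("taxonomy", []))
        levels += [""] * (len(RANKS) - len(levels))
        tax_rows[tid] = dict(zip(RANKS, levels))
    taxonomy = pd.DataFrame.from_dict(tax_rows, orient="index")
    return OtuTable(counts=counts, taxonomy=taxonomy, samples=samples,
                    month_order=tuple(month_order))


# ---------------------------------------------------------------------------
# filters and transforms


def filter_low_abundance(
    table: OtuTable, min_total_reads: int = 50, per_experiment: bool = False
) -> OtuTable:
    """Drop OTUs with fewer than ``min_total_reads`` reads summed over all
    samples (the ``split.abund`` convention; an OTU at exactly the
    threshold is kept).

    With ``per_experiment=True`` the filter is applied within each
    experiment and the surviving taxa are unioned, as when independently
    filtered per-experiment tables are merged.
    """
    if min_total_reads < 0:
        raise ValueError("min_total_reads must be >= 0")
    if per_experiment:
        totals = table.counts.T.groupby(
            table.samples["experiment"], observed=True
        ).sum().T
        keep = table.taxa[(totals >= min_total_reads).any(axis=1)]
    else:
        keep = table.taxa[table.counts.sum(axis=1) >= min_total_reads]
    return table.subset_taxa(keep)


def filter_for_network(
    table: OtuTable, min_samples: int = 5, min_reads_per_sample: int = 10
) -> OtuTable:
    """Network-input gate: keep OTUs with strictly more than
    ``min_reads_per_sample`` reads in at least ``min_samples`` samples."""
    if min_samples < 0 or min_reads_per_sample < 0:
        raise ValueError("thresholds must be >= 0")
    n_good = (table.counts > min_reads_per_sample).sum(axis=1)
    keep = table.taxa[n_good >= min_samples]
    return table.subset_taxa(keep)


def to_relative(table: OtuTable, log10_plus1: bool = False) -> RelAbundTable:
    """Close each sample to relative abundances; optionally apply
    log10(x+1) *after* closure (x on the proportion scale)."""
    depths = table.counts.sum(axis=0)
    zero = depths == 0
    if zero.any():
        logger.warning(
            "to_relative: %d all-zero sample(s) left as zero columns: %s",
            int(zero.sum()), list(depths.index[zero])[:5],
        )
    safe = depths.replace(0, 1)
    rel = table.counts.div(safe, axis=1).astype(float)
    if log10_plus1:
        rel = np.log10(rel + 1.0)
    return RelAbundTable(
        values=rel,
        samples=table.samples,
        log10_plus1=log10_plus1,
        month_order=table.month_order,
    )


def sparsity(table: OtuTable) -> float:
    """Fraction of zero cells in the count matrix."""
    vals = table.counts.to_numpy()
    if vals.size == 0:
        return 0.0
    return float((vals == 0).mean())
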