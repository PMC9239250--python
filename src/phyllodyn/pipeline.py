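"""End-to-end pipeline: simulate/load -> filter -> diversity -> core ->
month networks -> dynamics -> hubs, as one reproducible, configured run.

Every source of randomness derives from a single global seed via a
counter-based fan-out (stage k uses ``SeedSequence((seed, k))``), so
inserting a stage never reshuffles the randomness of later stages, and a
rerun with the same config+seed reproduces byte-identical outputs (the
manifest records sha256 hashes of every file written).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community_stats as cs
from . import core_taxa as ct
from . import hub_analysis as hub
from . import network_dynamics as dyn
from . import network_inference as ni
from .otu_io import (OtuTable, filter_for_network, filter_low_abundance,
                     read_otu_table, sparsity, to_relative, write_otu_table)
from .synth_data import CoreSpec, SimConfig, TrendSpec, generate_dataset

logger = logging.getLogger("phyllodyn")

#: fixed stage indices for the counter-based seed fan-out
_STAGES = ("simulate", "permanova", "network_sparcc", "network_spearman")


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2**31) from the global seed."""
    idx = _STAGES.index(stage)
    return int(np.random.SeedSequence((global_seed, idx)).generate_state(1)[0]
               % (2 ** 31))


@dataclass
class RunConfig:
    """Configuration of one pipeline run (mirrors module defaults)."""

    out_dir: str = "phyllodyn_run"
    seed: int = 0
    # input: either a simulation config or paths to TSVs
    sim: SimConfig | None = None
    counts_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    # filters
    min_total_reads: int = 50
    low_abundance_per_experiment: bool = True
    network_min_samples: int = 5
    network_min_reads: int = 10
    # community stats
    n_perm: int = 10_000
    permanova_terms: tuple[str, ...] = ("experiment", "month", "ecotype")
    # core
    core_thresholds: dict = field(
        default_factory=lambda: dict(ct.DEFAULT_THRESHOLDS))
    # networks
    methods: tuple[str, ...] = ("sparcc", "spearman")
    alpha: float = 0.001
    n_boot: int = 1000
    n_inner: int = 20
    quantile: float = 0.05
    hub_quantile: float = 0.05
    dn_weighting: str = "binary"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_raw is not None:
            core = tuple(CoreSpec(**c) for c in sim_raw.pop("core_spec", []))
            trend = tuple(TrendSpec(**t) for t in sim_raw.pop("trend_spec", []))
            for key in ("months",):
                if key in sim_raw:
                    sim_raw[key] = tuple(sim_raw[key])
            cfg.sim = SimConfig(core_spec=core, trend_spec=trend, **sim_raw)
        return cfg

    def to_dict(self) -> dict:
        # out_dir is execution context, not science: keep it out of the
        # serialized config so reruns in different directories hash equal
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        if self.sim is not None:
            d["sim"]["corr_spec"] = {
                m: [[list(p), r] for p, r in pairs]
                for m, pairs in self.sim.corr_spec.items()
            }
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kwargs)


def _load_input(config: RunConfig) -> OtuTable:
    if config.sim is not None:
        sim = dataclasses.replace(
            config.sim, seed=stage_seed(config.seed, "simulate"))
        table, truth = generate_dataset(sim)
        out = Path(config.out_dir)
        truth.to_json(out / "synthetic_truth.json")
        write_otu_table(table, out, prefix="simulated")
        return table
    if not all((config.counts_path, config.taxonomy_path, config.metadata_path)):
        raise ValueError("RunConfig needs either sim or the three input paths")
    return read_otu_table(config.counts_path, config.taxonomy_path,
                          config.metadata_path)


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written to the output
    directory).  Any stage failure aborts with the stage name attached."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "seed": config.seed,
        "stages": [],
        "outputs": {},
    }

    def finish_stage(stage: str, **info) -> None:
        manifest["stages"].append({"stage": stage, **info})
        logger.info("stage %s done: %s", stage, info)

    def fail(stage: str, exc: Exception):
        manifest["error"] = {"stage": stage, "message": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    stage = "input"
    try:
        table = _load_input(config)
        finish_stage(stage, n_taxa=table.n_taxa, n_samples=table.n_samples,
                     sparsity=round(sparsity(table), 4))

        stage = "filter"
        filtered = filter_low_abundance(
            table, config.min_total_reads,
            per_experiment=config.low_abundance_per_experiment)
        finish_stage(stage, n_taxa=filtered.n_taxa,
                     sparsity=round(sparsity(filtered), 4))

        stage = "diversity"
        shannon_rows = []
        for kingdom, sub in filtered.split_by_kingdom().items():
            h = cs.shannon_by_sample(sub)
            for s, v in h.items():
                shannon_rows.append(dict(
                    sample=s, kingdom=kingdom, shannon=v,
                    month=str(filtered.samples.loc[s, "month"]),
                ))
        _write_tsv(pd.DataFrame(shannon_rows), out / "shannon.tsv", index=False)

        stage = "permanova"
        rel = to_relative(filtered, log10_plus1=True)
        dm = cs.bray_curtis(rel)
        pres = cs.permanova(
            dm, filtered.samples, list(config.permanova_terms),
            n_perm=config.n_perm, seed=stage_seed(config.seed, "permanova"))
        _write_tsv(pres.table, out / "permanova.tsv", index_label="term")
        finish_stage(stage, n_perm=pres.n_permutations)

        stage = "dispersion"
        disp = cs.beta_dispersion(dm, filtered.samples["month"].astype(str))
        disp_df = pd.DataFrame({
            "dist_to_centroid": disp.distances, "month": disp.groups})
        _write_tsv(disp_df, out / "dispersion.tsv", index_label="sample")
        dunn = cs.dunn_test(disp.distances.to_numpy(),
                            disp.groups.to_numpy())
        _write_tsv(dunn.comparisons, out / "dispersion_dunn.tsv", index=False)
        finish_stage(stage, n_groups=int(disp.groups.nunique()))

        stage = "core"
        occ = ct.occurrence(filtered, by_experiment=True)
        core = ct.call_core(occ, config.core_thresholds)
        core_df = core.occurrence.copy()
        core_df.insert(0, "kingdom", core.kingdom)
        _write_tsv(core_df, out / "core_taxa.tsv", index_label="otu_id")
        _write_tsv(ct.core_fraction_by_month(filtered, core),
                   out / "core_fraction_by_month.tsv", index_label="kingdom")
        if len(core) >= 2:
            newick, _, _ = ct.taxonomy_dendrogram(core, filtered.taxonomy)
            (out / "core_dendrogram.nwk").write_text(newick + "\n")
        finish_stage(stage, n_core=len(core))

        stage = "networks"
        net_table = filter_for_network(
            filtered, config.network_min_samples, config.network_min_reads)
        series_by_method: dict[str, ni.NetworkSeries] = {}
        for method in config.methods:
            series = ni.build_month_networks(
                net_table, method=method,
                seed=stage_seed(config.seed, f"network_{method}"),
                alpha=config.alpha, n_boot=config.n_boot,
                n_inner=config.n_inner, quantile=config.quantile)
            series_by_method[method] = series
            for net in series:
                ni.write_edge_list(net, out / f"network_{method}_{net.month}.tsv")
        finish_stage(stage, n_taxa=net_table.n_taxa, methods=list(config.methods),
                     nodes={m: [n.n_nodes for n in s]
                            for m, s in series_by_method.items()})

        stage = "dynamics"
        for method, series in series_by_method.items():
            if len(series) >= 2:
                _write_tsv(dyn.dynamics_summary(series,
                                                weighting=config.dn_weighting),
                           out / f"dynamics_{method}.tsv", index=False)

        stage = "hubs"
        hubs_by_method = {}
        for method, series in series_by_method.items():
            cts = hub.centrality_series(series, core=core, q=config.hub_quantile)
            rows = []
            for m, table_m in cts.items():
                t = table_m.table.copy()
                t.insert(0, "month", m)
                rows.append(t)
            if rows:
                _write_tsv(pd.concat(rows), out / f"centrality_{method}.tsv",
                           index_label="otu_id")
                _write_tsv(hub.core_connectivity(cts, core),
                           out / f"core_connectivity_{method}.tsv",
                           index_label="otu_id")
            hubs_by_method[method] = {m: list(c.hubs) for m, c in cts.items()}
        (out / "hubs.json").write_text(
            json.dumps(hubs_by_method, indent=1, sort_keys=True))
        if len(hubs_by_method) == 2:
            a, b = config.methods
            _write_tsv(hub.hub_overlap(hubs_by_method[a], hubs_by_method[b]),
                       out / "hub_overlap.tsv")
        finish_stage(stage, hubs={m: {k: len(v) for k, v in h.items()}
                                  for m, h in hubs_by_method.items()})
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        fail(stage, exc)

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    (out / "config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True))
    manifest["outputs"]["config.yaml"] = _sha256(out / "config.yaml")
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
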