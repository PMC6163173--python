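"""Readers/writers for the pipeline's text formats plus the end-to-end runner.

Formats: expression as genes-in-rows TSV, module partitions as two-column
TSV, gene sets as GMT, gene positions as BED (0-based, half-open).  All of
them round-trip losslessly through this module's own readers.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import detect, enrich, meta, network, stats, synthetic

logger = logging.getLogger("coexnet")

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "read_bed",
    "write_bed",
    "read_partition",
    "write_partition",
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
]


# ---------------------------------------------------------------- expression

def read_expression_tsv(path: str | Path, transpose: bool = False) -> pd.DataFrame:
    """Expression TSV: first column gene ids, header row sample ids, numeric
    body.  Duplicate gene ids, missing values and non-numeric cells are
    rejected with the offending line/gene named."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if transpose:
        table = table.T
    dup = table.index[table.index.duplicated()].unique()
    if len(dup):
        raise ValueError(f"{path}: duplicate gene id(s): {list(dup)[:5]}")
    try:
        values = table.astype(float)
    except ValueError as exc:
        for lineno, (gene, row) in enumerate(table.iterrows(), start=2):
            try:
                row.astype(float)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric value in gene {gene!r}"
                ) from exc
        raise
    if values.isna().any().any():
        bad = values.index[values.isna().any(axis=1)]
        raise ValueError(f"{path}: missing value(s) in gene(s) {list(bad)[:5]}")
    values.index = values.index.astype(str)
    values.index.name = "gene_id"
    return values


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    expr = expr.copy()
    expr.index.name = "gene_id"
    expr.to_csv(path, sep="\t", lineterminator="\n")


# ----------------------------------------------------------------- GMT / BED

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: one set per line, ``name<TAB>description<TAB>member...``."""
    sets: dict[str, set[str]] = {}
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
        name = fields[0]
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        members = {m for m in fields[2:] if m}
        if not members:
            raise ValueError(f"{path}:{lineno}: set {name!r} has no members")
        sets[name] = members
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    lines = []
    for name in sets:
        desc = (descriptions or {}).get(name, "na")
        members = sorted(sets[name])
        lines.append("\t".join([name, desc, *members]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED4 (chrom, start, end, name), 0-based half-open -> positions frame."""
    path = Path(path)
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 4:
            raise ValueError(f"{path}:{lineno}: BED line needs >= 4 fields")
        chrom, start, end, name = fields[:4]
        try:
            start_i, end_i = int(start), int(end)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
        if start_i >= end_i:
            raise ValueError(f"{path}:{lineno}: start {start_i} >= end {end_i}")
        rows.append((name, chrom, start_i, end_i))
    frame = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end"])
    dup = frame["gene_id"][frame["gene_id"].duplicated()].unique()
    if len(dup):
        raise ValueError(f"{path}: duplicate gene id(s): {list(dup)[:5]}")
    return frame


def write_bed(positions: pd.DataFrame, path: str | Path) -> None:
    out = positions[["chromosome", "start", "end", "gene_id"]]
    out.to_csv(path, sep="\t", header=False, index=False, lineterminator="\n")


# ------------------------------------------------------------------ partition

def read_partition(path: str | Path) -> detect.ModulePartition:
    table = pd.read_csv(path, sep="\t", dtype=str)
    if list(table.columns[:2]) != ["gene_id", "module"]:
        raise ValueError(f"{path}: expected columns gene_id, module")
    return detect.ModulePartition(dict(zip(table["gene_id"], table["module"])))


def write_partition(partition: detect.ModulePartition, path: str | Path) -> None:
    frame = pd.DataFrame(
        {"gene_id": list(partition.assignments), "module": list(partition.assignments.values())}
    )
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ------------------------------------------------------------------- pipeline

@dataclass
class PipelineConfig:
    """End-to-end run configuration. Defaults follow the published
    parameters wherever one is stated: candidate powers include 14,
    stability is 1000 half-sample draws, the meta-network uses power 3 with
    minModuleSize 2, and the positional threshold is 7e-7."""

    expression_tsv: str | None = None
    gene_sets_gmt: str | None = None
    positions_bed: str | None = None
    condition_labels_tsv: str | None = None
    output_dir: str = "coexnet_out"
    seed: int = 0
    # simulation (used when expression_tsv is None)
    simulate: dict[str, Any] = field(default_factory=dict)
    # network
    log_transform: bool = True
    candidate_powers: Sequence[int] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)
    r2_cutoff: float = 0.8
    beta: int | None = None  # overrides power selection when set
    # cut
    minModuleSize: int = 30
    deepSplit: int = 2
    cut_height_fraction: float = 0.995
    gap_threshold: float = 0.05
    # stability
    stability_iterations: int = 1000
    sample_fraction: float = 0.5
    # meta
    meta_power: int = 3
    meta_minModuleSize: int = 2
    top_n_edges: int = 100
    # enrichment
    positional_threshold: float = 7e-7
    positional_window: int = 50
    positional_step: int = 25
    hub_top_n: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for attr in ("expression_tsv", "gene_sets_gmt", "positions_bed",
                     "condition_labels_tsv"):
            value = getattr(self, attr)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{attr}: {value} does not exist")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunManifest:
    config: dict[str, Any]
    seed: int
    stage_seconds: dict[str, float]
    outputs: dict[str, str]  # filename -> sha256
    chosen_power: int
    n_modules: int
    versions: dict[str, str]

    def write(self, path: str | Path) -> None:
        path = Path(path)
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(asdict(self), indent=2, sort_keys=True, default=str))
        tmp.replace(path)  # atomic on POSIX


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(timings: dict[str, float], name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            timings[name] = round(time.perf_counter() - self.t0, 3)
            if exc is not None:
                logger.error("stage %s: FAILED (%s)", name, exc)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, timings[name])

    return _Timer()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full chain: load/simulate -> power selection -> adjacency
    -> TOM -> clustering -> tree cut -> eigengenes -> per-module statistics
    -> meta-network -> enrichments; write every table plus a manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    logger.info("run_pipeline: config hash %s", config.config_hash())

    truth = None
    gmt_path = Path(config.gene_sets_gmt) if config.gene_sets_gmt else None
    bed_path = Path(config.positions_bed) if config.positions_bed else None
    with _stage(timings, "load"):
        if config.expression_tsv is not None:
            expr = read_expression_tsv(config.expression_tsv)
        else:
            sim_kwargs = dict(config.simulate)
            sim_kwargs.setdefault("seed", config.seed)
            if "module_sizes" in sim_kwargs:
                sim_kwargs["module_sizes"] = tuple(sim_kwargs["module_sizes"])
            sim_config = synthetic.SyntheticConfig(**sim_kwargs)
            expr, truth = synthetic.generate_expression(sim_config)
            write_expression_tsv(expr, out / "expression.tsv")
            truth_frame = pd.DataFrame(
                {"gene_id": list(truth.partition), "module": list(truth.partition.values())}
            )
            truth_frame.to_csv(out / "truth_partition.tsv", sep="\t", index=False,
                               lineterminator="\n")
            # matched annotation inputs so the enrichment stage has work to do
            sets = synthetic.generate_gene_sets(truth, n_decoy_sets=10,
                                                seed=sim_config.seed + 1)
            write_gmt(sets, out / "gene_sets.gmt")
            positions = synthetic.generate_positions(
                truth, sim_config.n_chromosomes, sim_config.seed + 2)
            write_bed(positions, out / "positions.bed")
            gmt_path = gmt_path or out / "gene_sets.gmt"
            bed_path = bed_path or out / "positions.bed"
        condition_labels = None
        if config.condition_labels_tsv is not None:
            lbl = pd.read_csv(config.condition_labels_tsv, sep="\t", dtype=str)
            condition_labels = pd.Series(
                lbl.iloc[:, 1].to_numpy(), index=lbl.iloc[:, 0].to_numpy()
            )
        elif truth is not None and truth.config and truth.config.condition_labels:
            condition_labels = pd.Series(
                list(truth.config.condition_labels), index=expr.columns
            )

    with _stage(timings, "network"):
        net_expr = np.log2(expr) if config.log_transform else expr
        net_expr = network.filter_zero_variance(net_expr)
        if config.beta is not None:
            beta = int(config.beta)
            selection = None
        else:
            selection = network.pick_soft_threshold(
                net_expr, config.candidate_powers, config.r2_cutoff
            )
            selection.to_frame().to_csv(out / "power_selection.tsv", sep="\t",
                                        index=False, lineterminator="\n")
            beta = selection.chosen_power
        cor = network.correlation_matrix(net_expr)
        adj = network.signed_adjacency(cor, beta)
        tom = network.topological_overlap(adj)
        k_all = network.connectivity(adj)
        k_all.to_series().rename_axis("gene_id").to_frame().to_csv(
            out / "connectivity.tsv", sep="\t", lineterminator="\n")

    with _stage(timings, "modules"):
        dend = detect.average_linkage_dendrogram(tom.dissimilarity(), list(tom.gene_ids))
        cut = detect.CutParams(
            minModuleSize=config.minModuleSize,
            deepSplit=config.deepSplit,
            cut_height_fraction=config.cut_height_fraction,
            gap_threshold=config.gap_threshold,
        )
        partition = detect.dynamic_tree_cut(dend, cut)
        write_partition(partition, out / "partition.tsv")
        eigengenes = detect.module_eigengenes(net_expr, partition)
        eigengenes.values.to_csv(out / "eigengenes.tsv", sep="\t", lineterminator="\n")
        pd.Series(eigengenes.variance_explained, name="variance_explained").rename_axis(
            "module").to_frame().to_csv(out / "variance_explained.tsv", sep="\t",
                                        lineterminator="\n")

    with _stage(timings, "stats"):
        kmod = stats.within_module_connectivity(net_expr, partition, beta)
        hubs = stats.hub_genes(kmod, top_n=config.hub_top_n)
        hub_rows = [
            (m, g, float(k[g])) for m, k in hubs.items() for g in k.index
        ]
        pd.DataFrame(hub_rows, columns=["module", "gene_id", "k"]).to_csv(
            out / "hub_genes.tsv", sep="\t", index=False, lineterminator="\n")
        stability = stats.stability_resampling(
            net_expr, partition, beta,
            stats.StabilityParams(config.stability_iterations, config.sample_fraction,
                                  seed=config.seed + 1),
        )
        stability.to_frame().to_csv(out / "stability.tsv", sep="\t", index=False,
                                    lineterminator="\n")
        rsd = stats.module_rsd(expr.loc[net_expr.index], partition)
        rsd.rename_axis("gene_id").to_csv(out / "gene_rsd.tsv", sep="\t",
                                          lineterminator="\n")
        rsd.attrs["module_means"].rename_axis("module").to_frame().to_csv(
            out / "module_rsd.tsv", sep="\t", lineterminator="\n")
        if condition_labels is not None:
            assoc = stats.condition_association(eigengenes, condition_labels)
            assoc.rename_axis("module").to_csv(out / "condition_association.tsv",
                                               sep="\t", lineterminator="\n")

    with _stage(timings, "meta"):
        if len(partition.module_labels) >= 3:
            metanet = meta.eigengene_meta_modules(
                eigengenes, config.meta_power, config.meta_minModuleSize
            )
            write_partition(metanet.partition, out / "meta_partition.tsv")
            meta.module_global_connectivity(metanet).to_csv(
                out / "module_global_connectivity.tsv", sep="\t", index=False,
                lineterminator="\n")
            meta.top_edges(metanet, config.top_n_edges).to_csv(
                out / "meta_top_edges.tsv", sep="\t", index=False, lineterminator="\n")
        else:
            logger.warning("fewer than 3 modules; meta-network skipped")

    with _stage(timings, "enrich"):
        background = set(map(str, net_expr.index))
        if gmt_path is not None:
            collection = read_gmt(gmt_path)
            rows = []
            for label in partition.module_labels:
                query = set(partition.genes_in(label)) & background
                if not query:
                    continue
                table = enrich.enrich_gene_sets(query, collection, background)
                table.insert(0, "module", label)
                rows.append(table)
            if rows:
                pd.concat(rows, ignore_index=True).to_csv(
                    out / "enrichment.tsv", sep="\t", index=False, lineterminator="\n")
        if bed_path is not None:
            positions = read_bed(bed_path)
            rows = []
            for label in partition.module_labels:
                module_genes = set(partition.genes_in(label)) & set(
                    positions["gene_id"].astype(str))
                if len(module_genes) < 2:
                    continue
                regions = enrich.positional_enrichment(
                    module_genes, positions,
                    window_size=config.positional_window,
                    step=config.positional_step,
                    p_threshold=config.positional_threshold,
                )
                if len(regions):
                    regions.insert(0, "module", label)
                    rows.append(regions)
            header = ["module", "chromosome", "start", "end", "n_window", "k",
                      "log10_p", "whole_chromosome"]
            (pd.concat(rows, ignore_index=True) if rows
             else pd.DataFrame(columns=header)).to_csv(
                out / "positional_enrichment.tsv", sep="\t", index=False,
                lineterminator="\n")

    with _stage(timings, "manifest"):
        outputs = {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.suffix in (".tsv", ".gmt", ".bed")
        }
        manifest = RunManifest(
            config=asdict(config),
            seed=config.seed,
            stage_seconds=timings,
            outputs=outputs,
            chosen_power=beta,
            n_modules=len(partition.module_labels),
            versions={
                "coexnet": _package_version(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        )
        manifest.write(out / "manifest.json")
    return manifest


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("coexnet")
    except PackageNotFoundError:
        return "unknown"
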