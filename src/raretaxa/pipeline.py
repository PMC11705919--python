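"""Config-driven end-to-end pipeline with a checksummed output manifest.

Stage order: rarefy -> low-count filter -> partition (+ census, occupancy,
abundance-occupancy) -> co-occurrence network (+ health comparison) ->
OPLS-DA screening -> ecological traits -> threshold indicator analysis ->
soil-function coupling. One top-level seed fans out into per-stage seeds
by stable derivation, so any stage rerun in isolation reproduces the full
run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import io as rio
from ._utils import child_seed
from .network import (
    build_network_from_table,
    compare_health_networks,
    link_decomposition,
    topology_metrics,
)
from .oplsda import fit_oplsda, screen_differential
from .partition import (
    classify_gsp,
    filter_low_count,
    gsp_fractions,
    abundance_occupancy,
    rarefy,
    taxonomic_census,
    GSP_CLASSES,
)
from .soilfun import (
    alpha_by_class,
    alpha_function_regression,
    beta_function_regression,
    bray_curtis,
    compare_alpha_by_health,
    zscore_functions,
)
from .titan import community_titan
from .traits import census_table, preference_census, trait_matrix

log = logging.getLogger("raretaxa")

STAGES = ("partition", "network", "oplsda", "traits", "titan", "soilfun")


@dataclasses.dataclass
class RunConfig:
    otu_table: str
    metadata: str
    env_table: str
    taxonomy: str | None = None
    output_dir: str = "raretaxa_out"
    seed: int = 0
    min_reads: int = 20
    rarefaction_depth: int | None = None  # None: minimum sample total
    filter_before_rarefy: bool = False
    abundance_mode: str = "pooled"
    r_threshold: float = 0.65
    alpha: float = 0.05
    vip_threshold: float = 1.0
    n_permutations: int = 200
    titan_variable: str | None = None  # None: first indicator
    titan_subset: str = "AT"
    min_split: int = 3
    titan_n_perm: int = 250
    titan_n_boot: int = 0
    stages: tuple[str, ...] = STAGES

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def validate_config(config: RunConfig) -> list[str]:
    """Return named problems (empty list means valid). Never raises."""
    problems: list[str] = []
    for attr in ("otu_table", "metadata", "env_table"):
        p = getattr(config, attr)
        if not Path(p).exists():
            problems.append(f"missing file for {attr}: {p}")
    if config.taxonomy and not Path(config.taxonomy).exists():
        problems.append(f"missing file for taxonomy: {config.taxonomy}")
    if not (0 < config.r_threshold < 1):
        problems.append("threshold outside (0,1): r_threshold")
    if not (0 < config.alpha < 1):
        problems.append("threshold outside (0,1): alpha")
    if config.min_reads < 1:
        problems.append("min_reads must be >= 1")
    for s in config.stages:
        if s not in STAGES:
            problems.append(f"unknown stage: {s}")
    if not problems:
        try:
            table = rio.read_otu_table(config.otu_table)
            meta = rio.read_metadata(config.metadata)
            env = rio.read_env_table(config.env_table)
            meta.check_covers(table)
            env.aligned_to(table)
        except Exception as exc:  # surface as a named problem, not a crash
            problems.append(f"input validation failed: {exc}")
    return problems


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.entries: list[dict] = []

    def add(self, path: Path, stage: str, seed: int | None = None, **params) -> None:
        self.entries.append(
            {
                "file": str(path.relative_to(self.outdir)),
                "stage": stage,
                "seed": seed,
                "parameters": params,
                "sha256": _sha256(path),
            }
        )

    def write(self) -> Path:
        p = self.outdir / "manifest.json"
        p.write_text(json.dumps(self.entries, indent=2, sort_keys=True))
        return p


def run_pipeline(config: RunConfig) -> list[dict]:
    """Execute the configured stages; returns the output manifest entries."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir)

    table = rio.read_otu_table(config.otu_table)
    meta = rio.read_metadata(config.metadata)
    env = rio.read_env_table(config.env_table)
    taxonomy = rio.read_taxonomy(config.taxonomy) if config.taxonomy else None

    rare_seed = child_seed(config.seed, 0)
    if config.filter_before_rarefy:
        n0 = table.shape[1]
        table = filter_low_count(table, config.min_reads)
        log.info("low-count filter: %d -> %d OTUs", n0, table.shape[1])
        table = rarefy(table, config.rarefaction_depth, seed=rare_seed)
    else:
        table = rarefy(table, config.rarefaction_depth, seed=rare_seed)
        n0 = table.shape[1]
        table = filter_low_count(table, config.min_reads)
        log.info("low-count filter: %d -> %d OTUs", n0, table.shape[1])
    proc_path = outdir / "processed_otu_table.tsv"
    rio.write_otu_table(table, proc_path)
    manifest.add(proc_path, "preprocess", seed=rare_seed,
                 min_reads=config.min_reads, depth=config.rarefaction_depth)

    partition = classify_gsp(table, abundance_mode=config.abundance_mode)

    if "partition" in config.stages:
        p = outdir / "gsp_partition.tsv"
        partition.table.to_csv(p, sep="\t", index_label="otu_id")
        manifest.add(p, "partition", abundance_mode=config.abundance_mode)
        ao = abundance_occupancy(partition)
        p = outdir / "abundance_occupancy.tsv"
        ao.to_csv(p, sep="\t", index_label="group")
        manifest.add(p, "partition")
        if taxonomy is not None:
            census = taxonomic_census(partition, taxonomy)
            p = outdir / "taxonomic_census.tsv"
            census.to_csv(p, sep="\t", index_label="taxa")
            manifest.add(p, "partition")
            fr = gsp_fractions(census)
            p = outdir / "gsp_fractions.tsv"
            pd.Series(fr).to_csv(p, sep="\t", header=["percent_of_otus"])
            manifest.add(p, "partition")

    if "network" in config.stages:
        net = build_network_from_table(
            table, partition, r_threshold=config.r_threshold, alpha=config.alpha
        )
        p = outdir / "network_edges.tsv"
        rio.write_network(net, p, format="edge-list")
        manifest.add(p, "network", r_threshold=config.r_threshold, alpha=config.alpha)
        p = outdir / "network.graphml"
        rio.write_network(net, p, format="graphml")
        manifest.add(p, "network")
        p = outdir / "link_decomposition.tsv"
        link_decomposition(net).to_csv(p, sep="\t")
        manifest.add(p, "network")
        node_metrics, graph_stats = topology_metrics(net)
        p = outdir / "node_metrics.tsv"
        node_metrics.to_csv(p, sep="\t", index_label="otu_id")
        manifest.add(p, "network")
        p = outdir / "graph_stats.tsv"
        pd.Series(graph_stats).to_csv(p, sep="\t", header=["value"])
        manifest.add(p, "network")
        try:
            cmp_ = compare_health_networks(
                table, partition, meta,
                r_threshold=config.r_threshold, alpha=config.alpha,
            )
            p = outdir / "health_network_stats.tsv"
            cmp_.stats.to_csv(p, sep="\t", index_label="health")
            manifest.add(p, "network")
        except ValueError as exc:
            log.warning("health comparison skipped: %s", exc)

    if "oplsda" in config.stages:
        seed = child_seed(config.seed, 1)
        rel = table.relative_abundance()
        y = meta.records.loc[table.sample_ids, "health"].to_numpy()
        rows = []
        hits = []
        for cls in GSP_CLASSES:
            otus = [o for o in partition.otus_in_class(cls) if o in rel.columns]
            if len(otus) < 2:
                continue
            X = rel[otus]
            model = fit_oplsda(X.to_numpy(), y, cv_seed=seed, feature_names=otus)
            rows.append({"gsp_class": cls, "R2Y": model.r2y, "Q2Y": model.q2y})
            sel = screen_differential(
                X, y, vip_threshold=config.vip_threshold,
                alpha=config.alpha, model=model,
            )
            sel.insert(0, "gsp_class", cls)
            hits.append(sel)
        p = outdir / "oplsda_summary.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        manifest.add(p, "oplsda", seed=seed)
        p = outdir / "differential_otus.tsv"
        hits = [h for h in hits if not h.empty]
        if hits:
            pd.concat(hits, ignore_index=True).to_csv(p, sep="\t", index=False)
        else:
            pd.DataFrame(
                columns=["gsp_class", "otu_id", "direction", "p", "VIP", "mean_diff"]
            ).to_csv(p, sep="\t", index=False)
        manifest.add(p, "oplsda", seed=seed, vip_threshold=config.vip_threshold)

    traits = None
    if "traits" in config.stages:
        traits = trait_matrix(table, env, alpha=config.alpha)
        p = outdir / "trait_matrix.tsv"
        traits.signs.to_csv(p, sep="\t", index_label="otu_id")
        manifest.add(p, "traits", alpha=config.alpha)
        census = preference_census(traits, partition)
        p = outdir / "preference_census.tsv"
        census_table(census).to_csv(p, sep="\t", index=False)
        manifest.add(p, "traits")

    if "titan" in config.stages:
        seed = child_seed(config.seed, 2)
        variable = config.titan_variable or env.indicators[0]
        gradient = env.aligned_to(table)[variable].to_numpy()
        otus = (
            partition.otus_in_class(config.titan_subset)
            if config.titan_subset in GSP_CLASSES
            else list(table.otu_ids)
        )
        sub = table.subset_otus([o for o in otus if o in table.counts.columns])
        res = community_titan(
            sub, gradient, min_split=config.min_split,
            n_perm=config.titan_n_perm, n_boot=config.titan_n_boot, seed=seed,
        )
        p = outdir / "titan_taxa.tsv"
        res.taxa.to_csv(p, sep="\t", index=False)
        manifest.add(p, "titan", seed=seed, variable=variable,
                     min_split=config.min_split)
        p = outdir / "titan_curves.tsv"
        res.curves.to_csv(p, sep="\t", index=False)
        manifest.add(p, "titan", seed=seed, variable=variable)

    if "soilfun" in config.stages:
        functions = zscore_functions(
            rio.EnvTable(env.aligned_to(table))
        )
        p = outdir / "soil_function_zscores.tsv"
        functions.z.to_csv(p, sep="\t", index_label="sample_id")
        manifest.add(p, "soilfun")
        alpha_df = alpha_by_class(table, partition)
        p = outdir / "alpha_diversity.tsv"
        alpha_df.to_csv(p, sep="\t", index_label="sample_id")
        manifest.add(p, "soilfun")
        fits = alpha_function_regression(alpha_df[list(GSP_CLASSES)], functions)
        p = outdir / "alpha_function_fits.tsv"
        fits.to_csv(p, sep="\t", index=False)
        manifest.add(p, "soilfun")
        beta_rows = []
        for cls in GSP_CLASSES:
            otus = [o for o in partition.otus_in_class(cls) if o in table.counts.columns]
            if len(otus) < 1:
                continue
            sub = table.subset_otus(otus)
            if (sub.counts.sum(axis=1) == 0).any():
                continue
            beta = bray_curtis(sub)
            beta_rows.append(beta_function_regression(beta, functions, gsp_class=cls))
        p = outdir / "beta_function_fits.tsv"
        pd.concat(beta_rows, ignore_index=True).to_csv(p, sep="\t", index=False)
        manifest.add(p, "soilfun")
        hm = compare_alpha_by_health(alpha_df["Whole"], meta)
        p = outdir / "alpha_health_test.tsv"
        pd.Series(hm).to_csv(p, sep="\t", header=["value"])
        manifest.add(p, "soilfun")

    manifest.write()
    return manifest.entries
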