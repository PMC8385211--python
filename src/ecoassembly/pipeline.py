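"""End-to-end orchestration: simulate/ingest -> rarefy -> classify ->
assembly nulls -> co-occurrence network -> report bundle.

Every stage output is a plain TSV (plus a JSON manifest echoing the
configuration and seeds), and the whole run is deterministic for a fixed
config + seed: outputs carry no timestamps and all randomness is derived
from the master seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import classify_all, subset_by_class
from .core import (
    CommunityTable,
    PhyloTree,
    ValidationError,
    match_tree_to_table,
    read_community_table,
    read_newick,
    relative_abundance,
    rarefy_counts,
    write_community_table,
    write_newick,
    cophenetic_matrix,
)
from .nullmodels import (
    beta_nti_matrix,
    niche_optima,
    partition_processes,
    phylo_signal_correlogram,
    rc_bray_matrix,
)
from .network import (
    build_network,
    edge_census,
    enrichment_labels,
    filter_min_sequences,
    modularity_partition,
    natural_connectivity,
    network_metrics,
    node_metrics,
    powerlaw_fit_r2,
    robustness_curve,
)
from .stats import alpha_diversity
from .synthetic import regime_preset, simulate_survey

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ReportBundle", "run_full_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a full run needs; loadable from YAML.

    Either ``preset`` (synthetic regime) or the three input paths must be
    given.  Null-model replicates default to 999; 199 is the documented
    fast mode.
    """

    seed: int
    outdir: str
    preset: str | None = None
    counts_path: str | None = None
    metadata_path: str | None = None
    tree_path: str | None = None
    n_otus: int = 300
    n_samples_per_group: int = 24
    depth: int | None = None
    null_reps: int = 999
    rare_cut: float = 1e-4
    abundant_cut: float = 1e-2
    r_threshold: float = 0.8
    p_threshold: float = 0.01
    min_total: int = 21
    alpha: float = 0.05
    subcommunities: tuple = ("CRT", "ART", "AT")
    run_network: bool = True
    run_phylo_signal: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.rare_cut < self.abundant_cut < 1:
            raise ValidationError("need 0 < rare_cut < abundant_cut < 1")
        if not 0 < self.r_threshold <= 1:
            raise ValidationError("r_threshold must be in (0, 1]")
        if not 0 < self.p_threshold <= 1:
            raise ValidationError("p_threshold must be in (0, 1]")
        if self.null_reps < 2:
            raise ValidationError("null_reps must be >= 2")
        if self.preset is None and not (
            self.counts_path and self.metadata_path and self.tree_path
        ):
            raise ValidationError("give either a preset or counts/metadata/tree paths")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class ReportBundle:
    outdir: Path
    manifest: dict

    @property
    def files(self) -> list[str]:
        return sorted(self.manifest["files"])


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_full_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute all stages in fixed order and write the report bundle.

    Stages: ingest/simulate -> rarefy -> relative abundance -> classify
    -> assembly nulls (total + per subcommunity) -> enrichment -> network
    -> robustness/modularity -> report.  Identical config + seed gives
    byte-identical outputs.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    t0 = time.monotonic()

    def register(name: str) -> Path:
        files.append(name)
        return out / name

    # -- stage: ingest or simulate ----------------------------------------
    if config.preset is not None:
        overrides = dict(
            n_otus=config.n_otus,
            n_samples_per_group=config.n_samples_per_group,
            seed=config.seed,
        )
        if config.depth is not None:
            overrides["depth"] = config.depth
        cfg = regime_preset(config.preset, **overrides)
        table, tree, truth = simulate_survey(cfg)
        write_community_table(table, register("counts.tsv"), register("metadata.tsv"))
        write_newick(tree, register("tree.nwk"))
        register("truth.json").write_text(truth.to_json() + "\n")
    else:
        table = read_community_table(config.counts_path, config.metadata_path)
        tree = read_newick(config.tree_path)
    tree = match_tree_to_table(tree, table)
    logger.info("ingest: %d OTUs x %d samples", *table.shape)

    # -- stage: rarefy + relative abundance --------------------------------
    depth = int(table.sample_totals().min())
    table = rarefy_counts(table, depth, seed=config.seed + 1)
    ra = relative_abundance(table)
    logger.info("rarefied to %d reads/sample", depth)

    # -- stage: alpha diversity --------------------------------------------
    alpha_rows = []
    for j, s in enumerate(table.sample_ids):
        a = alpha_diversity(table.counts[:, j])
        alpha_rows.append((s, table.sample_groups[s], a.richness, a.chao1, a.ace))
    _write_tsv(
        pd.DataFrame(alpha_rows, columns=["sample_id", "group", "richness", "chao1", "ace"]),
        register("alpha_diversity.tsv"),
    )

    # -- stage: classification ---------------------------------------------
    classification = classify_all(ra, rare_cut=config.rare_cut,
                                  abundant_cut=config.abundant_cut)
    _write_tsv(classification.to_frame(), register("classification.tsv"), index=True)
    _write_tsv(classification.summary(), register("classification_summary.tsv"), index=True)

    # -- stage: assembly nulls (total + subcommunities) ---------------------
    summaries = []
    for name in ("total", *config.subcommunities):
        if name == "total":
            sub = table
        else:
            try:
                sub = subset_by_class(table, classification, {name})
            except ValidationError:
                logger.warning("no OTUs in subcommunity %s; skipped", name)
                continue
            present = sub.counts.sum(axis=0) > 0
            if not present.all():
                sub = sub.subset_samples(
                    [s for s, ok in zip(sub.sample_ids, present) if ok]
                )
        if sub.shape[0] < 2 or len(sub.sample_ids) < 2:
            logger.warning("subcommunity %s too small; skipped", name)
            continue
        subtree = match_tree_to_table(tree, sub)
        bnti = beta_nti_matrix(sub, subtree, reps=config.null_reps,
                               seed=config.seed + 2)
        rc = rc_bray_matrix(sub, reps=config.null_reps, seed=config.seed + 3)
        pairs, summary = partition_processes(bnti, rc, sub.sample_groups)
        summary.insert(0, "community", name)
        summaries.append(summary)
        _write_tsv(pairs, register(f"assembly_pairs_{name}.tsv"))
        logger.info("assembly nulls done for %s (%d pairs)", name, len(pairs))
    _write_tsv(pd.concat(summaries, ignore_index=True),
               register("assembly_process_summary.tsv"))

    # -- stage: phylogenetic signal -----------------------------------------
    if config.run_phylo_signal and table.env is not None and "temperature" in table.env:
        optima = niche_optima(table, "temperature")
        D = cophenetic_matrix(tree)
        correlogram = phylo_signal_correlogram(
            optima, D, n_classes=5, permutations=min(config.null_reps, 999),
            seed=config.seed + 4,
        )
        _write_tsv(correlogram.to_frame(), register("phylo_signal_correlogram.tsv"))

    # -- stage: network ------------------------------------------------------
    network_summary = {}
    if config.run_network:
        filtered = filter_min_sequences(table, min_total=config.min_total)
        labels = enrichment_labels(filtered, alpha=config.alpha)
        net = build_network(
            relative_abundance(filtered),
            r_threshold=config.r_threshold,
            p_threshold=config.p_threshold,
            node_labels=labels,
            node_classes=classification.category,
        )
        _write_tsv(net.edge_table(), register("network_edges.tsv"))
        if net.n_edges > 0:
            nodes = node_metrics(net)
            partition, q = modularity_partition(net, seed=config.seed + 5)
            nodes["module"] = [partition[n] for n in nodes.index]
            nodes["label"] = [net.graph.nodes[n].get("label", "Others") for n in nodes.index]
            nodes["category"] = [net.graph.nodes[n].get("category", "") for n in nodes.index]
            _write_tsv(nodes, register("network_nodes.tsv"), index=True)
            metrics = network_metrics(net)
            fit = powerlaw_fit_r2(nodes["degree"].to_numpy())
            network_summary = {
                **metrics.to_dict(),
                "n_tested_otus": net.n_tested,
                "n_isolated": len(net.isolated),
                "modularity_q": q,
                "powerlaw_r2": fit.r_squared,
                "powerlaw_slope": fit.slope,
                "natural_connectivity": natural_connectivity(net),
            }
            _write_tsv(
                pd.DataFrame(sorted(network_summary.items()), columns=["metric", "value"]),
                register("network_summary.tsv"),
            )
            curve = robustness_curve(net, strategy="random", reps=20,
                                     seed=config.seed + 6)
            _write_tsv(curve.to_frame(), register("network_robustness.tsv"))
            _write_tsv(edge_census(net, labels), register("network_edge_census.tsv"))
        else:
            logger.warning("network has no edges at |rho| > %.2f", config.r_threshold)

    # -- stage: manifest -----------------------------------------------------
    manifest = {
        "tool": {"name": "ecoassembly", "version": __version__},
        "config": asdict(config),
        "depth": depth,
        "files": sorted(files),
        "network_summary": {k: (None if isinstance(v, float) and np.isnan(v) else v)
                            for k, v in network_summary.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    missing = [f for f in files if not (out / f).exists()]
    if missing:
        raise ValidationError(f"manifest references missing files: {missing}")
    logger.info("pipeline finished in %.1f s", time.monotonic() - t0)
    return ReportBundle(outdir=out, manifest=manifest)
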