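"""End-to-end orchestration: simulate/load -> orthology -> profiles ->
clustering -> association -> tree congruence, with TSV/Newick reports.

The default thresholds are the analysis chain's canonical values: 70% RBH
query coverage, core/Core-70 occupancy at 1.0/0.70, 70% PSSM coverage and 10%
domain overlap, cut scan starting at k = 3, alpha = 0.05, 80% focal presence
for adaptive functions, and support threshold 80.  Every override is recorded
in the run log.  All persisted outputs are deterministic given the
configuration and seed (no timestamps), so identical runs produce identical
checksums.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
import time
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import assoc as assoc_mod
from . import cluster as cluster_mod
from . import orthology as orth
from . import profiles as prof
from . import simulate as sim
from . import trees as trees_mod
from .exceptions import PipelineError, ValidationError

__all__ = [
    "PipelineConfig",
    "Report",
    "TreeComparison",
    "run_pipeline",
    "compare_trees_report",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Inputs, thresholds and options for a full pipeline run."""

    # either a simulation block ...
    simulate: Optional[sim.SimulationConfig] = None
    # ... or paths to user data
    hits: Optional[str] = None
    gene_map: Optional[str] = None
    assignments: Optional[str] = None
    environments: Optional[str] = None
    reference_tree: Optional[str] = None

    min_coverage: float = 0.70
    core_threshold: float = 0.70
    min_pssm_coverage: float = 0.70
    max_overlap: float = 0.10
    k_min: int = 3
    k_max: Optional[int] = None
    alpha: float = 0.05
    min_presence: float = 0.80
    support_threshold: int = 80
    linkage_methods: Sequence[str] = cluster_mod.LINKAGE_METHODS
    seed: int = 0
    outdir: Optional[str] = None

    def __post_init__(self):
        if self.k_min < 2:
            raise ValidationError("k_min must be >= 2")
        unknown = set(self.linkage_methods) - set(cluster_mod.LINKAGE_METHODS)
        if unknown:
            raise ValidationError(f"unknown linkage methods: {sorted(unknown)}")
        if self.simulate is None and self.hits is None:
            raise ValidationError("either a simulate block or input paths required")

    _DEFAULTS = {
        "min_coverage": 0.70, "core_threshold": 0.70,
        "min_pssm_coverage": 0.70, "max_overlap": 0.10, "k_min": 3,
        "alpha": 0.05, "min_presence": 0.80, "support_threshold": 80,
    }

    def overrides(self) -> Dict[str, object]:
        return {
            name: getattr(self, name)
            for name, default in self._DEFAULTS.items()
            if getattr(self, name) != default
        }

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = sim.SimulationConfig(**raw["simulate"])
        if "linkage_methods" in raw:
            raw["linkage_methods"] = tuple(raw["linkage_methods"])
        return cls(**raw)


@dataclasses.dataclass
class TreeComparison:
    """Square RF matrix plus per-tree supported-node counts."""

    rf_matrix: pd.DataFrame
    supported_nodes: pd.Series


@dataclasses.dataclass
class Report:
    """Computed results of a pipeline run (all also persisted as TSV)."""

    outdir: Optional[Path]
    genomes: List[str]
    n_core: int
    n_core70: int
    gss: orth.GSSMatrix
    nj_tree: dendropy.Tree
    ac_by_method: Dict[str, float]
    best_method: str
    merge_tree: cluster_mod.MergeTree
    partition: pd.Series
    silhouette: pd.Series
    scan: assoc_mod.ScanResult
    adaptive: pd.DataFrame
    tree_comparison: TreeComparison
    ari_environment: Optional[float] = None
    ari_clades: Optional[float] = None
    planted_truth: Optional[dict] = None


def compare_trees_report(
    trees: Mapping[str, dendropy.Tree], support_threshold: int = 80
) -> TreeComparison:
    """Pairwise RF matrix (zero diagonal) and supported-node counts."""
    names = list(trees)
    rf = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d = trees_mod.robinson_foulds(trees[a], trees[b])
            rf.loc[a, b] = rf.loc[b, a] = d
    supports = pd.Series(
        {name: trees_mod.count_supported_nodes(t, support_threshold)
         for name, t in trees.items()},
        name=f"nodes_support_ge_{support_threshold}",
    )
    return TreeComparison(rf_matrix=rf, supported_nodes=supports)


def _environment_series(path) -> pd.Series:
    table = pd.read_csv(path, sep="\t", header=None,
                        names=["genome_id", "environment"])
    env = table.set_index("genome_id")["environment"]
    unknown = ~env.isin(sim.ENVIRONMENTS)
    if unknown.any():
        logger.warning(
            "mapping %d unrecognized environment label(s) to Unknown",
            int(unknown.sum()),
        )
        env[unknown] = "Unknown"
    return env


def run_pipeline(config: PipelineConfig) -> Report:
    """Execute the full analysis chain and persist all stage outputs."""
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage: %s", name)
        return _Stage(name, outdir)

    truth: Optional[dict] = None
    reference_tree = None
    with stage("inputs"):
        if config.simulate is not None:
            cfg = config.simulate
            tree = sim.simulate_tree(cfg.n_genomes, seed=cfg.stage_seed("tree"),
                                     birth_rate=cfg.birth_rate)
            envassign = sim.assign_environments(
                tree, cfg.n_environments, cfg.polyphyly_events,
                seed=cfg.stage_seed("environments"),
            )
            genomeset = sim.evolve_gene_content(tree, envassign, cfg)
            hits = sim.synthesize_hit_table(genomeset, tree, cfg)
            assignments = sim.synthesize_assignments(genomeset, cfg)
            env = pd.Series(envassign.labels)
            reference_tree = tree
            truth = {
                "pools": genomeset.pools,
                "clade_labels": envassign.clade_labels,
                "reassigned": envassign.reassigned,
            }
        else:
            gene_map = pd.read_csv(config.gene_map, sep="\t", header=None) \
                if config.gene_map else None
            hits = orth.parse_hit_table(config.hits, gene_map=gene_map)
            assignments = prof.read_assignments(config.assignments)
            env = _environment_series(config.environments)
            if config.reference_tree:
                reference_tree = trees_mod.read_newick(config.reference_tree)
        genomes = sorted(env.index)

    with stage("orthology"):
        if "qgenome" not in hits.columns:
            hits = orth._ensure_genomes(hits)
        rbh = orth.all_pairwise_rbh(hits, min_coverage=config.min_coverage)
        core = orth.build_ortholog_groups(rbh, genomes, occupancy_threshold=1.0)
        core70 = orth.build_ortholog_groups(
            rbh, genomes, occupancy_threshold=config.core_threshold
        )
        gss = orth.compute_gss(rbh, genomes)
        nj_tree = orth.neighbor_joining(gss.distance)
        if outdir:
            rbh.to_csv(outdir / "rbh_pairs.tsv", sep="\t", index=False)
            core70.table.to_csv(outdir / "ortholog_groups.tsv", sep="\t", index=False)
            gss.gss.to_csv(outdir / "gss_matrix.tsv", sep="\t")
            trees_mod.write_newick(nj_tree, outdir / "gss_nj_tree.nwk")

    with stage("profiles"):
        filtered = prof.filter_assignments(
            assignments, min_pssm_coverage=config.min_pssm_coverage,
            max_overlap=config.max_overlap,
        )
        profiles = prof.build_profiles(filtered, genomes=genomes)
        jd = prof.profile_distance_matrix(profiles)
        if outdir:
            pairs = [(g, f) for g in sorted(profiles) for f in sorted(profiles[g])]
            pd.DataFrame(pairs, columns=["genome_id", "function_id"]).to_csv(
                outdir / "profiles.tsv", sep="\t", index=False
            )
            jd.to_csv(outdir / "jaccard_distance.tsv", sep="\t")

    with stage("clustering"):
        merge_trees = {
            m: cluster_mod.hierarchical_cluster(jd, method=m)
            for m in config.linkage_methods
        }
        ac_by_method = {
            m: cluster_mod.agglomerative_coefficient(mt)
            for m, mt in merge_trees.items()
        }
        best_method = max(sorted(ac_by_method), key=ac_by_method.get)
        merge_tree = merge_trees[best_method]
        partition = cluster_mod.cut_dendrogram(merge_tree, config.k_min)
        silhouette = cluster_mod.silhouette_values(jd, partition)
        if outdir:
            merge_tree.to_frame().to_csv(outdir / "merge_table.tsv", sep="\t",
                                         index=False)
            partition.rename("cluster").to_csv(outdir / "partition.tsv", sep="\t")
            silhouette.to_csv(outdir / "silhouette.tsv", sep="\t")

    with stage("association"):
        scan = assoc_mod.scan_cluster_environment_associations(
            merge_tree, env, k_min=config.k_min, k_max=config.k_max,
            alpha=config.alpha,
        )
        adaptive = assoc_mod.find_adaptive_functions(
            profiles, partition, min_presence=config.min_presence,
            alpha=config.alpha,
        )
        if outdir:
            scan.table.to_csv(outdir / "associations.tsv", sep="\t", index=False)
            adaptive.to_csv(outdir / "adaptive_functions.tsv", sep="\t", index=False)

    with stage("congruence"):
        named = {"gss_nj": nj_tree,
                 "content_dendrogram": trees_mod.mergetree_to_phylotree(merge_tree)}
        if reference_tree is not None:
            named["reference"] = reference_tree
        comparison = compare_trees_report(named, config.support_threshold)
        ari_env = ari_clades = None
        if truth is not None:
            ari_env = cluster_mod.adjusted_rand_index(partition, env.to_dict())
            ari_clades = cluster_mod.adjusted_rand_index(
                partition, truth["clade_labels"]
            )
        if outdir:
            comparison.rf_matrix.to_csv(outdir / "rf_matrix.tsv", sep="\t")
            comparison.supported_nodes.to_csv(outdir / "supported_nodes.tsv",
                                              sep="\t")

    report = Report(
        outdir=outdir, genomes=genomes, n_core=len(core), n_core70=len(core70),
        gss=gss, nj_tree=nj_tree, ac_by_method=ac_by_method,
        best_method=best_method, merge_tree=merge_tree, partition=partition,
        silhouette=silhouette, scan=scan, adaptive=adaptive,
        tree_comparison=comparison, ari_environment=ari_env,
        ari_clades=ari_clades, planted_truth=truth,
    )
    if outdir:
        _write_summary(report, config)
    return report


class _Stage:
    def __init__(self, name, outdir):
        self.name = name
        self.outdir = outdir
        self.start = time.perf_counter()

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        elapsed = time.perf_counter() - self.start
        if exc is not None:
            raise PipelineError(self.name, str(exc), self.outdir) from exc
        logger.info("stage %s done in %.2fs", self.name, elapsed)
        return False


def _write_summary(report: Report, config: PipelineConfig) -> None:
    outdir = report.outdir
    sig = report.scan.significant()
    lines = [
        "# convergene run summary",
        "",
        f"- genomes: {len(report.genomes)}",
        f"- core ortholog groups (occupancy 1.0): {report.n_core}",
        f"- Core-{int(config.core_threshold * 100)} ortholog groups: "
        f"{report.n_core70}",
        "- agglomerative coefficients: "
        + ", ".join(f"{m}={v:.4f}" for m, v in sorted(report.ac_by_method.items())),
        f"- best linkage by AC: {report.best_method}",
        f"- mean silhouette at k={config.k_min}: "
        f"{float(report.silhouette.mean()):.4f}",
        f"- significant cluster-environment associations: {len(sig)} "
        f"(last significant cut: {report.scan.last_significant_k})",
        f"- adaptive functions reported: {len(report.adaptive)}",
        "",
        "## Tree congruence (RF symmetric differences)",
        "",
        report.tree_comparison.rf_matrix.to_csv(sep="\t").rstrip(),
        "",
        "## Supported nodes",
        "",
        report.tree_comparison.supported_nodes.to_csv(sep="\t").rstrip(),
    ]
    if report.ari_environment is not None:
        lines.insert(
            9,
            f"- ARI(content cut, environments) = {report.ari_environment:.4f}; "
            f"ARI(content cut, true clades) = {report.ari_clades:.4f}",
        )
    (outdir / "summary.md").write_text("\n".join(lines) + "\n")
    log_lines = [
        f"convergene {__version__}",
        f"seed: {config.seed}",
        f"thresholds: min_coverage={config.min_coverage}, "
        f"core_threshold={config.core_threshold}, "
        f"min_pssm_coverage={config.min_pssm_coverage}, "
        f"max_overlap={config.max_overlap}, k_min={config.k_min}, "
        f"k_max={config.k_max}, alpha={config.alpha}, "
        f"min_presence={config.min_presence}, "
        f"support_threshold={config.support_threshold}",
    ]
    overrides = config.overrides()
    if overrides:
        log_lines.append(f"overridden defaults: {overrides}")
    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
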