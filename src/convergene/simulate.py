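"""Synthetic genomes evolving on a phylogeny with environment-driven gene gain.

The generator emulates the statistical structure the downstream analysis
assumes: a pure-birth (Yule) phylogeny; environment labels that are clade-wise
except for a controlled number of "polyphyly" reassignments; gene-family
content evolving by vertical gain/loss under an infinitely-many-genes model
(every gain is a brand-new family, so homoplasy is attributable solely to the
planted environment pools); disjoint per-environment pools of convergently
acquired families; and an all-vs-all hit table whose bitscores decay
exponentially with patristic distance, the signal the genomic similarity
score (GSS) integrates.

Everything is deterministic given ``SimulationConfig.seed``: the seed is split
into independent per-stage substreams (tree, environments, content, hits,
assignments) so stages can be regenerated independently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import random
import warnings
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Tuple

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .exceptions import ValidationError

__all__ = [
    "ENVIRONMENTS",
    "SimulationConfig",
    "EnvironmentAssignment",
    "GenomeSet",
    "simulate_tree",
    "assign_environments",
    "evolve_gene_content",
    "synthesize_hit_table",
    "synthesize_assignments",
    "write_fixture_bundle",
    "HIT_COLUMNS",
]

#: Closed environment vocabulary (isolation-source classes).
ENVIRONMENTS = ("Aquatic", "Terrestrial", "Facultative", "Specialized", "Unknown")

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "qcovs",
]

_STAGES = ("tree", "environments", "content", "hits", "assignments")


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of the generative model.

    Defaults are the package's reference study conditions: 60 genomes in three
    environment classes of comparable size (mirroring the balanced
    Terrestrial/Facultative/Aquatic classes of real isolate collections), a
    large shared core, a moderately labile accessory genome, and strong
    convergent acquisition from per-environment pools.
    """

    n_genomes: int = 60
    n_environments: int = 3
    #: tips reassigned into each environment from other clades
    polyphyly_events: int = 3
    core_size: int = 150
    ancestral_accessory: int = 80
    #: novel-family gains per unit branch length (Poisson rate)
    gain_rate: float = 0.4
    #: per-family loss rate per unit branch length
    loss_rate: float = 0.15
    #: families in each environment's convergent-transfer pool
    pool_size: int = 30
    #: probability a tip acquires each family of its environment's pool
    pool_gain_prob: float = 0.9
    #: bitscore decay rate per unit patristic distance
    bitscore_decay: float = 0.05
    #: Gaussian noise s.d. added to synthetic bitscores
    noise_sd: float = 5.0
    birth_rate: float = 1.0
    #: query-coverage threshold the downstream RBH filter will apply
    coverage_floor: float = 0.70
    #: fraction of families whose alignments fall below the coverage floor
    low_coverage_frac: float = 0.10
    #: spurious cross-family hits, as a fraction of true directed hits
    spurious_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        counts = {
            "n_genomes": self.n_genomes,
            "n_environments": self.n_environments,
            "polyphyly_events": self.polyphyly_events,
            "core_size": self.core_size,
            "ancestral_accessory": self.ancestral_accessory,
            "pool_size": self.pool_size,
        }
        for name, value in counts.items():
            if int(value) != value or value < 0:
                raise ValidationError(f"{name} must be a non-negative integer")
        probs = {
            "pool_gain_prob": self.pool_gain_prob,
            "coverage_floor": self.coverage_floor,
            "low_coverage_frac": self.low_coverage_frac,
            "spurious_rate": self.spurious_rate,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        rates = {
            "gain_rate": self.gain_rate,
            "loss_rate": self.loss_rate,
            "bitscore_decay": self.bitscore_decay,
            "noise_sd": self.noise_sd,
            "birth_rate": self.birth_rate,
        }
        for name, value in rates.items():
            if value < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_genomes < 2:
            raise ValidationError("n_genomes must be >= 2")
        if not 1 <= self.n_environments <= min(self.n_genomes, len(ENVIRONMENTS)):
            raise ValidationError(
                "n_environments must be between 1 and "
                f"min(n_genomes, {len(ENVIRONMENTS)})"
            )

    def substream(self, stage: str) -> np.random.Generator:
        """Independent per-stage random generator derived from the seed."""
        idx = _STAGES.index(stage)
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(idx,))
        )

    def stage_seed(self, stage: str) -> int:
        idx = _STAGES.index(stage)
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(idx,))
        return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclasses.dataclass
class EnvironmentAssignment:
    """Genome -> environment labels plus the planted ground truth.

    ``clade_labels`` is the purely clade-wise assignment before polyphyly
    reassignments; ``reassigned`` maps each moved tip to its (old, new)
    labels.
    """

    labels: Dict[str, str]
    clade_labels: Dict[str, str]
    reassigned: Dict[str, Tuple[str, str]]

    def counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for env in self.labels.values():
            out[env] = out.get(env, 0) + 1
        return out


@dataclasses.dataclass
class GenomeSet:
    """Per-genome gene-family presence plus the planted truths."""

    genomes: List[str]
    profiles: Dict[str, FrozenSet[str]]
    #: one row per gene: gene_id, genome_id, family_id
    genes: pd.DataFrame
    #: environment -> planted pool family IDs (disjoint across environments)
    pools: Dict[str, List[str]]
    core_families: List[str]

    def gene_lookup(self) -> Dict[Tuple[str, str], str]:
        """(genome_id, family_id) -> gene_id."""
        return {
            (g, f): gid
            for gid, g, f in self.genes[["gene_id", "genome_id", "family_id"]].itertuples(
                index=False
            )
        }

    def presence_frame(self) -> pd.DataFrame:
        families = sorted(set().union(*self.profiles.values()) if self.profiles else set())
        data = {
            g: [int(f in self.profiles[g]) for f in families] for g in self.genomes
        }
        return pd.DataFrame(data, index=families).T


def simulate_tree(n_tips: int, seed: int, birth_rate: float = 1.0) -> dendropy.Tree:
    """Pure-birth (Yule) tree with ``n_tips`` extant leaves.

    Leaves are relabelled ``G001..Gnnn`` in traversal order.  Deterministic
    given ``(n_tips, seed, birth_rate)``.
    """
    if n_tips < 2:
        raise ValidationError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValidationError("birth_rate must be > 0")
    rng = random.Random(int(seed))
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0, num_extant_tips=n_tips, rng=rng
    )
    width = max(3, len(str(n_tips)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"G{i:0{width}d}"
    tree.seed_node.edge.length = None  # drop the stem edge
    return tree


def _clade_sizes(tree: dendropy.Tree) -> Dict[int, int]:
    sizes: Dict[int, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sizes[id(node)] = 1
        else:
            sizes[id(node)] = sum(sizes[id(c)] for c in node.child_nodes())
    return sizes


def _balanced_clade_partition(tree: dendropy.Tree, k: int) -> List[List[str]]:
    """Partition the leaves into ``k`` monophyletic blocks, maximizing the
    smallest block (tree DP).  Deterministic."""
    sizes = _clade_sizes(tree)
    memo: Dict[Tuple[int, int], Tuple[float, Optional[list]]] = {}

    def best(node, j) -> Tuple[float, Optional[list]]:
        key = (id(node), j)
        if key in memo:
            return memo[key]
        if j == 1:
            result = (sizes[id(node)], [node])
        elif node.is_leaf() or j > sizes[id(node)]:
            result = (float("-inf"), None)
        else:
            children = node.child_nodes()
            # states[b] = (value, blocks) using a prefix of children, b blocks
            states: Dict[int, Tuple[float, list]] = {0: (float("inf"), [])}
            for idx, child in enumerate(children):
                remaining = len(children) - idx - 1
                new_states: Dict[int, Tuple[float, list]] = {}
                for used, (val, blocks) in states.items():
                    for jc in range(1, j - used - remaining + 1):
                        cval, cblocks = best(child, jc)
                        if cblocks is None:
                            continue
                        cand = (min(val, cval), blocks + cblocks)
                        prev = new_states.get(used + jc)
                        if prev is None or cand[0] > prev[0]:
                            new_states[used + jc] = cand
                states = new_states
            result = states.get(j, (float("-inf"), None))
        memo[key] = result
        return result

    value, blocks = best(tree.seed_node, k)
    if blocks is None:
        raise ValidationError(f"cannot cut tree into {k} clades")
    leaf_sets = []
    for node in blocks:
        leaf_sets.append([lf.taxon.label for lf in node.leaf_iter()])
    return leaf_sets


def assign_environments(
    tree: dendropy.Tree,
    n_environments: int,
    polyphyly_events: int,
    seed: int,
) -> EnvironmentAssignment:
    """Clade-wise environment labels with controlled polyphyly.

    The leaves are first partitioned into ``n_environments`` monophyletic
    blocks (chosen to be as balanced as the tree shape allows, emulating the
    comparably sized isolation-source classes of real collections).  Then, for
    each environment in turn, ``polyphyly_events`` random tips currently
    carrying a different label are reassigned to it, making the recipient
    environment polyphyletic.  Reassignments never empty a donor environment.
    """
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if not 1 <= n_environments <= len(tips):
        raise ValidationError("n_environments must be between 1 and n_tips")
    if n_environments > len(ENVIRONMENTS):
        raise ValidationError(
            f"at most {len(ENVIRONMENTS)} environment classes are available"
        )
    blocks = _balanced_clade_partition(tree, n_environments)
    order = {tip: i for i, tip in enumerate(tips)}
    blocks.sort(key=lambda b: min(order[t] for t in b))
    labels = {}
    for env, block in zip(ENVIRONMENTS, blocks):
        for tip in block:
            labels[tip] = env
    clade_labels = dict(labels)
    reassigned: Dict[str, Tuple[str, str]] = {}
    if n_environments > 1 and polyphyly_events > 0:
        rng = random.Random(int(seed))
        for env in ENVIRONMENTS[:n_environments]:
            for _ in range(polyphyly_events):
                counts: Dict[str, int] = {}
                for lab in labels.values():
                    counts[lab] = counts.get(lab, 0) + 1
                candidates = [
                    t for t in tips
                    if labels[t] != env and counts[labels[t]] > 1 and t not in reassigned
                ]
                if not candidates:
                    break
                tip = rng.choice(candidates)
                reassigned[tip] = (labels[tip], env)
                labels[tip] = env
    return EnvironmentAssignment(labels=labels, clade_labels=clade_labels,
                                 reassigned=reassigned)


def evolve_gene_content(
    tree: dendropy.Tree,
    envmap: Mapping[str, str] | EnvironmentAssignment,
    config: SimulationConfig,
) -> GenomeSet:
    """Evolve gene-family presence along ``tree`` with environment pools.

    The ancestral genome holds ``core_size`` universal families plus
    ``ancestral_accessory`` accessory families.  Along each branch of length
    ``l``, ``Poisson(gain_rate * l)`` brand-new families are gained and every
    present accessory family is lost with probability ``1 - exp(-loss_rate *
    l)``; core families are never lost.  At each tip in environment ``e``,
    each family of the disjoint pool ``P_e`` is acquired independently with
    probability ``pool_gain_prob``.
    """
    labels = envmap.labels if isinstance(envmap, EnvironmentAssignment) else dict(envmap)
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if set(tips) != set(labels):
        raise ValidationError("tree tips and environment labels differ")
    rng = config.substream("content")
    core = [f"CORE{i:05d}" for i in range(1, config.core_size + 1)]
    ancestral_acc = [f"ACC{i:05d}" for i in range(1, config.ancestral_accessory + 1)]
    envs = [e for e in ENVIRONMENTS if e in set(labels.values())]
    pools = {
        env: [f"POOL-{env}-{i:04d}" for i in range(1, config.pool_size + 1)]
        for env in envs
    }
    core_set = frozenset(core)
    profiles: Dict[str, FrozenSet[str]] = {}
    node_profile: Dict[int, FrozenSet[str]] = {}
    gain_counter = 0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            prof = frozenset(core) | frozenset(ancestral_acc)
        else:
            parent = node_profile[id(node.parent_node)]
            length = node.edge.length or 0.0
            accessory = sorted(parent - core_set)
            keep = rng.random(len(accessory)) < np.exp(-config.loss_rate * length)
            survivors = {f for f, k in zip(accessory, keep) if k}
            n_gain = int(rng.poisson(config.gain_rate * length))
            gained = {
                f"GAIN{gain_counter + i:06d}" for i in range(1, n_gain + 1)
            }
            gain_counter += n_gain
            prof = frozenset(core) | frozenset(survivors) | frozenset(gained)
        node_profile[id(node)] = prof
        if node.is_leaf():
            tip = node.taxon.label
            pool = pools[labels[tip]]
            acquired = rng.random(len(pool)) < config.pool_gain_prob
            profiles[tip] = prof | {f for f, a in zip(pool, acquired) if a}
    rows = []
    for genome in tips:
        for i, family in enumerate(sorted(profiles[genome]), start=1):
            rows.append((f"{genome}|g{i:05d}", genome, family))
    genes = pd.DataFrame(rows, columns=["gene_id", "genome_id", "family_id"])
    return GenomeSet(
        genomes=tips,
        profiles=profiles,
        genes=genes,
        pools=pools,
        core_families=core,
    )


def _patristic_matrix(tree: dendropy.Tree, tips: List[str]) -> np.ndarray:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(tips)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[tips[i]], taxa[tips[j]])
            dist[i, j] = dist[j, i] = d
    return dist


def synthesize_hit_table(
    genomes: GenomeSet,
    tree: dendropy.Tree,
    config: SimulationConfig,
) -> pd.DataFrame:
    """All-vs-all hit table in the 13-column BLAST tabular dialect.

    For every genome pair and shared family, reciprocal directed hits are
    emitted with ``bitscore = self_score * exp(-bitscore_decay * patristic) +
    N(0, noise_sd)``.  Query coverage has a family-level base (a
    ``low_coverage_frac`` fraction of families aligns below the downstream
    coverage floor) plus small per-hit jitter, so the coverage filter removes
    whole families rather than scattering random holes through the core.
    Self-hits are emitted at the self score; a ``spurious_rate`` fraction of
    low-scoring cross-family hits exercises best-hit tie-breaking.
    """
    rng = config.substream("hits")
    tips = genomes.genomes
    families = sorted(set().union(*genomes.profiles.values()))
    fam_index = {f: i for i, f in enumerate(families)}
    nfam = len(families)
    lengths = rng.integers(150, 601, size=nfam).astype(float)
    self_scores = 2.0 * lengths
    low = rng.random(nfam) < config.low_coverage_frac
    base_cov = rng.uniform(0.75, 1.0, size=nfam)
    base_cov[low] = rng.uniform(0.40, config.coverage_floor - 0.02, size=int(low.sum()))
    lookup = genomes.gene_lookup()
    dist = _patristic_matrix(tree, tips)

    q_parts, s_parts = [], []
    score_parts, len_parts, cov_parts, pid_parts = [], [], [], []

    def emit(qgenes, sgenes, scores, lens, covs, pids):
        q_parts.append(qgenes)
        s_parts.append(sgenes)
        score_parts.append(scores)
        len_parts.append(lens)
        cov_parts.append(covs)
        pid_parts.append(pids)

    for i in range(len(tips)):
        for j in range(i + 1, len(tips)):
            shared = sorted(genomes.profiles[tips[i]] & genomes.profiles[tips[j]])
            if not shared:
                continue
            idx = np.array([fam_index[f] for f in shared])
            factor = np.exp(-config.bitscore_decay * dist[i, j])
            base = self_scores[idx] * factor
            genes_i = np.array([lookup[(tips[i], f)] for f in shared])
            genes_j = np.array([lookup[(tips[j], f)] for f in shared])
            pid = np.clip(100.0 * factor, 15.0, 100.0).repeat(len(shared))
            for qg, sg in ((genes_i, genes_j), (genes_j, genes_i)):
                scores = base + rng.normal(0.0, config.noise_sd, size=len(shared))
                covs = np.clip(
                    base_cov[idx] + rng.uniform(-0.02, 0.02, size=len(shared)), 0.0, 1.0
                )
                emit(qg, sg, np.maximum(scores, 1.0), lengths[idx], covs, pid)

    # self-hits
    gene_ids = genomes.genes["gene_id"].to_numpy()
    gene_fam = np.array([fam_index[f] for f in genomes.genes["family_id"]])
    emit(
        gene_ids, gene_ids, self_scores[gene_fam], lengths[gene_fam],
        np.ones(len(gene_ids)), np.full(len(gene_ids), 100.0),
    )

    n_true = sum(len(p) for p in q_parts)
    n_spur = int(config.spurious_rate * n_true)
    if n_spur:
        qi = rng.integers(0, len(gene_ids), size=n_spur)
        si = rng.integers(0, len(gene_ids), size=n_spur)
        ok = (gene_fam[qi] != gene_fam[si])
        qi, si = qi[ok], si[ok]
        emit(
            gene_ids[qi], gene_ids[si],
            rng.uniform(20.0, 40.0, size=len(qi)),
            lengths[gene_fam[qi]],
            rng.uniform(config.coverage_floor, 1.0, size=len(qi)),
            rng.uniform(20.0, 35.0, size=len(qi)),
        )

    qseqid = np.concatenate(q_parts)
    sseqid = np.concatenate(s_parts)
    bitscore = np.round(np.concatenate(score_parts), 1)
    length = np.concatenate(len_parts).astype(int)
    qcovs = np.round(np.concatenate(cov_parts), 4)
    pident = np.round(np.concatenate(pid_parts), 2)
    mismatch = np.round(length * (1.0 - pident / 100.0)).astype(int)
    qend = np.maximum(1, np.round(length * qcovs)).astype(int)
    evalue = 10.0 ** (-np.clip(bitscore / 5.0, 0.0, 180.0))
    table = pd.DataFrame(
        {
            "qseqid": qseqid,
            "sseqid": sseqid,
            "pident": pident,
            "length": length,
            "mismatch": mismatch,
            "gapopen": np.zeros(len(qseqid), dtype=int),
            "qstart": np.ones(len(qseqid), dtype=int),
            "qend": qend,
            "sstart": np.ones(len(qseqid), dtype=int),
            "send": qend,
            "evalue": evalue,
            "bitscore": bitscore,
            "qcovs": qcovs,
        }
    )
    return table


def synthesize_assignments(genomes: GenomeSet, config: SimulationConfig) -> pd.DataFrame:
    """Function-assignment table (protein -> function) mirroring family truth.

    Every gene is assigned its family as its function at high PSSM coverage.
    A small fraction of proteins additionally carries a lower-scoring,
    heavily overlapping secondary assignment (removed by the overlap filter)
    or a non-overlapping secondary domain (retained), so the downstream
    filtering rules operate on realistic input.  Sub-threshold PSSM coverage
    is exercised by dedicated unit fixtures, not planted here, so that family
    presence in the profiles reflects the planted gene content.
    """
    rng = config.substream("assignments")
    genes = genomes.genes
    n = len(genes)
    lengths = rng.integers(150, 601, size=n)
    scores = np.round(rng.uniform(200.0, 1200.0, size=n), 1)
    coverage = np.round(rng.uniform(0.75, 1.0, size=n), 4)
    table = pd.DataFrame(
        {
            "protein_id": genes["gene_id"].to_numpy(),
            "function_id": genes["family_id"].to_numpy(),
            "score": scores,
            "pssm_coverage": coverage,
            "qstart": np.ones(n, dtype=int),
            "qend": lengths,
        }
    )
    dup = rng.random(n) < 0.03
    dup_rows = table[dup].copy()
    dup_rows["function_id"] = "XOVL-" + dup_rows["function_id"]
    dup_rows["score"] = np.round(dup_rows["score"] * 0.5, 1)
    ext = rng.random(n) < 0.01
    ext_rows = table[ext].copy()
    ext_rows["function_id"] = "XEXT-" + ext_rows["function_id"]
    ext_rows["score"] = np.round(ext_rows["score"] * 0.8, 1)
    ext_rows["qstart"] = ext_rows["qend"] + 10
    ext_rows["qend"] = ext_rows["qend"] + 150
    return pd.concat([table, dup_rows, ext_rows], ignore_index=True)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def write_fixture_bundle(outdir, config: SimulationConfig) -> dict:
    """Simulate a full dataset and write it as a six-file text bundle.

    Files: Newick tree, environment TSV, presence-matrix TSV, 13-column hit
    table TSV, function-assignment TSV, and a JSON manifest recording the
    configuration, per-file checksums and the planted truths (pool
    memberships, reassigned tips, clade labels).
    """
    from . import trees as trees_mod

    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {outdir}: {exc}") from exc

    tree = simulate_tree(config.n_genomes, seed=config.stage_seed("tree"),
                         birth_rate=config.birth_rate)
    env = assign_environments(
        tree, config.n_environments, config.polyphyly_events,
        seed=config.stage_seed("environments"),
    )
    genomes = evolve_gene_content(tree, env, config)
    hits = synthesize_hit_table(genomes, tree, config)
    assignments = synthesize_assignments(genomes, config)

    paths = {
        "tree": outdir / "tree.nwk",
        "environments": outdir / "environments.tsv",
        "presence_matrix": outdir / "presence_matrix.tsv",
        "hits": outdir / "hits.tsv",
        "assignments": outdir / "assignments.tsv",
    }
    trees_mod.write_newick(tree, paths["tree"])
    with open(paths["environments"], "w") as handle:
        for genome in genomes.genomes:
            handle.write(f"{genome}\t{env.labels[genome]}\n")
    genomes.presence_frame().to_csv(paths["presence_matrix"], sep="\t",
                                    index_label="genome_id")
    hits.to_csv(paths["hits"], sep="\t", header=False, index=False)
    assignments.to_csv(paths["assignments"], sep="\t", index=False)

    manifest = {
        "config": dataclasses.asdict(config),
        "files": {name: {"path": path.name, "sha256": _sha256(path)}
                  for name, path in paths.items()},
        "planted": {
            "pools": genomes.pools,
            "adaptive_families": sorted(
                f for fams in genomes.pools.values() for f in fams
            ),
            "reassigned_tips": {t: list(v) for t, v in env.reassigned.items()},
            "clade_labels": env.clade_labels,
            "core_families": len(genomes.core_families),
            "n_families": int(genomes.genes["family_id"].nunique()),
        },
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    manifest["files"]["manifest"] = {"path": manifest_path.name}
    return manifest
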