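"""Reciprocal-best-hit orthology, core/Core-70 selection, GSS and NJ trees.

Orthologs between two genomes are operationally defined as reciprocal best
hits (RBHs) in an all-vs-all similarity search, after removing alignments
covering less than ``min_coverage`` (default 70%) of the query protein.
Multi-genome ortholog groups are anchored on a reference genome: each
reference gene defines a group consisting of its RBH partners in every other
genome, and a group's occupancy is the fraction of genomes represented.  The
core genome is the set of groups with occupancy 1.0; "Core-70" relaxes this
to at least 70% of the genomes (membership count >= ceil(0.70 * n)).

The genomic similarity score between genomes A and B,

    GSS(A, B) = sum over RBH pairs [S(a->b) + S(b->a)]
                / sum over the same pairs [S(a->a) + S(b->b)],

is a bitscore-weighted, symmetric similarity in [0, 1] that reduces to 1 for
identical genomes and integrates both core and shared accessory content;
1 - GSS is used as a distance for neighbor joining.  This ratio-of-summed-
bitscores form is the package's working definition of the score (the
published GSSa normalization is not reproduced in the source describing this
analysis chain); it is symmetric, bounded, and unit for identical genomes.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .exceptions import MissingGenomeError, ParseError, ValidationError
from .simulate import HIT_COLUMNS

__all__ = [
    "parse_hit_table",
    "write_hit_table",
    "resolve_genomes",
    "find_rbh",
    "all_pairwise_rbh",
    "OrthologGroups",
    "build_ortholog_groups",
    "GSSMatrix",
    "compute_gss",
    "neighbor_joining",
]

RBH_COLUMNS = [
    "genome_a", "genome_b", "gene_a", "gene_b",
    "score_ab", "score_ba", "self_a", "self_b",
]


def resolve_genomes(gene_ids: pd.Series, gene_map=None) -> pd.Series:
    """Map gene IDs to genome IDs.

    ``gene_map`` may be a mapping, a two-column DataFrame (gene_id,
    genome_id), or None, in which case the ``genome|gene`` naming convention
    is assumed.
    """
    if gene_map is None:
        split = gene_ids.str.split("|", n=1)
        bad = split.str.len() < 2
        if bad.any():
            examples = gene_ids[bad].head(3).tolist()
            raise ValidationError(
                "gene IDs do not follow the 'genome|gene' convention and no "
                f"gene map was given (e.g. {examples})"
            )
        return split.str[0]
    if isinstance(gene_map, pd.DataFrame):
        gene_map = dict(zip(gene_map.iloc[:, 0], gene_map.iloc[:, 1]))
    mapped = gene_ids.map(gene_map)
    if mapped.isna().any():
        missing = sorted(gene_ids[mapped.isna()].unique()[:5])
        raise ValidationError(f"genes missing from gene map: {missing}")
    return mapped


def parse_hit_table(source, gene_map=None) -> pd.DataFrame:
    """Read a 13-column BLAST-tabular hit table (outfmt 6 + query coverage).

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend sstart
    send evalue bitscore qcovs, with qcovs a fraction in [0, 1].  Adds
    resolved ``qgenome``/``sgenome`` columns.
    """
    try:
        raw = pd.read_csv(source, sep="\t", header=None, comment=None,
                          dtype={0: str, 1: str})
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame(columns=range(len(HIT_COLUMNS)))
    except pd.errors.ParserError as exc:
        raise ParseError(f"ragged hit table: {exc}") from exc
    if len(raw.columns) != len(HIT_COLUMNS):
        raise ParseError(
            f"expected {len(HIT_COLUMNS)} tab-separated columns "
            f"(column 13 is qcovs), found {len(raw.columns)}"
        )
    raw.columns = HIT_COLUMNS
    if len(raw):
        numeric = raw[HIT_COLUMNS[2:]]
        if numeric.isna().any().any():
            line = int(raw.index[numeric.isna().any(axis=1)][0]) + 1
            raise ParseError(f"missing fields at line {line}")
        if (raw["bitscore"] < 0).any():
            line = int(raw.index[raw["bitscore"] < 0][0]) + 1
            raise ValidationError(f"negative bitscore at line {line}")
        if ((raw["qcovs"] < 0) | (raw["qcovs"] > 1)).any():
            raise ValidationError("qcovs must be a fraction in [0, 1]")
        raw["qgenome"] = resolve_genomes(raw["qseqid"], gene_map)
        raw["sgenome"] = resolve_genomes(raw["sseqid"], gene_map)
    else:
        raw["qgenome"] = pd.Series(dtype=str)
        raw["sgenome"] = pd.Series(dtype=str)
    return raw


def write_hit_table(hits: pd.DataFrame, path) -> None:
    hits[HIT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def _ensure_genomes(hits: pd.DataFrame, gene_map=None) -> pd.DataFrame:
    if "qgenome" not in hits.columns or "sgenome" not in hits.columns:
        hits = hits.copy()
        hits["qgenome"] = resolve_genomes(hits["qseqid"], gene_map)
        hits["sgenome"] = resolve_genomes(hits["sseqid"], gene_map)
    return hits


def _self_scores(hits: pd.DataFrame) -> pd.Series:
    self_hits = hits[hits["qseqid"] == hits["sseqid"]]
    return self_hits.groupby("qseqid")["bitscore"].max()


def all_pairwise_rbh(
    hits: pd.DataFrame,
    min_coverage: float = 0.70,
    gene_map=None,
    filter_before_rank: bool = True,
) -> pd.DataFrame:
    """Reciprocal best hits for every genome pair in one vectorized pass.

    Hits with query coverage below ``min_coverage`` are removed before best-
    hit determination (set ``filter_before_rank=False`` to rank first and
    drop filtered pairs afterwards).  Ties on bitscore are broken by higher
    percent identity, then longer alignment, then lexicographic subject ID,
    so results are deterministic.  Each unordered genome pair appears with
    ``genome_a < genome_b``.
    """
    hits = _ensure_genomes(hits, gene_map)
    selfscore = _self_scores(hits)
    cross = hits[(hits["qgenome"] != hits["sgenome"])]
    ranked = cross.sort_values(
        ["qseqid", "sgenome", "bitscore", "pident", "length", "sseqid"],
        ascending=[True, True, False, False, False, True],
        kind="mergesort",
    )
    if filter_before_rank:
        best = ranked[ranked["qcovs"] >= min_coverage].drop_duplicates(
            ["qseqid", "sgenome"]
        )
    else:
        best = ranked.drop_duplicates(["qseqid", "sgenome"])
        best = best[best["qcovs"] >= min_coverage]
    fwd = best[["qseqid", "sseqid", "qgenome", "sgenome", "bitscore"]]
    rev = fwd.rename(
        columns={
            "qseqid": "sseqid", "sseqid": "qseqid",
            "qgenome": "sgenome", "sgenome": "qgenome",
            "bitscore": "score_ba",
        }
    )
    pairs = fwd.merge(rev, on=["qseqid", "sseqid", "qgenome", "sgenome"])
    keep = pairs["qgenome"] < pairs["sgenome"]
    pairs = pairs[keep].rename(
        columns={
            "qgenome": "genome_a", "sgenome": "genome_b",
            "qseqid": "gene_a", "sseqid": "gene_b",
            "bitscore": "score_ab",
        }
    )
    pairs["self_a"] = pairs["gene_a"].map(selfscore)
    pairs["self_b"] = pairs["gene_b"].map(selfscore)
    return pairs[RBH_COLUMNS].reset_index(drop=True)


def find_rbh(
    hits: pd.DataFrame,
    genome_a: str,
    genome_b: str,
    min_coverage: float = 0.70,
    gene_map=None,
    filter_before_rank: bool = True,
) -> pd.DataFrame:
    """RBH ortholog pairs between two genomes (symmetric in its arguments)."""
    hits = _ensure_genomes(hits, gene_map)
    present = set(hits["qgenome"]) | set(hits["sgenome"])
    for genome in (genome_a, genome_b):
        if genome not in present:
            raise MissingGenomeError(f"genome {genome!r} absent from hit table")
    wanted = {genome_a, genome_b}
    sub = hits[hits["qgenome"].isin(wanted) & hits["sgenome"].isin(wanted)]
    return all_pairwise_rbh(
        sub, min_coverage=min_coverage, filter_before_rank=filter_before_rank
    )


@dataclasses.dataclass
class OrthologGroups:
    """Reference-anchored ortholog groups with per-family occupancy."""

    #: long table: family_id, genome_id, gene_id, occupancy
    table: pd.DataFrame
    occupancy: pd.Series
    n_genomes: int
    reference: str
    occupancy_threshold: float

    @property
    def families(self) -> List[str]:
        return list(self.occupancy.index)

    def __len__(self) -> int:
        return len(self.occupancy)


def build_ortholog_groups(
    rbh: pd.DataFrame,
    genomes: Sequence[str],
    occupancy_threshold: float = 0.70,
    reference: Optional[str] = None,
) -> OrthologGroups:
    """Group pairwise RBHs into multi-genome families via reference anchoring.

    Each gene of the reference genome (lexicographically first by default)
    defines a candidate family containing its RBH partner in every other
    genome.  A family is retained when its member count is at least
    ``ceil(occupancy_threshold * n_genomes)``; a threshold of 1.0 yields the
    core genome, 0.70 the Core-70 set, and 0 keeps every reference gene.
    """
    genomes = sorted(set(genomes))
    n = len(genomes)
    if n == 0:
        raise ValidationError("no genomes given")
    if not 0.0 <= occupancy_threshold <= 1.0:
        raise ValidationError("occupancy_threshold must be in [0, 1]")
    if reference is None:
        reference = genomes[0]
    if reference not in genomes:
        raise MissingGenomeError(f"reference genome {reference!r} not in genome list")
    is_a = rbh["genome_a"] == reference
    is_b = rbh["genome_b"] == reference
    ref_rows = pd.concat(
        [
            rbh[is_a].rename(
                columns={"gene_a": "ref_gene", "genome_b": "genome_id",
                         "gene_b": "gene_id"}
            )[["ref_gene", "genome_id", "gene_id"]],
            rbh[is_b].rename(
                columns={"gene_b": "ref_gene", "genome_a": "genome_id",
                         "gene_a": "gene_id"}
            )[["ref_gene", "genome_id", "gene_id"]],
        ],
        ignore_index=True,
    )
    members = ref_rows.groupby("ref_gene")["genome_id"].nunique() + 1
    ref_genes = sorted(set(rbh.loc[is_a, "gene_a"]) | set(rbh.loc[is_b, "gene_b"]))
    members = members.reindex(ref_genes, fill_value=1)
    required = math.ceil(occupancy_threshold * n)
    keep = members[members >= required]
    occupancy = (keep / n).rename("occupancy")
    rows = ref_rows[ref_rows["ref_gene"].isin(keep.index)].copy()
    ref_self = pd.DataFrame(
        {"ref_gene": keep.index, "genome_id": reference, "gene_id": keep.index}
    )
    table = pd.concat([ref_self, rows], ignore_index=True)
    table["family_id"] = "OG-" + table["ref_gene"]
    table["occupancy"] = table["ref_gene"].map(occupancy)
    table = table[["family_id", "genome_id", "gene_id", "occupancy"]].sort_values(
        ["family_id", "genome_id"], kind="mergesort"
    ).reset_index(drop=True)
    occupancy.index = "OG-" + occupancy.index
    return OrthologGroups(
        table=table,
        occupancy=occupancy.sort_index(),
        n_genomes=n,
        reference=reference,
        occupancy_threshold=occupancy_threshold,
    )


@dataclasses.dataclass
class GSSMatrix:
    """Symmetric GSS similarity matrix with its companion distance 1 - GSS."""

    gss: pd.DataFrame

    @property
    def distance(self) -> pd.DataFrame:
        dist = 1.0 - self.gss
        np.fill_diagonal(dist.values, 0.0)
        return dist


def compute_gss(rbh: pd.DataFrame, genomes: Sequence[str]) -> GSSMatrix:
    """Genomic similarity score for every genome pair from pairwise RBHs.

    ``GSS(A, B) = sum[S(a->b) + S(b->a)] / sum[S(a->a) + S(b->b)]`` over the
    RBH pairs of (A, B); defined as 0 when the pair has no RBHs.  The
    diagonal is 1.  Values are clipped into [0, 1] (score noise can push a
    cross score marginally above a self score).
    """
    genomes = list(dict.fromkeys(genomes))
    if len(rbh):
        if rbh[["self_a", "self_b"]].isna().any().any():
            raise ValidationError("self-scores missing for some RBH genes")
        if (rbh[["self_a", "self_b"]] <= 0).any().any():
            raise ValidationError("self-score must be positive for every RBH gene")
    matrix = pd.DataFrame(np.eye(len(genomes)), index=genomes, columns=genomes)
    if len(rbh):
        num = (rbh["score_ab"] + rbh["score_ba"]).groupby(
            [rbh["genome_a"], rbh["genome_b"]]
        ).sum()
        den = (rbh["self_a"] + rbh["self_b"]).groupby(
            [rbh["genome_a"], rbh["genome_b"]]
        ).sum()
        gss = (num / den).clip(0.0, 1.0)
        for (a, b), value in gss.items():
            if a in matrix.index and b in matrix.index:
                matrix.loc[a, b] = value
                matrix.loc[b, a] = value
    return GSSMatrix(gss=matrix)


def _validate_distance_matrix(dist: pd.DataFrame) -> np.ndarray:
    values = np.asarray(dist, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValidationError("distance matrix must be square")
    if np.isnan(values).any():
        raise ValidationError("distance matrix contains NaN")
    if not np.allclose(values, values.T, atol=1e-8):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(values), 0.0, atol=1e-8):
        raise ValidationError("distance matrix must have a zero diagonal")
    return values


def neighbor_joining(dist: pd.DataFrame) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; exact on additive distance matrices.

    Negative branch-length estimates are clamped to zero with the deficit
    transferred to the sister branch (Phylip-compatible), preserving the
    distance between the joined pair.  Returns an unrooted tree (trifurcating
    at the final join).
    """
    labels = list(dist.index) if isinstance(dist, pd.DataFrame) else [
        f"t{i}" for i in range(len(dist))
    ]
    matrix = _validate_distance_matrix(dist)
    n = len(labels)
    if n < 3:
        raise ValidationError("neighbor joining requires at least 3 taxa")
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for label in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    D = matrix.copy()
    active = list(range(n))

    def clamp(li: float, lj: float):
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        flat = q[iu]
        k = int(np.argmin(flat))
        ai, aj = iu[0][k], iu[1][k]
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        new_index = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        for a in active:
            if a in (i, j):
                continue
            d = 0.5 * (D[i, a] + D[j, a] - dij)
            D[new_index, a] = D[a, new_index] = max(d, 0.0)
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [new_index]

    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    root = dendropy.Node()
    for idx, length in ((i, li), (j, lj), (k, lk)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(length, 0.0)
    tree.seed_node = root
    tree.is_rooted = False
    return tree
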