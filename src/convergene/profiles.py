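"""Per-genome functional profiles and Jaccard distances.

A genome's functional profile is the *set* of function identifiers (COG- or
Figfam-like) assigned to its proteins, after two quality filters on the raw
domain-assignment table: assignments whose alignment covers less than 70% of
the PSSM are discarded, and overlapping assignments on the same protein are
resolved greedily best-score-first, dropping any assignment that overlaps an
already retained one by more than 10% (of the shorter interval, by default;
the denominator is configurable).  Profiles are compared with the Jaccard
index J(A,B) = |A n B| / |A u B| and clustered on the Jaccard distance
Jd = 1 - J.
"""

from __future__ import annotations

import warnings
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .orthology import resolve_genomes

__all__ = [
    "ASSIGNMENT_COLUMNS",
    "read_assignments",
    "filter_assignments",
    "build_profiles",
    "jaccard_index",
    "jaccard_distance",
    "profile_distance_matrix",
    "presence_frame",
]

ASSIGNMENT_COLUMNS = [
    "protein_id", "function_id", "score", "pssm_coverage", "qstart", "qend",
]


def read_assignments(source) -> pd.DataFrame:
    """Read a function-assignment TSV (with header) and validate it."""
    table = pd.read_csv(source, sep="\t")
    missing = [c for c in ASSIGNMENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"assignment table lacks columns: {missing}")
    _validate_assignments(table)
    return table[ASSIGNMENT_COLUMNS]


def _validate_assignments(table: pd.DataFrame) -> None:
    if len(table) == 0:
        return
    if (table["qstart"] > table["qend"]).any():
        bad = table.index[table["qstart"] > table["qend"]][0]
        raise ValidationError(f"interval start > end at row {bad}")
    if ((table["pssm_coverage"] < 0) | (table["pssm_coverage"] > 1)).any():
        raise ValidationError("pssm_coverage must be a fraction in [0, 1]")


def _overlap_fraction(s1, e1, s2, e2, denominator: str) -> float:
    overlap = min(e1, e2) - max(s1, s2) + 1
    if overlap <= 0:
        return 0.0
    len1, len2 = e1 - s1 + 1, e2 - s2 + 1
    denom = min(len1, len2) if denominator == "shorter" else max(len1, len2)
    return overlap / denom


def filter_assignments(
    assignments: pd.DataFrame,
    min_pssm_coverage: float = 0.70,
    max_overlap: float = 0.10,
    overlap_denominator: str = "shorter",
) -> pd.DataFrame:
    """Apply the PSSM-coverage and within-protein overlap filters.

    Coverage below ``min_pssm_coverage`` is dropped first; then, per protein,
    assignments are processed best-score-first (ties broken on function ID,
    then start) and an assignment is discarded when it overlaps any retained
    assignment by more than ``max_overlap`` of the shorter interval
    (intervals are 1-based inclusive).  The operation is idempotent.
    """
    if overlap_denominator not in ("shorter", "longer"):
        raise ValidationError("overlap_denominator must be 'shorter' or 'longer'")
    _validate_assignments(assignments)
    kept = assignments[assignments["pssm_coverage"] >= min_pssm_coverage]
    multi = kept["protein_id"].duplicated(keep=False)
    singles = kept[~multi]
    survivors = [singles]
    for _, group in kept[multi].groupby("protein_id", sort=False):
        ordered = group.sort_values(
            ["score", "function_id", "qstart"],
            ascending=[False, True, True], kind="mergesort",
        )
        retained = []
        for row in ordered.itertuples():
            clash = any(
                _overlap_fraction(row.qstart, row.qend, r.qstart, r.qend,
                                  overlap_denominator) > max_overlap
                for r in retained
            )
            if not clash:
                retained.append(row)
        survivors.append(group.loc[[r.Index for r in retained]])
    result = pd.concat(survivors)
    return result.loc[result.index.sort_values()]


def build_profiles(
    assignments: pd.DataFrame,
    gene_map=None,
    genomes: Optional[Sequence[str]] = None,
) -> Dict[str, FrozenSet[str]]:
    """Per-genome sets of distinct function IDs from filtered assignments.

    Proteins are mapped to genomes via ``gene_map`` or the ``genome|gene``
    naming convention.  ``genomes`` may list genomes that must appear even if
    they have no surviving assignments (flagged with a warning).
    """
    table = assignments.copy()
    table["genome_id"] = resolve_genomes(table["protein_id"], gene_map)
    profiles: Dict[str, FrozenSet[str]] = {
        genome: frozenset(group["function_id"])
        for genome, group in table.groupby("genome_id")
    }
    for genome in genomes or ():
        if genome not in profiles:
            warnings.warn(f"genome {genome!r} has an empty functional profile")
            profiles[genome] = frozenset()
    return profiles


def jaccard_index(a: Set[str], b: Set[str]) -> float:
    """|A n B| / |A u B|; two empty sets are considered identical (J = 1)."""
    a, b = set(a), set(b)
    union = len(a | b)
    if union == 0:
        return 1.0
    return len(a & b) / union


def jaccard_distance(a: Set[str], b: Set[str]) -> float:
    return 1.0 - jaccard_index(a, b)


def presence_frame(profiles: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Genomes x functions boolean presence matrix (sorted columns)."""
    functions = sorted(set().union(*map(set, profiles.values())) if profiles else set())
    data = np.zeros((len(profiles), len(functions)), dtype=bool)
    genomes = list(profiles)
    col = {f: i for i, f in enumerate(functions)}
    for r, genome in enumerate(genomes):
        for f in profiles[genome]:
            data[r, col[f]] = True
    return pd.DataFrame(data, index=genomes, columns=functions)


def profile_distance_matrix(profiles: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Square Jaccard-distance matrix over the genomes of ``profiles``."""
    if len(profiles) < 2:
        raise ValidationError("need at least 2 genomes for a distance matrix")
    X = presence_frame(profiles)
    counts = X.to_numpy().astype(np.int64)
    sizes = counts.sum(axis=1)
    inter = counts @ counts.T
    union = sizes[:, None] + sizes[None, :] - inter
    if (union == 0).any():
        warnings.warn("genome pair(s) with empty profiles: distance set to 0")
    with np.errstate(invalid="ignore"):
        jac = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    dist = 1.0 - jac
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=X.index, columns=X.index)
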