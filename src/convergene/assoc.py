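"""Cluster-environment enrichment and adaptive-function detection.

Association between genome clusters and isolation environments is assessed
with the one-sided hypergeometric over-representation tail: for a cluster of
size ``n`` containing ``k`` of the ``K`` genomes of an environment among
``N`` genomes overall, ``p = P(X >= k)`` with ``X ~ Hypergeom(N, K, n)``.
Dendrograms are scanned over cuts ``k = k_min..k_max`` (starting at 3, after
the analysis this package reproduces); p-values are Benjamini-Hochberg
adjusted within each cut, and the scan stops at the first cut yielding no
association with ``q <= alpha``.

Adaptive (group-specific) functions are detected with an exact one-sided
2x2 presence test per (function, group) contrast — a deliberate, documented
proxy for count-regression packages used in comparable analyses — followed by
BH adjustment across all contrasts.  A function is reported only when
``q <= alpha`` and it is present in at least ``min_presence`` (default 80%)
of the focal group.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .cluster import MergeTree, cut_dendrogram
from .exceptions import ValidationError
from .profiles import presence_frame

__all__ = [
    "hypergeometric_test",
    "bh_adjust",
    "ScanResult",
    "scan_cluster_environment_associations",
    "find_adaptive_functions",
]


def hypergeometric_test(k_in: int, n_cluster: int, K_env: int, N: int) -> float:
    """One-sided over-representation tail P(X >= k_in).

    ``X ~ Hypergeom(N, K_env, n_cluster)``: the count of environment members
    in a random cluster of the same size.  ``k_in = 0`` gives p = 1.
    """
    for name, value in (("k_in", k_in), ("n_cluster", n_cluster),
                        ("K_env", K_env), ("N", N)):
        if int(value) != value or value < 0:
            raise ValidationError(f"{name} must be a non-negative integer")
    if k_in > min(n_cluster, K_env) or n_cluster > N or K_env > N:
        raise ValidationError(
            f"inconsistent counts: k_in={k_in}, n_cluster={n_cluster}, "
            f"K_env={K_env}, N={N}"
        )
    return float(hypergeom.sf(k_in - 1, N, K_env, n_cluster))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclasses.dataclass
class ScanResult:
    """Association table over scanned cuts plus the last significant cut."""

    table: pd.DataFrame
    last_significant_k: Optional[int]
    alpha: float

    def significant(self) -> pd.DataFrame:
        if len(self.table) == 0:
            return self.table
        return self.table[self.table["significant"]]


_SCAN_COLUMNS = ["k", "cluster", "environment", "k_in", "n_cluster",
                 "K_env", "N", "p", "q", "significant"]


def scan_cluster_environment_associations(
    mt: MergeTree,
    env: Mapping[str, str],
    k_min: int = 3,
    k_max: Optional[int] = None,
    alpha: float = 0.05,
    fdr_scope: str = "per_cut",
    stop_when_lost: bool = True,
) -> ScanResult:
    """Hypergeometric cluster-environment scan across dendrogram cuts.

    Every (cluster, environment) pair is tested at each cut; environments
    covering no genome or all genomes are skipped (no contrast exists).  With
    ``fdr_scope='per_cut'`` (default) BH adjustment is applied within each
    cut; ``'global'`` pools all cuts before adjusting, in which case the scan
    cannot stop early.
    """
    if fdr_scope not in ("per_cut", "global"):
        raise ValidationError("fdr_scope must be 'per_cut' or 'global'")
    labels = pd.Series(env)
    missing = set(mt.labels) - set(labels.index)
    if missing:
        raise ValidationError(f"environment labels missing for {sorted(missing)}")
    labels = labels.reindex(mt.labels)
    N = mt.n
    k_max = N if k_max is None else k_max
    if k_max < k_min:
        raise ValidationError("k_max must be >= k_min")
    k_max = min(k_max, N)
    env_totals = labels.value_counts()
    testable = [e for e, K in env_totals.items() if 0 < K < N]
    rows: List[dict] = []
    last_significant = None
    for k in range(k_min, k_max + 1):
        part = cut_dendrogram(mt, k)
        cut_rows = []
        for cluster, members in part.groupby(part):
            in_cluster = labels.loc[members.index]
            for e in testable:
                k_in = int((in_cluster == e).sum())
                p = hypergeometric_test(k_in, len(members), int(env_totals[e]), N)
                cut_rows.append(
                    dict(k=k, cluster=int(cluster), environment=e, k_in=k_in,
                         n_cluster=len(members), K_env=int(env_totals[e]),
                         N=N, p=p)
                )
        if not cut_rows:
            break
        if fdr_scope == "per_cut":
            q = bh_adjust([r["p"] for r in cut_rows])
            any_sig = False
            for r, qv in zip(cut_rows, q):
                r["q"] = qv
                r["significant"] = bool(qv <= alpha)
                any_sig = any_sig or r["significant"]
            rows.extend(cut_rows)
            if any_sig:
                last_significant = k
            elif stop_when_lost:
                break
        else:
            rows.extend(cut_rows)
    if fdr_scope == "global" and rows:
        q = bh_adjust([r["p"] for r in rows])
        for r, qv in zip(rows, q):
            r["q"] = qv
            r["significant"] = bool(qv <= alpha)
        sig_ks = [r["k"] for r in rows if r["significant"]]
        last_significant = max(sig_ks) if sig_ks else None
    table = pd.DataFrame(rows, columns=_SCAN_COLUMNS)
    return ScanResult(table=table, last_significant_k=last_significant, alpha=alpha)


_ADAPTIVE_COLUMNS = ["function_id", "group", "other", "n_focal", "k_focal",
                     "focal_fraction", "other_fraction", "direction", "p", "q"]


def find_adaptive_functions(
    presence,
    groups: Mapping[str, int],
    min_presence: float = 0.80,
    alpha: float = 0.05,
    mode: str = "one_vs_rest",
    return_all: bool = False,
) -> pd.DataFrame:
    """Group-specific (putatively adaptive) functions between genome groups.

    ``presence`` is a genomes x functions boolean frame or a mapping
    genome -> set of functions; ``groups`` maps genomes to group labels.  For
    each function and focal group the 2x2 presence table against the union of
    the other groups (``mode='one_vs_rest'``) or against each other group
    separately (``mode='pairwise'``) is scored with the one-sided
    hypergeometric tail in the direction (over/under) suggested by the
    presence fractions.  BH adjustment runs across all contrasts; a function
    is reported when ``q <= alpha`` and its focal presence fraction is at
    least ``min_presence``.
    """
    if mode not in ("one_vs_rest", "pairwise"):
        raise ValidationError("mode must be 'one_vs_rest' or 'pairwise'")
    if isinstance(presence, Mapping):
        X = presence_frame(presence)
    else:
        X = presence.astype(bool)
    part = pd.Series(groups)
    if set(part.index) != set(X.index):
        raise ValidationError("groups and presence cover different genomes")
    part = part.reindex(X.index)
    group_ids = sorted(part.unique())
    if len(group_ids) < 2:
        raise ValidationError("need at least 2 groups")
    counts = X.groupby(part).sum()  # groups x functions
    sizes = part.value_counts()
    if (sizes < 1).any():
        raise ValidationError("empty group")

    def contrast(focal, k_focal, n_focal, k_other, n_other, other_label):
        with np.errstate(invalid="ignore"):
            f_focal = k_focal / n_focal
            f_other = k_other / n_other
        K = k_focal + k_other
        N = n_focal + n_other
        over = f_focal > f_other
        p_over = hypergeom.sf(k_focal - 1, N, K, n_focal)
        p_under = hypergeom.cdf(k_focal, N, K, n_focal)
        p = np.where(over, p_over, p_under)
        return pd.DataFrame(
            {
                "function_id": X.columns,
                "group": focal,
                "other": other_label,
                "n_focal": n_focal,
                "k_focal": k_focal,
                "focal_fraction": f_focal,
                "other_fraction": f_other,
                "direction": np.where(over, "over", "under"),
                "p": p,
            }
        )

    frames = []
    for g in group_ids:
        k_focal = counts.loc[g].to_numpy()
        n_focal = int(sizes[g])
        if mode == "one_vs_rest":
            k_other = counts.drop(index=g).sum().to_numpy()
            n_other = int(sizes.drop(index=g).sum())
            frames.append(contrast(g, k_focal, n_focal, k_other, n_other, "rest"))
        else:
            for h in group_ids:
                if h == g:
                    continue
                frames.append(
                    contrast(g, k_focal, n_focal, counts.loc[h].to_numpy(),
                             int(sizes[h]), h)
                )
    table = pd.concat(frames, ignore_index=True)
    table["q"] = bh_adjust(table["p"])
    table = table[_ADAPTIVE_COLUMNS]
    if return_all:
        return table
    reported = table[(table["q"] <= alpha)
                     & (table["focal_fraction"] >= min_presence)]
    return reported.reset_index(drop=True)
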