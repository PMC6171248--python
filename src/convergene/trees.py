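"""Newick I/O, Robinson-Foulds distances and support-value summaries.

Trees are represented as :class:`dendropy.Tree` objects throughout the
package; leaf taxon labels are genome identifiers.  Internal-node labels, when
numeric, are interpreted as branch support values on the usual 0-100 bootstrap
scale.  Robinson-Foulds distances are computed on unrooted, non-trivial
bipartitions (Phylip Treedist convention), so rooted and unrooted inputs
compare consistently.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Optional, Set, FrozenSet

import dendropy

from .exceptions import ParseError, ValidationError

__all__ = [
    "read_newick",
    "write_newick",
    "leaf_labels",
    "bipartitions",
    "robinson_foulds",
    "count_supported_nodes",
    "mergetree_to_phylotree",
]

_NEWICK_WRITE_KWARGS = dict(
    schema="newick",
    suppress_rooting=True,
    real_value_format_specifier=".10g",
)


def _looks_like_newick(text: str) -> bool:
    stripped = text.strip()
    return stripped.startswith("(") or stripped.endswith(";")


def read_newick(source) -> dendropy.Tree:
    """Parse a Newick tree from a path, file object or literal string.

    Integer (or numeric) internal-node labels are kept as node labels and read
    back as support values by :func:`count_supported_nodes`.  The
    bracketed-comment Newick dialect is rejected: supports must be plain
    internal-node labels.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        source = os.fspath(source)
        if _looks_like_newick(source):
            text = source
        else:
            with open(source) as handle:
                text = handle.read()
    if "[" in text or "]" in text:
        raise ParseError(
            "bracketed comments are not supported; encode supports as plain "
            "internal-node labels (e.g. '((A,B)95,C);')"
        )
    if text.count("(") != text.count(")"):
        raise ParseError(
            f"unbalanced parentheses: {text.count('(')} '(' vs "
            f"{text.count(')')} ')' (near position "
            f"{max(text.rfind('('), text.rfind(')'))})"
        )
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"malformed Newick: {exc}") from exc
    return tree


def write_newick(tree: dendropy.Tree, path=None) -> str:
    """Serialize ``tree`` to Newick (branch lengths to 10 significant digits).

    Returns the Newick text; if ``path`` is given the text is also written
    there.
    """
    text = tree.as_string(**_NEWICK_WRITE_KWARGS)
    if path is not None:
        with open(path, "w") as handle:
            handle.write(text)
    return text


def leaf_labels(tree: dendropy.Tree) -> list:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def bipartitions(tree: dendropy.Tree) -> Set[FrozenSet[str]]:
    """Non-trivial unrooted bipartitions of ``tree``.

    Each bipartition is canonicalized as the leaf block *not* containing the
    lexicographically smallest leaf label, so rooted and unrooted encodings of
    the same split coincide.  Trivial splits (one leaf against the rest) are
    excluded.  Polytomies simply contribute fewer bipartitions.
    """
    labels = leaf_labels(tree)
    if len(labels) != len(set(labels)):
        raise ValidationError("duplicate leaf labels")
    full = frozenset(labels)
    ref = min(full)
    n = len(full)
    splits: Set[FrozenSet[str]] = set()
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
        if node.parent_node is None:
            continue
        block = below[node]
        if len(block) < 2 or len(block) > n - 2:
            continue
        if ref in block:
            block = full - block
        splits.add(block)
    return splits


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds symmetric difference between two trees.

    The trees must share an identical leaf-label set and are treated as
    unrooted.  The value is the number of non-trivial bipartitions present in
    exactly one of the two trees; it is 0 iff the bipartition sets are equal,
    and at most ``2*(n-3)`` for binary trees with ``n`` leaves.
    """
    l1, l2 = set(leaf_labels(t1)), set(leaf_labels(t2))
    if l1 != l2:
        raise ValidationError(
            "leaf sets differ: only in first tree "
            f"{sorted(l1 - l2)}, only in second {sorted(l2 - l1)}"
        )
    return len(bipartitions(t1) ^ bipartitions(t2))


def _node_support(node) -> Optional[float]:
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def count_supported_nodes(tree: dendropy.Tree, threshold: int = 80) -> int:
    """Number of internal nodes with support >= ``threshold`` (inclusive).

    Nodes without a numeric support label are not counted.
    """
    count = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        support = _node_support(node)
        if support is not None and support >= threshold:
            count += 1
    return count


def mergetree_to_phylotree(mt) -> dendropy.Tree:
    """Convert a hierarchical-clustering merge tree to an ultrametric tree.

    Each merge at height ``h`` becomes an internal node at depth ``h/2`` from
    the leaves, so leaf-to-node path lengths equal half the cophenetic
    distance.  This allows Robinson-Foulds comparison between content
    dendrograms and phylogenies.
    """
    n = len(mt.labels)
    if n == 1:
        return read_newick(f"({mt.labels[0]}:0);")
    heights = [0.0] * n + [float(row[2]) for row in mt.linkage]
    texts = list(mt.labels)
    for step, row in enumerate(mt.linkage):
        i, j = int(row[0]), int(row[1])
        h = heights[n + step] / 2.0
        left = f"{texts[i]}:{h - heights[i] / 2.0:.10g}"
        right = f"{texts[j]}:{h - heights[j] / 2.0:.10g}"
        texts.append(f"({left},{right})")
    return read_newick(texts[-1] + ";")
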