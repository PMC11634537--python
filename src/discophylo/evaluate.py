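"""Species-tree comparison (normalized Robinson–Foulds) and replicate summaries."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy

from .trees import GeneTree, TreeError, write_newick

__all__ = ["TreeComparison", "ReplicateSummary", "rf_distance", "summarize_replicates"]


@dataclass(frozen=True)
class TreeComparison:
    """RF distance between two binary trees on the same n leaves.

    ``rf_raw`` is the size of the symmetric difference of the two
    nontrivial bipartition sets; ``rf_normalized`` divides by
    ``2(n - 3)``, the maximum for binary trees, and is 0 iff the trees
    are isomorphic.
    """

    rf_raw: int
    rf_normalized: float
    shared_leaf_count: int


@dataclass(frozen=True)
class ReplicateSummary:
    mean: float
    standard_error: float
    n: int


def _binary_unrooted(tree: GeneTree) -> bool:
    internals = tree.internal_nodes()
    for node in internals:
        degree = len(node.children) + (0 if node.parent is None else 1)
        if node.parent is None:
            if len(node.children) not in (2, 3):
                return False
        elif degree != 3:
            return False
    return True


def rf_distance(t1: GeneTree, t2: GeneTree) -> TreeComparison:
    """Normalized Robinson–Foulds distance between two species trees.

    Both trees must be binary with identical leaf sets of at least four
    species; mismatched leaf sets are an error (never silently
    restricted).  Leaves are matched by species label.
    """
    labels1 = set(t1.species_labels())
    labels2 = set(t2.species_labels())
    if len(labels1) != len(t1.leaves()) or len(labels2) != len(t2.leaves()):
        raise TreeError("rf_distance requires single-labeled trees")
    if labels1 != labels2:
        only1 = sorted(labels1 - labels2)
        only2 = sorted(labels2 - labels1)
        raise TreeError(
            f"leaf sets differ: only in first = {only1}; only in second = {only2}")
    n = len(labels1)
    if n < 4:
        raise TreeError(f"rf_distance requires at least 4 shared leaves, got {n}")
    if not _binary_unrooted(t1) or not _binary_unrooted(t2):
        raise TreeError("rf_distance requires binary trees (polytomies refused)")
    tns = dendropy.TaxonNamespace(is_case_sensitive=True)
    d1 = dendropy.Tree.get(data=write_newick(t1, include_lengths=False, use_species=True),
                           schema="newick", taxon_namespace=tns,
                           preserve_underscores=True, case_sensitive_taxon_labels=True)
    d2 = dendropy.Tree.get(data=write_newick(t2, include_lengths=False, use_species=True),
                           schema="newick", taxon_namespace=tns,
                           preserve_underscores=True, case_sensitive_taxon_labels=True)
    d1.is_rooted = False
    d2.is_rooted = False
    d1.encode_bipartitions()
    d2.encode_bipartitions()
    raw = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
    return TreeComparison(rf_raw=raw, rf_normalized=raw / (2 * (n - 3)),
                          shared_leaf_count=n)


def summarize_replicates(comparisons: Sequence[TreeComparison] | Iterable[TreeComparison]) -> ReplicateSummary:
    """Mean and standard error of normalized RF over replicates."""
    values = [c.rf_normalized for c in comparisons]
    if not values:
        raise ValueError("summarize_replicates requires a non-empty collection")
    n = len(values)
    mean = sum(values) / n
    if n == 1:
        se = 0.0
    else:
        var = sum((v - mean) ** 2 for v in values) / (n - 1)
        se = math.sqrt(var / n)
    return ReplicateSummary(mean=mean, standard_error=se, n=n)
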