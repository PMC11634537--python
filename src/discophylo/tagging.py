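"""Duplication/speciation tagging and duplication–loss parsimony rooting.

An internal node of a rooted, species-resolved gene tree is a
*duplication* if the species sets of its two child subtrees intersect
(some species is reachable from both children) and a *speciation*
otherwise.  An unrooted gene tree is rooted by scoring every possible
root edge under a weighted duplication–loss parsimony criterion and
keeping the minimum; this is the rooting/tagging heuristic the
decomposition stage depends on.

The loss count charged at a duplication node with child species sets A
and B is ``|A \\ B| + |B \\ A|``: a species present under one duplicate
but absent under the other implies one loss.  The formula is kept
behind :func:`duplication_losses` so alternative scoring schemes can be
swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass

from .trees import DUPLICATION, SPECIATION, GeneTree, Node, TreeError

__all__ = [
    "TagRootConfig",
    "tag_rooted",
    "dl_score",
    "duplication_losses",
    "root_and_tag",
    "count_duplications",
]


@dataclass(frozen=True)
class TagRootConfig:
    """Weights of the duplication–loss parsimony criterion.

    ``w_dup`` is the penalty per duplication node, ``w_loss`` the
    penalty per implied loss.  Equal unit weights are the default.
    """

    w_dup: float = 1.0
    w_loss: float = 1.0

    def __post_init__(self):
        if self.w_dup < 0 or self.w_loss < 0:
            raise ValueError("weights must be non-negative")
        if self.w_dup == 0 and self.w_loss == 0:
            raise ValueError("w_dup and w_loss must not both be zero")


def _check_species_resolved(tree: GeneTree) -> None:
    for leaf in tree.leaves():
        if leaf.species is None:
            raise TreeError(
                f"species labels not resolved (leaf {leaf.label!r}); "
                "apply a SpeciesMapping first")


def _species_sets(root: Node) -> dict[int, frozenset]:
    """Species set of the subtree below each node, keyed by id(node)."""
    sets: dict[int, frozenset] = {}
    for node in root.postorder():
        if node.is_leaf():
            sets[id(node)] = frozenset([node.species])
        else:
            acc: frozenset = frozenset()
            for c in node.children:
                acc = acc | sets[id(c)]
            sets[id(node)] = acc
    return sets


def tag_rooted(tree: GeneTree) -> GeneTree:
    """Tag every internal node of a rooted binary tree in place.

    A node becomes :data:`DUPLICATION` iff its two child subtrees share
    a species, :data:`SPECIATION` otherwise.  Pure function of topology
    and species labels, hence idempotent.
    """
    if not tree.is_rooted:
        raise TreeError("tag_rooted requires a rooted tree; use root_and_tag")
    _check_species_resolved(tree)
    sets = _species_sets(tree.root)
    for node in tree.internal_nodes():
        if len(node.children) != 2:
            raise TreeError("tag_rooted requires a binary tree")
        a, b = (sets[id(c)] for c in node.children)
        node.tag = DUPLICATION if a & b else SPECIATION
    return tree


def duplication_losses(a: frozenset, b: frozenset) -> int:
    """Losses implied at a duplication node with child species sets a, b."""
    return len(a ^ b)


def count_duplications(tree: GeneTree) -> int:
    """Number of duplication-tagged internal nodes."""
    return sum(1 for n in tree.internal_nodes() if n.tag == DUPLICATION)


def dl_score(tree: GeneTree, config: TagRootConfig = TagRootConfig()) -> float:
    """Weighted duplication–loss parsimony score of a tagged tree.

    ``w_dup * D + w_loss * L`` where D is the duplication-node count and
    L sums, over duplication nodes, the losses implied by the asymmetry
    of the two child species sets.  Zero iff there is no duplication.
    """
    _check_species_resolved(tree)
    sets = _species_sets(tree.root)
    dups = 0
    losses = 0
    for node in tree.internal_nodes():
        if node.tag is None:
            raise TreeError("dl_score requires a tagged tree; run tag_rooted first")
        if node.tag == DUPLICATION:
            a, b = (sets[id(c)] for c in node.children)
            dups += 1
            losses += duplication_losses(a, b)
    return config.w_dup * dups + config.w_loss * losses


# ---------------------------------------------------------------------------
# Rooting by duplication-loss parsimony
# ---------------------------------------------------------------------------


def _unrooted_adjacency(tree: GeneTree):
    """Adjacency view of the unrooted topology underlying *tree*.

    Returns ``(adj, lengths)`` where ``adj`` maps id(node) -> list of
    neighbor nodes (deterministic order: parent first, then children)
    and ``lengths`` maps frozenset({id,id}) -> branch length or None.
    A rooted binary root is suppressed (its two children become
    neighbors).
    """
    work = tree.copy()
    root = work.root
    adj: dict[int, list[Node]] = {}
    lengths: dict[frozenset, float | None] = {}
    nodes = list(root.postorder())
    for node in nodes:
        neigh = []
        if node.parent is not None:
            neigh.append(node.parent)
        neigh.extend(node.children)
        adj[id(node)] = neigh
        if node.parent is not None:
            lengths[frozenset((id(node), id(node.parent)))] = node.length
    if len(root.children) == 2:
        # suppress the root: its two children become direct neighbors
        a, b = root.children
        la = lengths.pop(frozenset((id(a), id(root))), None)
        lb = lengths.pop(frozenset((id(b), id(root))), None)
        merged = (la or 0.0) + (lb or 0.0) if (la is not None or lb is not None) else None
        adj[id(a)] = [b if n is root else n for n in adj[id(a)]]
        adj[id(b)] = [a if n is root else n for n in adj[id(b)]]
        lengths[frozenset((id(a), id(b)))] = merged
        del adj[id(root)]
        nodes = [n for n in nodes if n is not root]
    return nodes, adj, lengths


def _postorder_edges(start: Node, adj) -> list[tuple[Node, Node]]:
    """Edges (parent_side, child_side) in post-order of a DFS from *start*."""
    edges: list[tuple[Node, Node]] = []

    def dfs(u: Node, parent: Node | None):
        for v in adj[id(u)]:
            if v is parent:
                continue
            dfs(v, u)
            edges.append((u, v))

    dfs(start, None)
    return edges


def _root_on_edge(u: Node, v: Node, adj, lengths) -> GeneTree:
    """Build a rooted binary tree whose root splits the edge (u, v)."""

    def orient(x: Node, came_from: Node) -> Node:
        new = Node(x.label, x.species)
        key = frozenset((id(x), id(came_from)))
        new.length = lengths.get(key)
        for n in adj[id(x)]:
            if n is not came_from:
                new.add_child(orient(n, x))
        return new

    root = Node()
    left = orient(u, v)
    right = orient(v, u)
    edge_len = lengths.get(frozenset((id(u), id(v))))
    if edge_len is not None:
        left.length = edge_len / 2.0
        right.length = edge_len / 2.0
    else:
        left.length = right.length = None
    root.add_child(left)
    root.add_child(right)
    return GeneTree(root, is_rooted=True)


def root_and_tag(tree: GeneTree,
                 config: TagRootConfig = TagRootConfig()) -> GeneTree:
    """Root an (un)rooted gene tree by duplication–loss parsimony and tag it.

    Every edge of the unrooted topology is tried as a root position; the
    rooting whose tagging minimizes :func:`dl_score` wins, ties broken
    by the first minimizing edge in a deterministic post-order edge
    enumeration started from the leaf with the lexicographically
    smallest gene label.  Any rooting present in the input is ignored.
    """
    _check_species_resolved(tree)
    if tree.n_leaves < 2:
        raise TreeError("root_and_tag requires at least two leaves")
    nodes, adj, lengths = _unrooted_adjacency(tree)
    leaves = [n for n in nodes if len(adj[id(n)]) == 1]
    start = min(leaves, key=lambda n: n.label or "")
    edges = _postorder_edges(start, adj)
    best: GeneTree | None = None
    best_score = float("inf")
    for u, v in edges:
        candidate = _root_on_edge(u, v, adj, lengths)
        tag_rooted(candidate)
        score = dl_score(candidate, config)
        if score < best_score:
            best_score = score
            best = candidate
    assert best is not None
    return best
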