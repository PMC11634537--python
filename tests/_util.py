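"""Shared helpers and independent oracles for the test suite.

The oracle implementations here deliberately take different
computational routes from the package (dendropy rerooting, four-point
topological distances, recursive bipartition sets) so that agreement is
an actual cross-check.
"""

from __future__ import annotations

import itertools
import random

import dendropy

import discophylo as dp
from discophylo.trees import GeneTree, Node

WORKED_EXAMPLE = "(((a_1,b_1),p_1),(((c_1,d_1),(f_1,g_1)),((c_2,h_1),(d_2,e_1))));"

PREFIX_MAPPING = dp.SpeciesMapping.from_delimiter("_")


def worked_example_tagged() -> GeneTree:
    tree = dp.parse_newick(WORKED_EXAMPLE)
    dp.resolve_species(tree, PREFIX_MAPPING)
    return dp.tag_rooted(tree)


def species_tree_from_newick(nwk: str) -> GeneTree:
    tree = dp.parse_newick(nwk)
    for leaf in tree.leaves():
        leaf.species = leaf.label
    return tree


def ultrametric_species_tree_6taxa(pop_size: float) -> GeneTree:
    """Balanced-ish 6-taxon tree, every internal branch 2 coalescent units."""
    n = pop_size
    nwk = (f"(((A:{2*n},B:{2*n}):{2*n},(C:{2*n},D:{2*n}):{2*n}):{2*n},"
           f"(E:{4*n},F:{4*n}):{2*n});")
    return species_tree_from_newick(nwk)


def random_multicopy_dataset(n_trees: int, seed: int, *, n_taxa: int = 6,
                             dup_rate: float = 4e-6, loss_rate: float = 4e-6,
                             pop_size: float = 10000.0) -> dp.Dataset:
    """Simulated multi-copy gene trees on a random species tree."""
    labels = [f"S{i}" for i in range(n_taxa)]
    sp = dp.random_species_tree(labels, depth_scale=2.0 * pop_size,
                                rng=random.Random(seed))
    params = dp.DLCoalParams(species_tree=sp, dup_rate=dup_rate,
                             loss_rate=loss_rate, pop_size=pop_size,
                             n_genes=n_trees, seed=seed)
    return dp.generate_dataset(params)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def topological_distances(tree: GeneTree) -> dict[tuple[str, str], int]:
    """Pairwise topological leaf distances by BFS over an adjacency view."""
    adjacency: dict[int, list[Node]] = {}
    for node in tree.postorder():
        neighbors = ([node.parent] if node.parent is not None else []) + list(node.children)
        adjacency[id(node)] = neighbors
    leaves = tree.leaves()
    dist: dict[tuple[str, str], int] = {}
    for leaf in leaves:
        seen = {id(leaf): 0}
        frontier = [leaf]
        while frontier:
            nxt = []
            for node in frontier:
                for nb in adjacency[id(node)]:
                    if id(nb) not in seen:
                        seen[id(nb)] = seen[id(node)] + 1
                        nxt.append(nb)
            frontier = nxt
        for other in leaves:
            dist[(leaf.species, other.species)] = seen[id(other)]
    return dist


def four_point_quartet(dist, a, b, c, d) -> dp.QuartetTopology:
    """Induced quartet by the four-point condition on topological distances."""
    sums = {
        dp.QuartetTopology((a, b), (c, d)): dist[(a, b)] + dist[(c, d)],
        dp.QuartetTopology((a, c), (b, d)): dist[(a, c)] + dist[(b, d)],
        dp.QuartetTopology((a, d), (b, c)): dist[(a, d)] + dist[(b, c)],
    }
    return min(sums, key=sums.get)


def brute_force_gtf(trees) -> dp.QuartetTable:
    """Per-tree, per-4-subset recount via the four-point oracle."""
    table = dp.QuartetTable()
    for tree in trees:
        if tree.n_leaves < 4:
            continue
        dist = topological_distances(tree)
        species = sorted(tree.species_set())
        for quad in itertools.combinations(species, 4):
            table.add(four_point_quartet(dist, *quad), 1)
    return table


def dendropy_min_rooting_score(tree: GeneTree, w_dup: float = 1.0,
                               w_loss: float = 1.0):
    """Brute-force all-rootings duplication-loss minimum via dendropy.

    Returns (min_score, min_duplications_at_a_min_score_rooting).
    """
    nwk = dp.write_newick(tree, include_lengths=False)
    base = dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
    n_edges = len(base.edges())
    best = None
    for index in range(n_edges):
        work = dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
        work.is_rooted = True
        edge = work.edges()[index]
        if edge.head_node is work.seed_node:
            continue
        work.reroot_at_edge(edge, update_bipartitions=False)
        if len(work.seed_node.child_nodes()) != 2:
            continue
        score, dups = _dendropy_dl_score(work, w_dup, w_loss)
        if best is None or score < best[0]:
            best = (score, dups)
    assert best is not None
    return best


def _dendropy_dl_score(dtree: "dendropy.Tree", w_dup: float, w_loss: float):
    species_of = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            species_of[node] = frozenset([label.split("_")[0]])
        else:
            acc = frozenset()
            for child in node.child_nodes():
                acc = acc | species_of[child]
            species_of[node] = acc
    dups = 0
    losses = 0
    for node in dtree.postorder_internal_node_iter():
        kids = node.child_nodes()
        if len(kids) != 2:
            continue
        a, b = species_of[kids[0]], species_of[kids[1]]
        if a & b:
            dups += 1
            losses += len(a ^ b)
    return w_dup * dups + w_loss * losses, dups


def bipartition_set(tree: GeneTree) -> set[frozenset]:
    """Nontrivial unrooted bipartitions via direct recursion (RF oracle)."""
    labels = frozenset(tree.species_labels())
    parts: set[frozenset] = set()

    def clade(node: Node) -> frozenset:
        if node.is_leaf():
            return frozenset([node.species or node.label])
        acc = frozenset()
        for child in node.children:
            acc = acc | clade(child)
        if 1 < len(acc) < len(labels) - 1:
            parts.add(frozenset([acc, labels - acc]))
        return acc

    clade(tree.root)
    return parts


def enumerate_unrooted_topologies(labels):
    """All unrooted binary topologies as GeneTrees (test-local enumeration)."""
    labels = sorted(labels)

    def insertions(t, x):
        yield (t, x)
        if isinstance(t, tuple):
            left, right = t
            for nl in insertions(left, x):
                yield (nl, right)
            for nr in insertions(right, x):
                yield (left, nr)

    shapes = [labels[1]]
    for lab in labels[2:]:
        shapes = [s2 for s in shapes for s2 in insertions(s, lab)]

    def to_tree(shape):
        def conv(t):
            if isinstance(t, str):
                return Node(t, t)
            node = Node()
            node.add_child(conv(t[0]))
            node.add_child(conv(t[1]))
            return node

        root = Node()
        root.add_child(Node(labels[0], labels[0]))
        if isinstance(shape, tuple):
            root.add_child(conv(shape[0]))
            root.add_child(conv(shape[1]))
        else:
            root.add_child(conv(shape))
        return GeneTree(root, is_rooted=False)

    return [to_tree(s) for s in shapes]


def four_point_score(tree: GeneTree, table: dp.QuartetTable):
    """Satisfied table weight via the four-point oracle."""
    dist = topological_distances(tree)
    species = tree.species_set()
    satisfied = 0
    for topology, weight in table.items():
        if not topology.species <= species:
            continue
        a, b = topology.pair1
        c, d = topology.pair2
        if four_point_quartet(dist, a, b, c, d) == topology:
            satisfied += weight
    return satisfied
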