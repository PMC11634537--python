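"""Quartet enumeration, gene-tree-frequency tables and speciation-driven quartets.

A quartet topology on four species {a, b, c, d} is one of ab|cd, ac|bd,
ad|bc — an unordered pair of unordered pairs, kept in a canonical form.
The GTF (gene tree frequency) table maps each topology to the number of
input single-copy trees that contain the four species and induce it;
this is the weighting used by weighted quartet amalgamation.

A speciation-driven quartet (SQ) of a tagged multi-copy tree is an
induced quartet of four genes from four distinct species for which
every cross-pair least common ancestor is tagged speciation; only such
quartets carry speciation signal.  Both enumerations are explicit
O(n^4) scans over the 4-subsets of leaves.
"""

from __future__ import annotations

import re
from itertools import combinations
from typing import Iterable, Iterator

from .trees import GeneTree, Node, SPECIATION, TreeError

__all__ = [
    "QuartetTopology",
    "QuartetTable",
    "induced_quartet",
    "gene_quartet",
    "all_induced_quartets",
    "gtf_table",
    "sq_set",
    "covered_quartets",
    "write_quartets",
    "read_quartets",
]


class QuartetTopology:
    """Canonical unrooted quartet topology ``ab|cd`` on four species.

    Within each pair the labels are sorted; the pair containing the
    overall smallest label comes first.
    """

    __slots__ = ("pair1", "pair2")

    def __init__(self, pair1: Iterable[str], pair2: Iterable[str]):
        p1 = tuple(sorted(pair1))
        p2 = tuple(sorted(pair2))
        if len(p1) != 2 or len(p2) != 2:
            raise ValueError("each side of a quartet must have two labels")
        if len({*p1, *p2}) != 4:
            raise ValueError("quartet labels must be distinct")
        if p2[0] < p1[0]:
            p1, p2 = p2, p1
        self.pair1 = p1
        self.pair2 = p2

    @property
    def species(self) -> frozenset:
        return frozenset(self.pair1) | frozenset(self.pair2)

    def __eq__(self, other) -> bool:
        return (isinstance(other, QuartetTopology)
                and self.pair1 == other.pair1 and self.pair2 == other.pair2)

    def __hash__(self) -> int:
        return hash((self.pair1, self.pair2))

    def __lt__(self, other: "QuartetTopology") -> bool:
        return (self.pair1, self.pair2) < (other.pair1, other.pair2)

    def __repr__(self) -> str:
        return f"{self.pair1[0]},{self.pair1[1]}|{self.pair2[0]},{self.pair2[1]}"

    def newick(self) -> str:
        a, b = self.pair1
        c, d = self.pair2
        return f"(({a},{b}),({c},{d}));"


class QuartetTable(dict):
    """Mapping from :class:`QuartetTopology` to non-negative weight."""

    def add(self, topology: QuartetTopology, weight: float = 1) -> None:
        if weight < 0:
            raise ValueError("quartet weights must be non-negative")
        self[topology] = self.get(topology, 0) + weight

    @property
    def total_weight(self):
        return sum(self.values())

    def weight_on(self, species: Iterable[str]):
        """Total weight of entries whose species all lie in *species*."""
        wanted = set(species)
        return sum(w for t, w in self.items() if t.species <= wanted)


# ---------------------------------------------------------------------------
# Induced quartets of single-copy trees
# ---------------------------------------------------------------------------


def _ancestor_path(leaf: Node) -> list[Node]:
    path = []
    node: Node | None = leaf
    while node is not None:
        path.append(node)
        node = node.parent
    return path


def _path_nodes(x: Node, y: Node) -> set[int]:
    """ids of the nodes on the tree path between leaves x and y."""
    anc_x = _ancestor_path(x)
    anc_y = _ancestor_path(y)
    ids_x = {id(n): i for i, n in enumerate(anc_x)}
    for j, n in enumerate(anc_y):
        if id(n) in ids_x:
            i = ids_x[id(n)]
            return {id(m) for m in anc_x[: i + 1]} | {id(m) for m in anc_y[:j]}
    raise TreeError("leaves are not in the same tree")


def _quartet_of_leaves(l1: Node, l2: Node, l3: Node, l4: Node,
                       key=lambda n: n.species) -> QuartetTopology:
    """Topology induced on four leaves of one tree (path disjointness)."""
    for (a, b), (c, d) in (((l1, l2), (l3, l4)),
                           ((l1, l3), (l2, l4)),
                           ((l1, l4), (l2, l3))):
        if not (_path_nodes(a, b) & _path_nodes(c, d)):
            return QuartetTopology((key(a), key(b)), (key(c), key(d)))
    raise TreeError("no resolved quartet topology (tree not binary?)")


def induced_quartet(tree: GeneTree, species: Iterable[str]) -> QuartetTopology:
    """The unique topology *tree* induces on four species.

    The tree must be single-copy and contain all four species.
    """
    wanted = list(species)
    if len(set(wanted)) != 4:
        raise ValueError("exactly four distinct species required")
    by_species: dict[str, Node] = {}
    for leaf in tree.leaves():
        if leaf.species in by_species and leaf.species in wanted:
            raise TreeError(f"tree is not single-labeled (species {leaf.species!r})")
        by_species[leaf.species] = leaf
    missing = [s for s in wanted if s not in by_species]
    if missing:
        raise TreeError(f"species absent from tree: {', '.join(sorted(missing))}")
    leaves = [by_species[s] for s in wanted]
    return _quartet_of_leaves(*leaves)


def gene_quartet(tree: GeneTree, gene_labels: Iterable[str]) -> QuartetTopology:
    """Species-level topology induced on four named gene copies.

    The four genes must come from four distinct species (the sampling
    used when one copy is drawn per species from a multi-copy tree).
    """
    wanted = set(gene_labels)
    if len(wanted) != 4:
        raise ValueError("exactly four distinct gene labels required")
    leaves = [leaf for leaf in tree.leaves() if leaf.label in wanted]
    if len(leaves) != 4:
        missing = wanted - {leaf.label for leaf in leaves}
        raise TreeError(f"gene labels absent from tree: {', '.join(sorted(missing))}")
    if len({leaf.species for leaf in leaves}) != 4:
        raise TreeError("the four genes must come from four distinct species")
    return _quartet_of_leaves(*leaves)


def all_induced_quartets(tree: GeneTree) -> Iterator[QuartetTopology]:
    """Induced topology of every 4-subset of a single-copy tree."""
    leaves = sorted(tree.leaves(), key=lambda n: n.species or "")
    species = [leaf.species for leaf in leaves]
    if len(set(species)) != len(species):
        raise TreeError("tree is not single-labeled")
    for quad in combinations(leaves, 4):
        yield _quartet_of_leaves(*quad)


def gtf_table(trees: Iterable[GeneTree]) -> QuartetTable:
    """Gene-tree-frequency weights over a collection of single-copy trees.

    The weight of a topology is the number of trees that contain its
    four species and induce it; trees with fewer than four leaves are
    skipped (they induce no quartets).
    """
    table = QuartetTable()
    for tree in trees:
        if tree.n_leaves < 4:
            continue
        for topology in all_induced_quartets(tree):
            table.add(topology, 1)
    return table


def covered_quartets(trees: Iterable[GeneTree]) -> set[QuartetTopology]:
    """Union of induced quartet topologies over single-copy trees."""
    covered: set[QuartetTopology] = set()
    for tree in trees:
        if tree.n_leaves < 4:
            continue
        covered.update(all_induced_quartets(tree))
    return covered


# ---------------------------------------------------------------------------
# Speciation-driven quartets of tagged multi-copy trees
# ---------------------------------------------------------------------------


def _lca(x: Node, y: Node) -> Node:
    anc_x = _ancestor_path(x)
    ids_x = {id(n) for n in anc_x}
    node: Node | None = y
    while node is not None:
        if id(node) in ids_x:
            return node
        node = node.parent
    raise TreeError("leaves are not in the same tree")


def sq_set(tree: GeneTree) -> set[QuartetTopology]:
    """Speciation-driven quartets of a tagged tree, at species level.

    Every 4-subset of genes drawn from four distinct species is
    examined; its induced topology ``ab|cd`` is speciation-driven iff
    all cross-pair LCAs (LCA(x, y) for x in {a,b}, y in {c,d}; at most
    two distinct nodes) are tagged speciation.
    """
    leaves = tree.leaves()
    if any(n.tag is None for n in tree.internal_nodes()):
        raise TreeError("sq_set requires a tagged tree; run tag_rooted first")
    found: set[QuartetTopology] = set()
    for quad in combinations(leaves, 4):
        if len({leaf.species for leaf in quad}) != 4:
            continue
        topo_genes = _quartet_of_leaves(*quad, key=lambda n: n.label)
        by_label = {leaf.label: leaf for leaf in quad}
        side1 = [by_label[g] for g in topo_genes.pair1]
        side2 = [by_label[g] for g in topo_genes.pair2]
        if all(_lca(x, y).tag == SPECIATION for x in side1 for y in side2):
            found.add(QuartetTopology((side1[0].species, side1[1].species),
                                      (side2[0].species, side2[1].species)))
    return found


# ---------------------------------------------------------------------------
# Weighted quartet files
# ---------------------------------------------------------------------------

_QUARTET_LINE = re.compile(
    r"^\(\(([^(),;]+),([^(),;]+)\),\(([^(),;]+),([^(),;]+)\)\);\s+(\S+)$")


def write_quartets(table: QuartetTable, path) -> None:
    """Write ``((A,B),(C,D)); W`` lines in sorted, canonical order."""
    with open(path, "w") as fh:
        for topology in sorted(table):
            weight = table[topology]
            if isinstance(weight, float) and weight.is_integer():
                weight = int(weight)
            fh.write(f"{topology.newick()} {weight}\n")


def read_quartets(path) -> QuartetTable:
    """Read a weighted-quartet file written by :func:`write_quartets`."""
    table = QuartetTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            m = _QUARTET_LINE.match(line)
            if not m:
                raise ValueError(f"{path}:{lineno}: unparsable quartet line: {line!r}")
            a, b, c, d, w = m.groups()
            weight = float(w)
            if weight.is_integer():
                weight = int(weight)
            table.add(QuartetTopology((a, b), (c, d)), weight)
    return table
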