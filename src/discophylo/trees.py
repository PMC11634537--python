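"""Phylogenetic tree model and newick / species-mapping I/O.

The internal tree model is a small rooted node structure carrying the
fields the paralog-aware algorithms need: a gene label and a species
label on every leaf, and a duplication/speciation tag on internal nodes.
Multi-labeled trees (several leaves per species) are first-class; trees
whose newick root has three or more children are treated as unrooted.

Newick parsing is delegated to dendropy; polytomies below the root are
resolved deterministically to binary by a left-to-right caterpillar
expansion, since the tagging and decomposition algorithms assume binary
duplication nodes.
"""

from __future__ import annotations

import random
from typing import Callable, Iterable, Iterator, Sequence

import dendropy

__all__ = [
    "DUPLICATION",
    "SPECIATION",
    "TreeError",
    "NewickParseError",
    "MappingError",
    "Node",
    "GeneTree",
    "SpeciesMapping",
    "parse_newick",
    "read_newick_file",
    "write_newick",
    "write_newick_file",
    "resolve_species",
    "restrict_to_species",
    "canonical_topology",
    "unrooted_bipartitions",
    "random_resolved_topology",
]

DUPLICATION = "D"
SPECIATION = "S"


class TreeError(ValueError):
    """Base error for tree-structure problems."""


class NewickParseError(TreeError):
    """Raised when a newick string cannot be parsed."""


class MappingError(TreeError):
    """Raised when a species mapping does not cover the gene labels."""


class Node:
    """A node of a (possibly multi-labeled) gene tree.

    Leaves carry ``label`` (the gene label) and, after mapping
    resolution, ``species``.  Internal nodes may carry a ``tag``
    (:data:`DUPLICATION` or :data:`SPECIATION`) and an optional
    ``label`` (as read from or written to newick internal labels).
    """

    __slots__ = ("children", "parent", "label", "species", "tag", "length")

    def __init__(self, label: str | None = None, species: str | None = None,
                 length: float | None = None):
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.label = label
        self.species = species
        self.tag: str | None = None
        self.length = length

    # -- structure ---------------------------------------------------------

    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    def postorder(self) -> Iterator["Node"]:
        stack: list[tuple[Node, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            for c in reversed(node.children):
                stack.append(c)

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf()]

    def copy(self) -> "Node":
        new = Node(self.label, self.species, self.length)
        new.tag = self.tag
        for c in self.children:
            new.add_child(c.copy())
        return new

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.is_leaf():
            return f"<Leaf {self.label!r} sp={self.species!r}>"
        return f"<Node tag={self.tag!r} n_children={len(self.children)}>"


class GeneTree:
    """A rooted or unrooted gene tree over :class:`Node` objects."""

    def __init__(self, root: Node, is_rooted: bool = True):
        self.root = root
        self.is_rooted = is_rooted

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf()]

    def gene_labels(self) -> list[str]:
        return [leaf.label or "" for leaf in self.leaves()]

    def species_set(self) -> set[str]:
        return {leaf.species for leaf in self.leaves() if leaf.species is not None}

    def species_labels(self) -> list[str]:
        return [leaf.species or leaf.label or "" for leaf in self.leaves()]

    def is_binary(self) -> bool:
        """True if every internal node is binary (the root of an unrooted
        tree is allowed three children)."""
        for node in self.internal_nodes():
            if node is self.root and not self.is_rooted:
                if len(node.children) != 3 and len(node.children) != 2:
                    return False
            elif len(node.children) != 2:
                return False
        return True

    def copy(self) -> "GeneTree":
        return GeneTree(self.root.copy(), self.is_rooted)

    def __repr__(self) -> str:  # pragma: no cover
        kind = "rooted" if self.is_rooted else "unrooted"
        return f"<GeneTree {kind} n_leaves={self.n_leaves}>"


# ---------------------------------------------------------------------------
# Species mappings
# ---------------------------------------------------------------------------


class SpeciesMapping:
    """Assignment of gene labels to species labels.

    Either an explicit ``{gene: species}`` table (e.g. read from a
    two-column mapping file) or a delimiter rule under which the species
    is the prefix of the gene label before the first delimiter (labels
    without the delimiter map to themselves, so plain species names in
    single-copy trees resolve unchanged).
    """

    def __init__(self, pairs: dict[str, str] | None = None,
                 delimiter: str | None = None):
        if (pairs is None) == (delimiter is None):
            raise ValueError("provide exactly one of pairs or delimiter")
        self.pairs = dict(pairs) if pairs is not None else None
        self.delimiter = delimiter

    @classmethod
    def from_pairs(cls, pairs: dict[str, str]) -> "SpeciesMapping":
        return cls(pairs=pairs)

    @classmethod
    def from_delimiter(cls, delimiter: str = "_") -> "SpeciesMapping":
        if not delimiter:
            raise ValueError("delimiter must be non-empty")
        return cls(delimiter=delimiter)

    @classmethod
    def from_file(cls, path) -> "SpeciesMapping":
        """Read a two-column whitespace-separated ``gene species`` file."""
        pairs: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) != 2:
                    raise MappingError(
                        f"{path}:{lineno}: expected two columns, got {len(fields)}")
                pairs[fields[0]] = fields[1]
        return cls(pairs=pairs)

    def species_for(self, gene_label: str) -> str | None:
        if self.pairs is not None:
            return self.pairs.get(gene_label)
        assert self.delimiter is not None
        return gene_label.split(self.delimiter, 1)[0]

    def __repr__(self) -> str:  # pragma: no cover
        if self.pairs is not None:
            return f"<SpeciesMapping explicit n={len(self.pairs)}>"
        return f"<SpeciesMapping delimiter={self.delimiter!r}>"


def resolve_species(tree: GeneTree, mapping: SpeciesMapping) -> GeneTree:
    """Set ``species`` on every leaf of *tree* in place (and return it).

    Raises :class:`MappingError` listing any gene labels the mapping
    does not cover.  Idempotent.
    """
    missing = []
    for leaf in tree.leaves():
        if leaf.label is None:
            missing.append("<unlabeled leaf>")
            continue
        sp = mapping.species_for(leaf.label)
        if sp is None or sp == "":
            missing.append(leaf.label)
        else:
            leaf.species = sp
    if missing:
        raise MappingError(
            "species mapping does not cover gene labels: " + ", ".join(sorted(missing)))
    return tree


# ---------------------------------------------------------------------------
# Newick I/O (parsing via dendropy)
# ---------------------------------------------------------------------------


def _from_dendropy(dnode: "dendropy.Node") -> Node:
    node = Node()
    if dnode.is_leaf():
        if dnode.taxon is not None:
            node.label = dnode.taxon.label
        else:
            node.label = dnode.label
    else:
        node.label = dnode.label
    node.length = dnode.edge.length
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child))
    return node


def _resolve_polytomies(tree: GeneTree) -> None:
    """Left-to-right caterpillar expansion of polytomies, in place.

    The root of an unrooted tree is reduced to three children, every
    other internal node to two.
    """
    for node in list(tree.postorder()):
        limit = 3 if (node is tree.root and not tree.is_rooted) else 2
        while len(node.children) > limit:
            first, second = node.children[0], node.children[1]
            merged = Node()
            merged.add_child(first)
            merged.add_child(second)
            merged.parent = node
            node.children[0:2] = [merged]


def parse_newick(text: str, *, read_tags: bool = False,
                 resolve_polytomies: bool = True) -> GeneTree:
    """Parse a single newick string into a :class:`GeneTree`.

    Leaf labels are preserved verbatim (underscores included); branch
    lengths are kept when present.  A root with three or more children
    marks the tree unrooted.  With ``read_tags`` the internal-node
    labels ``"D"``/``"S"`` are interpreted as duplication/speciation
    tags (the dialect :func:`write_newick` emits).
    """
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickParseError(
            f"newick string must end in ';' (got {stripped[-10:]!r} at position {len(stripped)})")
    try:
        dtree = dendropy.Tree.get(
            data=stripped, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True, case_sensitive_taxon_labels=True,
            taxon_namespace=dendropy.TaxonNamespace(is_case_sensitive=True))
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed newick: {exc}") from exc
    root = _from_dendropy(dtree.seed_node)
    is_rooted = len(root.children) <= 2
    tree = GeneTree(root, is_rooted=is_rooted)
    if resolve_polytomies:
        _resolve_polytomies(tree)
    if read_tags:
        for node in tree.internal_nodes():
            if node.label in (DUPLICATION, SPECIATION):
                node.tag = node.label
    labels = tree.gene_labels()
    if any(not lab for lab in labels):
        raise NewickParseError("every leaf must carry a non-empty label")
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise NewickParseError(f"duplicate gene labels in tree: {', '.join(dupes)}")
    return tree


def read_newick_file(path, *, read_tags: bool = False) -> list[GeneTree]:
    """Read a multi-tree newick file, one tree per line."""
    trees = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                trees.append(parse_newick(line, read_tags=read_tags))
            except NewickParseError as exc:
                raise NewickParseError(f"{path}:{lineno}: {exc}") from exc
    return trees


def _format_length(length: float) -> str:
    return format(length, ".12g")


def write_newick(tree: GeneTree, *, include_tags: bool = False,
                 include_lengths: bool = True, use_species: bool = False) -> str:
    """Serialize a tree to a newick string (with trailing ``;``).

    With ``include_tags``, duplication/speciation tags are written as
    internal-node labels ``D``/``S``.  With ``use_species``, leaves are
    written under their species labels instead of gene labels.
    """

    def fmt(node: Node) -> str:
        if node.is_leaf():
            s = (node.species if use_species and node.species else node.label) or ""
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if include_tags and node.tag:
                s += node.tag
            elif node.label:
                s += node.label
        if include_lengths and node.length is not None:
            s += ":" + _format_length(node.length)
        return s

    return fmt(tree.root) + ";"


def write_newick_file(trees: Iterable[GeneTree], path, **kwargs) -> None:
    with open(path, "w") as fh:
        for tree in trees:
            fh.write(write_newick(tree, **kwargs) + "\n")


# ---------------------------------------------------------------------------
# Topology utilities
# ---------------------------------------------------------------------------


def _filtered_copy(node: Node, keep: Callable[[Node], bool]) -> Node | None:
    """Copy of the subtree at *node* keeping only leaves with keep(leaf),
    suppressing nodes left with a single child (branch lengths add)."""
    if node.is_leaf():
        return node.copy() if keep(node) else None
    kept = [c2 for c in node.children if (c2 := _filtered_copy(c, keep)) is not None]
    if not kept:
        return None
    if len(kept) == 1:
        child = kept[0]
        if node.length is not None or child.length is not None:
            child.length = (node.length or 0.0) + (child.length or 0.0)
        return child
    new = Node(node.label, node.species, node.length)
    new.tag = node.tag
    for c in kept:
        new.add_child(c)
    return new


def restrict_to_species(tree: GeneTree, species: Iterable[str]) -> GeneTree:
    """A new tree restricted to leaves whose species is in *species*."""
    wanted = set(species)
    root = _filtered_copy(tree.root, lambda leaf: leaf.species in wanted)
    if root is None:
        raise TreeError("restriction removed every leaf")
    return GeneTree(root, tree.is_rooted)


def canonical_topology(tree: GeneTree, *, use_species: bool = False):
    """A hashable canonical form of the rooted topology (child order
    independent).  Leaves are keyed by species label when requested."""

    def canon(node: Node):
        if node.is_leaf():
            key = (node.species if use_species else node.label) or ""
            return ("L", key)
        return ("I",) + tuple(sorted(canon(c) for c in node.children))

    return canon(tree.root)


def unrooted_bipartitions(tree: GeneTree, *, use_species: bool = False) -> set[frozenset]:
    """The set of nontrivial bipartitions of the unrooted topology, each
    as a frozenset of the two leaf-label frozensets."""
    all_labels = frozenset(tree.species_labels() if use_species else tree.gene_labels())
    biparts: set[frozenset] = set()

    def clade(node: Node) -> frozenset:
        if node.is_leaf():
            key = (node.species if use_species else node.label) or ""
            return frozenset([key])
        labels = frozenset().union(*(clade(c) for c in node.children))
        if 1 < len(labels) < len(all_labels) - 1:
            biparts.add(frozenset([labels, all_labels - labels]))
        return labels

    clade(tree.root)
    return biparts


def random_resolved_topology(labels: Sequence[str], rng: random.Random | int = 0) -> GeneTree:
    """A uniformly random unrooted binary topology on *labels* grown by
    stepwise random insertion; leaves get ``species == label``."""
    if isinstance(rng, int):
        rng = random.Random(rng)
    labels = list(labels)
    if len(labels) < 3:
        root = Node()
        for lab in labels:
            root.add_child(Node(lab, lab))
        return GeneTree(root, is_rooted=False)
    root = Node()
    for lab in labels[:3]:
        root.add_child(Node(lab, lab))
    # edges: nodes other than the root (each node identifies its parent edge)
    edges = [c for c in root.children]
    for lab in labels[3:]:
        target = rng.choice(edges)
        parent = target.parent
        idx = parent.children.index(target)
        mid = Node()
        leaf = Node(lab, lab)
        parent.children[idx] = mid
        mid.parent = parent
        mid.add_child(target)
        mid.add_child(leaf)
        edges.append(mid)
        edges.append(leaf)
    return GeneTree(root, is_rooted=False)
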