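"""DLCoal simulation: duplication/loss locus trees and bounded-coalescent gene trees.

The unified duplication–loss–coalescence model composes two stages.
Top-down, a locus tree grows from the species tree: along every
lineage, duplications arrive at rate ``dup_rate`` and losses at rate
``loss_rate`` (independent Poisson processes, per gene per generation);
a duplication spawns a daughter locus, a loss terminates the lineage.
Bottom-up, a gene tree is drawn inside the locus tree by the bounded
multispecies coalescent with constant haploid population size ``N``:
lineages coalesce at rate ``k(k-1)/(2N)`` within each locus branch, and
at a duplication node the daughter locus is constrained to exactly one
ancestral lineage at the duplication time.  The bound is enforced by
rejection — the daughter subtree's coalescent history is redrawn until
it satisfies the bound, which is exact whenever it terminates.

Branch lengths are in generations throughout; divide by ``N`` to read
them in (haploid) coalescent units.  Rates quoted per year convert to
per generation by multiplying with the generation time.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .trees import GeneTree, Node, TreeError

__all__ = [
    "DLCoalParams",
    "LocusNode",
    "LocusTree",
    "Dataset",
    "FamilyExtinctionError",
    "BoundedCoalescentError",
    "simulate_locus_tree",
    "simulate_gene_tree",
    "generate_dataset",
    "random_species_tree",
]

SPECIATION_EVENT = "speciation"
DUPLICATION_EVENT = "duplication"
LEAF_EVENT = "leaf"


class FamilyExtinctionError(RuntimeError):
    """Every copy of the gene family was lost before reaching the leaves."""


class BoundedCoalescentError(RuntimeError):
    """Rejection sampling of the bounded coalescent exhausted its retries."""


@dataclass(frozen=True)
class DLCoalParams:
    """Parameters of one DLCoal simulation.

    ``species_tree`` must be rooted with branch lengths in generations;
    ``dup_rate``/``loss_rate`` are per gene per generation; ``pop_size``
    is the constant haploid population size.
    """

    species_tree: GeneTree
    dup_rate: float
    loss_rate: float
    pop_size: float
    n_genes: int = 1
    seed: int = 0
    max_coalescent_retries: int = 500

    def __post_init__(self):
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.pop_size <= 0:
            raise ValueError("pop_size must be positive")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        for node in self.species_tree.postorder():
            if node.parent is not None and (node.length is None or node.length <= 0):
                raise ValueError("species tree branch lengths must be positive")


class LocusNode:
    """Node of a locus tree: a speciation, duplication or surviving copy.

    ``length`` is the time in generations since the parent locus node;
    at a duplication, ``daughter_index`` marks which child follows the
    novel locus (the other follows the mother locus).
    """

    __slots__ = ("event", "children", "parent", "length", "species",
                 "label", "daughter_index")

    def __init__(self, event: str, length: float = 0.0,
                 species: str | None = None):
        self.event = event
        self.children: list[LocusNode] = []
        self.parent: LocusNode | None = None
        self.length = length
        self.species = species
        self.label: str | None = None
        self.daughter_index: int | None = None

    def add_child(self, child: "LocusNode") -> "LocusNode":
        child.parent = self
        self.children.append(child)
        return child

    def postorder(self):
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def leaves(self):
        return [n for n in self.postorder() if not n.children]


@dataclass
class LocusTree:
    """A pruned locus tree (all extinct lineages removed)."""

    root: LocusNode
    n_duplications: int = 0

    def leaves(self) -> list[LocusNode]:
        return self.root.leaves()


@dataclass
class Dataset:
    """Output of :func:`generate_dataset`."""

    species_tree: GeneTree
    gene_trees: list[GeneTree] = field(default_factory=list)
    locus_trees: list[LocusTree] = field(default_factory=list)
    n_redraws: int = 0
    n_bound_failures: int = 0


# ---------------------------------------------------------------------------
# Locus tree: top-down duplication/loss
# ---------------------------------------------------------------------------


def _grow_lineage(sp_node: Node, remaining: float, dist: float,
                  dup_rate: float, loss_rate: float,
                  rng: random.Random) -> LocusNode:
    """One locus lineage evolving toward *sp_node* with *remaining* time
    left on the species branch; *dist* generations since the last locus
    node."""
    total = dup_rate + loss_rate
    while True:
        wait = rng.expovariate(total) if total > 0 else float("inf")
        if wait >= remaining:
            dist += remaining
            if sp_node.is_leaf():
                leaf = LocusNode(LEAF_EVENT, dist, species=sp_node.species or sp_node.label)
                return leaf
            node = LocusNode(SPECIATION_EVENT, dist)
            for child in sp_node.children:
                node.add_child(_grow_lineage(child, child.length, 0.0,
                                             dup_rate, loss_rate, rng))
            return node
        remaining -= wait
        dist += wait
        if rng.random() < dup_rate / total:
            node = LocusNode(DUPLICATION_EVENT, dist)
            node.add_child(_grow_lineage(sp_node, remaining, 0.0,
                                         dup_rate, loss_rate, rng))  # mother
            node.add_child(_grow_lineage(sp_node, remaining, 0.0,
                                         dup_rate, loss_rate, rng))  # daughter
            node.daughter_index = 1
            return node
        return LocusNode("loss", dist)


def _prune_extinct(node: LocusNode) -> LocusNode | None:
    """Remove lost lineages; contract nodes left with one child (their
    branch lengths add).  Duplication nodes survive as duplications only
    when both the mother and the daughter side persist."""
    if not node.children:
        return node if node.event == LEAF_EVENT else None
    kept: list[tuple[int, LocusNode]] = []
    for i, child in enumerate(node.children):
        pruned = _prune_extinct(child)
        if pruned is not None:
            kept.append((i, pruned))
    if not kept:
        return None
    if len(kept) == 1:
        child = kept[0][1]
        child.length += node.length
        child.parent = None
        return child
    new = LocusNode(node.event, node.length)
    for orig_idx, child in kept:
        new.add_child(child)
        if node.event == DUPLICATION_EVENT and orig_idx == node.daughter_index:
            new.daughter_index = len(new.children) - 1
    return new


def simulate_locus_tree(params: DLCoalParams,
                        rng: random.Random | None = None) -> LocusTree:
    """Draw one locus tree under the top-down duplication/loss process.

    Raises :class:`FamilyExtinctionError` when no copy survives.
    Deterministic given the rng state (``params.seed`` when none is
    passed).
    """
    if rng is None:
        rng = random.Random(params.seed)
    sp_root = params.species_tree.root
    root = LocusNode(SPECIATION_EVENT, 0.0)
    if sp_root.is_leaf():
        raise TreeError("species tree must have at least two species")
    for child in sp_root.children:
        root.add_child(_grow_lineage(child, child.length, 0.0,
                                     params.dup_rate, params.loss_rate, rng))
    pruned = _prune_extinct(root)
    if pruned is None:
        raise FamilyExtinctionError("all gene copies were lost")
    tree = LocusTree(pruned)
    counters: dict[str, int] = {}
    n_dups = 0
    for node in tree.root.postorder():
        if not node.children:
            counters[node.species] = counters.get(node.species, 0) + 1
            node.label = f"{node.species}_{counters[node.species]}"
        elif node.event == DUPLICATION_EVENT:
            n_dups += 1
    tree.n_duplications = n_dups
    return tree


# ---------------------------------------------------------------------------
# Gene tree: bottom-up bounded coalescent
# ---------------------------------------------------------------------------


def _depths(root: LocusNode) -> dict[int, float]:
    depth = {id(root): 0.0}
    stack = [root]
    while stack:
        node = stack.pop()
        for child in node.children:
            depth[id(child)] = depth[id(node)] + child.length
            stack.append(child)
    return depth


def _coalesce_interval(lineages: list[tuple[Node, float]], start_depth: float,
                       end_depth: float, pop_size: float,
                       rng: random.Random) -> list[tuple[Node, float]]:
    """Coalesce backwards in time from *start_depth* up to *end_depth*."""
    lineages = list(lineages)
    current = start_depth
    while len(lineages) >= 2:
        k = len(lineages)
        rate = k * (k - 1) / 2.0 / pop_size
        wait = rng.expovariate(rate)
        if current - wait < end_depth:
            break
        current -= wait
        i, j = sorted(rng.sample(range(k), 2))
        node_j, depth_j = lineages.pop(j)
        node_i, depth_i = lineages.pop(i)
        parent = Node()
        parent.add_child(node_i)
        parent.add_child(node_j)
        node_i.length = depth_i - current
        node_j.length = depth_j - current
        lineages.append((parent, current))
    return lineages


def simulate_gene_tree(locus: LocusTree, pop_size: float,
                       rng: random.Random | int = 0,
                       max_retries: int = 10000) -> GeneTree:
    """Draw a gene tree inside *locus* under the bounded coalescent.

    Leaf labels are the locus tree's ``species_index`` copy labels, with
    the species recoverable as the prefix before ``_``.
    """
    if isinstance(rng, int):
        rng = random.Random(rng)
    depth = _depths(locus.root)

    def gather(node: LocusNode) -> list[tuple[Node, float]]:
        """Gene lineages present at *node* (bottom of its own branch)."""
        if not node.children:
            return [(Node(node.label, node.species), depth[id(node)])]
        gathered: list[tuple[Node, float]] = []
        for idx, child in enumerate(node.children):
            if node.event == DUPLICATION_EVENT and idx == node.daughter_index:
                # bounded coalescent: the daughter locus must reach the
                # duplication time as a single lineage (rejection sampling)
                for _attempt in range(max_retries):
                    candidate = lineages_at_top(child)
                    if len(candidate) == 1:
                        gathered.extend(candidate)
                        break
                else:
                    raise BoundedCoalescentError(
                        f"daughter locus failed to coalesce to one lineage "
                        f"in {max_retries} draws")
            else:
                gathered.extend(lineages_at_top(child))
        return gathered

    def lineages_at_top(node: LocusNode) -> list[tuple[Node, float]]:
        """Gene lineages surviving to the top of *node*'s branch."""
        top = depth[id(node)] - node.length
        return _coalesce_interval(gather(node), depth[id(node)], top, pop_size, rng)

    root_lineages = gather(locus.root)
    # ancestral population: unbounded coalescence above the locus root
    current = 0.0
    while len(root_lineages) >= 2:
        k = len(root_lineages)
        rate = k * (k - 1) / 2.0 / pop_size
        current -= rng.expovariate(rate)
        i, j = sorted(rng.sample(range(k), 2))
        node_j, depth_j = root_lineages.pop(j)
        node_i, depth_i = root_lineages.pop(i)
        parent = Node()
        parent.add_child(node_i)
        parent.add_child(node_j)
        node_i.length = depth_i - current
        node_j.length = depth_j - current
        root_lineages.append((parent, current))
    root = root_lineages[0][0]
    root.length = None
    return GeneTree(root, is_rooted=True)


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------


def generate_dataset(params: DLCoalParams) -> Dataset:
    """Draw ``n_genes`` gene families, redrawing extinct ones.

    All randomness flows from ``params.seed``; the redraw count is
    reported on the returned :class:`Dataset`.
    """
    rng = random.Random(params.seed)
    dataset = Dataset(species_tree=params.species_tree)
    max_total_attempts = 1000 * params.n_genes + 1000
    attempts = 0
    while len(dataset.gene_trees) < params.n_genes:
        attempts += 1
        if attempts > max_total_attempts:
            raise FamilyExtinctionError(
                "too many extinct families; loss rate too high for these settings")
        try:
            locus = simulate_locus_tree(params, rng)
        except FamilyExtinctionError:
            dataset.n_redraws += 1
            continue
        try:
            gene = simulate_gene_tree(locus, params.pop_size, rng,
                                      params.max_coalescent_retries)
        except BoundedCoalescentError:
            # a family whose duplication history makes the daughter bound
            # (practically) unsatisfiable by rejection; redraw the family
            dataset.n_bound_failures += 1
            dataset.n_redraws += 1
            continue
        dataset.locus_trees.append(locus)
        dataset.gene_trees.append(gene)
    return dataset


def random_species_tree(labels, depth_scale: float,
                        rng: random.Random | int = 0) -> GeneTree:
    """An ultrametric species tree grown by a Kingman coalescent on
    *labels*: pairs merge at exponential times so branch lengths (in the
    same generations unit as *depth_scale*) are realistic for MSC work.
    ``depth_scale`` plays the role of the haploid population size that
    shapes the merge times (one coalescent unit = ``depth_scale``
    generations)."""
    if isinstance(rng, int):
        rng = random.Random(rng)
    lineages: list[tuple[Node, float]] = [(Node(lab, lab), 0.0) for lab in labels]
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.expovariate(k * (k - 1) / 2.0) * depth_scale
        i, j = sorted(rng.sample(range(k), 2))
        node_j, tj = lineages.pop(j)
        node_i, ti = lineages.pop(i)
        parent = Node()
        parent.add_child(node_i)
        parent.add_child(node_j)
        node_i.length = t - ti
        node_j.length = t - tj
        lineages.append((parent, t))
    root = lineages[0][0]
    root.length = None
    return GeneTree(root, is_rooted=True)
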