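"""DISCO / DISCO-R decomposition of tagged multi-copy gene trees.

A tagged rooted binary gene tree is traversed in post-order; at every
duplication node one child subtree is detached (the pruning strategy
decides which) and emitted as an output tree.  In DISCO-R mode a copy
of the detached subtree is additionally trimmed down to the species
absent from the remaining backbone and regrafted where the duplication
node stood, so no species is ever lost from the backbone.  The residual
backbone is emitted last.  Every output is single-copy: no species
labels two of its leaves.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .trees import DUPLICATION, SPECIATION, GeneTree, Node, TreeError, _filtered_copy

__all__ = [
    "DecompositionConfig",
    "DecompositionResult",
    "decompose",
    "check_single_labeled",
]

MODES = ("disco", "disco-r")
PRUNE_STRATEGIES = ("larger", "smaller", "random")


@dataclass(frozen=True)
class DecompositionConfig:
    """Decomposition mode and pruning strategy.

    ``larger`` prunes the strictly larger child subtree (ties prune the
    right child), ``smaller`` the strictly smaller one (ties again the
    right child), ``random`` a uniformly chosen child driven by
    ``seed``.
    """

    mode: str = "disco"
    prune_strategy: str = "larger"
    seed: int | None = None

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.prune_strategy not in PRUNE_STRATEGIES:
            raise ValueError(
                f"prune_strategy must be one of {PRUNE_STRATEGIES}, got {self.prune_strategy!r}")
        if self.prune_strategy == "random" and self.seed is None:
            raise ValueError("prune_strategy 'random' requires a seed")


@dataclass
class DecompositionResult:
    """Ordered single-copy output trees with per-output provenance.

    ``provenance[i]`` is ``"pruned@<k>"`` (k = post-order index of the
    duplication node in the input) for detached subtrees and
    ``"backbone"`` for the residual tree; ``n_duplications`` is the
    number of duplication nodes seen.
    """

    outputs: list[GeneTree] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)
    n_duplications: int = 0

    @property
    def backbone(self) -> GeneTree:
        return self.outputs[-1]

    def __len__(self) -> int:
        return len(self.outputs)


def check_single_labeled(tree: GeneTree) -> bool:
    """True iff no species labels two leaves of *tree*."""
    species = [leaf.species for leaf in tree.leaves()]
    if any(sp is None for sp in species):
        raise TreeError("species labels not resolved")
    return len(set(species)) == len(species)


def _count_leaves(node: Node) -> int:
    return sum(1 for n in node.postorder() if n.is_leaf())


def _species_below(node: Node) -> set[str]:
    return {n.species for n in node.postorder() if n.is_leaf()}


def _contract_unary(node: Node, root_holder: list[Node]) -> None:
    """Splice out *node* (which has exactly one child) from its tree."""
    (child,) = node.children
    if node.length is not None or child.length is not None:
        child.length = (node.length or 0.0) + (child.length or 0.0)
    parent = node.parent
    if parent is None:
        child.parent = None
        root_holder[0] = child
    else:
        idx = parent.children.index(node)
        parent.children[idx] = child
        child.parent = parent
    node.children = []
    node.parent = None


def decompose(tree: GeneTree, config: DecompositionConfig = DecompositionConfig()) -> DecompositionResult:
    """Decompose a tagged rooted binary multi-copy tree into single-copy trees.

    Exactly ``D + 1`` trees are produced (D = duplication-node count):
    one untrimmed detached subtree per duplication node, in post-order,
    plus the residual backbone.  In ``disco-r`` mode the backbone
    retains every species of the input exactly once.  The input tree is
    not modified.
    """
    if not tree.is_rooted:
        raise TreeError("decompose requires a rooted tree")
    work = tree.copy()
    rng = random.Random(config.seed) if config.prune_strategy == "random" else None
    result = DecompositionResult()
    root_holder = [work.root]
    postorder_nodes = list(work.root.postorder())
    for index, node in enumerate(postorder_nodes):
        if node.is_leaf():
            continue
        if node.tag is None:
            raise TreeError("decompose requires a tagged tree; run tag_rooted first")
        if node.tag != DUPLICATION:
            continue
        if len(node.children) != 2:
            raise TreeError("duplication node is not binary")
        result.n_duplications += 1
        left, right = node.children
        if config.prune_strategy == "larger":
            pruned = left if _count_leaves(left) > _count_leaves(right) else right
        elif config.prune_strategy == "smaller":
            pruned = left if _count_leaves(left) < _count_leaves(right) else right
        else:
            assert rng is not None
            pruned = left if rng.random() < 0.5 else right
        node.remove_child(pruned)
        pruned.length = None
        result.outputs.append(GeneTree(pruned, is_rooted=True))
        result.provenance.append(f"pruned@{index}")
        if config.mode == "disco-r":
            backbone_species = _species_below(root_holder[0])
            trimmed = _filtered_copy(
                pruned, lambda leaf: leaf.species not in backbone_species)
            if trimmed is not None:
                trimmed.length = None
                node.add_child(trimmed)
                node.tag = SPECIATION  # child species sets are now disjoint
            else:
                _contract_unary(node, root_holder)
        else:
            _contract_unary(node, root_holder)
    backbone = GeneTree(root_holder[0], is_rooted=True)
    result.outputs.append(backbone)
    result.provenance.append("backbone")
    return result
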