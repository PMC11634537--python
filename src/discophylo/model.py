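"""Species-tree estimation model: decompose-then-amalgamate end to end.

:class:`SpeciesTreeModel` holds a collection of (possibly multi-copy)
gene family trees together with the pipeline configuration; ``fit()``
runs duplication/loss rooting and tagging, DISCO or DISCO-R
decomposition, gene-tree-frequency quartet weighting and weighted
quartet amalgamation, and returns a :class:`SpeciesTreeResult` carrying
the estimated tree, its quartet-consistency score and per-stage counts.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

from . import amalgamate as _amalgamate
from .decompose import DecompositionConfig, decompose
from .evaluate import TreeComparison, rf_distance
from .quartets import QuartetTable, gtf_table
from .tagging import TagRootConfig, count_duplications, root_and_tag
from .trees import GeneTree, SpeciesMapping, read_newick_file, resolve_species, write_newick

__all__ = ["SpeciesTreeModel", "SpeciesTreeResult"]


@dataclass
class SpeciesTreeResult:
    """Fitted species tree with diagnostics.

    ``satisfied_weight`` / ``normalized_score`` follow the WMQC
    objective: total (and fraction of) gene-tree quartet weight
    consistent with the estimated tree.
    """

    species_tree: GeneTree
    satisfied_weight: float
    normalized_score: float
    method: str
    taxa: list[str]
    n_gene_trees: int
    n_duplications: int
    n_single_copy_trees: int
    n_quartet_entries: int
    total_quartet_weight: float
    quartet_table: QuartetTable
    config: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    @property
    def newick(self) -> str:
        return write_newick(self.species_tree, include_lengths=False)

    def rf_to(self, true_tree: GeneTree) -> TreeComparison:
        """Normalized RF distance to a reference species tree."""
        return rf_distance(self.species_tree, true_tree)

    def summary(self) -> str:
        lines = [
            "Species tree estimation (decompose-then-amalgamate WMQC)",
            "=" * 58,
            f"{'input gene trees':<28}{self.n_gene_trees:>10}",
            f"{'duplication nodes':<28}{self.n_duplications:>10}",
            f"{'single-copy trees':<28}{self.n_single_copy_trees:>10}",
            f"{'taxa':<28}{len(self.taxa):>10}",
            f"{'quartet table entries':<28}{self.n_quartet_entries:>10}",
            f"{'total quartet weight':<28}{self.total_quartet_weight:>10}",
            f"{'inference method':<28}{self.method:>10}",
            f"{'satisfied quartet weight':<28}{self.satisfied_weight:>10}",
            f"{'normalized quartet score':<28}{self.normalized_score:>10.4f}",
            "-" * 58,
            f"species tree: {self.newick}",
        ]
        for key, value in sorted(self.config.items()):
            lines.append(f"  config {key} = {value}")
        return "\n".join(lines)


class SpeciesTreeModel:
    """Estimator of a species tree from multi-copy gene family trees.

    Parameters
    ----------
    gene_trees:
        Collection of :class:`GeneTree`; rooted or unrooted, species
        labels resolved or resolvable through *mapping*.
    mapping:
        Optional :class:`SpeciesMapping` applied to every tree.
    mode:
        ``"disco"`` or ``"disco-r"`` decomposition (default
        ``"disco-r"``, which keeps every species in the backbone).
    prune_strategy:
        Child selection at duplication nodes: ``larger`` (default),
        ``smaller`` or ``random``.
    w_dup, w_loss:
        Duplication/loss parsimony weights for rooting and tagging.
    """

    def __init__(self, gene_trees, mapping: SpeciesMapping | None = None, *,
                 mode: str = "disco-r", prune_strategy: str = "larger",
                 w_dup: float = 1.0, w_loss: float = 1.0):
        self.gene_trees = [t.copy() for t in gene_trees]
        if not self.gene_trees:
            raise ValueError("at least one gene tree is required")
        if mapping is not None:
            for tree in self.gene_trees:
                resolve_species(tree, mapping)
        for tree in self.gene_trees:
            if any(leaf.species is None for leaf in tree.leaves()):
                raise ValueError(
                    "gene trees must have resolved species labels; pass a mapping")
        self.mode = mode
        self.prune_strategy = prune_strategy
        self.tag_config = TagRootConfig(w_dup=w_dup, w_loss=w_loss)
        # validate mode/strategy eagerly
        DecompositionConfig(mode=mode, prune_strategy=prune_strategy,
                            seed=0 if prune_strategy == "random" else None)

    @classmethod
    def from_newick(cls, path, mapping: SpeciesMapping | None = None, **kwargs):
        """Build a model from a one-tree-per-line newick file."""
        if mapping is None:
            mapping = SpeciesMapping.from_delimiter("_")
        return cls(read_newick_file(path), mapping=mapping, **kwargs)

    def fit(self, method: str = "auto", seed: int = 0) -> SpeciesTreeResult:
        """Run the full pipeline and return the estimated species tree.

        ``method`` is ``"exact"`` (exhaustive WMQC, up to 9 taxa),
        ``"heuristic"`` (FM-style divide and conquer) or ``"auto"``
        (exact when it applies, else heuristic).  Deterministic for a
        given seed.
        """
        timings: dict[str, float] = {}
        t0 = time.perf_counter()
        singles: list[GeneTree] = []
        n_dups = 0
        for i, tree in enumerate(self.gene_trees):
            if tree.n_leaves < 2:
                # a family with a single surviving copy: nothing to root,
                # tag or prune, and it induces no quartets
                singles.append(tree.copy())
                continue
            tagged = root_and_tag(tree, self.tag_config)
            config = DecompositionConfig(
                mode=self.mode, prune_strategy=self.prune_strategy,
                seed=(seed * 100003 + i) % (2 ** 31) if self.prune_strategy == "random" else None)
            result = decompose(tagged, config)
            n_dups += result.n_duplications
            singles.extend(result.outputs)
        timings["decompose"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        table = gtf_table(singles)
        timings["quartets"] = time.perf_counter() - t0

        taxa = sorted({sp for topology in table for sp in topology.species})
        if not taxa:
            raise ValueError(
                "no quartets could be generated (all decomposed trees have < 4 leaves)")
        if method == "auto":
            method = "exact" if len(taxa) <= _amalgamate.EXACT_MAX_TAXA else "heuristic"
        t0 = time.perf_counter()
        if method == "exact":
            amal = _amalgamate.exact_wmqc(table, taxa)
        elif method == "heuristic":
            amal = _amalgamate.heuristic_wmqc(table, taxa, seed=seed)
        else:
            raise ValueError(f"unknown method {method!r}")
        timings["amalgamate"] = time.perf_counter() - t0

        return SpeciesTreeResult(
            species_tree=amal.tree,
            satisfied_weight=amal.satisfied_weight,
            normalized_score=amal.normalized_score,
            method=amal.method,
            taxa=taxa,
            n_gene_trees=len(self.gene_trees),
            n_duplications=n_dups,
            n_single_copy_trees=len(singles),
            n_quartet_entries=len(table),
            total_quartet_weight=table.total_weight,
            quartet_table=table,
            config={
                "mode": self.mode,
                "prune_strategy": self.prune_strategy,
                "w_dup": self.tag_config.w_dup,
                "w_loss": self.tag_config.w_loss,
                "seed": seed,
            },
            timings=timings,
        )
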