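"""Weighted Maximum Quartet Consistency (WMQC) solvers.

Given a table of weighted quartet topologies on a taxon set, WMQC asks
for the unrooted binary species tree maximizing the total weight of
table quartets the tree satisfies.  Two solvers are provided:

* :func:`exact_wmqc` enumerates all ``(2n-5)!!`` unrooted binary
  topologies (guarded to 4 <= n <= 9) against a cached induced-quartet
  matrix, so the scan is a single vectorized gather per instance.  The
  exact solver is the correctness anchor for everything else.
* :func:`heuristic_wmqc` is a Fiduccia–Mattheyses-style divide and
  conquer: the taxon set is recursively bipartitioned (quartets
  spanning both sides are deferred via a dummy taxon standing for the
  opposite side), each bipartition chosen by an exhaustive scan over
  splits for small subproblems and by seeded FM passes (single-taxon
  moves with quartet-weight gain, taxa locked after moving, best move
  prefix kept) above that.

Scores stay in exact integer arithmetic whenever the weights are
integral.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .quartets import QuartetTable, QuartetTopology, induced_quartet
from .trees import GeneTree, Node, TreeError, random_resolved_topology

__all__ = [
    "AmalgamationResult",
    "exact_wmqc",
    "heuristic_wmqc",
    "quartet_score",
    "EXACT_MAX_TAXA",
]

EXACT_MIN_TAXA = 4
EXACT_MAX_TAXA = 9
# subproblem size up to which the heuristic scans all bipartitions
_EXHAUSTIVE_SPLIT_MAX = 9


@dataclass
class AmalgamationResult:
    """An unrooted species tree with its quartet-consistency score.

    ``satisfied_weight`` is the total table weight consistent with the
    tree; ``normalized_score`` divides by the weight of the table
    entries whose four species the tree spans (0 for an empty table).
    """

    tree: GeneTree
    satisfied_weight: float
    normalized_score: float
    method: str

    @property
    def newick(self) -> str:
        from .trees import write_newick

        return write_newick(self.tree, include_lengths=False)


def quartet_score(tree: GeneTree, table: QuartetTable,
                  method: str = "score") -> AmalgamationResult:
    """Score an existing single-copy tree against a quartet table.

    Table entries mentioning a species absent from the tree are ignored
    and excluded from the normalization denominator.
    """
    species = tree.species_set()
    satisfied = 0
    considered = 0
    for topology, weight in table.items():
        if not topology.species <= species:
            continue
        considered += weight
        if induced_quartet(tree, topology.species) == topology:
            satisfied += weight
    score = satisfied / considered if considered else 0.0
    return AmalgamationResult(tree, satisfied, score, method)


# ---------------------------------------------------------------------------
# Exact solver
# ---------------------------------------------------------------------------

# cache: n -> (structures, M) where structures[t] is a nested index tuple
# over leaves 1..n-1 (leaf 0 hangs at its root edge) and M[t, s] gives the
# arrangement (0: ij|kl, 1: ik|jl, 2: il|jk) tree t induces on the s-th
# 4-subset (combinations(range(n), 4) order).
_TOPOLOGY_CACHE: dict[int, tuple[list, np.ndarray]] = {}


def _insertions(t, x):
    yield (t, x)
    if isinstance(t, tuple):
        left, right = t
        for nl in _insertions(left, x):
            yield (nl, right)
        for nr in _insertions(right, x):
            yield (left, nr)


def _enumerate_structures(n: int) -> list:
    """All rooted binary shapes over leaves 1..n-1 (deterministic order)."""
    trees = [1]
    for x in range(2, n):
        trees = [t2 for t in trees for t2 in _insertions(t, x)]
    return trees


def _subset_arrangement(i, j, k, l, pair):
    """Arrangement index of subset (i<j<k<l) given one of its pairs."""
    if pair == (i, j) or pair == (k, l):
        return 0
    if pair == (i, k) or pair == (j, l):
        return 1
    return 2


def _structure_matrix(n: int) -> tuple[list, np.ndarray]:
    if n in _TOPOLOGY_CACHE:
        return _TOPOLOGY_CACHE[n]
    structures = _enumerate_structures(n)
    subsets = list(combinations(range(n), 4))
    subset_index = {s: i for i, s in enumerate(subsets)}
    M = np.full((len(structures), len(subsets)), -1, dtype=np.int8)
    taxa_all = set(range(n))
    for t_idx, struct in enumerate(structures):
        clades: list[tuple[int, ...]] = []

        def collect(t) -> tuple[int, ...]:
            if isinstance(t, int):
                return (t,)
            leaves = collect(t[0]) + collect(t[1])
            clades.append(leaves)
            return leaves

        collect(struct)
        row = M[t_idx]
        for clade in clades:
            if len(clade) < 2 or len(clade) > n - 2:
                continue  # trivial edge
            inside = sorted(clade)
            outside = sorted(taxa_all - set(clade))
            for a, b in combinations(inside, 2):
                for c, d in combinations(outside, 2):
                    quad = tuple(sorted((a, b, c, d)))
                    row[subset_index[quad]] = _subset_arrangement(
                        *quad, pair=(a, b) if a < b else (b, a))
        assert row.min() >= 0, "incomplete quartet assignment"
    _TOPOLOGY_CACHE[n] = (structures, M)
    return structures, M


def _structure_to_tree(struct, taxa: list[str]) -> GeneTree:
    def conv(t) -> Node:
        if isinstance(t, int):
            return Node(taxa[t], taxa[t])
        node = Node()
        node.add_child(conv(t[0]))
        node.add_child(conv(t[1]))
        return node

    root = Node()
    root.add_child(Node(taxa[0], taxa[0]))
    assert isinstance(struct, tuple)
    root.add_child(conv(struct[0]))
    root.add_child(conv(struct[1]))
    return GeneTree(root, is_rooted=False)


def _weight_array(table: QuartetTable, taxa: list[str]):
    """(n_subsets, 3) weight array plus the considered total weight."""
    n = len(taxa)
    index = {sp: i for i, sp in enumerate(taxa)}
    subsets = list(combinations(range(n), 4))
    subset_index = {s: i for i, s in enumerate(subsets)}
    W = np.zeros((len(subsets), 3))
    considered = 0
    for topology, weight in table.items():
        if not topology.species <= set(taxa):
            continue
        considered += weight
        ids = tuple(sorted(index[sp] for sp in topology.species))
        pair = tuple(sorted(index[sp] for sp in topology.pair1))
        W[subset_index[ids], _subset_arrangement(*ids, pair=pair)] += weight
    return W, considered


def exact_wmqc(table: QuartetTable, taxa) -> AmalgamationResult:
    """Optimal WMQC tree by exhaustive topology enumeration.

    Ties are broken by the first maximum in the deterministic
    enumeration order.  Guarded to 4..9 taxa: the scan enumerates
    (2n-5)!! topologies.
    """
    taxa = sorted(set(taxa))
    n = len(taxa)
    if n < EXACT_MIN_TAXA or n > EXACT_MAX_TAXA:
        raise ValueError(
            f"exact_wmqc handles {EXACT_MIN_TAXA}..{EXACT_MAX_TAXA} taxa, got {n}")
    structures, M = _structure_matrix(n)
    W, considered = _weight_array(table, taxa)
    n_subsets = M.shape[1]
    cols = np.arange(n_subsets)
    scores = np.empty(len(structures))
    chunk = 20000
    for lo in range(0, len(structures), chunk):
        block = M[lo: lo + chunk]
        scores[lo: lo + chunk] = W[cols[None, :], block].sum(axis=1)
    best = int(np.argmax(scores))
    satisfied = scores[best]
    if float(satisfied).is_integer():
        satisfied = int(satisfied)
    tree = _structure_to_tree(structures[best], taxa)
    score = satisfied / considered if considered else 0.0
    return AmalgamationResult(tree, satisfied, score, "exact")


# ---------------------------------------------------------------------------
# FM-style heuristic
# ---------------------------------------------------------------------------

_DUMMY_PREFIX = "￿dummy"


def _quartet_records(table: QuartetTable, taxa: set[str]):
    records = []
    for topology, weight in table.items():
        if topology.species <= taxa:
            records.append((frozenset(topology.pair1), frozenset(topology.pair2), weight))
    return records


def _partition_delta(records, in_a: dict[str, bool]):
    """Score of a bipartition: satisfied minus violated quartet weight."""
    score = 0
    for p1, p2, w in records:
        c1 = sum(in_a[t] for t in p1)
        c2 = sum(in_a[t] for t in p2)
        if c1 + c2 == 2:
            if c1 == 1:  # both pairs split across the cut
                score -= w
            else:
                score += w
    return score


def _exhaustive_split(members: list[str], records):
    """Best bipartition (sides >= 2) by scanning all splits."""
    first, rest = members[0], members[1:]
    best_score = None
    best_a = None
    for size_a in range(2, len(members) - 1):
        for combo in combinations(rest, size_a - 1):
            side_a = {first, *combo}
            in_a = {t: (t in side_a) for t in members}
            s = _partition_delta(records, in_a)
            if best_score is None or s > best_score:
                best_score = s
                best_a = side_a
    assert best_a is not None
    return best_a, set(members) - best_a


def _fm_split(members: list[str], records, rng: random.Random,
              restarts: int = 3, max_passes: int = 12):
    """Seeded FM bipartitioning: random initial split, single-taxon moves
    with locking, best move prefix kept, a few restarts."""
    by_taxon: dict[str, list] = {t: [] for t in members}
    for rec in records:
        for t in rec[0] | rec[1]:
            if t in by_taxon:
                by_taxon[t].append(rec)

    def gain(t: str, in_a: dict[str, bool]) -> float:
        base = after = 0
        for p1, p2, w in by_taxon[t]:
            c1 = sum(in_a[x] for x in p1)
            c2 = sum(in_a[x] for x in p2)
            if c1 + c2 == 2:
                base += w if c1 != 1 else -w
            moved1 = c1 + (0 if t not in p1 else (-1 if in_a[t] else 1))
            moved2 = c2 + (0 if t not in p2 else (-1 if in_a[t] else 1))
            if moved1 + moved2 == 2:
                after += w if moved1 != 1 else -w
        return after - base

    best_overall = None
    best_overall_score = None
    for _ in range(restarts):
        shuffled = sorted(members)
        rng.shuffle(shuffled)
        half = len(members) // 2
        in_a = {t: (i < half) for i, t in enumerate(shuffled)}
        for _pass in range(max_passes):
            locked: set[str] = set()
            history: list[str] = []
            gains: list[float] = []
            snapshot = dict(in_a)
            while True:
                size_a = sum(in_a.values())
                candidates = []
                for t in members:
                    if t in locked:
                        continue
                    # keep both sides >= 2
                    if in_a[t] and size_a <= 2:
                        continue
                    if not in_a[t] and len(members) - size_a <= 2:
                        continue
                    candidates.append(t)
                if not candidates:
                    break
                scored = [(gain(t, in_a), t) for t in candidates]
                g, t = max(scored, key=lambda pair: (pair[0], pair[1]))
                in_a[t] = not in_a[t]
                locked.add(t)
                history.append(t)
                gains.append(g)
            # best prefix of the move sequence
            cumulative = 0.0
            best_prefix = 0
            best_cum = 0.0
            for i, g in enumerate(gains, 1):
                cumulative += g
                if cumulative > best_cum:
                    best_cum = cumulative
                    best_prefix = i
            in_a = snapshot
            if best_prefix == 0:
                break
            for t in history[:best_prefix]:
                in_a[t] = not in_a[t]
        score = _partition_delta(records, in_a)
        if best_overall_score is None or score > best_overall_score:
            best_overall_score = score
            best_overall = dict(in_a)
    assert best_overall is not None
    side_a = {t for t, flag in best_overall.items() if flag}
    return side_a, set(members) - side_a


def _project_records(records, keep: set[str], dummy: str):
    """Quartets restricted to *keep*; a single outside taxon becomes the
    dummy, quartets with two or more outside taxa are dropped."""
    projected = []
    for p1, p2, w in records:
        out = (p1 | p2) - keep
        if not out:
            projected.append((p1, p2, w))
        elif len(out) == 1:
            (gone,) = out
            np1 = frozenset(dummy if t == gone else t for t in p1)
            np2 = frozenset(dummy if t == gone else t for t in p2)
            projected.append((np1, np2, w))
    return projected


def _detach_at_leaf(root: Node, leaf_label: str) -> Node:
    """Reorient the unrooted tree so the subtree opposite *leaf_label*
    becomes a root, and drop the leaf."""
    target = None
    for node in root.postorder():
        if node.is_leaf() and node.label == leaf_label:
            target = node
            break
    assert target is not None, leaf_label

    def orient(x: Node, came_from: Node | None) -> Node:
        new = Node(x.label, x.species)
        neighbors = ([x.parent] if x.parent is not None else []) + list(x.children)
        for nb in neighbors:
            if nb is came_from or nb is None:
                continue
            new.add_child(orient(nb, x))
        return new

    anchor = target.parent if target.parent is not None else None
    assert anchor is not None
    return orient(anchor, target)


def _find_leaf(root: Node, label: str) -> Node:
    for node in root.postorder():
        if node.is_leaf() and node.label == label:
            return node
    raise TreeError(f"leaf {label!r} not found")


def _build_subtree(members: set[str], records, rng: random.Random,
                   depth: int) -> Node:
    members_sorted = sorted(members)
    if len(members_sorted) <= 3:
        root = Node()
        for t in members_sorted:
            root.add_child(Node(t, t))
        return root
    if len(members_sorted) <= _EXHAUSTIVE_SPLIT_MAX:
        side_a, side_b = _exhaustive_split(members_sorted, records)
    else:
        side_a, side_b = _fm_split(members_sorted, records, rng)
    dummy_a = f"{_DUMMY_PREFIX}{depth}a"
    dummy_b = f"{_DUMMY_PREFIX}{depth}b"
    rec_a = _project_records(records, side_a, dummy_b)
    rec_b = _project_records(records, side_b, dummy_a)
    tree_a = _build_subtree(side_a | {dummy_b}, rec_a, rng, depth + 1)
    tree_b = _build_subtree(side_b | {dummy_a}, rec_b, rng, depth + 1)
    graft = _detach_at_leaf(tree_b, dummy_a)
    slot = _find_leaf(tree_a, dummy_b)
    parent = slot.parent
    assert parent is not None
    idx = parent.children.index(slot)
    parent.children[idx] = graft
    graft.parent = parent
    return tree_a


def heuristic_wmqc(table: QuartetTable, taxa, seed: int = 0) -> AmalgamationResult:
    """FM-style divide-and-conquer WMQC heuristic.

    Deterministic for a given seed; never applicable below four taxa.
    A seeded random topology is scored as a baseline floor: the
    heuristic tree is returned unless the baseline strictly beats it.
    """
    taxa = sorted(set(taxa))
    if len(taxa) < 4:
        raise ValueError(f"heuristic_wmqc requires at least 4 taxa, got {len(taxa)}")
    rng = random.Random(seed)
    records = _quartet_records(table, set(taxa))
    root = _build_subtree(set(taxa), records, rng, 0)
    tree = GeneTree(root, is_rooted=False)
    result = quartet_score(tree, table, method="heuristic")
    baseline_tree = random_resolved_topology(taxa, random.Random(seed + 1))
    baseline = quartet_score(baseline_tree, table, method="heuristic")
    if baseline.satisfied_weight > result.satisfied_weight:
        return baseline
    return result
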