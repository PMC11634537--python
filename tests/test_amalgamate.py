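"""Weighted maximum quartet consistency: exact solver, heuristic, scoring."""

import random

import pytest

import discophylo as dp
from discophylo.quartets import QuartetTopology as Q
from discophylo.trees import random_resolved_topology

import _util


def _coherent_table(labels, seed):
    tree = random_resolved_topology(labels, random.Random(seed))
    return tree, dp.gtf_table([tree])


class TestQuartetScore:
    def test_fully_satisfied(self):
        tree = random_resolved_topology(list("abcd"), 0)
        table = dp.gtf_table([tree])
        result = dp.quartet_score(tree, table)
        assert result.normalized_score == 1.0

    def test_fully_violated(self):
        tree, _ = _coherent_table(list("abcd"), 0)
        topology = dp.induced_quartet(tree, "abcd")
        (other,) = [q for q in (Q(("a", "b"), ("c", "d")), Q(("a", "c"), ("b", "d")),
                                Q(("a", "d"), ("b", "c")))
                    if q != topology][:1]
        table = dp.QuartetTable({other: 4})
        result = dp.quartet_score(tree, table)
        assert result.satisfied_weight == 0
        assert result.normalized_score == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_four_point_recount(self, seed):
        rng = random.Random(seed)
        tree = random_resolved_topology([f"t{i}" for i in range(7)], rng)
        table = dp.QuartetTable()
        labels = [f"t{i}" for i in range(7)]
        for _ in range(25):
            quad = rng.sample(labels, 4)
            table.add(Q(quad[:2], quad[2:]), rng.randint(1, 5))
        result = dp.quartet_score(tree, table)
        assert result.satisfied_weight == _util.four_point_score(tree, table)

    def test_entries_outside_tree_excluded_from_denominator(self):
        tree = random_resolved_topology(list("abcd"), 0)
        topology = dp.induced_quartet(tree, "abcd")
        table = dp.QuartetTable({topology: 3, Q(("a", "b"), ("x", "y")): 10})
        result = dp.quartet_score(tree, table)
        assert result.satisfied_weight == 3
        assert result.normalized_score == 1.0


class TestExact:
    def test_dominant_quartet(self):
        table = dp.QuartetTable({Q(("a", "b"), ("c", "d")): 5,
                                 Q(("a", "c"), ("b", "d")): 2})
        result = dp.exact_wmqc(table, "abcd")
        assert result.satisfied_weight == 5
        assert dp.induced_quartet(result.tree, "abcd") == Q(("a", "b"), ("c", "d"))

    @pytest.mark.parametrize("n,seed", [(5, 1), (6, 2), (7, 3), (8, 4)])
    def test_self_consistency(self, n, seed):
        """A table built from one tree is solved by that tree, score 1."""
        tree, table = _coherent_table([f"t{i}" for i in range(n)], seed)
        result = dp.exact_wmqc(table, [f"t{i}" for i in range(n)])
        assert result.normalized_score == 1.0
        assert dp.rf_distance(result.tree, tree).rf_raw == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_rescan(self, seed):
        """Vectorized scan equals a test-local enumeration + four-point scoring."""
        rng = random.Random(seed)
        labels = [f"t{i}" for i in range(6)]
        trees = [random_resolved_topology(labels, rng) for _ in range(3)]
        table = dp.gtf_table(trees)
        # perturb one weight so the instance is not trivially coherent
        some = sorted(table)[seed % len(table)]
        table[some] += 2
        result = dp.exact_wmqc(table, labels)
        best = max(_util.four_point_score(t, table)
                   for t in _util.enumerate_unrooted_topologies(labels))
        assert result.satisfied_weight == best

    def test_relabeling_invariance(self):
        labels = [f"t{i}" for i in range(6)]
        tree, table = _coherent_table(labels, 9)
        relabel = {old: new for old, new in zip(labels, "UVWXYZ")}
        table2 = dp.QuartetTable()
        for topology, weight in table.items():
            table2.add(Q([relabel[s] for s in topology.pair1],
                         [relabel[s] for s in topology.pair2]), weight)
        r1 = dp.exact_wmqc(table, labels)
        r2 = dp.exact_wmqc(table2, list("UVWXYZ"))
        biparts1 = {frozenset(frozenset(relabel[s] for s in side) for side in bp)
                    for bp in _util.bipartition_set(r1.tree)}
        assert biparts1 == _util.bipartition_set(r2.tree)

    @pytest.mark.parametrize("n", [3, 10])
    def test_taxon_guard(self, n):
        with pytest.raises(ValueError):
            dp.exact_wmqc(dp.QuartetTable(), [f"t{i}" for i in range(n)])


class TestHeuristic:
    @pytest.mark.parametrize("n,seed", [(6, 0), (8, 1), (10, 2), (13, 3)])
    def test_coherent_table_recovered(self, n, seed):
        tree, table = _coherent_table([f"t{i}" for i in range(n)], seed)
        result = dp.heuristic_wmqc(table, [f"t{i}" for i in range(n)], seed=seed)
        assert result.normalized_score == 1.0
        assert dp.rf_distance(result.tree, tree).rf_raw == 0

    def test_deterministic_per_seed_and_valid(self):
        labels = [f"t{i}" for i in range(9)]
        rng = random.Random(5)
        table = dp.gtf_table([random_resolved_topology(labels, rng) for _ in range(4)])
        for seed in (0, 1):
            a = dp.heuristic_wmqc(table, labels, seed=seed)
            b = dp.heuristic_wmqc(table, labels, seed=seed)
            assert a.newick == b.newick
            assert sorted(a.tree.species_labels()) == labels
            internal_ok = all(
                len(n.children) + (0 if n.parent is None else 1) == 3
                for n in a.tree.internal_nodes())
            assert internal_ok

    @pytest.mark.parametrize("seed", range(6))
    def test_never_beats_exact(self, seed):
        rng = random.Random(100 + seed)
        labels = [f"t{i}" for i in range(7)]
        table = dp.gtf_table([random_resolved_topology(labels, rng) for _ in range(5)])
        exact = dp.exact_wmqc(table, labels)
        heur = dp.heuristic_wmqc(table, labels, seed=seed)
        assert heur.satisfied_weight <= exact.satisfied_weight

    def test_beats_random_baseline(self):
        rng = random.Random(31)
        labels = [f"t{i}" for i in range(12)]
        table = dp.gtf_table([random_resolved_topology(labels, rng) for _ in range(6)])
        heur = dp.heuristic_wmqc(table, labels, seed=2)
        baseline = dp.quartet_score(random_resolved_topology(labels, random.Random(7)),
                                    table)
        assert heur.satisfied_weight >= baseline.satisfied_weight

    def test_minimum_taxa_guard(self):
        with pytest.raises(ValueError):
            dp.heuristic_wmqc(dp.QuartetTable(), ["a", "b", "c"])
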