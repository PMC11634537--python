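"""Induced quartets, GTF tables and speciation-driven quartets."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

import discophylo as dp
from discophylo.decompose import DecompositionConfig
from discophylo.quartets import QuartetTopology as Q

import _util


def _single_copy(nwk):
    tree = dp.parse_newick(nwk)
    for leaf in tree.leaves():
        leaf.species = leaf.label
    return tree


class TestCanonicalForm:
    def test_three_topologies_per_four_set(self):
        topologies = {Q(p1, p2) for p1, p2 in
                      [(("a", "b"), ("c", "d")), (("b", "a"), ("d", "c")),
                       (("c", "d"), ("a", "b")), (("a", "c"), ("b", "d")),
                       (("a", "d"), ("c", "b"))]}
        assert len(topologies) == 3

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.permutations(["a", "b", "c", "d"]))
    def test_pair_order_invariance(self, perm):
        w, x, y, z = perm
        assert Q((w, x), (y, z)) == Q((x, w), (z, y)) == Q((y, z), (w, x))

    def test_distinct_labels_required(self):
        with pytest.raises(ValueError):
            Q(("a", "a"), ("b", "c"))


class TestInducedQuartet:
    def test_balanced(self):
        assert dp.induced_quartet(_single_copy("((a,b),(c,d));"), "abcd") == \
            Q(("a", "b"), ("c", "d"))

    def test_caterpillar_cherry_dominates(self):
        assert dp.induced_quartet(_single_copy("(((a,b),c),d);"), "abcd") == \
            Q(("a", "b"), ("c", "d"))

    def test_disco_r_backbone_example(self, worked_example):
        backbone = dp.decompose(worked_example, DecompositionConfig("disco-r")).backbone
        assert dp.induced_quartet(backbone, ["a", "e", "c", "d"]) == \
            Q(("a", "e"), ("c", "d"))

    def test_absent_species_errors(self):
        with pytest.raises(dp.TreeError, match="absent"):
            dp.induced_quartet(_single_copy("((a,b),(c,d));"), "abcx")


class TestGtfTable:
    def test_single_tree(self):
        table = dp.gtf_table([_single_copy("((a,b),(c,d));")])
        assert table == {Q(("a", "b"), ("c", "d")): 1}

    def test_additivity(self):
        tree = "((a,b),(c,d));"
        table = dp.gtf_table([_single_copy(tree), _single_copy(tree)])
        assert table == {Q(("a", "b"), ("c", "d")): 2}

    def test_conflicting_trees(self):
        table = dp.gtf_table([_single_copy("((a,b),(c,d));"),
                              _single_copy("((a,c),(b,d));")])
        assert table == {Q(("a", "b"), ("c", "d")): 1, Q(("a", "c"), ("b", "d")): 1}

    def test_small_trees_skipped(self):
        table = dp.gtf_table([_single_copy("(a,(b,c));")])
        assert table == {}

    def test_multi_labeled_tree_rejected(self):
        tree = dp.parse_newick("((x_1,x_2),(b_1,c_1));")
        dp.resolve_species(tree, _util.PREFIX_MAPPING)
        with pytest.raises(dp.TreeError, match="single-labeled"):
            dp.gtf_table([tree])

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_four_point_recount(self, seed):
        """gtf_table equals an independent four-point-condition recount."""
        dataset = _util.random_multicopy_dataset(15, seed=400 + seed, n_taxa=8,
                                                 dup_rate=0.0, loss_rate=0.0)
        trees = dataset.gene_trees
        assert dp.gtf_table(trees) == _util.brute_force_gtf(trees)

    def test_weights_per_four_set_sum_to_tree_count(self):
        dataset = _util.random_multicopy_dataset(10, seed=91, n_taxa=6,
                                                 dup_rate=0.0, loss_rate=0.0)
        table = dp.gtf_table(dataset.gene_trees)
        by_set = {}
        for topology, weight in table.items():
            by_set[topology.species] = by_set.get(topology.species, 0) + weight
        for four_set, total in by_set.items():
            containing = sum(1 for t in dataset.gene_trees
                             if four_set <= t.species_set() and t.n_leaves >= 4)
            assert total == containing


class TestSpeciationDrivenQuartets:
    def test_worked_example_includes_missed_sqs(self, worked_example):
        sq = dp.sq_set(worked_example)
        for topology in [Q(("a", "c"), ("d", "e")), Q(("a", "h"), ("d", "e")),
                         Q(("a", "b"), ("p", "e")), Q(("a", "b"), ("p", "h"))]:
            assert topology in sq

    def test_worked_example_excludes_duplication_crossing_quartets(self, worked_example):
        sq = dp.sq_set(worked_example)
        assert Q(("a", "e"), ("c", "d")) not in sq
        assert Q(("a", "d"), ("h", "e")) not in sq

    def test_single_copy_tree_all_quartets_are_sqs(self):
        tree = dp.parse_newick("(((a_1,b_1),c_1),(d_1,e_1));")
        dp.resolve_species(tree, _util.PREFIX_MAPPING)
        dp.tag_rooted(tree)
        assert dp.sq_set(tree) == set(dp.quartets.all_induced_quartets(tree))

    def test_untagged_tree_rejected(self):
        tree = dp.parse_newick("((a_1,b_1),(c_1,d_1));")
        dp.resolve_species(tree, _util.PREFIX_MAPPING)
        with pytest.raises(dp.TreeError, match="tag"):
            dp.sq_set(tree)


class TestCoveredQuartets:
    def test_empty_collection(self):
        assert dp.covered_quartets([]) == set()

    def test_worked_example_disco_misses_listed_sqs(self, worked_example):
        covered = dp.covered_quartets(
            dp.decompose(worked_example, DecompositionConfig("disco")).outputs)
        for topology in [Q(("a", "b"), ("p", "e")), Q(("a", "b"), ("p", "h"))]:
            assert topology not in covered

    def test_worked_example_disco_r_gains_and_gaps(self, worked_example):
        covered = dp.covered_quartets(
            dp.decompose(worked_example, DecompositionConfig("disco-r")).outputs)
        for topology in [Q(("a", "b"), ("p", "e")), Q(("a", "b"), ("p", "h")),
                         Q(("b", "p"), ("h", "e")), Q(("a", "b"), ("h", "e"))]:
            assert topology in covered
        # non-SQs introduced by the regraft
        assert Q(("a", "e"), ("c", "d")) in covered
        assert Q(("a", "d"), ("h", "e")) in covered
        # still missing
        assert Q(("a", "c"), ("d", "e")) not in covered
        assert Q(("a", "h"), ("d", "e")) not in covered


class TestQuartetFiles:
    def test_write_format(self, tmp_path):
        table = dp.QuartetTable()
        table.add(Q(("a", "b"), ("c", "d")), 3)
        path = tmp_path / "q.wqt"
        dp.write_quartets(table, path)
        assert path.read_text() == "((a,b),(c,d)); 3\n"

    def test_empty_table_empty_file(self, tmp_path):
        path = tmp_path / "q.wqt"
        dp.write_quartets(dp.QuartetTable(), path)
        assert path.read_text() == ""

    def test_roundtrip(self, tmp_path, worked_example):
        table = dp.gtf_table(dp.decompose(worked_example, DecompositionConfig("disco-r")).outputs)
        path = tmp_path / "q.wqt"
        dp.write_quartets(table, path)
        assert dp.read_quartets(path) == table
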