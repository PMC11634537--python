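"""DLCoal simulator: locus trees, bounded coalescent, datasets."""

import math
import random

import pytest

import discophylo as dp
from discophylo.simulate import DLCoalParams, simulate_gene_tree, simulate_locus_tree

import _util


def _params(sp, dup, loss, n=10000.0, **kw):
    return DLCoalParams(species_tree=sp, dup_rate=dup, loss_rate=loss,
                        pop_size=n, **kw)


def _expected_duplications(tree, lam):
    """Closed-form expected surviving-duplication count with zero loss:
    a lineage mass m entering a branch of length l grows to m*e^(lam*l)
    and spawns m*(e^(lam*l) - 1) duplication events on the way."""
    def rec(node, mass):
        total = 0.0
        for child in node.children:
            grow = math.exp(lam * child.length)
            total += mass * (grow - 1.0)
            total += rec(child, mass * grow)
        return total

    return rec(tree.root, 1.0)


class TestLocusTree:
    def test_zero_rates_reproduce_species_tree(self):
        sp = _util.ultrametric_species_tree_6taxa(10000.0)
        locus = simulate_locus_tree(_params(sp, 0.0, 0.0, seed=3))
        assert sorted(l.species for l in locus.leaves()) == list("ABCDEF")
        assert locus.n_duplications == 0
        labels = {l.label for l in locus.leaves()}
        assert labels == {f"{s}_1" for s in "ABCDEF"}

    def test_duplication_mean_matches_branching_expectation(self):
        sp = _util.ultrametric_species_tree_6taxa(10000.0)
        lam = 1.5e-6
        expected = _expected_duplications(sp, lam)
        rng = random.Random(11)
        params = _params(sp, lam, 0.0)
        counts = [simulate_locus_tree(params, rng).n_duplications
                  for _ in range(3000)]
        mean = sum(counts) / len(counts)
        var = sum((c - mean) ** 2 for c in counts) / (len(counts) - 1)
        se = math.sqrt(var / len(counts))
        assert abs(mean - expected) < 3 * se + 1e-9

    def test_high_loss_reports_extinction(self):
        sp = _util.ultrametric_species_tree_6taxa(10000.0)
        with pytest.raises(dp.FamilyExtinctionError):
            # expected losses per branch >> 1: survival is (practically) impossible
            for seed in range(50):
                simulate_locus_tree(_params(sp, 0.0, 5e-4, seed=seed))

    def test_deterministic_given_seed(self):
        sp = _util.ultrametric_species_tree_6taxa(10000.0)
        a = simulate_locus_tree(_params(sp, 5e-6, 2e-6, seed=9))
        b = simulate_locus_tree(_params(sp, 5e-6, 2e-6, seed=9))
        assert [l.label for l in a.leaves()] == [l.label for l in b.leaves()]


class TestGeneTree:
    def test_pairwise_coalescence_mean(self):
        """Two species diverging at depth d: mean TMRCA is d + N."""
        n = 10000.0
        sp = _util.species_tree_from_newick(f"(A:{3 * n},B:{3 * n});")
        rng = random.Random(21)
        params = _params(sp, 0.0, 0.0, n=n)
        extra = []
        for _ in range(3000):
            locus = simulate_locus_tree(params, rng)
            gene = simulate_gene_tree(locus, n, rng)
            (leaf_a, leaf_b) = gene.leaves()
            extra.append(leaf_a.length - 3 * n)
        mean = sum(extra) / len(extra)
        se = math.sqrt(sum((x - mean) ** 2 for x in extra) / (len(extra) - 1)
                       / len(extra))
        assert abs(mean - n) < 3 * se

    def test_msc_quartet_discordance_closed_form(self):
        """Zero dup/loss: P(matching quartet) = 1 - (2/3) e^(-T)."""
        n = 10000.0
        big_t = 1.0
        sp = _util.species_tree_from_newick(
            f"(((A:{n},B:{n}):{big_t * n},C:{(1 + big_t) * n}):{n},"
            f"D:{(2 + big_t) * n});")
        params = _params(sp, 0.0, 0.0, n=n, n_genes=2500, seed=6)
        dataset = dp.generate_dataset(params)
        matching = dp.QuartetTopology(("A", "B"), ("C", "D"))
        observed = sum(dp.induced_quartet(g, "ABCD") == matching
                       for g in dataset.gene_trees) / len(dataset.gene_trees)
        expected = 1 - (2 / 3) * math.exp(-big_t)
        se = math.sqrt(expected * (1 - expected) / len(dataset.gene_trees))
        assert abs(observed - expected) < 3 * se

    def test_duplication_survives_into_gene_tree_and_tagging(self):
        """A surviving duplication puts a species on both sides; parsimony
        tagging then finds at least one duplication node."""
        sp = _util.ultrametric_species_tree_6taxa(10000.0)
        rng = random.Random(13)
        params = _params(sp, 4e-6, 0.0)
        found = 0
        for _ in range(200):
            locus = simulate_locus_tree(params, rng)
            if locus.n_duplications != 1:
                continue
            gene = simulate_gene_tree(locus, 10000.0, rng)
            species = [l.species for l in gene.leaves()]
            assert len(species) > len(set(species))  # some species duplicated
            tagged = dp.tag_rooted(gene)
            assert dp.count_duplications(tagged) >= 1
            found += 1
        assert found > 20


class TestDataset:
    def test_byte_identical_given_seed(self):
        sp = _util.ultrametric_species_tree_6taxa(10000.0)
        params = _params(sp, 3e-6, 3e-6, n_genes=20, seed=42)
        a = dp.generate_dataset(params)
        b = dp.generate_dataset(params)
        assert [dp.write_newick(t) for t in a.gene_trees] == \
            [dp.write_newick(t) for t in b.gene_trees]

    def test_zero_rates_all_single_copy(self):
        sp = _util.ultrametric_species_tree_6taxa(10000.0)
        dataset = dp.generate_dataset(_params(sp, 0.0, 0.0, n_genes=30, seed=1))
        assert all(dp.check_single_labeled(t) for t in dataset.gene_trees)
        assert dataset.n_redraws == 0

    def test_redraws_reported_under_heavy_loss(self):
        sp = _util.ultrametric_species_tree_6taxa(10000.0)
        dataset = dp.generate_dataset(_params(sp, 1e-6, 4e-5, n_genes=10, seed=2))
        assert len(dataset.gene_trees) == 10
        assert dataset.n_redraws > 0

    def test_invalid_params_rejected(self):
        sp = _util.ultrametric_species_tree_6taxa(10000.0)
        with pytest.raises(ValueError):
            _params(sp, -1e-6, 0.0)
        with pytest.raises(ValueError):
            _params(sp, 0.0, 0.0, n=0.0)
        with pytest.raises(ValueError):
            _params(sp, 0.0, 0.0, n_genes=0)
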