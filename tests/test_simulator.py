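"""Forward simulator: generative semantics, tree-sample noise, genomes."""

import math
from collections import Counter

import pytest

from dtlrec.ccp import observe_trees
from dtlrec.model import DTLRates, compute_extinction, normalize_rates
from dtlrec.phylo import parse_newick
from dtlrec.simulator import (GenomeOrder, enumerate_outcomes,
                              outcome_frequencies, perturb_tree_sample,
                              simulate_dataset, simulate_family,
                              simulate_genomes, transferred_leaf_genes)

GOLDEN_E = (3 - math.sqrt(5)) / 2


class TestSimulateFamily:
    def test_no_events_deterministic_cascade(self, tree8):
        fam = simulate_family(tree8, DTLRates(0, 0, 0), seed=1,
                              origination=tree8.root)
        assert sorted(fam.gene_to_species.values()) == sorted(tree8.leaf_index)
        assert all(ev[0] in ("O", "S", "C") for ev in fam.events)
        tree = parse_newick(fam.newick, expect_rooted=True)
        assert len(tree.leaf_names()) == tree8.n_leaves

    def test_origination_below_subtree(self, tree8):
        """With no events, the family spans exactly the leaves below the
        origination branch."""
        e = tree8.leaf_index["C"]
        fam = simulate_family(tree8, DTLRates(0, 0, 0), seed=2, origination=e)
        assert fam.genes == ["C_g1"]

    def test_survival_matches_extinction_complement(self, tree6):
        """Fraction of surviving families equals 1 - Ebar within 3 SE."""
        rates = DTLRates(0.1, 0.1, 0.6)
        probs = normalize_rates(rates, tree6)
        surv_expected = 1.0 - compute_extinction(probs, tree6).Ebar
        n = 40000
        from random import Random
        rng = Random(123)
        alive = sum(
            simulate_family(tree6, rates, rng=rng).size > 0 for _ in range(n))
        se = math.sqrt(surv_expected * (1 - surv_expected) / n)
        assert alive / n == pytest.approx(surv_expected, abs=3 * se)

    def test_byte_identical_under_seed(self, tree8, mid_rates):
        a = simulate_dataset(tree8, mid_rates, 10, seed=77)
        b = simulate_dataset(tree8, mid_rates, 10, seed=77)
        assert [f.newick for f in a] == [f.newick for f in b]
        assert [f.events for f in a] == [f.events for f in b]

    def test_explosion_guard(self, tree1):
        with pytest.raises(Exception):
            simulate_family(tree1, DTLRates(9, 0, 0), seed=3, max_genes=50)

    def test_forced_recipient(self, tree8):
        target = tree8.leaf_index["H"]
        fam = simulate_family(tree8, DTLRates(0, 0.5, 0), seed=5,
                              origination=tree8.leaf_index["A"],
                              recipient=target)
        for ev in fam.events:
            if ev[0] == "T":
                assert ev[2] == target


class TestPerturbTreeSample:
    TRUE = "(((a,b),c),(d,e));"

    def test_zero_probability_is_identity(self):
        sample = perturb_tree_sample(self.TRUE, 5, 0.0, seed=1)
        assert set(sample) == {self.TRUE}

    def test_single_tree_hook(self):
        assert len(perturb_tree_sample(self.TRUE, 1, 0.3, seed=2)) == 1

    def test_leafset_preserved(self):
        for t in perturb_tree_sample(self.TRUE, 100, 0.8, seed=3):
            assert sorted(parse_newick(t, expect_rooted=True).leaf_names()) \
                == ["a", "b", "c", "d", "e"]

    def resolution(self, newick):
        t = observe_trees("x", [newick], {x: x for x in "abcd"}, mode="unrooted")
        return tuple(sorted(c for c in t.clade_counts if bin(c).count("1") == 2))

    def test_forced_nni_enumerates_both_alternatives(self):
        """A quartet has one internal edge; a *forced* NNI yields exactly
        the two alternative resolutions and never the original."""
        seen = Counter(self.resolution(t) for t in
                       perturb_tree_sample("((a,b),(c,d));", 400, 1.0, seed=4))
        original = self.resolution("((a,b),(c,d));")
        assert original not in seen
        assert len(seen) == 2

    def test_intermediate_probability_reaches_all_resolutions(self):
        seen = Counter(self.resolution(t) for t in
                       perturb_tree_sample("((a,b),(c,d));", 400, 0.6, seed=5))
        assert len(seen) == 3


class TestEnumerateOutcomes:
    def test_no_events_unit_mass_per_origination(self, tree2):
        acc, tail = enumerate_outcomes(tree2, DTLRates(0, 0, 0), max_events=6)
        assert tail == pytest.approx(0.0, abs=1e-12)
        # origination on stem -> (A,B); on each leaf branch -> single gene
        assert acc["(A,B)"] == pytest.approx(1 / 3)
        assert acc["A"] == pytest.approx(1 / 3)
        assert acc["B"] == pytest.approx(1 / 3)

    def test_extinction_approaches_golden_ratio(self, tree1):
        acc, tail = enumerate_outcomes(tree1, DTLRates(1, 0, 1), max_events=16)
        assert acc["extinct"] == pytest.approx(GOLDEN_E, abs=5 * tail)

    def test_total_mass_bookkeeping(self, tree2):
        acc, tail = enumerate_outcomes(tree2, DTLRates(0.2, 0.1, 0.2),
                                       max_events=9)
        # accumulation error over ~1e6 enumerated paths
        assert sum(acc.values()) + tail == pytest.approx(1.0, abs=1e-9)

    def test_agreement_with_sampling(self, tree1):
        rates = DTLRates(0.3, 0.0, 0.4)
        acc, tail = enumerate_outcomes(tree1, rates, max_events=14)
        n = 50000
        freq = outcome_frequencies(tree1, rates, n, seed=6)
        for key in ("extinct", "A", "(A,A)"):
            p = acc[key]
            se = math.sqrt(p * (1 - p) / n)
            assert freq[key] / n == pytest.approx(p, abs=3 * se + tail)


class TestSimulateGenomes:
    def test_block_prob_zero_gives_single_gene_transfers(self, tree8):
        _, _, truth = simulate_genomes(tree8, DTLRates(0.02, 0.3, 0.05),
                                       30, block_prob=0.0, seed=7)
        assert truth
        assert all(t.block_size == 1 for t in truth)

    def test_block_prob_one_gives_pairs(self, tree8):
        _, _, truth = simulate_genomes(tree8, DTLRates(0.02, 0.3, 0.05),
                                       30, block_prob=1.0, seed=8)
        assert any(t.block_size == 2 for t in truth)
        assert all(t.block_size <= 2 for t in truth)

    def test_no_transfers_keeps_content_vertical(self, tree8):
        fams, orders, truth = simulate_genomes(tree8, DTLRates(0.05, 0.0, 0.1),
                                               25, block_prob=0.5, seed=9)
        assert truth == []
        for fam in fams:
            assert all(ev[0] != "T" for ev in fam.events)

    def test_orders_cover_exactly_surviving_genes(self, tree8, mid_rates):
        fams, orders, _ = simulate_genomes(tree8, mid_rates, 20,
                                           block_prob=0.3, seed=10)
        by_species: dict[str, set] = {}
        for fam in fams:
            for g, sp in fam.gene_to_species.items():
                by_species.setdefault(sp, set()).add((fam.family_id, g))
        for sp in orders.orders:
            listed = set(orders.orders[sp])
            assert listed == by_species.get(sp, set())
            assert len(orders.orders[sp]) == len(listed)   # each gene once

    def test_transferred_leaf_genes_from_truth(self, tree8):
        fams, orders, truth = simulate_genomes(tree8, DTLRates(0.02, 0.25, 0.05),
                                               30, block_prob=0.5, seed=11)
        marked = transferred_leaf_genes(fams, tree8)
        n_marked = sum(len(v) for v in marked.values())
        leaf_branches = set(range(tree8.n_leaves))
        terminal_truth = [t for t in truth if t.recipient in leaf_branches]
        if terminal_truth:
            assert n_marked > 0
        for sp, genes in marked.items():
            listed = {g for _, g in orders.orders[sp]}
            assert genes <= listed

    def test_deterministic(self, tree8, mid_rates):
        a = simulate_genomes(tree8, mid_rates, 15, 0.4, seed=12)
        b = simulate_genomes(tree8, mid_rates, 15, 0.4, seed=12)
        assert a[1].orders == b[1].orders
        assert a[2] == b[2]
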