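"""Reconciliation sampling and event aggregation."""

import numpy as np
import pytest
from scipy.stats import chisquare

from dtlrec.ccp import observe_trees
from dtlrec.model import DTLRates, compute_dp
from dtlrec.reconcile import (Event, Reconciliation, ancestral_copy_numbers,
                              replacement_fraction, sample_reconciliations,
                              summarize_events, summarize_families)
from dtlrec.simulator import perturb_tree_sample, simulate_dataset


def make_rec(events, n_branches=9, fid="f", idx=0):
    return Reconciliation(family_id=fid, root=None, events=events,
                          n_branches=n_branches, sample_index=idx, seed=0)


class TestSampler:
    def test_no_event_rates_give_pure_vertical_history(self, tree3,
                                                       single_copy_ccp3):
        recs = sample_reconciliations(single_copy_ccp3, tree3,
                                      DTLRates(0, 0, 0), n_samples=10, seed=1)
        for rec in recs:
            kinds = sorted(e.kind for e in rec.events)
            assert kinds == ["C", "C", "C", "O", "S", "S"]
            assert rec.events[0].kind == "O"
            assert rec.events[0].branch == tree3.root

    def test_zero_samples(self, tree3, single_copy_ccp3):
        assert sample_reconciliations(single_copy_ccp3, tree3,
                                      DTLRates(0, 0, 0), n_samples=0,
                                      seed=1) == []

    def test_root_branch_frequencies_match_dp(self, tree3, single_copy_ccp3,
                                              mid_rates):
        """Origination branches must be drawn proportional to pi(Gamma, e);
        the DP itself is the oracle (chi-square, alpha = 0.01)."""
        dp = compute_dp(single_copy_ccp3, tree3, mid_rates)
        n = 30000
        recs = sample_reconciliations(single_copy_ccp3, tree3, mid_rates,
                                      n_samples=n, seed=5, dp=dp)
        counts = np.zeros(tree3.n_branches)
        for rec in recs:
            counts[rec.events[0].branch] += 1
        pi = dp.pi[single_copy_ccp3.gamma]
        expected = n * pi / pi.sum()
        keep = expected > 5
        stat, p = chisquare(counts[keep], expected[keep] *
                            counts[keep].sum() / expected[keep].sum())
        assert p > 0.01

    def test_deterministic_given_seed(self, tree6, mid_rates):
        fams = simulate_dataset(tree6, mid_rates, 3, seed=8)
        fam = fams[0]
        ccp = observe_trees(fam.family_id,
                            perturb_tree_sample(fam.newick, 10, 0.2, 3),
                            fam.gene_to_species, mode="unrooted")
        a = sample_reconciliations(ccp, tree6, mid_rates, 20, seed=9)
        b = sample_reconciliations(ccp, tree6, mid_rates, 20, seed=9)
        assert [r.newick for r in a] == [r.newick for r in b]
        assert [[(e.kind, e.branch, e.recipient) for e in r.events]
                for r in a] == \
               [[(e.kind, e.branch, e.recipient) for e in r.events]
                for r in b]

    @pytest.mark.parametrize("seed", [11, 12])
    def test_conservation_invariants(self, tree6, mid_rates, seed):
        """#C events equals family size; every T/TL increments exactly one
        donor->recipient pair."""
        fams = simulate_dataset(tree6, mid_rates, 5, seed=seed)
        for fam in fams:
            ccp = observe_trees(fam.family_id, [fam.newick],
                                fam.gene_to_species, mode="rooted")
            recs = sample_reconciliations(ccp, tree6, mid_rates, 20, seed=seed)
            for rec in recs:
                assert rec.leaf_count() == fam.size
            summary = summarize_events(recs)
            assert sum(summary.pair_counts.values()) == pytest.approx(
                summary.T_in.sum())
            assert summary.T_in.sum() == pytest.approx(summary.T_out.sum())

    def test_zero_likelihood_rejected(self, tree3):
        ccp = observe_trees("f", ["((A_g,C_g),B_g);"],
                            {"A_g": "A", "B_g": "B", "C_g": "C"}, mode="rooted")
        with pytest.raises(ValueError):
            sample_reconciliations(ccp, tree3, DTLRates(0, 0, 0), 5, seed=1)


class TestSummaries:
    def test_single_transfer_counting(self):
        rec = make_rec([Event("O", 4), Event("T", 4, recipient=7),
                        Event("C", 7), Event("C", 0)])
        s = summarize_events([rec])
        assert s.pair_counts == {(4, 7): 1.0}
        assert s.T_out[4] == 1.0 and s.T_in[7] == 1.0
        assert s.gains[7] == 1.0

    def test_mean_over_samples(self):
        r1 = make_rec([Event("T", 4, recipient=7)], idx=0)
        r2 = make_rec([Event("S", 4)], idx=1)
        s = summarize_events([r1, r2])
        assert s.T_in[7] == pytest.approx(0.5)

    def test_summaries_add_across_families(self):
        r1 = make_rec([Event("T", 4, recipient=7)], fid="a")
        r2 = make_rec([Event("T", 4, recipient=7), Event("D", 3)], fid="b")
        merged = summarize_families([[r1], [r2]])
        lhs = summarize_events([r1]).add(summarize_events([r2]))
        assert np.allclose(merged.T_in, lhs.T_in)
        assert merged.pair_counts == lhs.pair_counts
        assert merged.n_families == 2

    def test_loss_attribution(self):
        """SL charges the lost child branch; TL charges the donor."""
        rec = make_rec([Event("SL", 8, lost=6), Event("TL", 3, recipient=5)])
        s = summarize_events([rec])
        assert s.L[6] == 1.0 and s.L[3] == 1.0
        assert s.T_in[5] == 1.0

    def test_mixed_trees_rejected(self):
        with pytest.raises(ValueError):
            summarize_events([make_rec([], n_branches=9),
                              make_rec([], n_branches=7)])


class TestCopyNumbers:
    def test_leaf_totals_equal_observed_gene_counts(self, tree6, mid_rates):
        fams = simulate_dataset(tree6, mid_rates, 10, seed=31)
        summaries = []
        per_species = {}
        for fam in fams:
            for g, sp in fam.gene_to_species.items():
                per_species[sp] = per_species.get(sp, 0) + 1
            ccp = observe_trees(fam.family_id, [fam.newick],
                                fam.gene_to_species, mode="rooted")
            recs = sample_reconciliations(ccp, tree6, mid_rates, 10, seed=31)
            summaries.append(summarize_events(recs))
        sizes = ancestral_copy_numbers(summaries)
        for sp, e in tree6.leaf_index.items():
            assert sizes[e] == pytest.approx(per_species.get(sp, 0))

    def test_vertical_families_give_constant_ancestral_content(self, tree3,
                                                               single_copy_ccp3):
        summaries = []
        for i in range(4):
            recs = sample_reconciliations(single_copy_ccp3, tree3,
                                          DTLRates(0, 0, 0), 5, seed=i)
            summaries.append(summarize_events(recs))
        sizes = ancestral_copy_numbers(summaries)
        assert np.allclose(sizes, 4.0)


class TestReplacementFraction:
    def test_constructed_half(self):
        """Two incoming transfers on one branch, one of the two families
        also loses a copy there in the same sample -> fraction 0.5."""
        r1 = make_rec([Event("T", 2, recipient=5), Event("SL", 8, lost=5)],
                      fid="a")
        r2 = make_rec([Event("T", 3, recipient=5)], fid="b")
        frac, med = replacement_fraction([[r1], [r2]], n_branches=9)
        assert frac[5] == pytest.approx(0.5)
        assert med == pytest.approx(0.5)

    def test_no_losses_gives_zero(self):
        r = make_rec([Event("T", 2, recipient=5), Event("T", 1, recipient=3)])
        frac, med = replacement_fraction([[r]], n_branches=9)
        assert med == 0.0

    def test_no_transfers_is_missing(self):
        r = make_rec([Event("S", 4), Event("SL", 4, lost=1)])
        _, med = replacement_fraction([[r]], n_branches=9)
        assert med is None

    def test_lossless_simulation_median_zero(self, tree6):
        rates = DTLRates(0.1, 0.2, 0.0)
        fams = simulate_dataset(tree6, rates, 10, seed=17)
        recs = []
        for fam in fams:
            ccp = observe_trees(fam.family_id, [fam.newick],
                                fam.gene_to_species, mode="rooted")
            recs.append(sample_reconciliations(ccp, tree6, rates, 10, seed=17))
        _, med = replacement_fraction(recs, tree6.n_branches)
        assert med in (None, 0.0)
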