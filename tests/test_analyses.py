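"""Downstream statistics: ratios, saturation fit, highways, tandem, synteny."""

import numpy as np
import pytest

from dtlrec.analyses import (RatioPoint, compare_ancestral_extant,
                             event_ratios, fit_saturation, rank_highways,
                             rarefaction, synteny_transfer_comparison,
                             tandem_analytic_null, tandem_enrichment,
                             transferred_calls, ancestral_vs_extant_sizes)
from dtlrec.ccp import observe_trees
from dtlrec.model import DTLRates
from dtlrec.phylo import GeneFamily
from dtlrec.reconcile import (EventSummary, Reconciliation, RecNode,
                              sample_reconciliations, summarize_families)
from dtlrec.simulator import GenomeOrder, simulate_dataset


def summary_with(T=0.0, D=0.0, L=0.0, n=9):
    s = EventSummary.zeros(n)
    s.T_in[1] = T
    s.D[2] = D
    s.L[3] = L
    return s


class TestEventRatios:
    def test_arithmetic(self):
        p = event_ratios(summary_with(T=30, D=10, L=40))
        assert p.t_ratio == pytest.approx(0.75)
        assert p.l_ratio == pytest.approx(0.5)

    def test_missing_when_no_births(self):
        p = event_ratios(summary_with(T=0, D=0, L=5))
        assert p.t_ratio is None

    @pytest.mark.parametrize("rates,expect", [
        (DTLRates(0.15, 0.0, 0.1), 0.0),   # no transfers possible
        (DTLRates(0.0, 0.15, 0.1), 1.0),   # no duplications possible
    ])
    def test_degenerate_simulations(self, tree6, rates, expect):
        fams = simulate_dataset(tree6, rates, 15, seed=3)
        recs = []
        for fam in fams:
            ccp = observe_trees(fam.family_id, [fam.newick],
                                fam.gene_to_species, mode="rooted")
            recs.append(sample_reconciliations(ccp, tree6, rates, 10, seed=3))
        p = event_ratios(summarize_families(recs))
        if p.t_ratio is not None:
            assert p.t_ratio == pytest.approx(expect)


class TestFitSaturation:
    def curve(self, n, a=0.75, y0=0.2, s=5.0):
        return a - (a - y0) * np.exp(-np.asarray(n) / s)

    def test_exact_recovery_at_zero_noise(self):
        n = list(range(2, 22, 2))
        fit = fit_saturation(list(zip(n, self.curve(n))))
        assert fit.a == pytest.approx(0.75, abs=1e-6)
        assert fit.y0 == pytest.approx(0.2, abs=1e-6)
        assert fit.s == pytest.approx(5.0, abs=1e-5)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_constant_data_degenerates(self):
        fit = fit_saturation([(2, 0.4), (4, 0.4), (8, 0.4)])
        assert fit.a == fit.y0 == pytest.approx(0.4)

    def test_needs_three_distinct_sizes(self):
        with pytest.raises(ValueError):
            fit_saturation([(2, 0.1), (2, 0.2), (4, 0.3)])

    def test_se_shrinks_with_replicates(self):
        rng = np.random.default_rng(0)
        n_small, n_big = 4, 40
        ses = []
        for reps in (n_small, n_big):
            pts = []
            for _ in range(reps):
                for n in range(2, 22, 2):
                    pts.append((n, self.curve([n])[0] + rng.normal(0, 0.02)))
            ses.append(fit_saturation(pts).se_a)
        assert ses[1] < ses[0]


class TestRankHighways:
    def test_sorting_and_ties(self):
        s = EventSummary.zeros(9)
        s.pair_counts = {(1, 2): 5.0, (3, 4): 2.0, (0, 5): 2.0}
        pairs, curve = rank_highways(s)
        assert pairs[0][:2] == (1, 2)
        assert [p[:2] for p in pairs[1:]] == [(0, 5), (3, 4)]   # tie by id
        assert list(curve) == [5.0, 2.0, 2.0]
        assert np.all(np.diff(curve) <= 0)

    def test_top_k_zero_keeps_curve(self):
        s = EventSummary.zeros(9)
        s.pair_counts = {(1, 2): 5.0}
        pairs, curve = rank_highways(s, top_k=0)
        assert pairs == []
        assert len(curve) == 1

    def test_unordered_pooling(self):
        s = EventSummary.zeros(9)
        s.pair_counts = {(1, 2): 2.0, (2, 1): 3.0}
        pairs, _ = rank_highways(s, ordered=False)
        assert pairs == [(1, 2, 5.0)]


class TestTandemEnrichment:
    def genome(self, n, name="X"):
        return GenomeOrder({name: [(f"fam{i}", f"{name}_g{i}") for i in range(n)]})

    def test_contiguous_block_maximal(self):
        orders = self.genome(40)
        transferred = {"X": {f"X_g{i}" for i in range(5)}}
        per, fold = tandem_enrichment(transferred, orders, permutations=400,
                                      seed=1)
        assert per["X"]["f_obs"] == pytest.approx(1.0)
        assert fold > 1.0

    def test_null_self_consistency(self):
        """Labels placed by the null itself give fold ~ 1."""
        from random import Random
        rng = Random(9)
        orders = GenomeOrder({
            f"S{j}": [(f"fam{i}", f"S{j}_g{i}") for i in range(60)]
            for j in range(6)})
        transferred = {
            f"S{j}": {f"S{j}_g{i}" for i in rng.sample(range(60), 10)}
            for j in range(6)}
        _, fold = tandem_enrichment(transferred, orders, permutations=600,
                                    seed=2)
        assert fold == pytest.approx(1.0, abs=0.35)

    def test_skips_sparse_genomes(self):
        per, fold = tandem_enrichment({"X": {"X_g1"}}, self.genome(10),
                                      permutations=10, seed=3)
        assert "note" in per["X"]
        assert fold is None

    def test_analytic_null_matches_permutations(self):
        orders = self.genome(50)
        transferred = {"X": {f"X_g{i}" for i in (0, 7, 19, 23, 31, 44)}}
        per, _ = tandem_enrichment(transferred, orders, permutations=3000,
                                   seed=4)
        assert per["X"]["f_null"] == pytest.approx(
            per["X"]["f_null_analytic"], abs=0.03)
        assert tandem_analytic_null(50, 1) == 0.0


def leaf(gene, branch, transfers=0):
    return RecNode(1, "C", branch, gene=gene, edge_transfers=transfers)


def pair_rec(fid, gx, gy, transferred):
    root = RecNode(3, "S", 0, [leaf(gx, 1), leaf(gy, 2, 1 if transferred else 0)])
    ev = []
    return [Reconciliation(fid, root, ev, 9, 0, 0)]


class TestSynteny:
    def build(self, transferred_fam="fam2", displaced=True):
        fams = []
        recs = []
        x_order, y_order = [], []
        for i in range(6):
            fid = f"fam{i}"
            gx, gy = f"X_{fid}", f"Y_{fid}"
            fams.append(GeneFamily(fid, [gx, gy], {gx: "X", gy: "Y"},
                                   [f"({gx},{gy});"]))
            recs.append(pair_rec(fid, gx, gy, fid == transferred_fam))
            x_order.append((fid, gx))
            y_order.append((fid, gy))
        if displaced:
            # move the transferred family's Y gene away from its X
            # neighbours (X: 0,1,2,3,4,5 -> Y: 0,1,3,4,2,5 puts fam2
            # between fam4 and fam5)
            entry = y_order.pop(2)
            y_order.insert(4, entry)
        orders = GenomeOrder({"X": x_order, "Y": y_order})
        return fams, recs, orders

    def test_displaced_transferred_gene_not_conserved(self):
        fams, recs, orders = self.build()
        df = synteny_transfer_comparison(fams, recs, orders, [("X", "Y")])
        row = df.iloc[0]
        assert row["n_transferred"] == 1
        assert row["conserved_transferred"] < row["conserved_nontransferred"]

    def test_vertical_families_fully_conserved(self):
        fams, recs, orders = self.build(transferred_fam="none",
                                        displaced=False)
        df = synteny_transfer_comparison(fams, recs, orders, [("X", "Y")])
        row = df.iloc[0]
        assert row["n_transferred"] == 0
        assert row["conserved_nontransferred"] == pytest.approx(1.0)

    def test_pair_without_single_copy_families_flagged(self):
        fams, recs, orders = self.build()
        df = synteny_transfer_comparison(fams, recs, orders, [("X", "Z")])
        assert df.iloc[0]["n_families"] == 0

    def test_transferred_calls_threshold(self):
        r_yes = pair_rec("f", "X_f", "Y_f", True)
        calls = transferred_calls([r_yes], threshold=0.5)
        # arrival flags are on the C nodes, not edge_transfers
        assert set(calls) == {"X_f", "Y_f"}


class TestCompareAncestralExtant:
    def test_identical_samples_p_one(self):
        a = np.full(8, 5000.0)
        out = compare_ancestral_extant(a, a.copy())
        assert out["p_value"] == pytest.approx(1.0)

    def test_inflated_ancestral_detected_one_sided(self):
        extant = np.linspace(4000, 6000, 10)
        out = compare_ancestral_extant(extant + 5000, extant, mode="greater")
        assert out["p_value"] < 0.01

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compare_ancestral_extant(np.array([]), np.array([1.0]))

    def test_size_split(self, tree3):
        sizes = np.arange(5, dtype=float)
        anc, ext = ancestral_vs_extant_sizes(sizes, tree3)
        assert sorted(ext) == [0, 1, 2]
        assert sorted(anc) == [3, 4]


@pytest.fixture(scope="module")
def tiny_input(tree6, mid_rates):
    fams = simulate_dataset(tree6, mid_rates, 12, seed=5)
    return [f.to_family() for f in fams]


class TestRarefaction:
    def test_deterministic(self, tiny_input, tree6):
        kw = dict(n_samples=5, opt_kwargs={"maxiter": 30})
        a = rarefaction(tiny_input, tree6, [4], 1, seed=11, **kw)
        b = rarefaction(tiny_input, tree6, [4], 1, seed=11, **kw)
        assert [(p.T, p.D, p.L) for p in a] == [(p.T, p.D, p.L) for p in b]

    def test_points_structure(self, tiny_input, tree6):
        pts = rarefaction(tiny_input, tree6, [4, 6], 1, seed=11,
                          n_samples=5, opt_kwargs={"maxiter": 30})
        assert {p.n_species for p in pts} <= {4, 6}
        for p in pts:
            if p.t_ratio is not None:
                assert 0.0 <= p.t_ratio <= 1.0

    def test_oversized_subsample_rejected(self, tiny_input, tree6):
        with pytest.raises(ValueError):
            rarefaction(tiny_input, tree6, [99], 1, seed=1)
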