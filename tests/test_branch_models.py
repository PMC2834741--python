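"""Branch hypotheses, parameter counting, fitting, and AIC ranking."""

import numpy as np
import pytest

from alchevo.evo import (
    CodonBranchModel,
    ModelFitRecord,
    PhyloTree,
    aic,
    count_parameters,
    focal_branches,
    free_ratios,
    model_selection,
    single_ratio,
)
from alchevo.synth import simulate_codon_alignment


def caterpillar(n):
    """Fully resolved unrooted caterpillar tree on n taxa."""
    taxa = [f"t{i}" for i in range(n)]
    inner = f"({taxa[0]}:0.1,{taxa[1]}:0.1)"
    for t in taxa[2:-1]:
        inner = f"({inner}:0.1,{t}:0.1)"
    return PhyloTree.from_newick(f"({inner}:0.1,{taxa[-1]}:0.1);"), taxa


class TestParameterCounting:
    def test_thirty_taxon_hypothesis_ladder(self):
        tree, taxa = caterpillar(30)
        assert tree.is_fully_resolved_unrooted()
        h0 = single_ratio("H0")
        h1 = focal_branches([[{taxa[5]}]], name="H1")
        h2 = focal_branches([[{taxa[5]}], [{taxa[6]}]], name="H2")
        h3 = focal_branches([[{taxa[5]}], [{taxa[0], taxa[1]}]], name="H3")
        h4 = free_ratios("H4")
        counts = [count_parameters(tree, h) for h in (h0, h1, h2, h3, h4)]
        assert counts == [59, 60, 61, 61, 115]

    def test_small_tree_two_classes(self):
        tree, taxa = caterpillar(4)
        h = focal_branches([[{taxa[0]}]], name="two")
        assert count_parameters(tree, h) == 5 + 1 + 2

    def test_unresolved_tree_rejected(self):
        star = PhyloTree(
            ["a", "b", "c", "d"],
            parent=[4, 4, 4, 4, -1],
            lengths=[0.1, 0.1, 0.1, 0.1, 0.0],
            root=4,
        )
        with pytest.raises(ValueError):
            count_parameters(star, single_ratio())

    def test_selector_matching_no_edge_rejected(self):
        tree, taxa = caterpillar(6)
        bad = focal_branches([[{taxa[0], taxa[3]}]], name="bad")
        with pytest.raises(ValueError, match="no edge"):
            bad.branch_classes(tree)

    def test_overlapping_groups_rejected(self):
        tree, taxa = caterpillar(6)
        bad = focal_branches([[{taxa[0]}], [{taxa[0]}]], name="bad")
        with pytest.raises(ValueError, match="two groups"):
            bad.branch_classes(tree)


class TestAIC:
    @pytest.mark.parametrize(
        "k,lnl,full,reported",
        [
            (59, -5645.4, 11408.8, 11409),
            (60, -5641.7, 11403.4, 11403),
            (61, -5641.6, 11405.2, 11405),
            (61, -5641.5, 11405.0, 11405),
            (115, -5610.3, 11450.6, 11451),
        ],
    )
    def test_reproduces_published_pairs(self, k, lnl, full, reported):
        value = aic(lnl, k)
        assert value == pytest.approx(full, abs=1e-9)
        assert int(round(value)) == reported

    def test_zero_case(self):
        assert aic(0.0, 0) == 0.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            aic(float("nan"), 3)


class TestModelSelection:
    def records(self):
        rows = [("H0", -5645.4, 59), ("H1", -5641.7, 60), ("H2", -5641.6, 61),
                ("H3", -5641.5, 61), ("H4", -5610.3, 115)]
        return [ModelFitRecord(h, l, k) for h, l, k in rows]

    def test_selects_two_ratio_model(self):
        table, best = model_selection(self.records())
        assert best.hypothesis == "H1"
        assert table.iloc[0]["AIC"] == 11403
        assert list(table["hypothesis"]) == ["H1", "H3", "H2", "H0", "H4"]
        assert table["best"].sum() == 1

    def test_aic_tie_broken_by_smaller_k(self):
        a = ModelFitRecord("big", -10.0, 7)   # AIC 34
        b = ModelFitRecord("small", -12.0, 5)  # AIC 34
        _, best = model_selection([a, b])
        assert best.hypothesis == "small"

    def test_single_candidate_rejected(self):
        with pytest.raises(ValueError):
            model_selection([ModelFitRecord("only", -1.0, 2)])

    def test_differing_data_signatures_rejected(self):
        a = ModelFitRecord("a", -1.0, 2, data_signature="d1")
        b = ModelFitRecord("b", -2.0, 2, data_signature="d2")
        with pytest.raises(ValueError):
            model_selection([a, b])


@pytest.fixture(scope="module")
def simulated():
    from alchevo.evo.gy94 import CodonSubstModel

    tree = PhyloTree.from_newick(
        "((a:0.15,b:0.2):0.1,(c:0.25,d:0.1):0.05,e:0.3);"
    )
    pi = np.full(61, 1.0 / 61)
    model = CodonSubstModel(2.0, {0: 0.15}, pi)
    aln, _ = simulate_codon_alignment(tree, model, 150, seed=31)
    return aln, tree


class TestFitting:
    def test_single_ratio_fit_recovers_reasonable_omega(self, simulated):
        aln, tree = simulated
        fit = CodonBranchModel(aln, tree, single_ratio("H0")).fit(
            n_starts=1, seed=0
        )
        assert 0.05 <= fit.omega_by_class[0] <= 0.4
        assert fit.k == 7 + 1 + 1
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.lnL, rel=1e-12)
        assert "kappa" in fit.summary()

    def test_added_class_never_decreases_loglik(self, simulated):
        # nested models with shared starts: the richer model starts from the
        # simpler model's solution
        aln, tree = simulated
        f0 = CodonBranchModel(aln, tree, single_ratio("H0")).fit(
            n_starts=1, seed=1
        )
        h1 = focal_branches([[{"e"}]], name="H1")
        m1 = CodonBranchModel(aln, tree, h1)
        f1 = m1.fit(starts=[(f0.kappa, {0: f0.omega_by_class[0],
                                        1: f0.omega_by_class[0]})])
        assert f1.lnL >= f0.lnL - 1e-6

    def test_taxon_input_order_invariance(self, simulated):
        aln, tree = simulated
        fit_a = CodonBranchModel(aln, tree, single_ratio()).fit(n_starts=1, seed=2)
        reordered = aln.reordered(["e", "c", "a", "d", "b"])
        fit_b = CodonBranchModel(reordered, tree, single_ratio()).fit(
            n_starts=1, seed=2
        )
        assert fit_a.lnL == pytest.approx(fit_b.lnL, abs=1e-6)

    def test_data_signature_ties_fits_to_alignment(self, simulated):
        aln, tree = simulated
        f0 = CodonBranchModel(aln, tree, single_ratio("H0")).fit(n_starts=1)
        other, _ = simulate_codon_alignment(
            tree, __import__("alchevo").evo.CodonSubstModel(
                2.0, {0: 0.15}, np.full(61, 1 / 61)
            ), 150, seed=99,
        )
        f1 = CodonBranchModel(other, tree, single_ratio("H1")).fit(n_starts=1)
        with pytest.raises(ValueError):
            model_selection([f0, f1])
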