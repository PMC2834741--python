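"""Synthetic-data generators: determinism and statistical identities."""

import math

import numpy as np
import pytest
from Bio.Seq import Seq

from alchevo.constants import kt
from alchevo.synth import (
    ScenarioSeeds,
    gen_bar_works,
    gen_dhdl,
    mc_restraint_oracle,
    selection_contrast_scenario,
    simulate_codon_alignment,
)
from alchevo.evo import CodonSubstModel, PhyloTree
from alchevo.evo.gy94 import TransitionMatrixFactory


class TestGenDhdl:
    def test_zero_noise_reproduces_profile(self):
        coef = [1.0, -2.0, 3.0]
        series, truth = gen_dhdl(coef, [0.0, 0.5, 1.0], 0.0, 5, seed=0)
        expected = [1.0, 1.0 - 1.0 + 0.75, 2.0]
        np.testing.assert_allclose(series.means(), expected, atol=1e-12)
        assert truth.values["integral_kJ_mol"] == pytest.approx(1.0 - 1.0 + 1.0)

    def test_seed_determinism(self):
        a, _ = gen_dhdl([1.0], np.linspace(0, 1, 5), 2.0, 50, seed=42)
        b, _ = gen_dhdl([1.0], np.linspace(0, 1, 5), 2.0, 50, seed=42)
        for x, y in zip(a.dhdl_samples, b.dhdl_samples):
            np.testing.assert_array_equal(x, y)

    def test_sample_means_obey_clt_bound(self):
        series, _ = gen_dhdl([5.0, 10.0], np.linspace(0, 1, 11), 5.0, 10000,
                             seed=3)
        lams = np.asarray(series.lambda_values)
        truth = 5.0 + 10.0 * lams
        bound = 4.0 * 5.0 / math.sqrt(10000)
        assert (np.abs(series.means() - truth) < bound).all()

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError):
            gen_dhdl([1.0], [], 1.0, 10, seed=0)


class TestGenBarWorks:
    def test_near_delta_limit_recovers_exactly(self):
        from alchevo.fe import bar_pair

        works, _ = gen_bar_works(6.0, 1e-6, 100, 100, 277.0, seed=0)
        assert bar_pair(works).value == pytest.approx(6.0, abs=1e-4)

    def test_zero_delta_f_symmetric(self):
        from alchevo.fe import bar_pair

        works, _ = gen_bar_works(0.0, 3.0, 4000, 4000, 277.0, seed=1)
        est = bar_pair(works)
        assert abs(est.value) <= 3.0 * est.stderr

    def test_jarzynski_identity(self):
        # <exp(-beta W_F)> = exp(-beta dF), within Monte-Carlo error
        temp, df, sd = 277.0, 4.0, 3.0
        beta = 1.0 / kt(temp)
        works, _ = gen_bar_works(df, sd, 100_000, 10, temp, seed=2)
        x = np.exp(-beta * works.forward_works)
        mc_err = x.std(ddof=1) / math.sqrt(x.size)
        assert abs(x.mean() - math.exp(-beta * df)) <= 4.0 * mc_err

    def test_crooks_mean_structure(self):
        temp, df, sd = 300.0, -5.0, 4.0
        beta = 1.0 / kt(temp)
        works, _ = gen_bar_works(df, sd, 200_000, 200_000, temp, seed=3)
        assert works.forward_works.mean() == pytest.approx(
            df + 0.5 * beta * sd**2, abs=0.05
        )
        assert works.reverse_works.mean() == pytest.approx(
            -df + 0.5 * beta * sd**2, abs=0.05
        )

    def test_invalid_sd_rejected(self):
        with pytest.raises(ValueError):
            gen_bar_works(1.0, 0.0, 10, 10, 277.0, seed=0)


class TestSimulateCodons:
    def test_zero_branch_lengths_copy_root(self, uniform_codon_model):
        tree = PhyloTree.from_newick("(a:0.0,b:0.0,c:0.0);")
        aln, _ = simulate_codon_alignment(tree, uniform_codon_model(), 30, seed=4)
        assert aln.sequence("a") == aln.sequence("b") == aln.sequence("c")

    def test_omega_zero_is_purely_synonymous(self, uniform_codon_model):
        tree = PhyloTree.from_newick("(a:0.5,b:0.5,c:0.5);")
        model = uniform_codon_model(omegas=(0.0,))
        aln, _ = simulate_codon_alignment(tree, model, 100, seed=5)
        proteins = {str(Seq(aln.sequence(t)).translate()) for t in aln.taxa}
        assert len(proteins) == 1

    def test_seed_determinism(self, uniform_codon_model, small_tree):
        a, _ = simulate_codon_alignment(small_tree, uniform_codon_model(), 50,
                                        seed=6)
        b, _ = simulate_codon_alignment(small_tree, uniform_codon_model(), 50,
                                        seed=6)
        np.testing.assert_array_equal(a.codons, b.codons)

    def test_long_branch_frequencies_converge_to_stationary(self):
        rng = np.random.default_rng(7)
        pi = rng.dirichlet(np.ones(61) * 20)
        model = CodonSubstModel(2.0, {0: 0.5}, pi)
        tree = PhyloTree.from_newick("(a:40.0,b:40.0,c:40.0);")
        n = 100_000
        aln, _ = simulate_codon_alignment(tree, model, n, seed=8)
        counts = np.bincount(aln.codons[0], minlength=61)
        stderr = np.sqrt(pi * (1 - pi) * n)
        assert (np.abs(counts - n * pi) <= 3.0 * stderr + 1e-9).mean() > 0.95

    def test_truth_records_parameters(self, uniform_codon_model, small_tree):
        _, truth = simulate_codon_alignment(small_tree, uniform_codon_model(),
                                            10, seed=9)
        assert truth.values["kappa"] == 2.0
        assert truth.seed == 9


class TestScenario:
    def test_selection_contrast_is_deterministic_and_well_formed(self):
        a, tree_a, truth_a = selection_contrast_scenario(seed=11)
        b, tree_b, _ = selection_contrast_scenario(seed=11)
        np.testing.assert_array_equal(a.codons, b.codons)
        assert tree_a.is_fully_resolved_unrooted()
        assert a.n_taxa == 8 and a.n_sites == 500
        assert truth_a.values["omega_class_0"] == 0.09
        assert truth_a.values["omega_class_1"] == 0.30

    def test_scenario_seeds_are_stable_and_stage_specific(self):
        s = ScenarioSeeds(5)
        assert s.for_stage("dhdl") == ScenarioSeeds(5).for_stage("dhdl")
        assert s.for_stage("dhdl") != s.for_stage("bar")
        assert 0 <= s.for_stage("bar") < 2**31


def test_truth_file_round_trip(tmp_path):
    _, truth = gen_dhdl([2.0], [0.0, 1.0], 0.0, 1, seed=1)
    out = tmp_path / "truth.tsv"
    truth.to_tsv(out)
    text = out.read_text()
    assert "integral_kJ_mol\t2" in text and "seed\t1" in text


def test_mc_oracle_seed_determinism():
    import math as m

    from alchevo.fe import RestraintSpec

    spec = RestraintSpec(0.6, m.pi / 2, m.pi / 2, 0, 1, 2,
                         1000, 1000, 1000, 1000, 1000, 1000)
    a = mc_restraint_oracle(spec, n_samples=5000, seed=3)
    b = mc_restraint_oracle(spec, n_samples=5000, seed=3)
    assert a.value == b.value
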