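"""Thermodynamic-cycle assembly and the insertion/deletion diagnostic."""

import numpy as np
import pytest

from alchevo import datasets
from alchevo.fe import (
    ALCHEMICAL_LEG_NAMES,
    CycleLeg,
    FreeEnergyEstimate,
    assemble_cycle,
    consistency_check,
)


def legs_from(values, direction="insertion", stderr=0.0,
              names=("elec-complex", "LJ-complex", "solution-recoupling")):
    return [
        CycleLeg(n, direction, FreeEnergyEstimate(v, stderr, "TI-poly", direction))
        for n, v in zip(names, values)
    ]


PUBLISHED = {
    "ER-alpha1": ((-21.5, -146.7, 48.9), -64.3),
    "ER-alpha2": ((-27.6, -126.5, 49.9), -49.2),
    "ER-beta1": ((-31.4, -132.4, 52.4), -56.4),
    "ER-beta2": ((-24.2, -144.1, 49.9), -63.4),
}


class TestAssembly:
    @pytest.mark.parametrize("isoform", list(PUBLISHED))
    def test_reproduces_published_binding_totals(self, isoform):
        components, total = PUBLISHED[isoform]
        cycle = assemble_cycle(legs_from(components), 61.8, -6.8,
                               sense="insertion", label=isoform)
        assert cycle.total_dG == pytest.approx(total, abs=1e-9)

    def test_bundled_reference_components_assemble_to_bundled_totals(self):
        comp = datasets.binding_components()
        totals = datasets.binding_totals()
        for isoform in totals.index:
            values = comp.loc[
                ["elec-complex", "LJ-complex", "solution-recoupling"], isoform
            ]
            cycle = assemble_cycle(legs_from(values), 61.8, -6.8, label=isoform)
            assert cycle.total_dG == pytest.approx(
                totals.loc[isoform, "dG_bind"], abs=1e-9
            )

    def test_null_cycle(self):
        cycle = assemble_cycle(legs_from((0.0, 0.0, 0.0)), 0.0, 0.0)
        assert cycle.total_dG == 0.0

    def test_linearity_in_components(self):
        comps = np.array([-21.5, -146.7, 48.9])
        base = assemble_cycle(legs_from(comps), 61.8, -6.8)
        scaled = assemble_cycle(legs_from(3.0 * comps), 3 * 61.8, 3 * -6.8)
        assert scaled.total_dG == pytest.approx(3.0 * base.total_dG, rel=1e-12)

    def test_leg_permutation_invariance(self):
        legs = legs_from((-5.0, 10.0, 2.5))
        a = assemble_cycle(legs, 1.0, -2.0)
        b = assemble_cycle(legs[::-1], 1.0, -2.0)
        assert a.total_dG == b.total_dG

    def test_opposite_direction_leg_contributes_negated(self):
        ins = CycleLeg("elec-complex", "insertion",
                       FreeEnergyEstimate(-20.0, 0.0, "TI-poly", "insertion"))
        dele = CycleLeg("LJ-complex", "deletion",
                        FreeEnergyEstimate(30.0, 0.0, "TI-poly", "deletion"))
        cycle = assemble_cycle([ins, dele], 0.0, 0.0, sense="insertion")
        assert cycle.total_dG == pytest.approx(-20.0 - 30.0)

    def test_reversing_declared_sense_negates_total(self):
        legs = legs_from((-21.5, -146.7, 48.9))
        fwd = assemble_cycle(legs, 61.8, -6.8, sense="insertion")
        rev = assemble_cycle(legs, 61.8, -6.8, sense="deletion")
        assert rev.total_dG == pytest.approx(-fwd.total_dG, rel=1e-12)

    def test_duplicate_leg_names_rejected(self):
        legs = legs_from((1.0, 2.0), names=("a", "a"))
        with pytest.raises(ValueError, match="duplicate"):
            assemble_cycle(legs, 0.0, 0.0)

    def test_missing_required_leg_rejected(self):
        legs = legs_from((1.0, 2.0, 3.0),
                         names=("elec-complex", "LJ-complex", "LJ-solution"))
        with pytest.raises(ValueError, match="missing"):
            assemble_cycle(legs, 0.0, 0.0, required=ALCHEMICAL_LEG_NAMES)

    def test_total_stderr_combines_in_quadrature(self):
        legs = legs_from((1.0, 2.0, 3.0), stderr=2.0)
        cycle = assemble_cycle(legs, 0.0, 0.0)
        assert cycle.total_stderr == pytest.approx(np.sqrt(12.0), rel=1e-12)


class TestConsistency:
    def test_identical_cycles_pass_with_zero_discrepancy(self):
        c = assemble_cycle(legs_from((1.0, 2.0, 3.0), stderr=1.0), 0.0, 0.0,
                           label="x")
        report = consistency_check(c, c)
        assert report.discrepancy == 0.0 and report.passed

    def test_large_discrepancy_fails(self):
        stderr = np.sqrt(0.5)  # one leg per cycle -> pooled stderr exactly 1
        a = assemble_cycle(legs_from((10.0,), stderr=stderr, names=("leg",)),
                           0.0, 0.0, label="x")
        b = assemble_cycle(legs_from((0.0,), stderr=stderr, names=("leg",)),
                           0.0, 0.0, label="x")
        report = consistency_check(a, b)
        assert report.discrepancy == pytest.approx(10.0)
        assert report.pooled_stderr == pytest.approx(1.0)
        assert not report.passed

    def test_mismatched_labels_rejected(self):
        a = assemble_cycle(legs_from((1.0, 1.0, 1.0)), 0.0, 0.0, label="x")
        b = assemble_cycle(legs_from((1.0, 1.0, 1.0)), 0.0, 0.0, label="y")
        with pytest.raises(ValueError):
            consistency_check(a, b)

    def test_opposite_sense_cycles_compare_on_common_scale(self):
        legs = legs_from((-5.0, -10.0, 3.0), stderr=1.0)
        ins = assemble_cycle(legs, 2.0, -1.0, sense="insertion", label="x")
        rev = assemble_cycle(legs, 2.0, -1.0, sense="deletion", label="x")
        report = consistency_check(ins, rev)
        assert report.discrepancy == pytest.approx(0.0, abs=1e-12)

    def test_noisy_replicates_calibrated_at_default_threshold(self):
        # independent unit noise around a shared truth with honestly declared
        # stderrs: the 2-pooled-stderr rule has nominal coverage
        # P(|Z| < 2) = 95.45%; the empirical pass rate over 200 replicates
        # must agree within 3 binomial standard errors
        rng = np.random.default_rng(123)
        truth = np.array([-21.5, -146.7, 48.9])
        passes = 0
        n_rep = 200
        for _ in range(n_rep):
            ins = assemble_cycle(
                legs_from(truth + rng.normal(0, 1, 3), stderr=1.0),
                61.8, -6.8, label="r",
            )
            dele = assemble_cycle(
                legs_from(truth + rng.normal(0, 1, 3), stderr=1.0),
                61.8, -6.8, label="r",
            )
            passes += consistency_check(ins, dele).passed
        nominal = 0.9545
        tol = 3.0 * np.sqrt(nominal * (1 - nominal) / n_rep)
        assert abs(passes / n_rep - nominal) <= tol
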