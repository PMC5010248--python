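"""The DnaA ATP/ADP regulatory cycle and its genotype phenotypes."""

import math
from dataclasses import replace

import numpy as np
import pytest

from orichron import dnaa_cycle as dc
from orichron import multifork as mf
from orichron.cell_cycle import CellCycleParams, gene_dosage
from orichron.errors import (
    CalibrationError,
    ConfigurationError,
    ParameterError,
    StepSizeError,
)


class TestGenotype:
    def test_wild_type_layout(self):
        wt = dc.wild_type()
        names = {l.name for l in wt.loci}
        assert names == {"datA", "DARS1", "DARS2"}
        (dars2,) = wt.named("DARS2")
        assert dars2.gating == dc.PRE_INITIATION_WINDOW

    def test_editing_helpers(self):
        wt = dc.wild_type()
        assert len(wt.without("datA").loci) == 2
        assert wt.relocated("DARS1", 0.05).named("DARS1")[0].x == 0.05
        assert wt.with_activity("DARS2", 0.0).named("DARS2")[0].activity == 0.0
        assert all(l.gating == dc.CONSTITUTIVE for l in wt.ungated().loci)

    def test_validation(self):
        with pytest.raises(ParameterError):
            dc.RegulatoryLocus("datA", x=1.5)
        with pytest.raises(ParameterError):
            dc.RegulatoryParams(theta=-1)


class TestInstantaneousCopies:
    def test_newborn(self, cc):
        state = mf.state_at_age(0.0, cc)
        locus = dc.RegulatoryLocus("datA", x=0.9, copies_modifier=3)
        assert dc.instantaneous_copies(locus, state) == 3

    def test_duplicated_after_fork_passage(self, cc):
        state = mf.state_at_age(0.0, cc)  # fork at 35/42 ~ 0.83
        locus = dc.RegulatoryLocus("datA", x=0.2)
        assert dc.instantaneous_copies(locus, state) == 2

    def test_population_average_matches_dosage(self, cc):
        """Time-averaged copy number over a noiseless population is the
        replication-associated gene dosage (the Cooper-Helmstetter oracle)."""
        pop = mf.sample_population(30_000, cc, seed=3)
        for x in (0.2, 0.42, 0.66):
            locus = dc.RegulatoryLocus("probe", x=x)
            cp = np.array([dc.instantaneous_copies(locus, s) for s in pop], float)
            se = cp.std(ddof=1) / math.sqrt(len(cp))
            assert abs(cp.mean() - gene_dosage(x, cc)) < 3.5 * se


class TestSimulate:
    def test_mass_balance(self, cc):
        """Total DnaA changes only through synthesis and division dilution:
        between divisions the pool never decreases and never grows faster
        than the synthesis flux allows."""
        reg = dc.RegulatoryParams()
        tr = dc.simulate(dc.wild_type(), reg, cc, duration=300, seed=4)
        total = tr["atp"] + tr["adp"]
        d = np.diff(total)
        # per-step synthesis is bounded by k_syn * mass * dosage modulation,
        # over dt plus the cascade span in initiation steps
        syn_cap = reg.k_syn * tr["mass"].max() * 2.0 * (reg.dt + reg.cascade_span)
        drops = d < -1e-9
        # decreases happen only at divisions and halve the pool (up to the
        # synthesis made in the same step)
        resid = d[drops] + 0.5 * total[:-1][drops]
        assert np.all((resid >= 0) & (resid < syn_cap))
        # between divisions the pool only grows, and no faster than synthesis
        assert np.all(d[~drops] <= syn_cap)

    def test_degenerate_synthesis_only(self, cc):
        """With every conversion rate zero, DnaA-ATP simply accumulates and
        initiation recurs whenever the threshold is crossed."""
        reg = dc.RegulatoryParams(k_rida=0, k_datA=0, k_dars1=0, k_dars2=0)
        tr = dc.simulate(dc.wild_type(), reg, cc, duration=40 * 40, seed=0)
        ev = tr["events"]
        assert len(ev) >= 10
        tail = np.diff(ev[ev > 20 * 40])
        assert len(tail) >= 3
        # recurrent initiation, on the doubling-time scale at steady state
        assert 0.5 * cc.tau <= np.median(tail) <= 2.0 * cc.tau

    def test_step_size_guard(self, cc):
        reg = dc.RegulatoryParams(dt=10.0)
        with pytest.raises(StepSizeError, match="dt"):
            dc.simulate(dc.wild_type(), reg, cc, duration=100)

    def test_seeded_reproducibility(self, cc):
        reg = dc.RegulatoryParams()
        a = dc.simulate(dc.wild_type(), reg, cc, duration=200, seed=9)
        b = dc.simulate(dc.wild_type(), reg, cc, duration=200, seed=9)
        assert np.array_equal(a["atp"], b["atp"])
        assert np.array_equal(a["events"], b["events"])


class TestCalibration:
    def test_wild_type_postcondition(self, cc, calibrated):
        reg, base = calibrated
        assert abs(base.mean_initiation_interval / cc.tau - 1.0) <= 0.05
        assert base.A < 0.1
        # consistent with the deterministic schedule's origin number
        assert base.mean_origins == pytest.approx(2 ** (75 / 40), rel=0.15)

    def test_no_rejuvenation_fails(self, cc):
        bad = dc.RegulatoryParams(k_dars1=0.0, k_dars2=0.0, theta=1e5)
        with pytest.raises(CalibrationError):
            dc.calibrate(cc, reg0=bad, seed=0, max_iter=2)

    def test_phenotype_requires_baseline(self, cc, calibrated):
        reg, _ = calibrated
        with pytest.raises(ConfigurationError):
            dc.phenotype(dc.wild_type(), reg, cc, n_cells=10, seed=0)

    def test_rescaled_params_time_invariant(self, cc):
        reg = dc.RegulatoryParams()
        cc2 = CellCycleParams(C=cc.C * 2, D=cc.D * 2, tau=cc.tau * 2)
        a = dc.raw_phenotype(dc.wild_type(), reg, cc, n_cells=40, seed=5)
        b = dc.raw_phenotype(
            dc.wild_type(), reg.rescaled(2.0), cc2, n_cells=40, seed=5,
            duration=28 * cc.tau,
        )
        assert a.histogram.frequencies() == pytest.approx(b.histogram.frequencies())
        assert a.A == pytest.approx(b.A)


@pytest.fixture(scope="module")
def suite(cc, calibrated):
    """Phenotypes of the directional genotype panel under calibrated
    wild-type parameters (computed once; ~10 s)."""
    reg, base = calibrated
    wt = dc.wild_type()
    genotypes = {
        "wt": wt,
        "delta_datA": wt.without("datA"),
        "delta_DARS1": wt.without("DARS1"),
        "delta_DARS2": wt.without("DARS2"),
        "datA_ter": wt.relocated("datA", 1.0),
        "datA_double_ter": wt.without("datA").with_extra(
            dc.RegulatoryLocus("datA", x=1.0, copies_modifier=2)
        ),
        "DARS1_ori": wt.relocated("DARS1", 0.02),
        "DARS2_ter": wt.relocated("DARS2", 1.0),
        "datA_inactivated": wt.with_activity("datA", 0.0),
    }
    return {
        name: dc.phenotype(
            g, reg, cc, n_cells=150, seed=7, baseline=base.raw_origins_per_mass
        )
        for name, g in genotypes.items()
    }


class TestDirectionalSuite:
    """Sign pattern of the relocation experiments under the calibrated model."""

    def test_wild_type_reference(self, suite):
        assert suite["wt"].origins_per_mass_rel == pytest.approx(1.0, abs=0.1)
        assert suite["wt"].A < 0.1

    def test_datA_deletion_raises_origin_concentration(self, suite):
        assert suite["delta_datA"].origins_per_mass_rel > 1.05

    def test_dars_deletions_lower_origin_concentration(self, suite):
        assert suite["delta_DARS1"].origins_per_mass_rel < 0.95
        assert suite["delta_DARS2"].origins_per_mass_rel < 0.95

    def test_only_dars2_loss_causes_asynchrony(self, suite):
        assert suite["delta_DARS2"].A > 0.1
        assert suite["delta_DARS2"].asynchrony.asynchronous
        assert suite["delta_DARS1"].A < 0.1

    def test_datA_at_terminus_partial_loss_of_function(self, suite):
        opm = suite["datA_ter"].origins_per_mass_rel
        assert 1.0 < opm < suite["delta_datA"].origins_per_mass_rel
        assert suite["datA_ter"].A < 0.1

    def test_second_terminal_datA_copy_restores(self, suite):
        assert suite["datA_double_ter"].origins_per_mass_rel <= 1.0
        assert suite["datA_double_ter"].A < 0.1

    def test_dars1_near_origin_over_initiates(self, suite):
        assert suite["DARS1_ori"].origins_per_mass_rel > 1.05

    def test_dars2_at_terminus_asynchronous_but_milder(self, suite):
        ph = suite["DARS2_ter"]
        assert ph.A > 0.1
        assert (
            suite["delta_DARS2"].origins_per_mass_rel
            < ph.origins_per_mass_rel
            < 1.0
        )

    def test_transcription_through_equals_deletion(self, suite):
        """Activity 0 (transcription through the locus) phenocopies the
        deletion exactly under a shared seed."""
        a = suite["datA_inactivated"]
        b = suite["delta_datA"]
        assert a.origins_per_mass_rel == pytest.approx(b.origins_per_mass_rel)
        assert a.A == pytest.approx(b.A)


def test_removing_gating_collapses_dars_distinction(cc, calibrated):
    """With DARS2 made constitutive (its burst spread over the whole cycle
    at equivalent total activity), relocating it to the terminus no longer
    produces the asynchrony that distinguishes it from a DARS1-like locus."""
    reg, base = calibrated
    spread = reg.k_dars2 * (reg.window + reg.cascade_span) / cc.tau
    reg_const = replace(reg, k_dars2=spread)
    wt_const = dc.wild_type().ungated()
    base_c = dc.raw_phenotype(wt_const, reg_const, cc, n_cells=120, seed=6)
    ter_dars2 = dc.raw_phenotype(
        wt_const.relocated("DARS2", 1.0), reg_const, cc, n_cells=120, seed=8
    )
    ter_dars1 = dc.raw_phenotype(
        wt_const.relocated("DARS1", 1.0), reg_const, cc, n_cells=120, seed=8
    )
    # same classification for DARS2-like and DARS1-like relocation
    assert ter_dars2.asynchrony.classification == ter_dars1.asynchrony.classification
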