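"""Serial-passage competition, clonality readouts and junction calling."""

import numpy as np
import pandas as pd
import pytest

from orichron import evolution as ev
from orichron import synthetic as syn
from orichron.errors import EmptyInputError, ParameterError


def two_clones(s_a=0.05, s_b=0.0):
    return [
        ev.InsertionClone(100, "+", s_a, 0.5),
        ev.InsertionClone(200, "+", s_b, 0.5),
    ]


class TestSimulateCompetition:
    def test_neutral_deterministic_constant(self):
        traj = ev.simulate_competition(two_clones(0, 0), bottleneck_cells=None)
        assert np.allclose(traj.frequencies, 0.5)

    def test_deterministic_fixation_closed_form(self):
        """A 5% advantage compounds to (1.05)**700 ~ 6.9e14 and fixes the
        fitter clone to machine precision by generation 700."""
        traj = ev.simulate_competition(two_clones(), bottleneck_cells=None)
        f = traj.at(700)
        ratio = f[0] / f[1]
        assert ratio == pytest.approx(1.05**700, rel=1e-9)
        assert f[0] > 0.99

    def test_frequencies_are_probability_vectors(self):
        rng = np.random.default_rng(0)
        pool = pd.DataFrame(
            {
                "position_bp": rng.integers(0, 4_641_652, 2000),
                "fitness": 0.0,
            }
        )
        traj = ev.simulate_competition(pool, bottleneck_cells=100_000, seed=1)
        sums = traj.frequencies.sum(axis=0)
        assert np.allclose(sums, 1.0)
        assert (traj.frequencies >= 0).all()

    def test_drift_erodes_heterozygosity(self):
        rng = np.random.default_rng(2)
        pool = pd.DataFrame(
            {"position_bp": rng.integers(0, 4_641_652, 5000), "fitness": 0.0}
        )
        traj = ev.simulate_competition(pool, bottleneck_cells=20_000, seed=3)
        h0 = ev.heterozygosity(traj.at(0))
        h700 = ev.heterozygosity(traj.at(700))
        assert h700 < h0

    def test_neutral_martingale(self):
        """Under s=0 the expected frequency is constant: batch means across
        seeds stay within sampling error of the initial frequency."""
        pool = [
            ev.InsertionClone(0, "+", 0.0, 0.2),
            ev.InsertionClone(1, "+", 0.0, 0.8),
        ]
        finals = [
            ev.simulate_competition(
                pool, total_gens=200, bottleneck_cells=2000, seed=s
            ).at(200)[0]
            for s in range(200)
        ]
        se = np.std(finals, ddof=1) / np.sqrt(len(finals))
        assert abs(np.mean(finals) - 0.2) < 4 * max(se, 1e-3)

    def test_dominant_clone_fixes_across_seeds(self):
        """A clone with a >= 0.05 advantage over the field fixes by
        generation 700 at a 1e5 bottleneck."""
        rng = np.random.default_rng(4)
        n = 500
        fitness = np.zeros(n)
        fitness[0] = 0.05
        pool = pd.DataFrame(
            {"position_bp": rng.integers(0, 4_641_652, n), "fitness": fitness}
        )
        wins = sum(
            ev.simulate_competition(pool, bottleneck_cells=100_000, seed=s).at(700)[0]
            > 0.99
            for s in range(10)
        )
        assert wins == 10

    def test_empty_pool_rejected(self):
        with pytest.raises(EmptyInputError):
            ev.simulate_competition([])


class TestBandCount:
    def test_examples(self):
        assert ev.band_count(np.array([0.97, 0.02, 0.01]), 0.05) == 1
        uniform = np.full(70_000, 1 / 70_000)
        assert ev.band_count(uniform, 0.05) == 0

    def test_single_band_after_selection(self):
        traj = ev.simulate_competition(two_clones(), bottleneck_cells=None)
        assert ev.band_count(traj.at(0), 0.05) == 2
        assert ev.band_count(traj.at(700), 0.05) == 1

    def test_expected_band_count_non_increasing(self):
        rng = np.random.default_rng(5)
        pool = pd.DataFrame(
            {
                "position_bp": rng.integers(0, 4_641_652, 40),
                "fitness": rng.normal(0, 0.01, 40),
            }
        )
        traj = ev.simulate_competition(pool, bottleneck_cells=50_000, seed=6)
        bands = [ev.band_count(traj.at(g), 0.02) for g in traj.generations]
        # not strictly monotone per-seed, but never recovers lost diversity
        assert bands[-1] <= bands[0]
        assert min(bands) == bands[-1]


class TestPairwiseCompetition:
    def test_equal_fitness_flat(self):
        out = ev.pairwise_competition(0.02, 0.02, gens=80)
        assert np.allclose(out["log10_ratio"], 0.0)

    def test_closed_form_log_difference(self):
        out = ev.pairwise_competition(0.043, 0.0, gens=80)
        expected = 80 * np.log10(1.043)
        assert out["log10_ratio"].iloc[-1] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.46, abs=0.01)

    def test_sign_flip_symmetry(self):
        a = ev.pairwise_competition(0.03, 0.0, gens=40)
        b = ev.pairwise_competition(0.0, 0.03, gens=40)
        assert np.allclose(a["log10_ratio"], -b["log10_ratio"])

    def test_sampling_grid(self):
        out = ev.pairwise_competition(0.01, 0.0, gens=80, sample_every=10)
        assert list(out["generation"]) == list(range(0, 90, 10))
        with pytest.raises(ParameterError):
            ev.pairwise_competition(0.01, 0.0, gens=85, sample_every=10)


@pytest.fixture(scope="module")
def small_reference(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("ref")
    spec = syn.SyntheticSpec(seed=11, genome_length_bp=10_000)
    fa, loci, truth = syn.make_reference(spec, tmp)
    return fa


class TestJunctionCalling:
    def test_error_free_exact_recovery(self, small_reference, tmp_path):
        ins = [(4321, "+", 1.0)]
        fq, _ = syn.make_junction_reads(
            small_reference, ins, tmp_path / "r.fq", n_reads=50, seed=1
        )
        res = ev.call_insertion_sites(fq, syn.DEFAULT_TN_END, small_reference)
        assert len(res.calls) == 1
        call = res.calls.iloc[0]
        assert (call["position_bp"], call["strand"], call["support"]) == (4321, "+", 50)
        assert not call["ambiguous"]

    def test_two_sites_with_proportions(self, small_reference, tmp_path):
        ins = [(1234, "+", 0.7), (8000, "-", 0.3)]
        fq, _ = syn.make_junction_reads(
            small_reference, ins, tmp_path / "r.fq", n_reads=400, seed=2
        )
        res = ev.call_insertion_sites(fq, syn.DEFAULT_TN_END, small_reference)
        assert len(res.calls) == 2
        by_pos = res.calls.set_index("position_bp")
        assert by_pos.loc[1234, "strand"] == "+"
        assert by_pos.loc[8000, "strand"] == "-"
        frac = by_pos.loc[1234, "support"] / res.calls["support"].sum()
        assert frac == pytest.approx(0.7, abs=0.08)  # binomial CI at n=400

    def test_recall_with_sequencing_errors(self, small_reference, tmp_path):
        """>= 95% of reads with 1% substitution errors still yield the
        planted call at min_seed = 20."""
        ins = [(4321, "+", 0.5), (7777, "-", 0.5)]
        fq, _ = syn.make_junction_reads(
            small_reference, ins, tmp_path / "r.fq",
            n_reads=500, error_rate=0.01, seed=3,
        )
        res = ev.call_insertion_sites(
            fq, syn.DEFAULT_TN_END, small_reference, min_seed=20
        )
        good = res.unambiguous()
        assert set(zip(good["position_bp"], good["strand"])) == {
            (4321, "+"), (7777, "-"),
        }
        assert good["support"].sum() >= 0.95 * 500

    def test_pure_transposon_read_skipped(self, small_reference):
        reads = [syn.DEFAULT_TN_END * 5]
        res = ev.call_insertion_sites(reads, syn.DEFAULT_TN_END, small_reference)
        assert len(res.calls) == 0
        assert res.skipped_short_flank == 1

    def test_read_without_transposon_skipped(self, small_reference):
        res = ev.call_insertion_sites(
            ["ACGT" * 30], syn.DEFAULT_TN_END, small_reference
        )
        assert res.skipped_no_transposon == 1

    def test_ambiguous_flank_flagged(self, tmp_path):
        # a reference with an exact 60 bp repeat at two positions
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), 2000))
        repeat = "".join(rng.choice(list("ACGT"), 60))
        ref = seq[:500] + repeat + seq[500:1500] + repeat + seq[1500:]
        read = syn.DEFAULT_TN_END + repeat
        res = ev.call_insertion_sites([read], syn.DEFAULT_TN_END, ref)
        assert res.calls["ambiguous"].all()

    def test_min_seed_validation(self, small_reference):
        with pytest.raises(ParameterError):
            ev.call_insertion_sites([], "ACGT", small_reference, min_seed=20)


class TestInsertionDensity:
    def test_values(self):
        assert ev.insertion_density(70_000, 4_641_652) == pytest.approx(66.3, abs=0.05)
        assert ev.insertion_density(1, 999) == 999
        assert ev.insertion_density(999, 999) == 1
        with pytest.raises(ParameterError):
            ev.insertion_density(0, 100)
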