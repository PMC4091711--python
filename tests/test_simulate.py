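"""Simulator: steady-state ages, replication timing, positional program."""

import numpy as np
import pytest
from scipy import stats

from choreo.genome import default_genome_map, default_locus_panel
from choreo.io import write_cell_table
from choreo.simulate import (
    CellCycleModel,
    CohesionSpec,
    GrowthModel,
    LocusProgram,
    PositionProgram,
    daughter_frame_position,
    default_replication_model,
    position_at_age,
    preset_scenario,
    replication_time,
    sample_population,
    sister_homes,
    steady_state_age_cdf,
    steady_state_ages,
)


class TestSteadyStateAges:
    def test_matches_analytic_cdf(self):
        ages = steady_state_ages(100_000, 55.0, seed=1)
        stat, p = stats.kstest(ages, lambda a: steady_state_age_cdf(a, 55.0))
        assert stat < 0.01
        # median of the age distribution: tau * log2(4/3)
        assert np.median(ages) == pytest.approx(55.0 * np.log2(4 / 3), abs=0.3)

    def test_support(self):
        ages = steady_state_ages(10_000, 55.0, seed=2)
        assert ages.min() >= 0.0 and ages.max() < 55.0

    def test_errors(self):
        with pytest.raises(ValueError):
            steady_state_ages(10, -1.0, seed=0)
        with pytest.raises(ValueError):
            steady_state_ages(0, 55.0, seed=0)


class TestReplicationTime:
    def setup_method(self):
        self.gmap = default_genome_map()
        self.model = default_replication_model(self.gmap)
        self.panel = default_locus_panel()

    def test_ori_replicates_at_initiation(self):
        assert replication_time(self.panel["ori_I"], self.model, self.gmap) == pytest.approx(11.0)

    def test_ter_replicates_at_end_of_c_period(self):
        # arm end = B + C with forks sized to finish replication in C
        assert replication_time(self.panel["ter_I"], self.model, self.gmap) == pytest.approx(43.0)
        assert replication_time(self.panel["ter_II"], self.model, self.gmap) == pytest.approx(43.0)

    def test_chromosome_ii_initiation_delayed(self):
        assert self.model["II"].initiation_time_min > self.model["I"].initiation_time_min

    def test_ectopic_origin_zero_distance(self):
        gmap = default_genome_map(ectopic_ori_left_kb=651.0)
        model = default_replication_model(gmap)
        panel = default_locus_panel()
        # a locus at the ectopic origin position replicates at initiation
        from choreo.dataset import Locus

        at_ect = Locus("at_ect", "I", gmap["I"].ectopic_ori_kb, "left")
        assert replication_time(at_ect, model, gmap) == pytest.approx(11.0)
        # L3_I is 1 kb from the ectopic origin: nearly as early
        t = replication_time(panel["L3_I"], model, gmap)
        assert t == pytest.approx(11.0, abs=0.1)


class TestPositionProgram:
    def make_program(self, **kw):
        defaults = dict(h_pre=0.8, cohesion=CohesionSpec(mean_min=0.0), noise_sd=0.0)
        defaults.update(kw)
        return PositionProgram({"X": LocusProgram(**defaults)})

    def test_sister_home_mapping(self):
        assert sister_homes(0.8) == pytest.approx((0.1, 0.9))
        assert sister_homes(0.5) == pytest.approx((0.25, 0.75))

    def test_division_self_similarity(self):
        # the affine sister-home mapping returns h_pre in each daughter frame
        for h in (0.8, 0.5, 0.1, 0.55, 0.28, 0.7):
            new_home, old_home = sister_homes(h)
            assert daughter_frame_position(old_home, "old") == pytest.approx(h, abs=1e-12)
            assert daughter_frame_position(new_home, "new") == pytest.approx(h, abs=1e-12)

    def test_static_prelocation_and_split(self):
        prog = self.make_program()
        cycle = CellCycleModel()
        assert position_at_age("X", 5.0, prog, cycle, split_age_min=20.0) == (0.8,)
        # far past the split: sisters at their homes exactly
        pos = position_at_age("X", 50.0, prog, cycle, split_age_min=20.0)
        assert pos == pytest.approx((0.1, 0.9))

    def test_midcell_early_relocation(self):
        prog = self.make_program(h_pre=0.1, mode="midcell_early", midcell_age_min=47.0)
        cycle = CellCycleModel()
        assert position_at_age("X", 47.0, prog, cycle) == (0.5,)
        assert position_at_age("X", 50.0, prog, cycle) == (0.5,)
        assert position_at_age("X", 30.0, prog, cycle) == (0.1,)
        mid = position_at_age("X", 44.5, prog, cycle)[0]
        assert 0.1 < mid < 0.5


class TestCohesion:
    def test_dividing_fraction_calibration(self):
        # exponential delay tied to division: fraction of dividing-age cells
        # with two foci matches the configured target
        spec = CohesionSpec(dividing_fraction=0.10)
        mean = spec.resolve_mean(t_rep_min=43.0, tau_min=55.0)
        rng = np.random.default_rng(7)
        delays = rng.exponential(mean, 200_000)
        assert np.mean(delays <= 55.0 - 43.0) == pytest.approx(0.10, abs=0.01)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            CohesionSpec()
        with pytest.raises(ValueError):
            CohesionSpec(mean_min=1.0, dividing_fraction=0.5)


class TestSamplePopulation:
    def test_reproducible_bytes(self, tmp_path, wt_scenario):
        a, _ = sample_population(wt_scenario, 100, seed=42, channels=("ori_I",))
        b, _ = sample_population(wt_scenario, 100, seed=42, channels=("ori_I",))
        write_cell_table(a, tmp_path / "a.tsv")
        write_cell_table(b, tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_length_range_calibration(self, wt_full):
        ds, _ = wt_full
        lengths = np.array([c.length_um for c in ds.cells])
        assert np.mean((lengths >= 1.9) & (lengths <= 4.3)) >= 0.90

    def test_flip_probability(self, wt_scenario):
        _, truth = sample_population(wt_scenario, 10_000, seed=8, channels=("ori_I",))
        assert truth.frame["flipped"].mean() == pytest.approx(0.5, abs=0.02)

    def test_truth_consistent_with_dataset(self, wt_pair):
        ds, truth = wt_pair
        frame = truth.frame.set_index("cell_id")
        for cell in ds.cells[:50]:
            assert cell.count("ori_I") == frame.loc[cell.cell_id, "ori_I_count"]

    def test_positions_within_cell(self, wt_full):
        ds, _ = wt_full
        for cell in ds.cells:
            for xs in cell.foci.values():
                assert all(0 < x < cell.length_um for x in xs)


class TestPresets:
    def test_wt_homes(self, wt_scenario):
        prog = wt_scenario.program
        assert prog["ori_I"].h_pre == pytest.approx(0.8)
        assert prog["ter_I"].h_pre == pytest.approx(0.1)
        assert prog["ori_II"].h_pre == pytest.approx(0.55)
        assert prog["ter_II"].h_pre == pytest.approx(0.28)

    def test_delta_pars_ori_home(self):
        scen = preset_scenario("delta_parS")
        assert scen.program["ori_I"].h_pre == pytest.approx(0.7)
        assert scen.program["ori_I"].noise_sd > preset_scenario("WT").program["ori_I"].noise_sd
        # terminus region pinned
        assert scen.program["ter_I"].h_pre == pytest.approx(0.1)

    def test_pars_displacement_reanchors_ramp(self):
        wt = preset_scenario("WT")
        pd650 = preset_scenario("parS_displaced", parS_kb=650)
        # the locus nearest the displaced site (L3_I, at the site) gets the
        # most polar chromosome-I home; L2_I (170 kb away) is next
        homes = {n: pd650.program[n].h_pre for n in ("ori_I", "L1_I", "L2_I", "L3_I", "R2_I")}
        assert homes["L3_I"] == max(homes.values())
        assert homes["L2_I"] > homes["ori_I"]
        # ori_I (650 kb from the anchor) gets the home the WT ramp assigns at
        # that genomic distance from its anchor
        assert homes["ori_I"] == pytest.approx(wt.program["L3_I"].h_pre, abs=1e-9)
        # ter region pinned and unchanged
        assert pd650.program["ter_I"].h_pre == wt.program["ter_I"].h_pre

    def test_ectopic_preset_has_two_origins(self):
        scen = preset_scenario("delta_parS_ectopic_ori")
        assert len(scen.replication["I"].origins_kb) == 2
        assert scen.program["ori_I"].sister_home_shift > 0

    def test_unknown_preset(self):
        with pytest.raises(ValueError):
            preset_scenario("nope")


class TestModelInvariants:
    def test_cycle_periods_sum(self):
        with pytest.raises(ValueError):
            CellCycleModel(tau_min=55.0, B_min=10.0, C_min=32.0, D_min=12.0)

    def test_growth_doubling(self):
        g = GrowthModel()
        assert g.length_at_age(2.1, 55.0, 55.0) == pytest.approx(4.2)
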