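"""Orientation inference: pole preferences, scoring, template refinement."""

import numpy as np
import pytest

from choreo.orient import (
    classify_all_preferences,
    classify_pole_preference,
    orient_cells,
    orient_dataset,
    refine_orientation,
    PolePreference,
)

from conftest import flip_all, make_cell, make_dataset


def dividing_cells_with(focus_fracs, n=25, length=4.0, channel="ori_I"):
    cells = []
    for i in range(n):
        cells.append(
            make_cell(f"d{i}", length, {channel: [f * length for f in focus_fracs]})
        )
    # short cells so the 90th-percentile threshold selects the long ones
    for i in range(n * 9):
        cells.append(make_cell(f"s{i}", 2.0, {}))
    return make_dataset(cells, channels=(channel,))


class TestClassifyPolePreference:
    def test_septum_proximal_is_new_pole(self):
        ds = dividing_cells_with([0.48])
        pref = classify_pole_preference(ds, "ori_I")
        assert pref.preference == "new_pole"

    def test_pole_proximal_is_old_pole(self):
        ds = dividing_cells_with([0.05, 0.95])
        pref = classify_pole_preference(ds, "ori_I")
        assert pref.preference == "old_pole"

    def test_equidistant_tie_breaks_old_pole(self):
        # at 0.25 L the septum and the nearest pole are equally far
        ds = dividing_cells_with([0.25])
        pref = classify_pole_preference(ds, "ori_I")
        assert pref.preference == "old_pole"

    def test_too_few_dividing_cells(self, caplog):
        ds = dividing_cells_with([0.05], n=5)
        with caplog.at_level("WARNING"):
            pref = classify_pole_preference(ds, "ori_I")
        assert pref.preference == "ambiguous"

    def test_simulated_wt_preferences(self, wt_pair):
        ds, _ = wt_pair
        prefs = classify_all_preferences(ds)
        assert prefs["ori_I"].preference == "old_pole"
        assert prefs["ter_I"].preference == "new_pole"


class TestOrientCells:
    prefs = {"ori_I": PolePreference("ori_I", "old_pole", margin=0.5, n_cells=100)}

    def test_old_pole_focus_not_flipped(self):
        ds = make_dataset([make_cell("a", 2.0, {"ori_I": [1.6]})], channels=("ori_I",))
        out = orient_cells(ds, self.prefs)
        cell = out.cells[0]
        assert cell.orientation == "oriented" and not cell.polarity_flip
        assert cell.relative_positions("ori_I")[0] == pytest.approx(0.8)

    def test_stored_flip_recovered(self):
        ds = make_dataset([make_cell("a", 2.0, {"ori_I": [0.4]})], channels=("ori_I",))
        out = orient_cells(ds, self.prefs)
        cell = out.cells[0]
        assert cell.orientation == "oriented" and cell.polarity_flip
        assert cell.relative_positions("ori_I")[0] == pytest.approx(0.8)

    def test_symmetric_cell_is_ambiguous(self):
        ds = make_dataset([make_cell("a", 2.0, {"ori_I": [0.2, 1.8]})], channels=("ori_I",))
        out = orient_cells(ds, self.prefs)
        assert out.cells[0].orientation == "ambiguous"

    def test_all_ambiguous_preferences_flag(self):
        ds = make_dataset([make_cell("a", 2.0, {"ori_I": [1.6]})], channels=("ori_I",))
        out = orient_cells(ds, {"ori_I": PolePreference("ori_I", "ambiguous", 0.0)})
        assert "orientation_error" in out.meta
        assert out.cells[0].orientation == "unoriented"

    def test_input_not_mutated(self, wt_pair):
        ds, _ = wt_pair
        prefs = classify_all_preferences(ds)
        before = ds.cells[0].foci["ori_I"]
        orient_cells(ds, prefs)
        assert ds.cells[0].foci["ori_I"] == before
        assert ds.cells[0].orientation == "unoriented"


class TestSimulatedRecovery:
    def accuracy(self, oriented, truth):
        flip = truth.frame.set_index("cell_id")["flipped"]
        ok = tot = 0
        for c in oriented.cells:
            if c.orientation == "oriented":
                tot += 1
                ok += c.polarity_flip == bool(flip[c.cell_id])
        return ok / tot, tot

    def test_wt_orientation_recovery(self, wt_pair, wt_pair_oriented):
        _, truth = wt_pair
        acc, n = self.accuracy(wt_pair_oriented, truth)
        assert acc >= 0.95
        amb = sum(1 for c in wt_pair_oriented.cells if c.orientation == "ambiguous")
        assert amb / len(wt_pair_oriented.cells) <= 0.15

    def test_orientation_invariant_to_stored_axis(self, wt_pair):
        ds, _ = wt_pair
        a = orient_dataset(ds)
        b = orient_dataset(flip_all(ds))
        for ca, cb in zip(a.cells, b.cells):
            assert ca.orientation == cb.orientation
            if ca.orientation == "oriented":
                for ch in ("ori_I", "ter_I"):
                    assert np.allclose(
                        sorted(ca.relative_positions(ch)),
                        sorted(cb.relative_positions(ch)),
                        atol=1e-9,
                    )


class TestRefineOrientation:
    def test_template_match_orients_cell(self, wt_pair_oriented):
        # plant an ambiguous cell whose ter focus matches the newborn profile
        ds = wt_pair_oriented.copy()
        cell = make_cell("planted", 2.1, {"ter_I": [0.25]}, orientation="ambiguous")
        ds.cells.append(cell)
        out = refine_orientation(ds)
        planted = out.cells[-1]
        assert planted.orientation == "oriented" and not planted.polarity_flip

    def test_exact_tie_stays_ambiguous(self, wt_pair_oriented):
        ds = wt_pair_oriented.copy()
        # perfectly symmetric foci: flipped and unflipped deviations are equal
        cell = make_cell("tie", 2.1, {"ori_I": [1.05]}, orientation="ambiguous")
        ds.cells.append(cell)
        out = refine_orientation(ds)
        assert out.cells[-1].orientation == "ambiguous"

    def test_rescued_cells_match_ground_truth(self, wt_pair, wt_pair_oriented):
        # knock out the orientation of a labelled subset of cells with a
        # polar single ter focus; the template pass must re-orient nearly all
        # of them in agreement with the generating orientation
        _, truth = wt_pair
        ds = wt_pair_oriented.copy()
        knocked = set()
        for i, cell in enumerate(ds.cells):
            rel = cell.relative_positions("ter_I")
            if (
                cell.orientation == "oriented"
                and len(rel) == 1
                and abs(rel[0] - 0.5) >= 0.2
                and i % 3 == 0
            ):
                cell.orientation = "ambiguous"
                knocked.add(cell.cell_id)
        assert len(knocked) >= 100
        refined = refine_orientation(ds)
        flip = truth.frame.set_index("cell_id")["flipped"]
        rescued = [
            c for c in refined.cells if c.cell_id in knocked and c.orientation == "oriented"
        ]
        assert len(rescued) >= 0.8 * len(knocked)
        correct = sum(c.polarity_flip == bool(flip[c.cell_id]) for c in rescued)
        assert correct / len(rescued) >= 0.95

    def test_midcell_foci_never_inform_rescue(self, wt_pair_oriented):
        # a cell whose only focus sits at midcell carries no axis
        # information and must stay ambiguous whatever the templates say
        ds = wt_pair_oriented.copy()
        cell = make_cell("noinfo", 3.8, {"ter_I": [0.45 * 3.8]}, orientation="ambiguous")
        ds.cells.append(cell)
        out = refine_orientation(ds)
        assert out.cells[-1].orientation == "ambiguous"
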