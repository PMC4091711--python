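"""Cell-axis orientation from dual-label pole preferences.

Snapshot images carry no pole identity, but loci have stereotyped homes on
the new→old pole axis.  Orientation proceeds in three steps:

1. :func:`classify_pole_preference` decides, per channel, whether the locus
   lives near the new pole or the old pole, from dividing cells only: a
   locus closer to the septum than to the poles in dividing cells is a
   new-pole locus (it will sit near the new pole of the daughters).
2. :func:`orient_cells` scores each cell by a weighted sum of per-channel
   displacements from midcell, signed by the pole preference, and flips the
   stored axis when the score is negative.  Cells whose score is within an
   ambiguity tolerance of zero stay unoriented: after sister loci have
   segregated to spatially symmetric homes a cell may carry no orientation
   signal at all.
3. :func:`refine_orientation` is a template pass that tries to rescue
   ambiguous cells against the length-binned position profiles of the
   oriented population, assigning an orientation only when one direction
   fits the templates by a clear margin.

Duplication-frequency and distance statistics never require orientation;
only position trajectories consume it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .choreography import SizeBinnedProfile, bin_edge, bin_index, position_profile
from .dataset import CellRecord, StrainDataset

logger = logging.getLogger(__name__)

DEFAULT_DIVIDING_PERCENTILE = 90.0
DEFAULT_MIN_DIVIDING_CELLS = 20
DEFAULT_MARGIN_THRESHOLD = 0.1
DEFAULT_AMBIGUITY_TOLERANCE = 0.05
DEFAULT_TEMPLATE_GAP = 0.1
DEFAULT_MIN_POLAR = 0.15


@dataclass(frozen=True)
class PolePreference:
    """Population-level pole call for one channel."""

    channel: str
    preference: str  # old_pole | new_pole | ambiguous
    margin: float
    n_cells: int = 0

    @property
    def sign(self) -> int:
        """+1 for old-pole loci, -1 for new-pole loci (0 when ambiguous)."""
        return {"old_pole": 1, "new_pole": -1}.get(self.preference, 0)


def dividing_length_threshold(
    ds: StrainDataset, percentile: float = DEFAULT_DIVIDING_PERCENTILE
) -> float:
    """Length cut for "dividing cells": the top length decile by default."""
    lengths = [ds.binned_length(c) for c in ds.cells]
    return float(np.percentile(lengths, percentile))


def classify_pole_preference(
    ds: StrainDataset,
    channel: str,
    dividing_length_threshold_um: float | None = None,
    min_cells: int = DEFAULT_MIN_DIVIDING_CELLS,
    margin_threshold: float = DEFAULT_MARGIN_THRESHOLD,
) -> PolePreference:
    """Call a channel's pole preference from dividing cells.

    Per qualifying cell (1 or 2 foci) the mean focus distance to the septum
    (|x - L/2|) is compared with the mean distance to the nearest pole; the
    cell votes new-pole when the septum is closer (old-pole on the exact
    tie).  The preference is the majority vote with margin
    |vote fraction - 0.5|; below ``margin_threshold`` (or with fewer than
    ``min_cells`` voters) the call is ambiguous.
    """
    if dividing_length_threshold_um is None:
        dividing_length_threshold_um = dividing_length_threshold(ds)
    votes_new = 0
    votes_old = 0
    for cell in ds.cells:
        if ds.binned_length(cell) < dividing_length_threshold_um:
            continue
        xs = cell.foci.get(channel, ())
        if len(xs) not in (1, 2):
            continue
        L = cell.length_um
        d_sept = np.mean([abs(x - L / 2.0) for x in xs])
        d_pole = np.mean([min(x, L - x) for x in xs])
        if d_sept < d_pole:
            votes_new += 1
        else:
            votes_old += 1  # fixed tie-break: old pole
    n = votes_new + votes_old
    if n < min_cells:
        logger.warning(
            "channel %s: only %d dividing cells (need %d); preference ambiguous",
            channel,
            n,
            min_cells,
        )
        return PolePreference(channel=channel, preference="ambiguous", margin=0.0, n_cells=n)
    frac_new = votes_new / n
    margin = abs(frac_new - 0.5)
    if margin < margin_threshold:
        return PolePreference(channel=channel, preference="ambiguous", margin=margin, n_cells=n)
    preference = "new_pole" if frac_new > 0.5 else "old_pole"
    return PolePreference(channel=channel, preference=preference, margin=margin, n_cells=n)


def classify_all_preferences(
    ds: StrainDataset, dividing_length_threshold_um: float | None = None
) -> dict[str, PolePreference]:
    if dividing_length_threshold_um is None:
        dividing_length_threshold_um = dividing_length_threshold(ds)
    return {
        ch: classify_pole_preference(ds, ch, dividing_length_threshold_um)
        for ch in ds.channels
    }


def _orientation_score(
    cell: CellRecord, preferences: dict[str, PolePreference]
) -> float | None:
    """Weighted relative displacement score; None when no channel informs."""
    num = 0.0
    wsum = 0.0
    for ch, pref in preferences.items():
        if pref.sign == 0:
            continue
        xs = cell.foci.get(ch, ())
        if len(xs) not in (1, 2):
            continue
        mean_rel = float(np.mean(xs)) / cell.length_um
        num += pref.margin * pref.sign * (mean_rel - 0.5)
        wsum += pref.margin
    if wsum == 0.0:
        return None
    return num / wsum


def orient_cells(
    ds: StrainDataset,
    preferences: dict[str, PolePreference],
    ambiguity_tolerance: float = DEFAULT_AMBIGUITY_TOLERANCE,
) -> StrainDataset:
    """Orient every cell's axis so relative position 0 is the new pole.

    The per-cell score S averages, over channels with a non-ambiguous
    preference, margin-weighted signed displacements of the mean focus
    position from midcell (old-pole channels count positive displacement
    towards the stored far pole).  S < 0 flips the axis; |S| below the
    tolerance (in relative-position units) marks the cell ambiguous (fixed
    tie-break: S = 0 is not flipped).  Returns a new dataset; the input is
    untouched.
    """
    out = ds.copy()
    if all(p.sign == 0 for p in preferences.values()):
        out.meta["orientation_error"] = "all pole preferences ambiguous"
        logger.error("orientation aborted: all pole preferences ambiguous")
        return out
    n_flip = n_amb = 0
    for cell in out.cells:
        score = _orientation_score(cell, preferences)
        if score is None or abs(score) < ambiguity_tolerance:
            cell.orientation = "ambiguous"
            n_amb += 1
            continue
        if score < 0:
            flipped = cell.flipped()
            cell.foci = flipped.foci
            cell.polarity_flip = not cell.polarity_flip
            n_flip += 1
        cell.orientation = "oriented"
    out.meta["orientation"] = {
        "n_cells": len(out.cells),
        "n_flipped": n_flip,
        "n_ambiguous": n_amb,
        "ambiguity_tolerance": ambiguity_tolerance,
    }
    return out


def _template_deviations(
    cell: CellRecord,
    binned_length: float,
    profiles: dict[str, SizeBinnedProfile],
    min_polar: float = DEFAULT_MIN_POLAR,
) -> tuple[float, float] | None:
    """(unflipped, flipped) summed |deviation| from profile medians.

    Only channels whose focus count matches the dominant type of the cell's
    length interval contribute, and only when every focus of the channel
    sits at least ``min_polar`` away from midcell — foci near midcell carry
    no axis information, whatever the window template says (the window
    median mixes cells at different relocation stages).  None when nothing
    contributes.
    """
    dev_u = dev_f = 0.0
    used = 0
    for ch, profile in profiles.items():
        if profile.table.empty:
            continue
        k = bin_index(binned_length, profile.interval_width_um)
        edge = bin_edge(k, profile.interval_width_um)
        if edge not in profile.table.index:
            continue
        row = profile.table.loc[edge]
        xs = sorted(cell.relative_positions(ch))
        if any(abs(x - 0.5) < min_polar for x in xs):
            continue
        if row["dominant_type"] == "one" and len(xs) == 1 and not np.isnan(row["med_1"]):
            dev_u += abs(xs[0] - row["med_1"])
            dev_f += abs((1.0 - xs[0]) - row["med_1"])
            used += 1
        elif row["dominant_type"] == "two" and len(xs) == 2 and not np.isnan(row["med_lo"]):
            lo_f, hi_f = 1.0 - xs[1], 1.0 - xs[0]
            dev_u += abs(xs[0] - row["med_lo"]) + abs(xs[1] - row["med_hi"])
            dev_f += abs(lo_f - row["med_lo"]) + abs(hi_f - row["med_hi"])
            used += 1
    if used == 0:
        return None
    return dev_u, dev_f


def refine_orientation(
    ds: StrainDataset,
    profiles: dict[str, SizeBinnedProfile] | None = None,
    max_iter: int = 3,
    min_gap: float = DEFAULT_TEMPLATE_GAP,
) -> StrainDataset:
    """Template pass: rescue ambiguous cells against position profiles.

    Each ambiguous cell is compared, unflipped and flipped, with the profile
    medians of its length interval; it is oriented in the direction with the
    smaller summed absolute deviation, but only when the two deviations
    differ by more than ``min_gap`` (~2x the focus noise scale) — exact and
    near ties stay ambiguous, since a spatially symmetric cell carries no
    orientation information.  Profiles are recomputed from the growing
    oriented set and the pass iterates to a fixed point or ``max_iter``.
    """
    out = ds.copy()
    for _ in range(max_iter):
        current = profiles if profiles is not None else {
            ch: position_profile(out, ch) for ch in out.channels
        }
        profiles = None  # recompute from the updated dataset on later passes
        changed = 0
        for cell in out.cells:
            if cell.orientation != "ambiguous":
                continue
            devs = _template_deviations(cell, out.binned_length(cell), current)
            if devs is None:
                continue
            dev_u, dev_f = devs
            if abs(dev_u - dev_f) <= min_gap:
                continue
            if dev_f < dev_u:
                flipped = cell.flipped()
                cell.foci = flipped.foci
                cell.polarity_flip = not cell.polarity_flip
            cell.orientation = "oriented"
            changed += 1
        if changed == 0:
            break
    n_amb = sum(1 for c in out.cells if c.orientation == "ambiguous")
    out.meta.setdefault("orientation", {})
    out.meta["orientation"]["n_ambiguous"] = n_amb
    return out


def orient_dataset(
    ds: StrainDataset,
    ambiguity_tolerance: float = DEFAULT_AMBIGUITY_TOLERANCE,
    refine: bool = True,
) -> StrainDataset:
    """Convenience wrapper: classify preferences, score, then refine."""
    prefs = classify_all_preferences(ds)
    oriented = orient_cells(ds, prefs, ambiguity_tolerance)
    if refine and "orientation_error" not in oriented.meta:
        oriented = refine_orientation(oriented)
    return oriented
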