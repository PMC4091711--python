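"""Per-pole "most polar locus" statistic.

In dividing cells where two competing loci are both duplicated with one
sister of each in each cell half, each pole is scored by which locus sits
closer to it.  The statistic is computed per pole on the stored axis (both
poles of every qualifying cell are scored), so it is orientation-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .dataset import StrainDataset
from .orient import dividing_length_threshold

logger = logging.getLogger(__name__)

DEFAULT_TIE_TOLERANCE = 0.01  # in units of cell length


@dataclass(frozen=True)
class PolarityCount:
    """Per-pole tallies for a locus pair (A vs B)."""

    pair: str
    n_poles: int
    n_a_most_polar: int
    n_b_most_polar: int
    n_ties: int
    n_poles_skipped: int = 0
    n_cells_scored: int = 0

    def __post_init__(self) -> None:
        if self.n_a_most_polar + self.n_b_most_polar + self.n_ties != self.n_poles:
            raise ValueError("pole tallies do not sum to n_poles")

    @property
    def proportion_a(self) -> float:
        decided = self.n_a_most_polar + self.n_b_most_polar
        if decided == 0:
            return float("nan")
        return self.n_a_most_polar / decided


def per_pole_most_polar(
    ds: StrainDataset,
    channel_a: str,
    channel_b: str,
    dividing_length_threshold_um: float | None = None,
    tie_tolerance: float = DEFAULT_TIE_TOLERANCE,
) -> PolarityCount:
    """Tally which locus is most polar at each pole of dividing cells.

    Qualifying cells are at least as long as the dividing threshold (top
    length decile by default) with exactly two foci in each channel.  Cells
    are split at midcell (a focus exactly at midcell goes to the lower
    half, flagged in the log); a pole is scored only when its half contains
    exactly one focus of each channel.  Distances within
    ``tie_tolerance * L`` of each other count as ties.
    """
    for ch in (channel_a, channel_b):
        if ch not in ds.channels:
            raise KeyError(f"channel {ch!r} not in dataset")
    if dividing_length_threshold_um is None:
        dividing_length_threshold_um = dividing_length_threshold(ds)

    n_a = n_b = n_tie = n_skip = n_cells = 0
    n_midcell = 0
    for cell in ds.cells:
        if ds.binned_length(cell) < dividing_length_threshold_um:
            continue
        xa = cell.foci.get(channel_a, ())
        xb = cell.foci.get(channel_b, ())
        if len(xa) != 2 or len(xb) != 2:
            continue
        L = cell.length_um
        half = np.round(L / 2.0 / L, 9)
        rel_a = np.round(np.asarray(xa) / L, 9)
        rel_b = np.round(np.asarray(xb) / L, 9)
        n_midcell += int(np.sum(rel_a == half) + np.sum(rel_b == half))
        cell_scored = False
        for pole in ("lower", "upper"):
            if pole == "lower":
                in_half_a = rel_a <= half
                in_half_b = rel_b <= half
                d_a, d_b = rel_a, rel_b
            else:
                in_half_a = rel_a > half
                in_half_b = rel_b > half
                d_a, d_b = 1.0 - rel_a, 1.0 - rel_b
            if in_half_a.sum() != 1 or in_half_b.sum() != 1:
                n_skip += 1
                continue
            da = float(d_a[in_half_a][0])
            db = float(d_b[in_half_b][0])
            if abs(da - db) <= tie_tolerance:
                n_tie += 1
            elif da < db:
                n_a += 1
            else:
                n_b += 1
            cell_scored = True
        n_cells += int(cell_scored)
    if n_midcell:
        logger.info("%d foci exactly at midcell assigned to the lower half", n_midcell)
    if n_skip:
        logger.info("%d poles skipped (half-cell without one focus of each locus)", n_skip)
    return PolarityCount(
        pair=f"{channel_a}:{channel_b}",
        n_poles=n_a + n_b + n_tie,
        n_a_most_polar=n_a,
        n_b_most_polar=n_b,
        n_ties=n_tie,
        n_poles_skipped=n_skip,
        n_cells_scored=n_cells,
    )


def polarity_report(counts: PolarityCount, n_target: int = 100) -> dict:
    """Proportion with Wilson 95% interval; warns on thin pole counts."""
    decided = counts.n_a_most_polar + counts.n_b_most_polar
    if counts.n_poles == 0:
        return {
            "pair": counts.pair,
            "error": "no poles scored",
            "n_poles": 0,
        }
    low, high = proportion_confint(counts.n_a_most_polar, decided, alpha=0.05, method="wilson") if decided else (float("nan"),) * 2
    report = {
        "pair": counts.pair,
        "n_poles": counts.n_poles,
        "n_cells_scored": counts.n_cells_scored,
        "n_ties": counts.n_ties,
        "proportion_a": counts.proportion_a,
        "wilson_95ci": [float(low), float(high)],
    }
    if counts.n_poles < 2 * n_target:
        report["warning"] = (
            f"only {counts.n_poles} poles scored (target {2 * n_target})"
        )
        logger.warning(report["warning"])
    return report
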