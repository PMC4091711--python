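"""Inter-locus and sister-locus relative distance summaries.

Distances are one-dimensional axial separations divided by the measured
cell length, so they are invariant under the stored axis direction and
never require orientation.  Summaries report the 5th/25th/50th/75th/95th
percentiles.  Relative distances are rounded to 1e-9 (far below any
physical localisation precision) before summarising, which makes the
statistics bit-identical under axis flips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .choreography import (
    DEFAULT_INTERVAL_UM,
    DEFAULT_MIN_CELLS,
    DEFAULT_WINDOW_UM,
    _window_masks,
)
from .dataset import StrainDataset

PERCENTILES = (5, 25, 50, 75, 95)
DEFAULT_SISTER_MIN_LENGTH_UM = 3.4


def _round_rel(values: np.ndarray) -> np.ndarray:
    return np.round(values, 9)


@dataclass(frozen=True)
class DistanceSummary:
    """Percentile summary of relative distances for one pair spec."""

    pair: str
    n_cells: int
    p5: float
    p25: float
    median: float
    p75: float
    p95: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def _summarise(pair: str, distances: np.ndarray) -> DistanceSummary:
    if distances.size == 0:
        raise ValueError(f"no qualifying cells for {pair}")
    p5, p25, p50, p75, p95 = np.percentile(distances, PERCENTILES)
    return DistanceSummary(
        pair=pair,
        n_cells=int(distances.size),
        p5=float(p5),
        p25=float(p25),
        median=float(p50),
        p75=float(p75),
        p95=float(p95),
    )


def _single_focus_distances(
    ds: StrainDataset, channel_a: str, channel_b: str
) -> tuple[np.ndarray, np.ndarray]:
    """(relative |xA - xB|, binned lengths) over cells with exactly one
    focus of each locus."""
    dist = []
    lengths = []
    for cell in ds.cells:
        xa = cell.foci.get(channel_a, ())
        xb = cell.foci.get(channel_b, ())
        if len(xa) == 1 and len(xb) == 1:
            dist.append(abs(xa[0] - xb[0]) / cell.length_um)
            lengths.append(ds.binned_length(cell))
    return _round_rel(np.asarray(dist)), np.asarray(lengths)


def interlocus_distance(
    ds: StrainDataset, channel_a: str, channel_b: str
) -> DistanceSummary:
    """Relative distance between two loci in single-focus cells."""
    for ch in (channel_a, channel_b):
        if ch not in ds.channels:
            raise KeyError(f"channel {ch!r} not in dataset")
    dist, _ = _single_focus_distances(ds, channel_a, channel_b)
    return _summarise(f"{channel_a}:{channel_b}", dist)


def sister_distance(
    ds: StrainDataset,
    channel: str,
    min_length_um: float = DEFAULT_SISTER_MIN_LENGTH_UM,
) -> DistanceSummary:
    """Relative distance between separated sisters in long cells.

    Only cells strictly longer than ``min_length_um`` with exactly two foci
    qualify; by then sisters of most loci have reached their homes, so the
    median recovers the spatial separation of the sister home positions.
    """
    if channel not in ds.channels:
        raise KeyError(f"channel {channel!r} not in dataset")
    dist = []
    for cell in ds.cells:
        xs = cell.foci.get(channel, ())
        if len(xs) == 2 and ds.binned_length(cell) > min_length_um:
            dist.append(abs(xs[0] - xs[1]) / cell.length_um)
    return _summarise(f"{channel}:sisters", _round_rel(np.asarray(dist)))


def distance_vs_elongation(
    ds: StrainDataset,
    channel_a: str,
    channel_b: str,
    interval_width: float = DEFAULT_INTERVAL_UM,
    window_um: float = DEFAULT_WINDOW_UM,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> pd.DataFrame:
    """Windowed inter-locus distance summaries (same windowing as profiles).

    One row per populated interval; windows with fewer than ``min_cells``
    qualifying cells are masked.
    """
    for ch in (channel_a, channel_b):
        if ch not in ds.channels:
            raise KeyError(f"channel {ch!r} not in dataset")
    dist, lengths = _single_focus_distances(ds, channel_a, channel_b)
    if dist.size == 0:
        raise ValueError("no qualifying single-focus cells")
    rows = {}
    for edge, mask in _window_masks(lengths, interval_width, window_um):
        row = {"center": edge + interval_width / 2.0, "n_cells": int(mask.sum())}
        if mask.sum() >= min_cells:
            p5, p25, p50, p75, p95 = np.percentile(dist[mask], PERCENTILES)
            row.update(p5=p5, p25=p25, median=p50, p75=p75, p95=p95)
        else:
            row.update(p5=np.nan, p25=np.nan, median=np.nan, p75=np.nan, p95=np.nan)
        rows[edge] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.attrs["pair"] = f"{channel_a}:{channel_b}"
    return out
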