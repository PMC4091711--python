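"""Length-binned, sliding-window locus statistics.

Cells are classified by length into half-open 0.1 µm intervals labelled by
their lower edge; each interval's statistics pool the cells of a centred
0.3 µm sliding window [c - 0.15, c + 0.15), c the interval centre.  Per
window we report the duplication frequency (fraction of 1-/2-focus cells
showing two foci) and, for the dominant cell type, the median and quartiles
of the relative focus positions (two ordered sister series when the
two-focus type dominates).  Duplication frequencies are orientation-free;
position profiles require oriented cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .dataset import GenomeMap, Locus, StrainDataset

DEFAULT_INTERVAL_UM = 0.1
DEFAULT_WINDOW_UM = 0.3
DEFAULT_MIN_CELLS = 10
_EDGE_EPS = 1e-9  # guards floor() against float representation of lengths


def bin_index(length_um: float, interval_width: float = DEFAULT_INTERVAL_UM) -> int:
    """Index of the half-open interval [k*w, (k+1)*w) containing a length."""
    if length_um <= 0:
        raise ValueError("length must be positive")
    return int(math.floor(length_um / interval_width + _EDGE_EPS))


def bin_edge(index: int, interval_width: float = DEFAULT_INTERVAL_UM) -> float:
    """Lower-edge label of an interval index."""
    return round(index * interval_width, 10)


@dataclass
class SizeBinnedProfile:
    """Sliding-window duplication and position statistics for one channel.

    ``table`` is indexed by interval lower edge with columns: ``center``,
    ``n_cells``, ``n_1focus``, ``n_2focus``, ``duplication_fraction``,
    ``dominant_type`` ('one'/'two'), single-focus percentiles ``med_1``,
    ``p25_1``, ``p75_1`` and per-rank sister percentiles ``med_lo`` ...
    ``p75_hi``.  Windows with fewer than ``min_cells`` scoreable cells are
    masked (NaN).
    """

    channel: str
    interval_width_um: float = DEFAULT_INTERVAL_UM
    window_um: float = DEFAULT_WINDOW_UM
    min_cells: int = DEFAULT_MIN_CELLS
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.insert(0, "interval", out.index)
        return out.reset_index(drop=True)

    @property
    def duplication_curve(self) -> pd.Series:
        return self.table["duplication_fraction"]


def window_reach(interval_width: float, window_um: float) -> int:
    """Number of whole intervals the window extends on each side of its centre.

    The centred window [c - w/2, c + w/2) around an interval centre c covers
    exactly ``2r + 1`` whole intervals when the window is an odd multiple of
    the interval width (the default 0.3 µm window = three 0.1 µm intervals).
    Tying membership to whole intervals keeps the sliding statistics exactly
    reproducible by per-interval recounting.
    """
    m = window_um / interval_width
    if abs(m - round(m)) > 1e-6 or round(m) % 2 != 1:
        raise ValueError("window must be an odd multiple of the interval width")
    return (int(round(m)) - 1) // 2


def _window_masks(
    lengths: np.ndarray, interval_width: float, window_um: float
) -> list[tuple[float, np.ndarray]]:
    """(interval edge, boolean member mask) for every candidate window."""
    reach = window_reach(interval_width, window_um)
    idx = np.array([bin_index(float(x), interval_width) for x in lengths])
    lo, hi = int(idx.min()), int(idx.max())
    out = []
    for k in range(lo, hi + 1):
        edge = bin_edge(k, interval_width)
        out.append((edge, np.abs(idx - k) <= reach))
    return out


def duplication_frequency(
    ds: StrainDataset,
    channel: str,
    interval_width: float = DEFAULT_INTERVAL_UM,
    window_um: float = DEFAULT_WINDOW_UM,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> pd.Series:
    """Per-interval sliding-window duplication fraction (orientation-free).

    Fraction = 2-focus / (1-focus + 2-focus) over the window; intervals
    with fewer than ``min_cells`` scoreable cells are NaN.
    """
    if channel not in ds.channels:
        raise KeyError(f"channel {channel!r} not in dataset")
    frame = ds.channel_frame(channel)
    scoreable = frame[frame["count"].isin([1, 2])]
    if scoreable.empty:
        return pd.Series(dtype=float, name=channel)
    lengths = scoreable["binned_length_um"].to_numpy()
    counts = scoreable["count"].to_numpy()
    data = {}
    for edge, mask in _window_masks(lengths, interval_width, window_um):
        n1 = int(np.sum(counts[mask] == 1))
        n2 = int(np.sum(counts[mask] == 2))
        data[edge] = n2 / (n1 + n2) if n1 + n2 >= min_cells else np.nan
    return pd.Series(data, name=channel)


def position_profile(
    ds: StrainDataset,
    channel: str,
    interval_width: float = DEFAULT_INTERVAL_UM,
    window_um: float = DEFAULT_WINDOW_UM,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> SizeBinnedProfile:
    """Dominant-cell-type position percentiles per sliding window.

    Only oriented cells contribute (relative positions are on the new→old
    pole axis); the dominant type is 'two' when the duplication fraction is
    >= 0.5.  Percentiles are linear-interpolation (type 7) medians and
    quartiles; for the two-focus type the sisters are ordered per cell and
    summarised per rank.
    """
    if channel not in ds.channels:
        raise KeyError(f"channel {channel!r} not in dataset")
    frame = ds.channel_frame(channel)
    frame = frame[(frame["orientation"] == "oriented") & frame["count"].isin([1, 2])]
    profile = SizeBinnedProfile(
        channel=channel,
        interval_width_um=interval_width,
        window_um=window_um,
        min_cells=min_cells,
    )
    if frame.empty:
        profile.table = pd.DataFrame()
        return profile

    lengths = frame["binned_length_um"].to_numpy()
    counts = frame["count"].to_numpy()
    rel1 = frame["rel1"].to_numpy()
    rel2 = frame["rel2"].to_numpy()
    lo_rank = np.fmin(rel1, rel2)
    hi_rank = np.fmax(rel1, rel2)

    rows = {}
    for edge, mask in _window_masks(lengths, interval_width, window_um):
        c = counts[mask]
        n1, n2 = int(np.sum(c == 1)), int(np.sum(c == 2))
        row = {
            "center": edge + interval_width / 2.0,
            "n_cells": int(mask.sum()),
            "n_1focus": n1,
            "n_2focus": n2,
            "duplication_fraction": np.nan,
            "dominant_type": "",
            "med_1": np.nan,
            "p25_1": np.nan,
            "p75_1": np.nan,
            "med_lo": np.nan,
            "p25_lo": np.nan,
            "p75_lo": np.nan,
            "med_hi": np.nan,
            "p25_hi": np.nan,
            "p75_hi": np.nan,
        }
        if n1 + n2 >= min_cells:
            frac = n2 / (n1 + n2)
            row["duplication_fraction"] = frac
            if frac >= 0.5:
                row["dominant_type"] = "two"
                sel = mask & (counts == 2)
                lo, hi = lo_rank[sel], hi_rank[sel]
                row["p25_lo"], row["med_lo"], row["p75_lo"] = np.percentile(lo, [25, 50, 75])
                row["p25_hi"], row["med_hi"], row["p75_hi"] = np.percentile(hi, [25, 50, 75])
            else:
                row["dominant_type"] = "one"
                sel = mask & (counts == 1)
                xs = rel1[sel]
                row["p25_1"], row["med_1"], row["p75_1"] = np.percentile(xs, [25, 50, 75])
        rows[edge] = row
    profile.table = pd.DataFrame.from_dict(rows, orient="index")
    return profile


def first_crossing(
    curve: pd.Series | SizeBinnedProfile, threshold: float = 0.5
) -> float | None:
    """Smallest interval (lower edge) whose fraction reaches the threshold."""
    if isinstance(curve, SizeBinnedProfile):
        curve = curve.duplication_curve
    for edge in sorted(curve.index):
        frac = curve[edge]
        if not np.isnan(frac) and frac >= threshold:
            return float(edge)
    return None


@dataclass
class DuplicationRanking:
    """Loci ordered by their first duplication-threshold crossing."""

    order: list[str]
    crossings: dict[str, float]
    ties: list[tuple[str, str]]
    uncrossed: list[str]


def rank_loci_by_duplication(
    curves: Mapping[str, pd.Series],
    loci: Mapping[str, Locus],
    genome_map: GenomeMap,
    threshold: float = 0.5,
) -> DuplicationRanking:
    """Sort loci by first-crossing interval; ties broken by distance from ori.

    Loci whose curve never reaches the threshold are excluded from the order
    and listed in ``uncrossed``.  Pairs crossing in the same interval are
    flagged as ties (their relative duplication timing is unresolved at this
    binning resolution).
    """
    crossings: dict[str, float] = {}
    uncrossed: list[str] = []
    for name, curve in curves.items():
        c = first_crossing(curve, threshold)
        if c is None:
            uncrossed.append(name)
        else:
            crossings[name] = c
    if len(crossings) < 2:
        raise ValueError("need at least two loci with threshold crossings")

    def ori_distance(name: str) -> float:
        return genome_map.locus_path(loci[name])[1]

    order = sorted(crossings, key=lambda nm: (crossings[nm], ori_distance(nm)))
    ties = [
        (a, b)
        for i, a in enumerate(order)
        for b in order[i + 1 :]
        if crossings[a] == crossings[b]
    ]
    return DuplicationRanking(order=order, crossings=crossings, ties=ties, uncrossed=sorted(uncrossed))
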