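"""Core data containers for single-cell focus tables.

A snapshot dataset is a collection of segmented cells, each carrying its
long-axis length and, per fluorescent channel, the axial coordinates of the
detected foci.  Axial coordinates are one-dimensional positions along the
cell long axis, in micrometres, measured from an arbitrary reference pole
until the cell has been oriented.  Once oriented, relative positions run
from 0 (new pole) to 1 (old pole).

Cells may show 0, 1, 2 or more foci per channel.  The analysis modules only
interpret the 1- and 2-focus states; cells with more foci in a channel are
retained in the dataset but excluded from that channel's statistics.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CHROMOSOMES = ("I", "II")
ARMS = ("left", "right", "ori", "ter")
ORIENTATIONS = ("unoriented", "oriented", "ambiguous")


@dataclass(frozen=True)
class Locus:
    """A tagged genomic locus on one of the two chromosomes.

    ``map_position_kb`` is the coordinate on the circular map (origin of the
    coordinate system at the chromosome's ``ori``); ``arm`` records which
    replichore the locus sits on (``ori``/``ter`` for the endpoints).
    """

    name: str
    chromosome: str
    map_position_kb: float
    arm: str

    def __post_init__(self) -> None:
        if self.chromosome not in CHROMOSOMES:
            raise ValueError(f"unknown chromosome {self.chromosome!r}")
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.map_position_kb < 0:
            raise ValueError("map_position_kb must be >= 0")


@dataclass(frozen=True)
class ChromosomeMap:
    """Replication landmarks of one circular chromosome (coordinates in kb)."""

    length_kb: float
    ori_kb: float
    dif_kb: float
    parS_kb: tuple[float, ...] = ()
    matS_domain_kb: tuple[float, float] | None = None
    ectopic_ori_kb: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.ori_kb < self.length_kb:
            raise ValueError("ori_kb outside chromosome")
        if not 0 <= self.dif_kb < self.length_kb:
            raise ValueError("dif_kb outside chromosome")
        if self.matS_domain_kb is not None:
            lo, hi = self.matS_domain_kb
            if not (lo <= self.dif_kb <= hi):
                raise ValueError("matS domain must contain dif")

    @property
    def origins_kb(self) -> tuple[float, ...]:
        if self.ectopic_ori_kb is None:
            return (self.ori_kb,)
        return (self.ori_kb, self.ectopic_ori_kb)

    def arc_distance(self, a_kb: float, b_kb: float) -> float:
        """Shortest genomic distance between two positions on the circle."""
        d = abs(a_kb - b_kb) % self.length_kb
        return min(d, self.length_kb - d)

    def path_from_ori(self, position_kb: float) -> tuple[str, float]:
        """Replichore and path distance from ori for a map position.

        The two arms are delimited by ori and dif; the "right" arm is the one
        traversed clockwise (increasing coordinate) from ori.
        """
        off = (position_kb - self.ori_kb) % self.length_kb
        dif_off = (self.dif_kb - self.ori_kb) % self.length_kb
        if off <= dif_off:
            return ("right", off)
        return ("left", self.length_kb - off)

    @property
    def arm_lengths_kb(self) -> tuple[float, float]:
        dif_off = (self.dif_kb - self.ori_kb) % self.length_kb
        return (self.length_kb - dif_off, dif_off)  # (left, right)


@dataclass(frozen=True)
class GenomeMap:
    """Per-chromosome replication landmarks."""

    chromosomes: Mapping[str, ChromosomeMap]

    def __getitem__(self, chromosome: str) -> ChromosomeMap:
        return self.chromosomes[chromosome]

    def locus_path(self, locus: Locus) -> tuple[str, float]:
        return self[locus.chromosome].path_from_ori(locus.map_position_kb)


@dataclass(frozen=True)
class FocusObservation:
    """A single detected focus in one channel of one cell."""

    channel: str
    axial_position_um: float


@dataclass
class CellRecord:
    """One segmented cell: length plus per-channel focus coordinates.

    ``foci`` maps channel name to a tuple of axial positions (µm).
    ``polarity_flip`` records whether the stored axis was reversed during
    orientation so that position 0 is the new pole.
    """

    cell_id: str
    length_um: float
    foci: dict[str, tuple[float, ...]] = field(default_factory=dict)
    orientation: str = "unoriented"
    polarity_flip: bool = False

    def __post_init__(self) -> None:
        if self.length_um <= 0:
            raise ValueError("length_um must be positive")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        for ch, xs in self.foci.items():
            for x in xs:
                if not 0 <= x <= self.length_um:
                    raise ValueError(
                        f"focus at {x} µm outside cell of length {self.length_um} µm"
                        f" (channel {ch})"
                    )

    def count(self, channel: str) -> int:
        return len(self.foci.get(channel, ()))

    def relative_positions(self, channel: str) -> tuple[float, ...]:
        return tuple(x / self.length_um for x in self.foci.get(channel, ()))

    def flipped(self) -> "CellRecord":
        """A copy of the cell with the stored axis reversed."""
        return CellRecord(
            cell_id=self.cell_id,
            length_um=self.length_um,
            foci={
                ch: tuple(self.length_um - x for x in xs)
                for ch, xs in self.foci.items()
            },
            orientation=self.orientation,
            polarity_flip=not self.polarity_flip,
        )


@dataclass
class StrainDataset:
    """A strain's cell collection plus channel→locus mapping.

    ``length_offset_um`` is the cross-strain realignment shift; it affects
    only the length used for binning (see :mod:`choreo.realign`), never the
    relative positions, which stay ratios against the measured length.
    """

    strain_id: str
    channel_locus_map: dict[str, Locus]
    cells: list[CellRecord]
    length_offset_um: float = 0.0
    scenario: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def channels(self) -> tuple[str, ...]:
        seen: dict[str, None] = dict.fromkeys(self.channel_locus_map)
        for cell in self.cells:
            seen.update(dict.fromkeys(cell.foci))
        return tuple(seen)

    def __len__(self) -> int:
        return len(self.cells)

    def binned_length(self, cell: CellRecord) -> float:
        return cell.length_um + self.length_offset_um

    def copy(self) -> "StrainDataset":
        return copy.deepcopy(self)

    def channel_frame(self, channel: str, max_foci: int = 2) -> pd.DataFrame:
        """Tabular view of one channel: lengths, counts, focus coordinates.

        Focus columns ``x1..x{max_foci}`` hold µm coordinates in stored-axis
        order (NaN where absent); ``rel1..`` the corresponding ratios to the
        measured length.  ``count`` is the true focus count, which may exceed
        ``max_foci``.
        """
        rows = []
        for cell in self.cells:
            xs = cell.foci.get(channel, ())
            row = {
                "cell_id": cell.cell_id,
                "length_um": cell.length_um,
                "binned_length_um": self.binned_length(cell),
                "count": len(xs),
                "orientation": cell.orientation,
            }
            for i in range(max_foci):
                x = xs[i] if i < len(xs) else np.nan
                row[f"x{i + 1}"] = x
                row[f"rel{i + 1}"] = x / cell.length_um if i < len(xs) else np.nan
            rows.append(row)
        frame = pd.DataFrame(
            rows,
            columns=["cell_id", "length_um", "binned_length_um", "count", "orientation"]
            + [c for i in range(max_foci) for c in (f"x{i + 1}", f"rel{i + 1}")],
        )
        return frame


@dataclass
class ValidationReport:
    """Report-only summary of a dataset; validation never mutates data."""

    strain_id: str
    n_cells: int
    length_range_um: tuple[float, float] | None
    focus_count_histogram: dict[str, dict[int, int]]
    unmapped_channels: tuple[str, ...]
    length_offset_um: float

    def to_dict(self) -> dict:
        return {
            "strain_id": self.strain_id,
            "n_cells": self.n_cells,
            "length_range_um": list(self.length_range_um)
            if self.length_range_um
            else None,
            "focus_count_histogram": {
                ch: {str(k): v for k, v in hist.items()}
                for ch, hist in self.focus_count_histogram.items()
            },
            "unmapped_channels": list(self.unmapped_channels),
            "length_offset_um": self.length_offset_um,
        }


def validate_dataset(ds: StrainDataset) -> ValidationReport:
    """Count cells, per-channel focus-count histograms and length range.

    Channels that appear in cells but are missing from the channel→locus map
    are flagged in ``unmapped_channels``.
    """
    hist: dict[str, dict[int, int]] = {}
    unmapped: list[str] = []
    for cell in ds.cells:
        for ch, xs in cell.foci.items():
            hist.setdefault(ch, {})
            hist[ch][len(xs)] = hist[ch].get(len(xs), 0) + 1
            if ch not in ds.channel_locus_map and ch not in unmapped:
                unmapped.append(ch)
    lengths = [c.length_um for c in ds.cells]
    return ValidationReport(
        strain_id=ds.strain_id,
        n_cells=len(ds.cells),
        length_range_um=(min(lengths), max(lengths)) if lengths else None,
        focus_count_histogram=hist,
        unmapped_channels=tuple(unmapped),
        length_offset_um=ds.length_offset_um,
    )


def build_dataset(
    strain_id: str,
    channel_locus_map: Mapping[str, Locus],
    cells: Iterable[CellRecord],
    scenario: str = "",
) -> StrainDataset:
    return StrainDataset(
        strain_id=strain_id,
        channel_locus_map=dict(channel_locus_map),
        cells=list(cells),
        scenario=scenario,
    )
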