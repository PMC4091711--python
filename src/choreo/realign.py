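"""Cross-strain cell-length realignment.

Strains grown side by side can have slightly different length
distributions; their length axes are realigned using a shared anchor: the
first interval where a reference locus's duplication frequency reaches a
threshold, or where a terminus locus is recruited to midcell.  The offset
(a whole number of intervals) is added to the target strain's lengths for
binning purposes only — relative positions always stay ratios against the
measured length of each cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .choreography import (
    DEFAULT_INTERVAL_UM,
    DEFAULT_MIN_CELLS,
    DEFAULT_WINDOW_UM,
    duplication_frequency,
    first_crossing,
)
from .dataset import StrainDataset

ANCHOR_KINDS = ("duplication_threshold", "midcell_recruitment")
DEFAULT_MIDCELL_BAND = 0.1
DEFAULT_MIDCELL_PERSISTENCE = 2


class AnchorNotReachedError(RuntimeError):
    """The anchor condition is never met in one of the datasets."""


@dataclass(frozen=True)
class AnchorSpec:
    """Anchor definition: channel plus anchor type.

    ``duplication_threshold`` anchors on the first interval whose
    duplication fraction reaches ``threshold``; ``midcell_recruitment`` on
    the first interval where the single-focus population sits at midcell
    (median folded distance from midcell within ``band_halfwidth``) for at
    least ``persistence`` consecutive intervals.
    """

    channel: str
    kind: str = "duplication_threshold"
    threshold: float = 0.5
    band_halfwidth: float = DEFAULT_MIDCELL_BAND
    persistence: int = DEFAULT_MIDCELL_PERSISTENCE

    def __post_init__(self) -> None:
        if self.kind not in ANCHOR_KINDS:
            raise ValueError(f"unknown anchor kind {self.kind!r}")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")


@dataclass(frozen=True)
class AlignmentOffset:
    reference_id: str
    target_id: str
    anchor: AnchorSpec
    offset_um: float


def _midcell_anchor_interval(
    ds: StrainDataset,
    anchor: AnchorSpec,
    interval_width: float,
    window_um: float,
    min_cells: int,
) -> float | None:
    """First interval of a persistent midcell run of the single-focus type.

    Works on the folded distance from midcell |x/L - 1/2| of single-focus
    cells, so no orientation is required and the anchor is flip-invariant.
    """
    frame = ds.channel_frame(anchor.channel)
    singles = frame[frame["count"] == 1]
    if singles.empty:
        return None
    from .choreography import _window_masks  # shared windowing

    lengths = singles["binned_length_um"].to_numpy()
    folded = np.abs(singles["rel1"].to_numpy() - 0.5)
    run: list[float] = []
    for edge, mask in _window_masks(lengths, interval_width, window_um):
        if mask.sum() < min_cells:
            # unpopulated windows break the persistence run
            run = []
            continue
        if float(np.median(folded[mask])) <= anchor.band_halfwidth:
            run.append(edge)
            if len(run) >= anchor.persistence:
                return run[0]
        else:
            run = []
    return None


def anchor_interval(
    ds: StrainDataset,
    anchor: AnchorSpec,
    interval_width: float = DEFAULT_INTERVAL_UM,
    window_um: float = DEFAULT_WINDOW_UM,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> float:
    """Interval (lower edge) where the anchor condition is first met."""
    if anchor.channel not in ds.channels:
        raise KeyError(f"anchor channel {anchor.channel!r} not in dataset {ds.strain_id}")
    if anchor.kind == "duplication_threshold":
        curve = duplication_frequency(ds, anchor.channel, interval_width, window_um, min_cells)
        edge = first_crossing(curve, anchor.threshold)
    else:
        edge = _midcell_anchor_interval(ds, anchor, interval_width, window_um, min_cells)
    if edge is None:
        raise AnchorNotReachedError(
            f"anchor {anchor.kind}({anchor.channel}) never reached in {ds.strain_id}"
        )
    return edge


def compute_offset(
    ref_ds: StrainDataset,
    target_ds: StrainDataset,
    anchor: AnchorSpec,
    interval_width: float = DEFAULT_INTERVAL_UM,
    window_um: float = DEFAULT_WINDOW_UM,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> AlignmentOffset:
    """Offset (added to target lengths) aligning the two anchor intervals.

    The offset is the difference of the anchor interval positions, hence a
    whole multiple of the interval width.
    """
    ref_edge = anchor_interval(ref_ds, anchor, interval_width, window_um, min_cells)
    tgt_edge = anchor_interval(target_ds, anchor, interval_width, window_um, min_cells)
    offset = round(ref_edge - tgt_edge, 10)
    return AlignmentOffset(
        reference_id=ref_ds.strain_id,
        target_id=target_ds.strain_id,
        anchor=anchor,
        offset_um=offset,
    )


def apply_offset(ds: StrainDataset, offset: AlignmentOffset | float) -> StrainDataset:
    """Shift the dataset's binning lengths by the offset.

    The shift is a population-comparison device, not a cell-geometry claim:
    it accumulates into ``length_offset_um`` and affects only binned
    lengths; measured lengths, focus coordinates and relative positions are
    untouched.
    """
    shift = offset.offset_um if isinstance(offset, AlignmentOffset) else float(offset)
    out = ds.copy()
    out.length_offset_um = round(out.length_offset_um + shift, 10)
    min_binned = min(out.binned_length(c) for c in out.cells)
    if min_binned <= 0:
        raise ValueError(f"offset {shift} µm produces non-positive binned lengths")
    return out
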