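"""Readers and writers for focus tables, configs and result tables.

Focus tables are delimited text (tab or comma, auto-detected) with one row
per cell.  The default schema has a ``cell_id`` column, a ``length_um``
column and, per channel, focus-coordinate columns ``{channel}_x1``,
``{channel}_x2``, ... in µm (blank where the focus is absent).  Column
names are configurable through :class:`TableSchema` since no standard
format exists for focus tables.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import CellRecord, Locus, StrainDataset
from .genome import default_locus_panel

logger = logging.getLogger(__name__)

_FOCUS_COL = re.compile(r"^(?P<channel>.+)_x(?P<rank>\d+)$")


@dataclass
class TableSchema:
    """Column naming of a focus table.

    When ``channel_columns`` is empty, channels are auto-detected from
    columns matching ``{channel}_x{rank}``.
    """

    length_column: str = "length_um"
    cell_id_column: str = "cell_id"
    channel_columns: dict[str, list[str]] = field(default_factory=dict)


def _detect_channels(columns: list[str], schema: TableSchema) -> dict[str, list[str]]:
    if schema.channel_columns:
        return schema.channel_columns
    found: dict[str, list[tuple[int, str]]] = {}
    for col in columns:
        m = _FOCUS_COL.match(col)
        if m and col not in (schema.length_column, schema.cell_id_column):
            found.setdefault(m["channel"], []).append((int(m["rank"]), col))
    return {ch: [c for _, c in sorted(cols)] for ch, cols in found.items()}


def read_cell_table(
    path: str | Path,
    schema: TableSchema | None = None,
    channel_locus_map: dict[str, Locus] | None = None,
    strain_id: str | None = None,
    scenario: str = "",
) -> StrainDataset:
    """Read a delimited focus table into a validated dataset.

    Rows with a missing or non-numeric length, or with a focus coordinate
    outside the cell, are rejected (counted and logged).  Empty focus cells
    yield focus count 0.  When ``channel_locus_map`` is omitted, channels
    matching the default locus panel are mapped automatically.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    schema = schema or TableSchema()
    table = pd.read_csv(path, sep=None, engine="python")
    if schema.length_column not in table.columns:
        raise ValueError(f"missing mandatory column {schema.length_column!r}")
    channels = _detect_channels(list(table.columns), schema)

    panel = default_locus_panel()
    if channel_locus_map is None:
        channel_locus_map = {ch: panel[ch] for ch in channels if ch in panel}

    cells: list[CellRecord] = []
    n_bad_length = n_bad_focus = 0
    for i, row in table.iterrows():
        length = pd.to_numeric(row[schema.length_column], errors="coerce")
        if pd.isna(length) or length <= 0:
            n_bad_length += 1
            continue
        cell_id = (
            str(row[schema.cell_id_column])
            if schema.cell_id_column in table.columns
            else f"row{i}"
        )
        foci: dict[str, tuple[float, ...]] = {}
        ok = True
        for ch, cols in channels.items():
            xs = [
                float(v)
                for v in (pd.to_numeric(row[c], errors="coerce") for c in cols if c in row)
                if not pd.isna(v)
            ]
            if any(x < 0 or x > length for x in xs):
                ok = False
                break
            if xs:
                foci[ch] = tuple(xs)
        if not ok:
            n_bad_focus += 1
            continue
        cells.append(CellRecord(cell_id=cell_id, length_um=float(length), foci=foci))
    if n_bad_length:
        logger.warning("%s: rejected %d rows with missing/invalid length", path.name, n_bad_length)
    if n_bad_focus:
        logger.warning("%s: rejected %d rows with foci outside the cell", path.name, n_bad_focus)
    return StrainDataset(
        strain_id=strain_id or path.stem,
        channel_locus_map=channel_locus_map,
        cells=cells,
        scenario=scenario,
        meta={"n_rejected_length": n_bad_length, "n_rejected_focus": n_bad_focus},
    )


def write_cell_table(ds: StrainDataset, path: str | Path, sep: str = "\t") -> None:
    """Write a dataset as a focus table (stable column order, round-trips)."""
    channels = sorted(ds.channels)
    max_foci = {ch: max((c.count(ch) for c in ds.cells), default=1) or 1 for ch in channels}
    rows = []
    for cell in ds.cells:
        row: dict = {"cell_id": cell.cell_id, "length_um": cell.length_um}
        for ch in channels:
            xs = cell.foci.get(ch, ())
            for i in range(max_foci[ch]):
                row[f"{ch}_x{i + 1}"] = xs[i] if i < len(xs) else np.nan
        rows.append(row)
    cols = ["cell_id", "length_um"] + [
        f"{ch}_x{i + 1}" for ch in channels for i in range(max_foci[ch])
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=sep, index=False, float_format="%.10g")


def write_profile_table(obj, path: str | Path, sep: str = "\t") -> None:
    """Write any profile/summary object exposing ``to_frame`` (or a frame)."""
    frame = obj.to_frame() if hasattr(obj, "to_frame") else pd.DataFrame(obj)
    frame.to_csv(path, sep=sep, index=False, float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def resolve_channel_locus_map(channels: dict) -> dict[str, Locus]:
    """Resolve a config's channel section to Locus objects.

    Each value is either the name of a default-panel locus or a mapping
    with ``name``/``chromosome``/``map_position_kb``/``arm``.
    """
    panel = default_locus_panel()
    out: dict[str, Locus] = {}
    for ch, spec in channels.items():
        if isinstance(spec, str):
            out[ch] = panel[spec]
        else:
            out[ch] = Locus(**spec)
    return out


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
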