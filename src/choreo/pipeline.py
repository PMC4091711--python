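"""End-to-end pipeline driver and fixture generation.

A pipeline run takes a configuration (dict, or YAML/JSON file) describing
one or more strains — each either simulated from a preset scenario or read
from a focus table — and executes: simulate → orient → choreography →
realign (multi-strain, via a shared anchor) → distances → polarity.  It
writes one TSV per statistic plus a single machine-readable JSON summary
recording every threshold used, per-stage cell counts, anchors, offsets,
crossings and polarity proportions.

Example configuration::

    seed: 42
    interval_width_um: 0.1
    window_um: 0.3
    strains:
      - id: wt
        simulate: {scenario: WT, n: 800, channels: [ori_I, L3_I, ter_I]}
    anchor: {channel: L3_I, kind: duplication_threshold, threshold: 0.5}
    distance_pairs: [[ori_I, ter_I]]
    sister_channels: [ori_I]
    polarity_pairs: [[ori_I, L3_I]]
"""

from __future__ import annotations

import logging
from pathlib import Path

from . import __version__
from .choreography import duplication_frequency, first_crossing, position_profile
from .dataset import StrainDataset, validate_dataset
from .distances import interlocus_distance, sister_distance
from .io import load_config, read_cell_table, write_cell_table, write_json, write_profile_table
from .orient import orient_dataset
from .polarity import per_pole_most_polar, polarity_report
from .realign import AnchorSpec, apply_offset, compute_offset
from .simulate import preset_scenario, sample_population

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage and strain."""


def _stage(stage: str, strain: str | None = None):
    tag = f"[{stage}{':' + strain if strain else ''}]"

    def fail(exc: Exception) -> PipelineError:
        return PipelineError(f"{tag} {exc}")

    return fail


def _load_strain(entry: dict, seed: int, outdir: Path) -> StrainDataset:
    sid = entry["id"]
    fail = _stage("load", sid)
    try:
        if "simulate" in entry:
            sim = entry["simulate"]
            scenario = preset_scenario(sim["scenario"], parS_kb=sim.get("parS_kb"))
            ds, _truth = sample_population(
                scenario,
                n=int(sim.get("n", 800)),
                seed=int(sim.get("seed", seed)),
                channels=sim.get("channels"),
            )
            ds.strain_id = sid
            write_cell_table(ds, outdir / f"{sid}_cells.tsv")
            return ds
        ds = read_cell_table(entry["table"], strain_id=sid)
        return ds
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage-tagged re-raise
        raise fail(exc) from exc


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Execute the configured pipeline and return the run summary.

    Outputs (cell tables, profile TSVs, ``summary.json``) are written under
    ``outdir`` (or the config's ``outdir``).  Any stage error aborts with a
    stage-tagged message.  The summary is reproducible: the same config and
    seed give identical outputs.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir or config.get("outdir", "choreo_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    interval = float(config.get("interval_width_um", 0.1))
    window = float(config.get("window_um", 0.3))
    min_cells = int(config.get("min_cells", 10))
    summary: dict = {
        "version": __version__,
        "seed": seed,
        "thresholds": {
            "interval_width_um": interval,
            "window_um": window,
            "min_cells": min_cells,
            "dominant_type_threshold": 0.5,
            "ambiguity_tolerance": float(config.get("ambiguity_tolerance", 0.05)),
            "sister_min_length_um": float(config.get("sister_min_length_um", 3.4)),
        },
        "strains": {},
    }

    datasets: dict[str, StrainDataset] = {}
    for entry in config["strains"]:
        sid = entry["id"]
        ds = _load_strain(entry, seed, outdir)
        datasets[sid] = ds
        summary["strains"][sid] = {"validation": validate_dataset(ds).to_dict()}

    # realign all strains to the first one
    strain_ids = list(datasets)
    if "anchor" in config and len(strain_ids) > 1:
        anchor = AnchorSpec(**config["anchor"])
        ref = datasets[strain_ids[0]]
        summary["anchor"] = {
            "channel": anchor.channel,
            "kind": anchor.kind,
            "threshold": anchor.threshold,
        }
        for sid in strain_ids[1:]:
            fail = _stage("realign", sid)
            try:
                off = compute_offset(ref, datasets[sid], anchor, interval, window, min_cells)
                datasets[sid] = apply_offset(datasets[sid], off)
                summary["strains"][sid]["length_offset_um"] = off.offset_um
            except Exception as exc:  # noqa: BLE001
                raise fail(exc) from exc

    for sid, ds in datasets.items():
        fail = _stage("orient", sid)
        try:
            oriented = orient_dataset(
                ds, ambiguity_tolerance=summary["thresholds"]["ambiguity_tolerance"]
            )
        except Exception as exc:  # noqa: BLE001
            raise fail(exc) from exc
        datasets[sid] = oriented
        summary["strains"][sid]["orientation"] = oriented.meta.get(
            "orientation", {"error": oriented.meta.get("orientation_error")}
        )

        fail = _stage("choreography", sid)
        try:
            crossings = {}
            for ch in oriented.channels:
                curve = duplication_frequency(oriented, ch, interval, window, min_cells)
                profile = position_profile(oriented, ch, interval, window, min_cells)
                write_profile_table(profile, outdir / f"{sid}_{ch}_profile.tsv")
                crossings[ch] = first_crossing(curve, 0.5)
            summary["strains"][sid]["first_crossing_50"] = crossings
        except Exception as exc:  # noqa: BLE001
            raise fail(exc) from exc

        fail = _stage("distances", sid)
        try:
            dist = {}
            for pair in config.get("distance_pairs", []):
                a, b = pair
                if a in oriented.channels and b in oriented.channels:
                    s = interlocus_distance(oriented, a, b)
                    dist[f"{a}:{b}"] = s.median
                    write_profile_table(s, outdir / f"{sid}_{a}_{b}_dist.tsv")
            for ch in config.get("sister_channels", []):
                if ch in oriented.channels:
                    s = sister_distance(
                        oriented, ch, summary["thresholds"]["sister_min_length_um"]
                    )
                    dist[f"{ch}:sisters"] = s.median
                    write_profile_table(s, outdir / f"{sid}_{ch}_sisters.tsv")
            summary["strains"][sid]["median_distances"] = dist
        except Exception as exc:  # noqa: BLE001
            raise fail(exc) from exc

        fail = _stage("polarity", sid)
        try:
            pol = {}
            for pair in config.get("polarity_pairs", []):
                a, b = pair
                if a in oriented.channels and b in oriented.channels:
                    counts = per_pole_most_polar(oriented, a, b)
                    pol[f"{a}:{b}"] = polarity_report(counts)
            summary["strains"][sid]["polarity"] = pol
        except Exception as exc:  # noqa: BLE001
            raise fail(exc) from exc

    write_json(summary, outdir / "summary.json")
    return summary


# ---------------------------------------------------------------------------
# Hand-constructed fixtures with documented expected outputs
# ---------------------------------------------------------------------------

def make_fixtures(outdir: str | Path) -> dict:
    """Write tiny hand-constructed focus tables with known statistics.

    Returns (and writes alongside, as ``expectations.json``) the expected
    values: duplication fractions, a distance, a polarity proportion and a
    realignment offset.  Used by the test suite as an end-to-end check.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # basic: 2.0-2.2 µm intervals with (1-focus, 2-focus) counts (3,0), (2,1),
    # (1,2) -> window fraction at the 2.1 interval = 3/9; ter at 0.25 L.
    lines = ["cell_id\tlength_um\tori_I_x1\tori_I_x2\tter_I_x1"]
    basic = [
        (2.05, [1.6], 0.5), (2.02, [1.7], 0.5), (2.08, [1.65], 0.52),
        (2.15, [1.7], 0.54), (2.12, [1.8], 0.53), (2.18, [0.4, 1.9], 0.55),
        (2.25, [1.9], 0.56), (2.22, [0.3, 2.0], 0.57), (2.28, [0.35, 2.05], 0.56),
    ]
    for i, (length, ori, ter_frac) in enumerate(basic):
        ori_cols = [f"{x:.6g}" for x in ori] + [""] * (2 - len(ori))
        lines.append(
            f"c{i}\t{length}\t" + "\t".join(ori_cols) + f"\t{ter_frac * length:.6g}"
        )
    (outdir / "fixture_basic.tsv").write_text("\n".join(lines) + "\n")

    # polarity: 2 dividing cells, ori always most polar at both poles.
    lines = ["cell_id\tlength_um\tori_I_x1\tori_I_x2\tL3_I_x1\tL3_I_x2"]
    lines.append("p0\t4.0\t0.2\t3.9\t0.9\t3.0")
    lines.append("p1\t4.0\t0.1\t3.8\t1.0\t2.9")
    # plus short cells so the dividing threshold (90th pct) selects the two
    for i in range(18):
        lines.append(f"s{i}\t2.0\t1.6\t\t1.0\t")
    (outdir / "fixture_polarity.tsv").write_text("\n".join(lines) + "\n")

    # realign pair: shifted copy; duplication 50% crossing shifts by 0.2 µm.
    def dup_rows(shift: float) -> list[str]:
        rows = []
        k = 0
        for edge, n1, n2 in [(2.0, 12, 0), (2.1, 12, 0), (2.2, 6, 6), (2.3, 0, 12), (2.4, 0, 12)]:
            for _ in range(n1):
                rows.append(f"r{k}\t{edge + 0.05 + shift:.6g}\t{0.8 * (edge + 0.05 + shift):.6g}\t")
                k += 1
            for _ in range(n2):
                L = edge + 0.05 + shift
                rows.append(f"r{k}\t{L:.6g}\t{0.25 * L:.6g}\t{0.75 * L:.6g}")
                k += 1
        return rows
    header = "cell_id\tlength_um\tL3_I_x1\tL3_I_x2"
    (outdir / "fixture_ref.tsv").write_text("\n".join([header] + dup_rows(0.0)) + "\n")
    (outdir / "fixture_shifted.tsv").write_text("\n".join([header] + dup_rows(0.2)) + "\n")

    expectations = {
        "fixture_basic": {
            "ori_I_window_2.1_fraction": 3 / 9,
            "ter_I_fraction_everywhere": 0.0,
            "note": "window at the 2.1 µm interval pools intervals 2.0/2.1/2.2 "
            "with (1-focus, 2-focus) counts (3,0)+(2,1)+(1,2) -> 3/9",
        },
        "fixture_polarity": {"ori_I_vs_L3_I_proportion": 1.0, "n_poles": 4},
        "fixture_realign": {"offset_um": -0.2, "anchor": "L3_I duplication >= 0.5"},
    }
    write_json(expectations, outdir / "expectations.json")
    return expectations
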