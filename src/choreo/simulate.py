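"""Steady-state snapshot population simulator with ground truth.

The simulator emulates snapshot microscopy of exponentially growing cells:

* cell ages drawn from the steady-state age distribution
  f(a) = (2 ln2 / tau) * 2**(-a/tau) on [0, tau);
* exponential single-cell growth, L(a) = Lb * 2**(a/tau), with the birth
  length Lb sampled per cell (newborns ~2.1 µm, dividing cells ~4.2 µm);
* a three-period cell cycle (B = pre-replication, C = replication,
  D = post-replication; defaults 11/32/12 min of a 55 min generation time)
  with bidirectional replication from ori at constant fork speed, and a
  delayed chromosome II initiation chosen so both chromosomes terminate
  together at the end of C;
* per-locus focus duplication when the cell age passes the locus replication
  time plus a sampled sister-cohesion delay;
* a longitudinal positional program: each locus holds a pre-duplication home
  position h (0 = new pole, 1 = old pole) and, after duplication, the two
  sisters travel to the homes 0.5 - h/2 (new-pole half) and 0.5 + h/2
  (old-pole half).  This affine mapping is the unique choice that makes the
  newborn pattern self-similar across divisions.  Terminus-region loci are
  instead recruited to midcell shortly before division and duplicate late;
* Gaussian positional noise and a random stored-axis flip with probability
  0.5 (snapshot images carry no pole identity; the true orientation is
  recorded in the ground truth).

Perturbation presets re-anchor the positional program (parS displacement),
shrink it towards midcell (parS deletion), or drive it by replication timing
with a second origin (ectopic oriC on the left arm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import CellRecord, GenomeMap, Locus, StrainDataset
from .genome import (
    ECTOPIC_ORI_LEFT_KB,
    TER_CLASS,
    default_genome_map,
    default_locus_panel,
)

PRESET_NAMES = ("WT", "parS_displaced", "delta_parS", "delta_parS_ectopic_ori")

# Relative positions are clamped away from the poles: foci are never detected
# exactly at a pole.
CLAMP = (0.02, 0.98)


@dataclass(frozen=True)
class CellCycleModel:
    """Generation time and the B/C/D period durations, in minutes."""

    tau_min: float = 55.0
    B_min: float = 11.0
    C_min: float = 32.0
    D_min: float = 12.0

    def __post_init__(self) -> None:
        if self.tau_min <= 0:
            raise ValueError("tau_min must be positive")
        if min(self.B_min, self.C_min, self.D_min) < 0:
            raise ValueError("periods must be non-negative")
        if not math.isclose(self.B_min + self.C_min + self.D_min, self.tau_min):
            raise ValueError("B + C + D must equal tau")


@dataclass(frozen=True)
class GrowthModel:
    """Exponential growth in length; division length is twice birth length."""

    birth_length_mean_um: float = 2.1
    birth_length_sd_um: float = 0.1
    growth_law: str = "exponential"

    def __post_init__(self) -> None:
        if self.birth_length_mean_um <= 0:
            raise ValueError("birth length must be positive")
        if self.growth_law != "exponential":
            raise ValueError("only exponential growth is supported")

    def length_at_age(self, birth_length_um: float, age_min: float, tau_min: float) -> float:
        return birth_length_um * 2.0 ** (age_min / tau_min)


@dataclass(frozen=True)
class ChromosomeReplication:
    """Initiation age, fork speed and active origins for one chromosome."""

    initiation_time_min: float
    fork_speed_kb_per_min: float
    origins_kb: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.fork_speed_kb_per_min <= 0:
            raise ValueError("fork speed must be positive")


@dataclass(frozen=True)
class ReplicationModel:
    chromosomes: Mapping[str, ChromosomeReplication]

    def __getitem__(self, chromosome: str) -> ChromosomeReplication:
        return self.chromosomes[chromosome]


@dataclass(frozen=True)
class CohesionSpec:
    """Post-replication sister-cohesion delay (exponential).

    Either an explicit mean, or a target fraction of dividing cells showing
    two foci; the latter ties the delay to division and is resolved to a
    mean via  m = -(tau - t_rep) / ln(1 - p).
    """

    mean_min: float | None = None
    dividing_fraction: float | None = None

    def __post_init__(self) -> None:
        if (self.mean_min is None) == (self.dividing_fraction is None):
            raise ValueError("specify exactly one of mean_min, dividing_fraction")
        if self.mean_min is not None and self.mean_min < 0:
            raise ValueError("cohesion mean must be >= 0")
        if self.dividing_fraction is not None and not 0 < self.dividing_fraction < 1:
            raise ValueError("dividing_fraction must be in (0, 1)")

    def resolve_mean(self, t_rep_min: float, tau_min: float) -> float:
        if self.mean_min is not None:
            return self.mean_min
        window = max(tau_min - t_rep_min, 0.0)
        return -window / math.log1p(-self.dividing_fraction)


@dataclass(frozen=True)
class LocusProgram:
    """Positional choreography of one locus.

    ``h_pre``: pre-duplication home position (0 = new pole, 1 = old pole).
    ``mode``: ``static`` (stay at home until duplication) or ``midcell_early``
    (linear relocation to midcell completed at ``midcell_age_min``).
    ``seg_transition_um``: elongation over which sisters travel to their new
    homes after the split.  ``sister_home_shift``: common offset applied to
    both sister homes (used for the asymmetric ori segregation with an
    ectopic origin).
    """

    h_pre: float
    mode: str = "static"
    midcell_age_min: float | None = None
    relocation_window_min: float = 5.0
    cohesion: CohesionSpec = field(default_factory=lambda: CohesionSpec(mean_min=3.0))
    seg_transition_um: float = 0.1
    noise_sd: float = 0.05
    sister_home_shift: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.h_pre < 1:
            raise ValueError("h_pre must be in (0, 1)")
        if self.mode not in ("static", "midcell_early"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "midcell_early" and self.midcell_age_min is None:
            raise ValueError("midcell_early mode requires midcell_age_min")
        if self.noise_sd < 0 or self.seg_transition_um <= 0:
            raise ValueError("invalid noise/transition parameters")


@dataclass(frozen=True)
class PositionProgram:
    loci: Mapping[str, LocusProgram]

    def __getitem__(self, name: str) -> LocusProgram:
        return self.loci[name]


@dataclass(frozen=True)
class Scenario:
    """A fully parameterised simulation condition."""

    name: str
    genome_map: GenomeMap
    cycle: CellCycleModel
    growth: GrowthModel
    replication: ReplicationModel
    program: PositionProgram
    panel: Mapping[str, Locus]
    channels: tuple[str, ...]
    shrink: float = 1.0


@dataclass
class GroundTruth:
    """Per-cell generating state: age, true orientation, noiseless positions.

    ``frame`` has one row per cell with columns ``age_min``,
    ``birth_length_um``, ``flipped`` and, per channel, ``{ch}_count``,
    ``{ch}_pos1``, ``{ch}_pos2`` (noiseless relative positions on the true
    axis, NaN where absent).
    """

    scenario: str
    frame: pd.DataFrame


def sister_homes(h_pre: float, shift: float = 0.0) -> tuple[float, float]:
    """Post-split sister home positions (new-pole sister, old-pole sister)."""
    return (0.5 - h_pre / 2.0 + shift, 0.5 + h_pre / 2.0 + shift)


def daughter_frame_position(position: float, half: str) -> float:
    """Map a mother-cell relative position into a daughter's 0–1 frame.

    ``half`` is which daughter: "old" inherits the mother's old-pole half
    [0.5, 1], "new" the other.  The mother's septum becomes the daughter's
    new pole; the mother's new pole becomes the "new" daughter's old pole.
    """
    if half == "old":
        return (position - 0.5) / 0.5
    if half == "new":
        return (0.5 - position) / 0.5
    raise ValueError(f"unknown half {half!r}")


def steady_state_ages(
    n: int, tau_min: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Sample cell ages from the steady-state exponential-growth distribution.

    Inverse-CDF sampling of F(a) = 2 (1 - 2**(-a/tau)) on [0, tau).
    """
    if tau_min <= 0:
        raise ValueError("tau_min must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    u = rng.random(n)
    return -tau_min * np.log2(1.0 - u / 2.0)


def steady_state_age_cdf(age_min: np.ndarray | float, tau_min: float):
    """Analytic CDF of the steady-state age distribution."""
    a = np.asarray(age_min, dtype=float)
    return 2.0 * (1.0 - 2.0 ** (-a / tau_min))


def replication_time(
    locus: Locus, replication_model: ReplicationModel, genome_map: GenomeMap
) -> float:
    """Cell age (min) at which a locus is replicated.

    Bidirectional replication from every active origin at constant fork
    speed; the locus is replicated by whichever fork arrives first:
    t = min over origins of (initiation age + arc distance / fork speed).
    """
    chrom_map = genome_map[locus.chromosome]
    model = replication_model[locus.chromosome]
    if not 0 <= locus.map_position_kb < chrom_map.length_kb:
        raise ValueError(f"locus {locus.name} outside chromosome")
    return min(
        model.initiation_time_min
        + chrom_map.arc_distance(locus.map_position_kb, origin)
        / model.fork_speed_kb_per_min
        for origin in model.origins_kb
    )


def position_at_age(
    locus: str | Locus,
    age_min: float,
    program: PositionProgram,
    cycle: CellCycleModel,
    *,
    split_age_min: float | None = None,
    birth_length_um: float = 2.1,
) -> tuple[float, ...]:
    """Noiseless relative position(s) of a locus at a given cell age.

    Before ``split_age_min`` (replication + cohesion) the locus shows one
    position: its home ``h_pre`` for static loci, or a linear relocation to
    0.5 completed at ``midcell_age_min`` for terminus-class loci.  After the
    split the two sisters interpolate linearly from the split position to
    their homes over ``seg_transition_um`` of cell elongation.
    """
    name = locus.name if isinstance(locus, Locus) else locus
    prog = program[name]
    tau = cycle.tau_min

    def single(a: float) -> float:
        if prog.mode == "static":
            return prog.h_pre
        end = prog.midcell_age_min
        start = end - prog.relocation_window_min
        if a >= end:
            return 0.5
        if a <= start:
            return prog.h_pre
        frac = (a - start) / (end - start)
        return prog.h_pre + frac * (0.5 - prog.h_pre)

    if split_age_min is None or age_min < split_age_min:
        return (single(age_min),)

    p0 = single(split_age_min)
    home_new, home_old = sister_homes(prog.h_pre, prog.sister_home_shift)
    length_now = birth_length_um * 2.0 ** (age_min / tau)
    length_split = birth_length_um * 2.0 ** (split_age_min / tau)
    frac = min(max((length_now - length_split) / prog.seg_transition_um, 0.0), 1.0)
    a_pos = p0 + frac * (home_new - p0)
    b_pos = p0 + frac * (home_old - p0)
    return (a_pos, b_pos) if a_pos <= b_pos else (b_pos, a_pos)


def focus_state(
    locus: Locus,
    age_min: float,
    scenario: Scenario,
    rng: np.random.Generator,
    *,
    birth_length_um: float | None = None,
) -> tuple[int, tuple[float, ...]]:
    """Sampled focus count and noisy relative positions for one cell/locus."""
    if birth_length_um is None:
        birth_length_um = scenario.growth.birth_length_mean_um
    t_rep = replication_time(locus, scenario.replication, scenario.genome_map)
    prog = scenario.program[locus.name]
    mean = prog.cohesion.resolve_mean(t_rep, scenario.cycle.tau_min)
    delay = rng.exponential(mean) if mean > 0 else 0.0
    t_split = t_rep + delay
    noiseless = position_at_age(
        locus.name,
        age_min,
        scenario.program,
        scenario.cycle,
        split_age_min=t_split,
        birth_length_um=birth_length_um,
    )
    if prog.noise_sd > 0:
        noisy = np.asarray(noiseless) + rng.normal(0.0, prog.noise_sd, len(noiseless))
    else:
        noisy = np.asarray(noiseless, dtype=float)
    noisy = np.clip(noisy, CLAMP[0], CLAMP[1])
    return len(noiseless), tuple(float(v) for v in np.sort(noisy))


def sample_population(
    scenario: Scenario,
    n: int,
    seed: int,
    channels: Sequence[str] | None = None,
) -> tuple[StrainDataset, GroundTruth]:
    """Simulate a snapshot population of n cells with ground truth.

    Each cell's stored axis is flipped with probability 0.5; the true
    orientation (and the noiseless true-axis positions) are recorded only in
    the :class:`GroundTruth`.  One master seed; per-cell substreams are
    spawned deterministically, so the same seed yields an identical dataset.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    chans = tuple(channels) if channels is not None else scenario.channels
    unknown = [c for c in chans if c not in scenario.panel]
    if unknown:
        raise ValueError(f"channels not in scenario panel: {unknown}")

    tau = scenario.cycle.tau_min
    growth = scenario.growth
    # per-locus constants
    t_rep = {
        c: replication_time(scenario.panel[c], scenario.replication, scenario.genome_map)
        for c in chans
    }
    cohesion_mean = {
        c: scenario.program[c].cohesion.resolve_mean(t_rep[c], tau) for c in chans
    }

    cell_seeds = np.random.SeedSequence(seed).spawn(n)
    cells: list[CellRecord] = []
    truth_rows: list[dict] = []
    for i, child in enumerate(cell_seeds):
        rng = np.random.default_rng(child)
        age = float(-tau * np.log2(1.0 - rng.random() / 2.0))
        lb = max(0.5, rng.normal(growth.birth_length_mean_um, growth.birth_length_sd_um))
        length = growth.length_at_age(lb, age, tau)
        flip = bool(rng.random() < 0.5)
        foci: dict[str, tuple[float, ...]] = {}
        row: dict = {
            "cell_id": f"cell{i:05d}",
            "age_min": age,
            "birth_length_um": lb,
            "flipped": flip,
        }
        for ch in chans:
            prog = scenario.program[ch]
            delay = rng.exponential(cohesion_mean[ch]) if cohesion_mean[ch] > 0 else 0.0
            t_split = t_rep[ch] + delay
            noiseless = position_at_age(
                ch,
                age,
                scenario.program,
                scenario.cycle,
                split_age_min=t_split,
                birth_length_um=lb,
            )
            noisy = np.asarray(noiseless, dtype=float)
            if prog.noise_sd > 0:
                noisy = noisy + rng.normal(0.0, prog.noise_sd, noisy.size)
            noisy = np.clip(noisy, CLAMP[0], CLAMP[1])
            stored_rel = 1.0 - noisy if flip else noisy
            foci[ch] = tuple(float(v) for v in np.sort(stored_rel * length))
            row[f"{ch}_count"] = len(noiseless)
            row[f"{ch}_pos1"] = noiseless[0]
            row[f"{ch}_pos2"] = noiseless[1] if len(noiseless) > 1 else np.nan
        cells.append(CellRecord(cell_id=row["cell_id"], length_um=length, foci=foci))
        truth_rows.append(row)

    ds = StrainDataset(
        strain_id=f"sim_{scenario.name}_seed{seed}",
        channel_locus_map={c: scenario.panel[c] for c in chans},
        cells=cells,
        scenario=scenario.name,
    )
    truth = GroundTruth(scenario=scenario.name, frame=pd.DataFrame(truth_rows))
    return ds, truth


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

# Fractions of dividing cells with two foci for the terminus-class loci.
DIVIDING_FRACTIONS = {"L5_I": 0.50, "R5_I": 0.40, "ter_I": 0.10, "ter_II": 0.35}
STANDARD_COHESION_MEAN_MIN = 3.0
TER_MIDCELL_AGE_MIN = 47.0
DELTA_PARS_SHRINK = 2.0 / 3.0  # pulls ori_I home from 0.8 to 0.7
DELTA_PARS_NOISE_SD = 0.08


def _wt_home(chromosome: str, path_frac: float) -> float:
    """WT longitudinal ramp: ori→ter homes 0.8→0.1 (chr I), 0.55→0.28 (chr II)."""
    if chromosome == "I":
        return 0.8 - 0.7 * path_frac
    return 0.55 - 0.27 * path_frac


def default_replication_model(
    genome_map: GenomeMap, cycle: CellCycleModel | None = None
) -> ReplicationModel:
    """Forks sized so chromosome I replicates in exactly the C period, and
    chromosome II initiation delayed so both chromosomes terminate together."""
    cycle = cycle or CellCycleModel()
    chr1, chr2 = genome_map["I"], genome_map["II"]
    arm1 = max(chr1.arm_lengths_kb)
    fork = arm1 / cycle.C_min
    arm2 = max(chr2.arm_lengths_kb)
    init2 = cycle.B_min + cycle.C_min - arm2 / fork
    if init2 < cycle.B_min:
        raise ValueError("chromosome II initiation earlier than chromosome I")
    return ReplicationModel(
        chromosomes={
            "I": ChromosomeReplication(cycle.B_min, fork, chr1.origins_kb),
            "II": ChromosomeReplication(init2, fork, chr2.origins_kb),
        }
    )


def _cohesion_for(name: str) -> CohesionSpec:
    if name in DIVIDING_FRACTIONS:
        return CohesionSpec(dividing_fraction=DIVIDING_FRACTIONS[name])
    return CohesionSpec(mean_min=STANDARD_COHESION_MEAN_MIN)


def _base_program_entry(name: str, h: float, noise_sd: float = 0.05) -> LocusProgram:
    if name in TER_CLASS:
        return LocusProgram(
            h_pre=h,
            mode="midcell_early",
            midcell_age_min=TER_MIDCELL_AGE_MIN,
            cohesion=_cohesion_for(name),
            noise_sd=0.05,  # ter positioning escapes the perturbations
        )
    return LocusProgram(h_pre=h, cohesion=_cohesion_for(name), noise_sd=noise_sd)


def _wt_program(genome_map: GenomeMap, panel: Mapping[str, Locus]) -> dict[str, LocusProgram]:
    prog = {}
    for name, locus in panel.items():
        chrom = genome_map[locus.chromosome]
        _, dist = chrom.path_from_ori(locus.map_position_kb)
        frac = dist / max(chrom.arm_lengths_kb)
        prog[name] = _base_program_entry(name, _wt_home(locus.chromosome, frac))
    return prog


def preset_scenario(name: str, parS_kb: float | None = None) -> Scenario:
    """Build a fully parameterised preset scenario.

    ``WT``: longitudinal ramp anchored at ori.  ``parS_displaced`` (requires
    ``parS_kb``, the left-arm path position of the displaced parS sites):
    the chromosome I ramp is re-anchored on genomic distance from the
    displaced site, terminus region pinned.  ``delta_parS``: homes shrunk
    towards midcell (ori home 0.7) with inflated noise.
    ``delta_parS_ectopic_ori``: two origins; chromosome I homes driven by
    replication time, with asymmetric ori sister homes.
    """
    cycle = CellCycleModel()
    growth = GrowthModel()
    panel = default_locus_panel()

    if name == "WT":
        gmap = default_genome_map()
        program = _wt_program(gmap, panel)
        return Scenario(
            name="WT",
            genome_map=gmap,
            cycle=cycle,
            growth=growth,
            replication=default_replication_model(gmap, cycle),
            program=PositionProgram(program),
            panel=panel,
            channels=tuple(panel),
        )

    if name == "parS_displaced":
        if parS_kb is None:
            raise ValueError("parS_displaced preset requires parS_kb")
        gmap = default_genome_map()
        anchor = gmap["I"].length_kb - parS_kb  # circular position, left arm
        program = _wt_program(gmap, panel)
        for lname, locus in panel.items():
            if locus.chromosome != "I" or lname in TER_CLASS:
                continue
            d = gmap["I"].arc_distance(locus.map_position_kb, anchor)
            frac = min(d / max(gmap["I"].arm_lengths_kb), 1.0)
            program[lname] = _base_program_entry(lname, _wt_home("I", frac))
        return Scenario(
            name=f"parS_displaced_{parS_kb:g}",
            genome_map=gmap,
            cycle=cycle,
            growth=growth,
            replication=default_replication_model(gmap, cycle),
            program=PositionProgram(program),
            panel=panel,
            channels=tuple(panel),
        )

    if name == "delta_parS":
        gmap = default_genome_map()
        program = _wt_program(gmap, panel)
        for lname, locus in panel.items():
            if locus.chromosome != "I" or lname in TER_CLASS:
                continue
            h = 0.5 + DELTA_PARS_SHRINK * (program[lname].h_pre - 0.5)
            program[lname] = _base_program_entry(lname, h, noise_sd=DELTA_PARS_NOISE_SD)
        return Scenario(
            name="delta_parS",
            genome_map=gmap,
            cycle=cycle,
            growth=growth,
            replication=default_replication_model(gmap, cycle),
            program=PositionProgram(program),
            panel=panel,
            channels=tuple(panel),
            shrink=DELTA_PARS_SHRINK,
        )

    if name == "delta_parS_ectopic_ori":
        gmap = default_genome_map(ectopic_ori_left_kb=ECTOPIC_ORI_LEFT_KB)
        replication = default_replication_model(gmap, cycle)
        program = _wt_program(gmap, panel)
        for lname, locus in panel.items():
            if locus.chromosome != "I" or lname in TER_CLASS:
                continue
            t = replication_time(locus, replication, gmap)
            u = min(max((t - cycle.B_min) / cycle.C_min, 0.0), 1.0)
            h = 0.65 - 0.5 * u  # earlier-replicating loci sit more polar
            entry = _base_program_entry(lname, h, noise_sd=DELTA_PARS_NOISE_SD)
            if lname == "ori_I":
                # one sister stays relatively polar, the other is more central
                entry = replace(entry, sister_home_shift=0.05)
            program[lname] = entry
        return Scenario(
            name="delta_parS_ectopic_ori",
            genome_map=gmap,
            cycle=cycle,
            growth=growth,
            replication=replication,
            program=PositionProgram(program),
            panel=panel,
            channels=tuple(panel),
            shrink=DELTA_PARS_SHRINK,
        )

    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
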