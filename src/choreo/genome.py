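"""Default genome map and tagged-locus panel for the two V. cholerae chromosomes.

Coordinates are in kb on the circular maps, with each chromosome's ori at 0.
Lengths are rounded to keep the two replichores exactly equal (chromosome I:
2960 kb with dif at 1480; chromosome II: 1072 kb with dif at 536), which
matches the published ~2.96/1.07 Mb sizes to the resolution that matters for
replication-timing arithmetic.

The panel mirrors the experimental design: ori, five right-arm (R1..R5) and
five left-arm (L1..L5) loci plus ter on chromosome I; ori, three right-arm,
two left-arm loci plus ter on chromosome II.  L3_I sits at 650 kb on the
left arm, the site used for the largest parS displacement, with L2_I 170 kb
away at 480 kb.
"""

from __future__ import annotations

from .dataset import ChromosomeMap, GenomeMap, Locus

CHR_I_LENGTH_KB = 2960.0
CHR_II_LENGTH_KB = 1072.0
NATURAL_PARS1_KB = 65.0  # on the left arm, close to ori_I
ECTOPIC_ORI_LEFT_KB = 651.0  # path distance of the ectopic oriC1 from ori_I

# (arm, path distance from ori in kb) for every tagged locus
PANEL_PATHS: dict[str, tuple[str, float]] = {
    "ori_I": ("ori", 0.0),
    "R1_I": ("right", 180.0),
    "R2_I": ("right", 480.0),
    "R3_I": ("right", 740.0),
    "R4_I": ("right", 1040.0),
    "R5_I": ("right", 1310.0),
    "ter_I": ("ter", 1480.0),
    "L1_I": ("left", 180.0),
    "L2_I": ("left", 480.0),
    "L3_I": ("left", 650.0),
    "L4_I": ("left", 1040.0),
    "L5_I": ("left", 1310.0),
    "ori_II": ("ori", 0.0),
    "R1_II": ("right", 90.0),
    "R2_II": ("right", 180.0),
    "R3_II": ("right", 330.0),
    "ter_II": ("ter", 536.0),
    "L1_II": ("left", 170.0),
    "L2_II": ("left", 340.0),
}

# Loci in the replication-terminus region; they follow the midcell-recruitment
# segregation mode and their sister cohesion persists into division.
TER_CLASS = frozenset({"L5_I", "R5_I", "ter_I", "ter_II"})


def default_genome_map(ectopic_ori_left_kb: float | None = None) -> GenomeMap:
    """Two-chromosome map; optionally with an ectopic origin on chr I left arm.

    ``ectopic_ori_left_kb`` is the path distance of the extra origin from
    ori_I along the left replichore.
    """
    ect = None
    if ectopic_ori_left_kb is not None:
        ect = CHR_I_LENGTH_KB - ectopic_ori_left_kb
    chr1 = ChromosomeMap(
        length_kb=CHR_I_LENGTH_KB,
        ori_kb=0.0,
        dif_kb=CHR_I_LENGTH_KB / 2,
        parS_kb=(CHR_I_LENGTH_KB - NATURAL_PARS1_KB,),
        matS_domain_kb=(CHR_I_LENGTH_KB / 2 - 400.0, CHR_I_LENGTH_KB / 2 + 400.0),
        ectopic_ori_kb=ect,
    )
    chr2 = ChromosomeMap(
        length_kb=CHR_II_LENGTH_KB,
        ori_kb=0.0,
        dif_kb=CHR_II_LENGTH_KB / 2,
        parS_kb=(20.0,),
        matS_domain_kb=(CHR_II_LENGTH_KB / 2 - 150.0, CHR_II_LENGTH_KB / 2 + 150.0),
    )
    return GenomeMap(chromosomes={"I": chr1, "II": chr2})


def _circular_position(chromosome: str, arm: str, path_kb: float) -> float:
    length = CHR_I_LENGTH_KB if chromosome == "I" else CHR_II_LENGTH_KB
    if arm in ("ori", "right", "ter"):
        return path_kb
    return length - path_kb


def default_locus_panel() -> dict[str, Locus]:
    """The 19-locus panel keyed by locus name (channel names match)."""
    panel: dict[str, Locus] = {}
    for name, (arm, path_kb) in PANEL_PATHS.items():
        chromosome = "I" if name.endswith("_I") else "II"
        panel[name] = Locus(
            name=name,
            chromosome=chromosome,
            map_position_kb=_circular_position(chromosome, arm, path_kb),
            arm=arm,
        )
    return panel


def locus_path_kb(name: str) -> float:
    """Path distance from ori for a panel locus."""
    return PANEL_PATHS[name][1]
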