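# Methods

## Scope and data model

`choreo` reconstructs the segregation choreography of tagged chromosomal
loci from snapshot microscopy of exponentially growing bacterial cells —
specifically the two-chromosome arrangement of *Vibrio cholerae*.  The
input is a per-cell focus table: each segmented cell contributes its
long-axis length (µm) and, per fluorescent channel, the axial coordinates
of its detected foci.  Axial coordinates are straight-line positions along
the long axis, not curved-midline arclengths: every statistic in the
package is one-dimensional and the simulator produces 1-D positions.
Image segmentation and spot detection are upstream of this package.

Positions are stored relative to an arbitrary pole until the cell is
oriented; oriented relative positions run from 0 (new pole, formed at the
last division) to 1 (old pole).  Cells with more than two foci in a
channel are retained but excluded from that channel's statistics; the
analysis interprets only the one-focus and two-focus states.

## Length binning and sliding windows

Cells are classified by length into half-open 0.1 µm intervals labelled
by their lower edge, and every per-interval statistic pools the cells of a
centred 0.3 µm sliding window.  Window membership is tied to whole
intervals: the window centred on interval *k* contains exactly intervals
*k−1, k, k+1*.  This is equivalent to the continuous window
[c − 0.15, c + 0.15) around the interval centre and makes every sliding
statistic exactly reproducible by per-interval recounting, which the test
suite exploits as an oracle.  Windows with fewer than 10 scoreable cells
(configurable) are masked.  The window width must be an odd multiple of
the interval width.

The duplication frequency of a window is n₂/(n₁+n₂) over its 1-/2-focus
cells.  The dominant cell type of a window is "two" when this fraction is
≥ 0.5 (mirroring the ≥ 50 % alignment convention).  Position profiles
report the median and quartiles of the dominant type: single-focus
positions, or the two per-cell-ordered sister ranks.  Percentiles use
linear interpolation (type 7), fixed for cross-implementation
reproducibility.

## Orientation inference

Pole preferences are classified per channel from dividing cells (top
length decile by default): a cell votes "new pole" when its foci are on
average closer to the septum (midcell) than to the nearest pole; votes tie
to "old pole".  The majority vote with margin |fraction − 0.5| below 0.1,
or fewer than 20 voting cells, yields an ambiguous preference.

Each cell is then scored by S = Σ w_c · sign_c · (mean relative focus
position − ½) / Σ w_c over channels with a non-ambiguous preference
(sign +1 old-pole, −1 new-pole; weight w_c the preference margin).  S < 0
flips the stored axis; |S| < 0.05 (≈ the focus noise scale) marks the
cell ambiguous, with S = 0 fixed to "no flip".  After sister loci have
segregated, their homes are spatially symmetric about midcell, so a
late-cycle cell whose terminus focus has reached midcell genuinely carries
no orientation signal; such cells are expected to stay ambiguous.
Duplication frequencies, distances and polarity never require orientation,
which limits the damage of residual ambiguity to position trajectories.

A template refinement pass then compares each ambiguous cell, unflipped
and flipped, against the profile medians of its length interval (computed
from the already-oriented cells) and orients it in the better-fitting
direction.  Two guards keep rescues high-confidence: (i) the two summed
deviations must differ by more than 0.1 (≈ 2× the focus noise), and (ii) a
channel contributes only when all of its foci lie at least 0.15 from
midcell — window medians mix cells at different relocation stages, so a
near-midcell focus can produce a spuriously decisive-looking deviation gap
while carrying no axis information.  The pass iterates to a fixed point
(≤ 3 rounds).  On simulated wild-type populations (800 cells, default
noise) ≈ 98 % of non-ambiguous calls match the generating orientation and
≈ 9–12 % of cells stay ambiguous.

## Realignment, distances, polarity

Strains are realigned on a shared anchor: the first interval where a
common locus's duplication frequency reaches a threshold (50 % typically;
25 % for terminus loci that never reach 50 %), or where a terminus locus
is recruited to midcell — implemented as the first run of ≥ 2 consecutive
populated intervals whose single-focus median folded distance from midcell
is ≤ 0.1.  The folded form makes the anchor orientation-free.  The offset
is the difference of anchor intervals, hence a whole number of intervals,
and is added to the target strain's lengths *for binning only*; relative
positions always remain ratios against the measured length (the shift is a
population-comparison device, not a cell-geometry claim).  When an anchor
is never reached the package raises and refuses to align rather than
guessing.

Inter-locus distances are |x_A − x_B|/L over cells with exactly one focus
of each locus; sister distances |x₁ − x₂|/L over cells strictly longer
than 3.4 µm with exactly two foci.  The polarity statistic splits each
dividing cell at midcell and, per pole, asks which of two loci is closer
to it, over cells with two foci per channel and one focus of each channel
per half; both poles of each qualifying cell are scored and counts are
reported in poles.  Distances within 0.01·L tie; a focus exactly at
midcell goes to the lower half (fixed tie-break, logged).  Proportions
carry Wilson 95 % intervals.  All of these statistics are computed from
relative coordinates rounded to 1e-9 — far below localisation precision —
which makes them bit-identical under reversal of every stored axis.

## The population simulator

The simulator provides labelled data with the statistical structure the
analysis assumes.

**Cell cycle and growth.**  Generation time τ = 55 min split into
B = 11 min (pre-replication), C = 32 min (replication), D = 12 min
(post-replication).  Ages are sampled from the steady-state age density
f(a) = (2 ln2/τ)·2^(−a/τ) by inverse CDF.  Growth is exponential in
length, L(a) = L_b·2^(a/τ), with birth length L_b ~ N(2.1 µm, 0.1 µm):
newborns ≈ 2.1 µm, dividing cells ≈ 4.2 µm, and ≥ 90 % of snapshot
lengths fall in 1.9–4.3 µm.

**Replication.**  Bidirectional from ori at constant fork speed, sized so
the longer chromosome-I arm (1480 kb) replicates in exactly the C period
(46.25 kb/min).  Chromosome II (arm 536 kb) initiates at 31.4 min, chosen
so both chromosomes terminate together at B + C — the delayed firing of
the chromosome II origin with a single shared C period.  A locus's
replication time is the minimum over active origins of initiation age +
arc distance / fork speed, which also covers the ectopic-origin scenario
(forks meet wherever arrival times are equal).

**Duplication.**  A cell shows two foci of a locus when its age exceeds
the locus replication time plus a sister-cohesion delay, exponential with
a locus-class mean: 3 min for most loci; for terminus-class loci the mean
is tied to division so that a configured fraction of dividing cells shows
two foci (50 % for L5, 40 % for R5, 10 % for ter on chromosome I, 35 % for
ter on chromosome II), via m = −(τ − t_rep)/ln(1 − p).

**Positional program.**  Each locus has a pre-duplication home h (0 = new
pole, 1 = old pole).  Wild type interpolates h linearly in genomic path
fraction from ori to ter: 0.8 → 0.1 on chromosome I, 0.55 → 0.28 on
chromosome II.  After duplication the sisters travel, over 0.1 µm of
elongation, to the homes 0.5 − h/2 and 0.5 + h/2.  This affine mapping is
the unique single-parameter choice that is self-similar across division:
mapping each sister home into its daughter's frame returns h exactly, so
newborn patterns are consistent across generations without extra
parameters.  It also reproduces the strongly asymmetric ori segregation
(0.8 → 0.9 and 0.1: one copy nearly immobile, the other crossing the
cell) and the symmetric mid-arm segregation (h ≈ 0.5 → 0.25/0.75) as
special cases of one rule.  Terminus-class loci instead relocate linearly
to midcell over the 5 min ending at age 47 min, then duplicate near
division with sisters staying around midcell.  Gaussian positional noise
(sd 0.05 relative units) is added and positions are clamped to
[0.02, 0.98] — foci are never detected exactly at a pole.  Each cell's
stored axis is flipped with probability exactly ½; the truth table
records the flip and the noiseless true-axis positions.

**Perturbation presets.**
*parS_displaced(p)* re-anchors the chromosome I ramp on genomic arc
distance from the displaced parS site at left-arm position p (300, 490 or
650 kb in the experiments), terminus region pinned; with the ramp
re-anchored at 650 kb the locus 170 kb away inherits the most polar home
and ori receives the home the wild-type ramp assigns at 650 kb — the
home-position switch seen experimentally.
*delta_parS* shrinks chromosome I homes towards midcell by the factor 2/3
(ori home 0.8 → 0.7) and inflates noise to 0.08, reflecting the looser
control without the Par anchor.
*delta_parS_ectopic_ori* adds a second origin 651 kb out on the left arm
and derives chromosome I homes from replication time,
h = 0.65 − 0.5·(t_rep − B)/C, so early-replicating loci sit polar; ori
additionally receives a +0.05 common shift of its sister homes (one copy
relatively polar, the other more central).  Under these presets the
per-pole ori-vs-L3 polarity proportion falls from ≈ 98 % (WT) to ≈ 55 %
(parS at 300 kb) to ≈ 12 % (parS at 490 kb), and from ≈ 85 % (ΔparS) to
≈ 50 % (ΔparS + ectopic origin), reproducing the experimental ordering;
the analysis pipeline is validated on these orderings, not on the exact
percentages.

**Timing of terminus recruitment.**  Placing the midcell recruitment of
the terminus class at ages 42–47 min (completed shortly before division)
keeps the fraction of cells without any orienting signal near 10 %.  An
earlier recruitment would be closer to the observed relocation of the
ter-flanking loci relative to upstream duplication but would leave > 20 %
of simulated cells unorientable; we prioritise the orientation contract,
and the recruitment age is configurable per locus.

**What the generator does not emulate.**  No 2-D/3-D cell geometry, no
multifork replication or replication arrest, no lineage structure between
snapshot cells, no segmentation or spot-detection artefacts (misdetected
or merged foci), and focus counts are capped at the two-chromatid regime.
Passing tests therefore demonstrate the internal consistency of the
statistics and their recovery of a known generating program under
realistic noise — not robustness to imaging artefacts.

## Numerical choices

* Interval membership uses floor(length/width + 1e-9): lengths sitting on
  a representable edge (2.0, 4.2, …) land in the interval they label.
* Offsets are quantized to the interval width by construction; alignment
  refuses (raises) when an anchor is never reached.
* Tie-breaks are fixed and documented: pole-preference votes tie to old
  pole, orientation score 0 to "no flip + ambiguous", template ties stay
  ambiguous, midcell foci to the lower half.
* The steady-state sampler is exact inverse-CDF, so the Kolmogorov–
  Smirnov check against the analytic CDF fails only at its nominal rate.
* Problem sizes follow the study conditions: 800 cells per strain for
  population statistics, 10⁵ ages for the distributional check, three
  seeds for scenario orderings; all analyses run in seconds.

## Known limitations

* Cells whose informative loci all sit near midcell are unorientable by
  construction; they are reported, excluded from trajectories, and no
  attempt is made to guess their axis.
* The midcell-recruitment anchor needs ≥ 2 consecutive populated
  intervals inside the band; sparse terminal windows can push the anchor
  earlier by one interval.
* The polarity statistic scores both poles of a cell, so its effective
  sample size is between one and two per cell (pole scores within a cell
  are correlated); the Wilson interval treats poles as independent and is
  therefore slightly anti-conservative.
* Realignment assumes a rigid shift of the length distribution; strains
  with genuinely different cycle structure should not be force-aligned,
  and the anchor-not-reached error is the intended failure mode.
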