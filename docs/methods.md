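# Methods

## Model structure and assumptions

The simulator follows a population of rod-shaped cells in discrete time.
Each cell is an ordered chain of compartments (old pole → new pole); a
compartment is the segment around one chromosome and is the unit of
growth. Cell length is by construction the sum of compartment lengths,
and this identity is audited by `validate_state` after structural
operations. Minicells are counted but not sized or grown: they carry no
chromosome and never divide again, so their only observable role here is
their number.

Growth is exponential per compartment, `L(τ) = L_start · 2^(τ/T_d)`,
with the doubling time redrawn from N(Td_mean, Td_sd²) at the start of
every replication round ("growth rates are assigned upon initiation of a
new round of replication"). Growth and replication are synchronous: a
fresh chromosome is ready to segregate exactly when its compartment has
doubled, encoded by the timer `T_seg = T_d · log₂(L_end/L_start)` with
`L_end = 2·L_start`. The per-step update multiplies length by
`2^(Δt/T_d)`, which telescopes to the closed form exactly (up to float
rounding), so no integration error accumulates.

There are no spatial coordinates for chromosomes and no explicit
replication forks; slow-growth conditions are assumed throughout, so
overlapping replication rounds do not occur.

## Division-site dynamics

Potential division sites are the two poles plus every boundary between
neighbouring chromosomes. An *active* site holds an assigned waiting
time `t_w` and a progression variable `s` advanced by `f·Δt` per step;
it fires at `s ≥ t_w`, checked at step boundaries (timing error ≤ Δt,
with Δt = 1 min ≈ 6% of the 17.7-min WT waiting scale). In models 1–3
f = 1, so the site is a plain countdown. In model 4 the sites of a cell
compete for a machinery pool proportional to cell length:
`f = ftsz_factor · c · L_op / (n_sites · Lc)`, where `L_op` is the full
length in minB⁻ and half the length in WT (the Min oscillations confine
the machinery to roughly half the cell around midcell), and `n_sites`
counts the active sites — poles included in minB⁻, excluded in WT.

Waiting-time draws are plain normals, not truncated: resampling
N(17.7, 11.9²) to positive values would inflate the mean by ~1.7 min and
deflate the SD by ~1.5 min, i.e. the assigned distribution would no
longer be the measured one. A non-positive draw simply means the site
completes at its first progression check. Doubling times and lengths
*are* resampled to positive values; there the tail mass is ≤ 10⁻⁶ and
the distortion is negligible.

## The segregation defect (blocking)

The minB⁻ chromosome-segregation defect is modelled as effective
blocking. Whenever a new potential site appears in a cell — chromosome
duplication or formation of a new pole — fresh uniform marks are given
to that site and to every currently blocked site of the cell, and marks
above `p_th = max(0, 1 − n_target/n_randomized)` are (or stay) blocked.
This is the unique linear-expectation threshold that leaves
`min(n_target, n_randomized)` sites blocked on average per
re-randomisation. Blocked chromosome boundaries are represented
implicitly: the flanking chromosomes stay inside one compartment
(`n_chrom ≥ 2`), which makes the blocked-site count structural rather
than a flag that could desynchronise. A boundary that unblocks
segregates immediately — the compartment splits, the pieces start fresh
replication rounds — and a pole that unblocks becomes active with its
waiting time assigned *then*. Since the measured polar waiting time runs
from pole *formation*, time spent blocked lengthens it; this is the
mechanism behind the emergent polar waiting excess, and with the
blocking expectation pegged at 2 the realized steady-state time-average
lands slightly above 2 (~2.09 in the shipped conditions) because each
division triggers two daughter re-randomisations.

Blocking applies to poles as well as chromosome boundaries in models
2–4; WT runs never block (no segregation defect).

## Placement noise

Non-polar placement is midcell ± δ, δ ~ N(0, delta_sd²), resampled until
the daughter deviates at most 10% from half the parent (hard abort after
10⁴ rejections, which flags a misconfigured delta_sd). Multi-way splits
(several boundaries unblocking at once) cut sequentially in proportion
to chromosome counts, each cut capped at 10% of its smaller nominal
side; the two-way case reduces exactly to the midcell rule.

## Parameters

| parameter | default | unit | origin |
|---|---|---|---|
| Td_mean ± Td_sd | 75 ± 15 | min | measured doubling-time normal |
| w_wt | 17.7 ± 11.9 | min | measured WT waiting-time normal |
| w_nonpolar | 25 ± 15 | min | package default (see below) |
| w_polar | 40 ± 20 | min | package default (see below) |
| L0 | 2500 ± 250 | nm | package default |
| Lc | 5000 | nm | calibration choice (see below) |
| delta_sd | 100 | nm | package default |
| n_block_target | 2 | sites/cell | cluster-count regression |
| c_rate | 2 | — | WT reference calibration |
| dt | 1 | min | resolution choice |
| n_init | 1000 | cells | standard run size |

The minB⁻ waiting-time normals and the length scales are configuration
with documented defaults chosen once to match the qualitative record:
minB⁻ waits are longer than WT and polar longer than non-polar; newborn
cells in slow growth are ~2.5 µm. `Lc` is set to twice the mean newborn
length so that a WT cell at the moment its midcell site appears (length
≈ 2·L0, one active site) has f ≈ 1 — the stated calibration intent that
model-4 WT reproduce the measured WT waiting distribution. With `c = 2`
the reference identity `f(L = Lc, n = 1) = 1` holds exactly.

## Initialization and the time loop

Runs start with `n_init` cells holding 1–3 chromosomes (uniform), one
compartment per chromosome, lengths drawn from the newborn normal and
grown by a uniform random age fraction, timers set consistently, and all
sites unblocked with assigned waiting times; the blocking structure
builds up within the first ~100 min. Steady-state statistics are
insensitive to `n_init` (checked by KS comparison across run sizes);
transient population-composition curves are not, and are therefore not
used as quantitative outputs.

Each step applies, in fixed order: growth/timers → segregation →
progression → divisions. Divisions execute in the detecting step, polar
events first, then at most one non-polar division per cell (leftmost
completed boundary; any further completed site carries into a daughter
and fires next step, within the Δt resolution). Iteration follows
insertion order of the cell table and a single `numpy` Generator drives
all randomness, so a fixed seed reproduces the event log byte for byte.
After a non-polar division the distal daughter is reversed so both
daughters are ordered old pole → new pole; the septum pole is each
daughter's new pole, the inherited pole its old pole. After a polar
division the pole is retained under its existing identity and re-enters
the lottery as a newly formed site.

## Synthetic tracking data

`generate_tracking` emulates lineage microscopy without the simulator's
mechanics: exponential lineages, a site appearing one doubling time
after birth, class-specific waiting normals, capped placement noise,
cluster counts `round(L/L0 − n_target + noise)`, and right-censoring at
the observation window (events dividing after the window are dropped and
counted, reproducing the downward bias a finite movie inflicts on mean
waiting times — kept deliberately, and switchable off for unbiased
estimator tests). It does not emulate blocking dynamics, minicell
geometry, or density effects on growth, so round-trip recovery tests
validate the observables layer, not the simulator.

## Numerical and design notes

* Observable estimators are deliberately simple closed forms: the
  cluster offset is the mean residual of the unit-slope regression
  (cross-checked against generic least squares in the tests), and the
  bulk doubling time is the inverse slope of a log₂-linear fit of total
  length over the final two-thirds of a run.
* The fitted bulk doubling time of a model-1 WT culture comes out ~1 min
  below the 75-min per-cell mean: lineages with fast doubling times
  carry more biomass weight, a Jensen-type effect of the rate
  dispersion, well inside the ±2 min acceptance band.
* Division-history classification uses birth-order pole labels; after a
  non-polar first division the two pole identities of the second event
  are pooled into one "polar" category, giving the five history types.
  When a cell's predecessor event cannot be linked the event is counted
  as an orphan rather than silently dropped.
* Problem sizes in tests and in `scripts/acceptance.py` (run lengths
  300–320 min, 300–1000 initial cells, 3–10 seeds) are chosen as the
  smallest sizes at which the Monte-Carlo error is comfortably inside
  each stated tolerance.
* Known limitations: no nucleoid occlusion, no explicit Z-ring kinetics
  or FRAP-level dynamics, no minicell sizes, no molecular Min
  oscillation model; the blocking rule is an effective description of
  the segregation defect, not a mechanism.
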