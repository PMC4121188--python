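# mindiv

Stochastic population models of cell growth, chromosome segregation and
division timing in *Escherichia coli*, with and without a functional Min
system.

## The problem

The MinCDE proteins oscillate pole to pole and confine Z-ring assembly
to midcell. In Δ*minB* cells division also happens at the poles
(producing chromosome-free minicells), cells become filamentous, and —
less obviously — the *timing* of division changes: the division waiting
time (from the appearance of a division site to the division event at
that site) is longer and more variable than in wild type, and polar
sites appear slower than non-polar ones. `mindiv` implements a ladder of
four agent-based models that explain these observations from single-cell
growth, a chromosome-segregation defect, and competition of division
sites for a limited pool of division machinery (FtsZ). It is aimed at
quantitative microbiologists and modellers who want to simulate these
scenarios, compute the same statistics from their own lineage-tracking
tables, or test analysis pipelines on synthetic data.

## The models

Every cell is an ordered chain of compartments, each holding one (or,
when segregation is blocked, several) chromosomes. Per time step Δt a
compartment of birth length L₀ and doubling time T_d (drawn from
N(75, 15²) min) grows by

    ΔL = L₀ · (2^((τ+Δt)/T_d) − 2^(τ/T_d)),

and a fresh chromosome in a compartment growing from L_s to L_e carries
the replication timer T_seg = T_d · log₂(L_e/L_s). When the timer
expires the chromosomes duplicate and the new boundary is a potential
division site. Division sites carry a progression variable s and an
assigned waiting time t_w; the site fires when s ≥ t_w, with ds/dt = f:

* **Model 1** — f = 1; waiting times drawn per site kind (WT:
  N(17.7, 11.9²) min); every boundary segregates.
* **Model 2** — model 1 plus the segregation defect: whenever a new
  potential site appears in a cell, fresh uniform marks are assigned to
  the blocked and the new site(s) and marks above
  p_th = max(0, 1 − n_target/n_randomized) stay blocked, keeping on
  average n_target = 2 sites per cell blocked.
* **Model 3** — model 2, but polar sites draw from the *non-polar*
  waiting distribution; the longer measured polar waiting then emerges
  from the time poles spend blocked.
* **Model 4** — model 3, but t_w is drawn from the WT distribution for
  every site and the progression rate encodes competition for division
  machinery: f = c·L/(n·L_c) in minB⁻, f = c·(L/2)/(n·L_c) in WT (Min
  confines the machinery to half the cell and keeps the poles out), with
  c calibrated so a WT reference cell has f = 1. A doubled FtsZ level is
  an `ftsz_factor` of 2.

Non-polar placement is midcell ± Gaussian noise, resampled so the
daughter never deviates more than 10% from half the parent. Polar
divisions only increment a minicell counter.

## Worked example

```python
from mindiv import SimConfig, run, waiting_time_distribution

cfg = SimConfig(model_variant=3, strain="minB", n_init=300, t_max=300.0,
                rng_seed=1)
result = run(cfg)
ts = result.timeseries
sel = ts[ts.t_min >= 120]
print("blocked sites per cell:",
      round(float((sel.n_blocked_sites / sel.n_cells).mean()), 2))
for cls in ("nonpolar", "polar"):
    s = waiting_time_distribution(result.tracking, site_class=cls)
    print(f"{cls} waiting: mean {s.mean:.1f} min (n={s.n})")
```

prints

```
blocked sites per cell: 2.1
nonpolar waiting: mean 22.8 min (n=4805)
polar waiting: mean 73.1 min (n=6276)
```

The blocking rule holds ~2 potential division sites per cell blocked;
non-polar waiting times track the assigned 25-min normal (shortened a
little by the finite run), while the measured polar waiting is almost
three times the assigned mean — an emergent property of blocking, not an
input. The same functions accept any tracking table with the documented
columns, e.g. one written by `mindiv synth`.

The numbered scripts under `analysis/` run the full story — bulk-growth
calibration, the model 1–4 comparison, assigned-versus-emergent waiting
times, and the FtsZ-rescue of the minB⁻ length distribution — and write
their tables under `results/`. A CLI is included:
`mindiv simulate|synth|analyze|compare --help`.

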