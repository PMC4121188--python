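"""Population simulator: the time loop over grow -> segregate -> divide.

Each step applies, in fixed order: exponential growth and timer ticks,
chromosome segregation (with blocking in models 2-4), progression of
septum formation at every active site, and execution of completed
divisions.  Divisions detected within a step execute in that step -
polar events first, then at most one non-polar division per cell
(leftmost completed boundary); any further completed site fires on the
next step, within the one-``dt`` completion resolution.  Iteration order
is insertion order of the cell table, so a fixed seed and configuration
reproduce a run bit for bit.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .division import (
    advance_progression,
    assign_doubling_time,
    assign_waiting_time,
    execute_division,
    positive_normal,
)
from .growth import grow_and_tick
from .params import DistParams, SimConfig
from .segregation import segregate
from .state import (
    NONPOLAR,
    POLAR_NEW,
    POLAR_OLD,
    Cell,
    Compartment,
    DivisionSite,
    SimState,
)

TIMESERIES_COLUMNS = [
    "t_min",
    "n_cells",
    "total_length_nm",
    "n_compartments",
    "n_chromosomes",
    "n_blocked_sites",
    "n_blocked_boundaries",
    "n_active_sites",
    "minicell_count",
]

SNAPSHOT_COLUMNS = [
    "cell_id",
    "parent_id",
    "born_at",
    "length_nm",
    "birth_length_nm",
    "n_compartments",
    "n_chromosomes",
    "n_blocked_sites",
    "n_active_sites",
]


@dataclass
class RunResult:
    """Everything a finished run produced."""

    config: SimConfig
    events: pd.DataFrame
    tracking: pd.DataFrame
    timeseries: pd.DataFrame
    snapshots: List[Tuple[float, pd.DataFrame]]
    state: SimState
    aborted: bool = False

    @property
    def final_snapshot(self) -> pd.DataFrame:
        return self.snapshots[-1][1]


def init_population(
    n_init: int,
    rng: np.random.Generator,
    params: DistParams,
    strain: str = "minB",
    model_variant: int = 1,
    shared_Td: bool = False,
) -> SimState:
    """Randomly initialised starting population.

    Each cell gets 1-3 chromosomes (uniformly), one compartment per
    chromosome; compartment lengths are drawn from the newborn-length
    normal and grown by a uniform random fraction of their doubling
    time, with the replication timer set consistently.  All sites start
    unblocked with assigned waiting times (minB-; WT poles stay inert),
    so any blocking structure is built up by the dynamics.
    """
    if n_init < 1:
        raise ValueError(f"n_init must be >= 1, got {n_init}")
    state = SimState()
    for _ in range(n_init):
        k = int(rng.integers(1, 4))
        comps: List[Compartment] = []
        for _ in range(k):
            L0c = positive_normal(rng, params.L0_mean, params.L0_sd)
            Td = assign_doubling_time(rng, params, shared=shared_Td)
            u = float(rng.random())
            comps.append(
                Compartment(
                    length=L0c * 2.0 ** u,
                    Td=Td,
                    tau=u * Td,
                    T_seg=(1.0 - u) * Td,
                    L_start=L0c,
                    n_chrom=1,
                )
            )
        np_sites = []
        for _ in range(k - 1):
            s = DivisionSite(NONPOLAR, formed_at=0.0, appeared_at=0.0)
            s.t_w = assign_waiting_time(NONPOLAR, model_variant, strain, rng, params)
            np_sites.append(s)
        polar_old = DivisionSite(POLAR_OLD, formed_at=0.0)
        polar_new = DivisionSite(POLAR_NEW, formed_at=0.0)
        if strain == "minB":
            for pole in (polar_old, polar_new):
                pole.t_w = assign_waiting_time(
                    pole.kind, model_variant, strain, rng, params
                )
                pole.appeared_at = 0.0
        length = sum(c.length for c in comps)
        cell = Cell(
            id=state.new_id(),
            parent_id=-1,
            compartments=comps,
            polar_old=polar_old,
            polar_new=polar_new,
            np_sites=np_sites,
            L0=length,
            born_at=0.0,
            length=length,
        )
        state.add_cell(cell)
    return state


def snapshot_frame(state: SimState, strain: str) -> pd.DataFrame:
    rows = [
        (
            c.id,
            c.parent_id,
            c.born_at,
            c.length,
            c.L0,
            len(c.compartments),
            c.n_chromosomes,
            c.n_blocked_sites,
            len(c.active_sites(strain)),
        )
        for c in state.cells.values()
    ]
    return pd.DataFrame(rows, columns=SNAPSHOT_COLUMNS)


def run(config: SimConfig) -> RunResult:
    """Advance a population from t=0 to ``t_max`` in steps of ``dt``.

    Emits a per-step population time series, per-cell snapshots every
    ``snapshot_every`` minutes (final state always included), the event
    log, and the division tracking table.  Aborts in a controlled way,
    keeping partial outputs, if the population exceeds the compartment
    cap.
    """
    rng = np.random.default_rng(config.rng_seed)
    params = config.dist_params
    state = init_population(
        config.n_init,
        rng,
        params,
        strain=config.strain,
        model_variant=config.model_variant,
        shared_Td=config.shared_Td,
    )
    dt = config.dt
    n_steps = int(round(config.t_max / dt)) if config.t_max > 0 else 0

    ts_rows: List[tuple] = []
    snapshots: List[Tuple[float, pd.DataFrame]] = []
    aborted = False

    def record_ts() -> None:
        n_blocked = 0
        n_blocked_bnd = 0
        n_active = 0
        n_comp = 0
        n_chrom = 0
        total_len = 0.0
        for c in state.cells.values():
            total_len += c.length
            n_comp += len(c.compartments)
            n_chrom += c.n_chromosomes
            nb = c.n_blocked_boundaries
            n_blocked_bnd += nb
            n_blocked += nb
            n_blocked += 1 if c.polar_old.blocked else 0
            n_blocked += 1 if c.polar_new.blocked else 0
            n_active += len(c.active_sites(config.strain))
        ts_rows.append(
            (
                state.t,
                len(state.cells),
                total_len,
                n_comp,
                n_chrom,
                n_blocked,
                n_blocked_bnd,
                n_active,
                state.minicell_count,
            )
        )

    record_ts()
    snapshots.append((0.0, snapshot_frame(state, config.strain)))
    snap_period = max(1, int(round(config.snapshot_every / dt)))

    for step in range(n_steps):
        state.t = (step + 1) * dt
        ready = grow_and_tick(state, dt)
        for cell in ready:
            segregate(cell, state, rng, config)
        completed = advance_progression(state, dt, config)
        if completed:
            _execute_completions(state, completed, rng, config)
        record_ts()
        if (step + 1) % snap_period == 0:
            snapshots.append((state.t, snapshot_frame(state, config.strain)))
        if state.total_compartments() > config.max_compartments:
            aborted = True
            break

    if not snapshots or snapshots[-1][0] != state.t:
        snapshots.append((state.t, snapshot_frame(state, config.strain)))

    return RunResult(
        config=config,
        events=state.event_log.to_frame(),
        tracking=state.tracking_frame(),
        timeseries=pd.DataFrame(ts_rows, columns=TIMESERIES_COLUMNS),
        snapshots=snapshots,
        state=state,
        aborted=aborted,
    )


def _execute_completions(state, completed, rng, config) -> None:
    """Run the divisions detected in one step in deterministic order.

    Polar (minicell) events first; then, per cell in id order, the
    leftmost completed non-polar boundary.  Remaining completed sites
    carry their progression into the daughters and fire next step.
    """
    polar = [(c, s) for c, s in completed if s.kind != NONPOLAR]
    nonpolar = [(c, s) for c, s in completed if s.kind == NONPOLAR]
    polar.sort(key=lambda cs: (cs[0].id, 0 if cs[1].kind == POLAR_OLD else 1))
    for cell, site in polar:
        if cell.id in state.cells:
            execute_division(state, cell, site, rng, config)
    chosen = {}
    for cell, site in nonpolar:
        j = cell.np_sites.index(site)
        if cell.id not in chosen or j < chosen[cell.id][1]:
            chosen[cell.id] = (site, j)
    for cell_id in sorted(chosen):
        if cell_id in state.cells:
            site = chosen[cell_id][0]
            execute_division(state, state.cells[cell_id], site, rng, config)


def scenario(name: str, **overrides) -> SimConfig:
    """Resolve a named scenario to a full configuration.

    ``wt``: model 4 with the machinery confined to half the cell, poles
    inactive, no segregation defect.  ``minB``: the Min deletion mutant
    (model 4 by default; pass ``model_variant`` to select another).
    ``minB_2xftsz``: minB- with doubled FtsZ level and a reduced
    blocking target (default 1), mirroring the observation that extra
    FtsZ shortens the distance between septa.
    """
    presets = {
        "wt": dict(
            strain="WT",
            model_variant=4,
            ftsz_factor=1.0,
            dist_params=DistParams(n_block_target=0.0),
        ),
        "minB": dict(strain="minB", model_variant=4, ftsz_factor=1.0),
        "minB_2xftsz": dict(
            strain="minB",
            model_variant=4,
            ftsz_factor=2.0,
            dist_params=DistParams(n_block_target=1.0),
        ),
    }
    if name not in presets:
        raise ValueError(
            f"unknown scenario {name!r}; choose from {sorted(presets)}"
        )
    base = presets[name]
    dist_overrides = overrides.pop("dist_params", None)
    cfg = dict(base)
    cfg.update(overrides)
    if dist_overrides is not None:
        if isinstance(dist_overrides, DistParams):
            cfg["dist_params"] = dist_overrides
        else:
            merged = cfg.get("dist_params", DistParams()).model_dump()
            merged.update(dist_overrides)
            cfg["dist_params"] = DistParams(**merged)
    return SimConfig(**cfg)
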