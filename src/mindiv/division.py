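"""Division-site waiting times, progression dynamics, and division events.

Every active site carries an assigned waiting time ``t_w`` and a
progression variable ``s`` measuring how far septum formation has
proceeded; the site divides once ``s >= t_w``.  In models 1-3 the
progression rate is 1 (plain countdown).  In model 4 the sites of one
cell compete for a division machinery whose amount scales with cell
length, so the rate per site is

    minB-:  f = ftsz_factor * c * L / (n_sites * Lc)
    WT:     f = ftsz_factor * c * (L/2) / (n_sites * Lc)

with ``L`` the cell length, ``n_sites`` the number of active sites and
``Lc`` the reference chromosome size.  In WT the Min oscillations
confine the machinery to roughly half the cell around midcell (hence
``L/2``) and keep the poles out of the competition.  ``c`` is calibrated
so a WT reference cell (one compartment of length ``Lc``, one active
site) has ``f = 1``, which makes model-4 WT reproduce the measured WT
waiting-time distribution.
"""
from __future__ import annotations

from typing import List, Tuple

import numpy as np

from .params import DistParams, SimConfig
from .state import NONPOLAR, POLAR_NEW, POLAR_OLD, Cell, DivisionSite, SimState

_MAX_RESAMPLE = 10_000


def positive_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw resampled to be strictly positive (lengths, doubling times)."""
    if sd == 0:
        return mean
    for _ in range(_MAX_RESAMPLE):
        x = rng.normal(mean, sd)
        if x > 0:
            return x
    raise RuntimeError(
        f"could not draw a positive value from normal({mean}, {sd})"
    )


def assign_doubling_time(rng: np.random.Generator, params: DistParams,
                         shared: bool = False) -> float:
    """Draw a compartment doubling time (minutes).

    With ``shared`` every compartment in the culture uses the mean
    doubling time (the modified variant used to test sensitivity to
    growth-rate dispersion).
    """
    if shared:
        return params.Td_mean
    return positive_normal(rng, params.Td_mean, params.Td_sd)


def assign_waiting_time(
    site_kind: str,
    model_variant: int,
    strain: str,
    rng: np.random.Generator,
    params: DistParams,
    blocked: bool = False,
) -> float:
    """Draw the waiting time assigned to a newly active division site.

    WT strains and model 4 use the WT distribution for every site kind;
    model 3 uses the non-polar distribution for both kinds; models 1-2
    distinguish polar from non-polar sites.  Draws are plain normals:
    the assigned distribution is exactly the configured one, and a
    non-positive draw simply completes at the first progression check.
    """
    if blocked:
        raise ValueError("cannot assign a waiting time to a blocked site")
    if strain == "WT" or model_variant == 4:
        mean, sd = params.w_wt_mean, params.w_wt_sd
    elif model_variant == 3:
        mean, sd = params.w_nonpolar_mean, params.w_nonpolar_sd
    elif site_kind == NONPOLAR:
        mean, sd = params.w_nonpolar_mean, params.w_nonpolar_sd
    else:
        mean, sd = params.w_polar_mean, params.w_polar_sd
    if sd == 0:
        return mean
    return rng.normal(mean, sd)


def progression_rate(
    L: float,
    n_sites: int,
    model_variant: int,
    strain: str,
    ftsz_factor: float,
    params: DistParams,
) -> float:
    """Septum-formation rate per active site (dimensionless)."""
    if n_sites < 1:
        raise ValueError(f"need at least one active site, got {n_sites}")
    if L <= 0:
        raise ValueError(f"cell length must be positive, got {L}")
    if model_variant != 4:
        return 1.0
    operating_length = 0.5 * L if strain == "WT" else L
    return ftsz_factor * params.c_rate * operating_length / (n_sites * params.Lc)


def advance_progression(
    state: SimState, dt: float, config: SimConfig
) -> List[Tuple[Cell, DivisionSite]]:
    """Accumulate divisional work on every active site; return completed sites.

    The rate is recomputed each step from the current cell length and
    active-site count (in model 4 it changes as the cell grows or as
    sites appear).  Completion is checked at step boundaries only, so
    realized waiting times carry an error of at most ``dt``.
    """
    completed: List[Tuple[Cell, DivisionSite]] = []
    mv = config.model_variant
    strain = config.strain
    ftsz = config.ftsz_factor
    params = config.dist_params
    for cell in state.cells.values():
        sites = cell.active_sites(strain)
        if not sites:
            continue
        f = progression_rate(cell.length, len(sites), mv, strain, ftsz, params)
        ds = f * dt
        for site in sites:
            site.s += ds
            if site.s >= site.t_w:
                completed.append((cell, site))
    return completed


def execute_division(
    state: SimState,
    cell: Cell,
    site: DivisionSite,
    rng: np.random.Generator,
    config: SimConfig,
) -> None:
    """Carry out a completed division event.

    Non-polar: the cell splits at the compartment boundary carrying the
    site; daughters inherit the compartments (and the sites they
    contain, with their progression) on their side, the septum becomes
    each daughter's new pole, and each fresh pole enters the blocking
    lottery (models 2-4, minB-) or is armed directly (model 1).
    Orientation: the distal daughter is reversed so both daughters are
    ordered old pole -> new pole.

    Polar: a chromosome-free minicell is pinched off; only the count is
    kept (minicells are far smaller than nucleated cells), the cell's
    length and compartments are unchanged, and the pole re-forms as a
    fresh potential site.
    """
    if site.blocked:
        raise RuntimeError("attempted division at a blocked site")
    t = state.t
    params = config.dist_params
    mv = config.model_variant
    strain = config.strain

    if site.kind != NONPOLAR:
        # Polar division: minicell. The pole is retained (same identity)
        # and re-armed as a newly formed potential site.
        state.minicell_count += 1
        state.event_log.append(
            t, "minicell", cell.id, cell.parent_id, site.kind,
            cell.length, len(cell.compartments),
        )
        state.tracking_rows.append(
            (cell.id, cell.parent_id, cell.born_at, t, cell.L0, cell.length,
             site.kind, site.formed_at, len(cell.compartments))
        )
        cell.last_division_kind = "polar"
        site.t_w = float("nan")
        site.s = 0.0
        site.blocked = False
        site.p_rand = float("nan")
        site.formed_at = t
        site.appeared_at = float("nan")
        _arm_new_pole(cell, [site], state, rng, config)
        return

    j = cell.np_sites.index(site)
    left_comps = cell.compartments[: j + 1]
    right_comps = cell.compartments[j + 1 :][::-1]
    left_np = cell.np_sites[:j]
    right_np = cell.np_sites[j + 1 :][::-1]

    left_len = sum(c.length for c in left_comps)
    right_len = sum(c.length for c in right_comps)

    state.event_log.append(
        t, "division", cell.id, cell.parent_id, NONPOLAR,
        cell.length, len(cell.compartments),
    )
    state.tracking_rows.append(
        (cell.id, cell.parent_id, cell.born_at, t, cell.L0, cell.length,
         NONPOLAR, site.appeared_at, len(cell.compartments))
    )

    left_new_pole = DivisionSite(POLAR_NEW, formed_at=t)
    right_new_pole = DivisionSite(POLAR_NEW, formed_at=t)
    # The distal daughter's inherited pole (the parent's new pole) is its
    # old pole from birth onward; the site keeps its state.
    right_old_pole = cell.polar_new
    right_old_pole.kind = POLAR_OLD

    left = Cell(
        id=state.new_id(), parent_id=cell.id, compartments=left_comps,
        polar_old=cell.polar_old, polar_new=left_new_pole, np_sites=left_np,
        L0=left_len, born_at=t, length=left_len, last_division_kind="none",
    )
    right = Cell(
        id=state.new_id(), parent_id=cell.id, compartments=right_comps,
        polar_old=right_old_pole, polar_new=right_new_pole, np_sites=right_np,
        L0=right_len, born_at=t, length=right_len, last_division_kind="none",
    )
    del state.cells[cell.id]
    state.add_cell(left)
    state.add_cell(right)
    for daughter, pole in ((left, left_new_pole), (right, right_new_pole)):
        _arm_new_pole(daughter, [pole], state, rng, config)


def _arm_new_pole(
    cell: Cell,
    new_poles: List[DivisionSite],
    state: SimState,
    rng: np.random.Generator,
    config: SimConfig,
) -> None:
    """Activate or lottery a freshly formed pole depending on model/strain."""
    from .segregation import rerandomize_blocking

    params = config.dist_params
    mv = config.model_variant
    strain = config.strain
    if strain == "WT":
        return  # poles never active in WT (Min suppression)
    if mv == 1:
        for pole in new_poles:
            pole.t_w = assign_waiting_time(pole.kind, mv, strain, rng, params)
            pole.s = 0.0
            pole.appeared_at = state.t
        return
    # models 2-4: the new pole is a new potential site -> re-randomise the
    # cell's blocked sites together with it.
    rerandomize_blocking(cell, state, rng, config, new_pole_candidates=new_poles)
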