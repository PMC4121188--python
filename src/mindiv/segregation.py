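"""Chromosome segregation, division-site creation, and the blocking defect.

When the chromosomes of a compartment finish replication they are
duplicated and the boundary between them becomes a potential division
site.  In model 1 (and in WT, which has no segregation defect) every
such boundary segregates immediately, splitting the compartment in two
with noisy midpoint placement.  In models 2-4 (minB-) the segregation
defect is modelled as effective blocking: whenever a new potential site
appears in a cell, fresh uniform marks are assigned to the new site(s)
and to every currently blocked site (chromosome boundaries and poles
alike), and sites whose mark exceeds the threshold

    p_th = max(0, 1 - n_block_target / n_randomized)

stay blocked, so that on average ``n_block_target`` sites per cell are
blocked.  Chromosomes do not segregate at a blocked boundary - the
flanking chromosomes remain one unsplit compartment - and a blocked
pole cannot start septum formation.
"""
from __future__ import annotations

from typing import List, Optional, Sequence, Set

import numpy as np

from .division import assign_doubling_time, assign_waiting_time
from .params import DistParams, SimConfig
from .state import NONPOLAR, Cell, Compartment, DivisionSite, SimState

_MAX_RESAMPLE = 10_000


class PlacementError(RuntimeError):
    """Placement noise incompatible with the 10% deviation cap."""


def block_threshold(n_randomized: int, n_block_target: float) -> float:
    """Uniform-mark threshold keeping ``n_block_target`` sites blocked on average.

    ``n_randomized`` fresh uniform marks compared against the returned
    ``p_th`` leave an expected ``min(n_block_target, n_randomized)``
    marks above it (blocked).
    """
    if n_randomized < 1:
        raise ValueError(f"need at least one randomized site, got {n_randomized}")
    if n_block_target < 0:
        raise ValueError(f"blocking target must be >= 0, got {n_block_target}")
    return max(0.0, 1.0 - n_block_target / n_randomized)


def _bounded_noise(rng: np.random.Generator, sd: float, cap: float) -> float:
    """Placement-noise draw resampled until within ``[-cap, cap]``."""
    if sd == 0.0:
        return 0.0
    for _ in range(_MAX_RESAMPLE):
        d = rng.normal(0.0, sd)
        if abs(d) <= cap:
            return d
    raise PlacementError(
        f"placement noise sd={sd} rejected {_MAX_RESAMPLE} times at cap {cap}; "
        "delta_sd is too large for the 10% deviation rule"
    )


def split_lengths(
    L_parent: float, rng: np.random.Generator, params: DistParams
) -> tuple:
    """Split a compartment at its noisy midpoint.

    One daughter gets ``L_parent/2 + delta`` with ``delta`` drawn from
    ``normal(0, delta_sd)`` and resampled until the daughter deviates at
    most 10% from half the parent length; lengths are conserved exactly.
    """
    if L_parent <= 0:
        raise ValueError(f"parent length must be positive, got {L_parent}")
    half = 0.5 * L_parent
    delta = _bounded_noise(rng, params.delta_sd, 0.1 * half)
    L1 = half + delta
    return L1, L_parent - L1


def _multiway_lengths(
    L: float,
    group_sizes: Sequence[int],
    rng: np.random.Generator,
    params: DistParams,
) -> List[float]:
    """Noisy lengths for splitting ``L`` among chromosome groups.

    Sequential cuts proportional to chromosome counts; each cut's noise
    is capped at 10% of the smaller nominal side, so the two-group case
    reduces exactly to :func:`split_lengths`.
    """
    lengths: List[float] = []
    remaining_L = L
    remaining_n = sum(group_sizes)
    for g in group_sizes[:-1]:
        nominal = remaining_L * g / remaining_n
        cap = 0.1 * min(nominal, remaining_L - nominal)
        piece = nominal + _bounded_noise(rng, params.delta_sd, cap)
        lengths.append(piece)
        remaining_L -= piece
        remaining_n -= g
    lengths.append(remaining_L)
    return lengths


def _reset_compartment(
    comp: Compartment, rng: np.random.Generator, params: DistParams, shared_Td: bool
) -> None:
    """Start a new round of growth/replication for a compartment.

    A fresh doubling time is assigned upon initiation of each new round;
    the replication timer is the time needed to double the current
    length (replication finishes when the compartment has doubled).
    """
    comp.Td = assign_doubling_time(rng, params, shared=shared_Td)
    comp.tau = 0.0
    comp.L_start = comp.length
    comp.T_seg = comp.Td
    comp._gf_dt = -1.0


def _new_compartment(
    length: float,
    n_chrom: int,
    rng: np.random.Generator,
    params: DistParams,
    shared_Td: bool,
) -> Compartment:
    Td = assign_doubling_time(rng, params, shared=shared_Td)
    return Compartment(
        length=length, Td=Td, tau=0.0, T_seg=Td, L_start=length, n_chrom=n_chrom
    )


def rerandomize_blocking(
    cell: Cell,
    state: SimState,
    rng: np.random.Generator,
    config: SimConfig,
    new_pole_candidates: Sequence[DivisionSite] = (),
    dirty: Optional[Set[int]] = None,
) -> List[DivisionSite]:
    """Run the blocking lottery over one cell and segregate what unblocks.

    Candidates are every unsegregated chromosome boundary (the blocked
    and the newly created ones are indistinguishable once marks are
    redrawn) plus every blocked or newly formed pole.  Returns the
    non-polar sites created by segregation.  ``dirty`` marks compartment
    indices that just completed a replication round and must start a new
    one even if nothing unblocks.
    """
    params = config.dist_params
    dirty = dirty or set()

    n_boundaries = sum(c.n_chrom - 1 for c in cell.compartments)
    poles = [
        p
        for p in (cell.polar_old, cell.polar_new)
        if p.blocked or any(p is q for q in new_pole_candidates)
    ]
    n_rand = n_boundaries + len(poles)
    if n_rand == 0:
        for idx in dirty:
            _reset_compartment(cell.compartments[idx], rng, params, config.shared_Td)
        return []
    p_th = block_threshold(n_rand, params.n_block_target)

    new_sites = _segregate_boundaries(cell, state, rng, config, p_th, dirty)

    for pole in poles:
        u = float(rng.random())
        pole.p_rand = u
        if u > p_th:
            pole.blocked = True
            pole.t_w = float("nan")
            pole.s = 0.0
            pole.appeared_at = float("nan")
        else:
            pole.blocked = False
            if not pole.active:
                pole.t_w = assign_waiting_time(
                    pole.kind, config.model_variant, config.strain, rng, params
                )
                pole.s = 0.0
                pole.appeared_at = state.t
    return new_sites


def _segregate_boundaries(
    cell: Cell,
    state: SimState,
    rng: np.random.Generator,
    config: SimConfig,
    p_th: float,
    dirty: Set[int],
) -> List[DivisionSite]:
    """Split compartments at boundaries whose fresh mark stays below ``p_th``.

    With ``p_th = 1`` every boundary segregates (model 1 / WT path,
    where no marks are meaningful but the geometry is identical).
    """
    params = config.dist_params
    draw_marks = p_th < 1.0
    new_comps: List[Compartment] = []
    new_np: List[DivisionSite] = []
    new_sites: List[DivisionSite] = []
    t = state.t

    for idx, comp in enumerate(cell.compartments):
        if idx > 0:
            new_np.append(cell.np_sites[idx - 1])
        m = comp.n_chrom
        if m == 1:
            if idx in dirty:
                _reset_compartment(comp, rng, params, config.shared_Td)
            new_comps.append(comp)
            continue
        if draw_marks:
            marks = rng.random(m - 1)
            open_boundaries = [j for j in range(m - 1) if marks[j] <= p_th]
        else:
            open_boundaries = list(range(m - 1))
        if not open_boundaries:
            if idx in dirty:
                _reset_compartment(comp, rng, params, config.shared_Td)
            new_comps.append(comp)
            continue
        # chromosome group sizes between open boundaries
        groups: List[int] = []
        prev = -1
        for j in open_boundaries:
            groups.append(j - prev)
            prev = j
        groups.append(m - 1 - prev)
        lengths = _multiway_lengths(comp.length, groups, rng, params)
        pieces = [
            _new_compartment(L, g, rng, params, config.shared_Td)
            for L, g in zip(lengths, groups)
        ]
        new_comps.append(pieces[0])
        for piece in pieces[1:]:
            site = DivisionSite(NONPOLAR, formed_at=t, appeared_at=t)
            site.t_w = assign_waiting_time(
                NONPOLAR, config.model_variant, config.strain, rng, params
            )
            new_np.append(site)
            new_sites.append(site)
            new_comps.append(piece)

    cell.compartments = new_comps
    cell.np_sites = new_np
    for _ in new_sites:
        state.event_log.append(
            t, "segregation", cell.id, cell.parent_id, NONPOLAR,
            cell.length, len(new_comps),
        )
    return new_sites


def segregate(
    cell: Cell,
    state: SimState,
    rng: np.random.Generator,
    config: SimConfig,
) -> List[DivisionSite]:
    """Process every replication-complete compartment of one cell.

    Chromosomes whose timer reached zero are duplicated; in model 1 and
    in WT every resulting boundary segregates, in models 2-4 (minB-) the
    blocking lottery decides.  Returns the newly created non-polar
    division sites.
    """
    dirty: Set[int] = set()
    for idx, comp in enumerate(cell.compartments):
        if comp.T_seg <= 0.0:
            comp.n_chrom *= 2
            dirty.add(idx)
    if not dirty:
        return []
    if config.strain == "WT" or config.model_variant == 1:
        return _segregate_boundaries(cell, state, rng, config, 1.0, dirty)
    return rerandomize_blocking(cell, state, rng, config, dirty=dirty)
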