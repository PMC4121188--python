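"""Exponential single-cell growth and chromosome-replication timers.

Single cells (and compartments) grow exponentially: a compartment of
starting length ``L_start`` and doubling time ``Td`` has length
``L_start * 2**(tau/Td)`` at age ``tau``, so over one time step it gains

    dL = L_start * (2**((tau+dt)/Td) - 2**(tau/Td)).

Chromosome replication is tied to growth: a fresh chromosome in a
compartment that must grow from ``L_start`` to ``L_end`` before it is
fully replicated gets the travel time ``T_seg = Td * log2(L_end/L_start)``,
which is counted down every step.
"""
from __future__ import annotations

import math
from typing import List

from .state import Cell, SimState


def length_increment(L0: float, Td: float, tau: float, dt: float) -> float:
    """Length gained over ``[tau, tau+dt]`` by an exponentially growing cell.

    ``L0`` is the length at birth (``tau = 0``).  Applying the increment
    cumulatively from age 0 to ``Td`` exactly doubles the length.
    """
    if Td <= 0:
        raise ValueError(f"doubling time must be positive, got {Td}")
    if dt < 0:
        raise ValueError(f"time step must be non-negative, got {dt}")
    if L0 <= 0:
        raise ValueError(f"birth length must be positive, got {L0}")
    if tau < 0:
        raise ValueError(f"age must be non-negative, got {tau}")
    return L0 * (2.0 ** ((tau + dt) / Td) - 2.0 ** (tau / Td))


def replication_time(L_start: float, L_end: float, Td: float) -> float:
    """Replication/segregation-readiness timer for a fresh chromosome.

    Equals the time an exponentially growing compartment needs to go
    from ``L_start`` to ``L_end``.
    """
    if Td <= 0:
        raise ValueError(f"doubling time must be positive, got {Td}")
    if L_start <= 0:
        raise ValueError(f"starting length must be positive, got {L_start}")
    if L_end < L_start:
        raise ValueError(
            f"ending length {L_end} smaller than starting length {L_start}"
        )
    return Td * math.log2(L_end / L_start)


def grow_and_tick(state: SimState, dt: float) -> List[Cell]:
    """Advance every compartment by one step; return replication-complete cells.

    Each compartment's length is multiplied by ``2**(dt/Td)`` (the exact
    closed form of :func:`length_increment` given the current length),
    its age advanced, and its replication timer reduced (floored at 0).
    Cells holding at least one compartment whose timer reached zero are
    returned so the segregation stage can process them.
    """
    if dt < 0:
        raise ValueError(f"time step must be non-negative, got {dt}")
    ready: List[Cell] = []
    if dt == 0:
        return ready
    for cell in state.cells.values():
        total = 0.0
        cell_ready = False
        for comp in cell.compartments:
            if comp._gf_dt != dt:
                comp._gf = 2.0 ** (dt / comp.Td)
                comp._gf_dt = dt
            comp.length *= comp._gf
            comp.tau += dt
            if comp.T_seg > 0.0:
                comp.T_seg -= dt
                if comp.T_seg < 1e-9:
                    comp.T_seg = 0.0
            if comp.T_seg == 0.0:
                cell_ready = True
            total += comp.length
        cell.length = total
        if cell_ready:
            ready.append(cell)
    return ready
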