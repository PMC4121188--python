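"""Simulation state: compartments, division sites, cells, event log.

A cell is an ordered sequence of compartments (old pole -> new pole).
Each compartment carries ``n_chrom`` chromosomes; the ``n_chrom - 1``
internal boundaries are exactly the *blocked* potential division sites
of that compartment (a boundary where segregation has not happened keeps
its flanking chromosomes inside one compartment).  Unblocked non-polar
sites live between adjacent compartments, and the two poles are
potential division sites of their own (active only in minB- strains).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, List, Optional

import pandas as pd

POLAR_OLD = "polar_old"
POLAR_NEW = "polar_new"
NONPOLAR = "nonpolar"

NAN = float("nan")

EVENT_COLUMNS = [
    "t_min",
    "event",
    "cell_id",
    "parent_id",
    "site_class",
    "cell_length_nm",
    "n_compartments",
]

TRACKING_COLUMNS = [
    "cell_id",
    "parent_id",
    "birth_t",
    "division_t",
    "birth_length",
    "division_length",
    "division_class",
    "site_appeared_t",
    "n_clusters",
]


@dataclass(slots=True)
class Compartment:
    """A chromosome-containing cell segment; the unit of growth.

    ``T_seg`` is the remaining time until the chromosomes of this
    compartment are completely replicated and ready to segregate;
    ``tau`` is the age since the compartment was (re)initialised and
    ``L_start`` its length at that moment, so the current length is
    ``L_start * 2**(tau / Td)``.
    """

    length: float
    Td: float
    tau: float = 0.0
    T_seg: float = 0.0
    L_start: float = 0.0
    n_chrom: int = 1
    # cached per-step growth factor 2**(dt/Td); invalid while _gf_dt != dt
    _gf: float = 1.0
    _gf_dt: float = -1.0

    @property
    def n_blocked(self) -> int:
        return self.n_chrom - 1


@dataclass(slots=True)
class DivisionSite:
    """A potential division locus.

    ``formed_at`` is when the locus physically came into existence (pole
    formation, or chromosome segregation for non-polar sites);
    ``appeared_at`` is when it became an *active* site with an assigned
    waiting time ``t_w``.  For non-polar sites the two coincide; a polar
    site can spend time blocked between formation and activation, which
    is what makes the measured polar waiting time an emergent quantity.
    ``s`` is the accumulated divisional work; the site completes when
    ``s >= t_w``.
    """

    kind: str
    t_w: float = NAN
    s: float = 0.0
    blocked: bool = False
    p_rand: float = NAN
    formed_at: float = 0.0
    appeared_at: float = NAN

    @property
    def active(self) -> bool:
        return (not self.blocked) and self.t_w == self.t_w  # t_w not NaN


@dataclass(slots=True)
class Cell:
    id: int
    parent_id: int
    compartments: List[Compartment]
    polar_old: DivisionSite
    polar_new: DivisionSite
    np_sites: List[DivisionSite]  # one per inter-compartment boundary
    L0: float
    born_at: float
    length: float
    last_division_kind: str = "none"

    @property
    def sites(self) -> List[DivisionSite]:
        """All site objects in spatial order, old pole -> new pole."""
        return [self.polar_old, *self.np_sites, self.polar_new]

    @property
    def n_chromosomes(self) -> int:
        return sum(c.n_chrom for c in self.compartments)

    @property
    def n_blocked_boundaries(self) -> int:
        """Blocked chromosome-boundary sites (unsegregated boundaries)."""
        return sum(c.n_chrom - 1 for c in self.compartments)

    @property
    def n_blocked_sites(self) -> int:
        """All blocked potential division sites, poles included."""
        n = self.n_blocked_boundaries
        n += 1 if self.polar_old.blocked else 0
        n += 1 if self.polar_new.blocked else 0
        return n

    def active_sites(self, strain: str) -> List[DivisionSite]:
        """Active (unblocked, waiting-time-assigned) sites.

        In WT the Min oscillations suppress polar Z-ring assembly, so
        the poles never become active sites.
        """
        out = [s for s in self.np_sites if s.active]
        if strain == "minB":
            if self.polar_old.active:
                out.append(self.polar_old)
            if self.polar_new.active:
                out.append(self.polar_new)
        return out

    def sum_length(self) -> float:
        return sum(c.length for c in self.compartments)


class EventLog:
    """Append-only record of segregation, division and minicell events."""

    def __init__(self) -> None:
        self._rows: List[tuple] = []

    def append(
        self,
        t: float,
        event: str,
        cell_id: int,
        parent_id: int,
        site_class: str,
        cell_length_nm: float,
        n_compartments: int,
    ) -> None:
        self._rows.append(
            (t, event, cell_id, parent_id, site_class, cell_length_nm, n_compartments)
        )

    def __len__(self) -> int:
        return len(self._rows)

    def __iter__(self) -> Iterator[tuple]:
        return iter(self._rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows, columns=EVENT_COLUMNS)


@dataclass
class SimState:
    t: float = 0.0
    cells: "dict[int, Cell]" = field(default_factory=dict)
    minicell_count: int = 0
    event_log: EventLog = field(default_factory=EventLog)
    tracking_rows: List[tuple] = field(default_factory=list)
    next_id: int = 0

    def new_id(self) -> int:
        i = self.next_id
        self.next_id += 1
        return i

    def add_cell(self, cell: Cell) -> None:
        self.cells[cell.id] = cell

    def total_length(self) -> float:
        return sum(c.length for c in self.cells.values())

    def total_compartments(self) -> int:
        return sum(len(c.compartments) for c in self.cells.values())

    def tracking_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.tracking_rows, columns=TRACKING_COLUMNS)


def validate_state(state: SimState) -> List[str]:
    """Check every structural invariant; return human-readable violations.

    Reports rather than raises, so it can be used as a post-step audit.
    """
    out: List[str] = []
    if state.minicell_count < 0:
        out.append(f"minicell_count negative: {state.minicell_count}")
    for cell in state.cells.values():
        label = f"cell {cell.id}"
        if not cell.compartments:
            out.append(f"{label}: no compartments")
            continue
        total = cell.sum_length()
        if not math.isclose(cell.length, total, rel_tol=1e-6, abs_tol=1e-6):
            out.append(
                f"{label}: recorded length {cell.length:.6g} != "
                f"sum of compartments {total:.6g}"
            )
        n_np = len(cell.np_sites)
        n_comp = len(cell.compartments)
        if n_np != n_comp - 1:
            out.append(
                f"{label}: {n_np} non-polar sites for {n_comp} compartments "
                f"(expected {n_comp - 1})"
            )
        if cell.polar_old.kind != POLAR_OLD or cell.polar_new.kind != POLAR_NEW:
            out.append(f"{label}: polar site kinds inconsistent")
        for i, comp in enumerate(cell.compartments):
            if comp.length <= 0:
                out.append(f"{label}: compartment {i} non-positive length")
            if comp.T_seg < 0:
                out.append(f"{label}: compartment {i} negative T_seg")
            if comp.tau < 0:
                out.append(f"{label}: compartment {i} negative age")
            if comp.n_chrom < 1:
                out.append(f"{label}: compartment {i} without chromosome")
        for site in cell.sites:
            if site.s < 0:
                out.append(f"{label}: site with negative progression")
            if site.p_rand == site.p_rand and not (0.0 <= site.p_rand <= 1.0):
                out.append(f"{label}: site mark outside [0, 1]")
            if site.blocked and site.active:
                out.append(f"{label}: site both blocked and active")
    return out
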