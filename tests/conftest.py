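import numpy as np
import pytest

from mindiv import Cell, Compartment, DistParams, DivisionSite, SimConfig, SimState
from mindiv.state import NONPOLAR, POLAR_NEW, POLAR_OLD


@pytest.fixture
def params() -> DistParams:
    return DistParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_cell(
    comp_lengths,
    cell_id=0,
    Td=75.0,
    strain="minB",
    waiting=20.0,
    n_chroms=None,
    t=0.0,
):
    """Hand-built cell: one compartment per length, sites armed with `waiting`."""
    comps = []
    for i, L in enumerate(comp_lengths):
        n = 1 if n_chroms is None else n_chroms[i]
        comps.append(
            Compartment(length=L, Td=Td, tau=0.0, T_seg=Td, L_start=L, n_chrom=n)
        )
    np_sites = [
        DivisionSite(NONPOLAR, t_w=waiting, formed_at=t, appeared_at=t)
        for _ in range(len(comps) - 1)
    ]
    polar_old = DivisionSite(POLAR_OLD, formed_at=t)
    polar_new = DivisionSite(POLAR_NEW, formed_at=t)
    if strain == "minB":
        for pole in (polar_old, polar_new):
            pole.t_w = waiting
            pole.appeared_at = t
    length = sum(comp_lengths)
    return Cell(
        id=cell_id,
        parent_id=-1,
        compartments=comps,
        polar_old=polar_old,
        polar_new=polar_new,
        np_sites=np_sites,
        L0=length,
        born_at=t,
        length=length,
    )


def make_state(cells, t=0.0) -> SimState:
    state = SimState(t=t)
    for cell in cells:
        state.add_cell(cell)
    state.next_id = max((c.id for c in cells), default=-1) + 1
    return state
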