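"""Pseudo-experimental lineage records for testing the observables layer.

The generator emulates microscopy-derived single-cell tracking over a
finite observation window: exponentially growing lineages (doubling
times 75 +/- 15 min), per-class division waiting times with the
configured normal structure, placement noise within the 10% cap, and
chromosome-cluster counts depressed by the blocking level.  Events whose
division falls beyond the window are right-censored (dropped and
counted), reproducing the estimator bias a finite movie has.
"""
from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .division import positive_normal
from .params import DistParams
from .segregation import split_lengths
from .state import TRACKING_COLUMNS


def _waiting_params(params: DistParams, strain: str, kind: str) -> Tuple[float, float]:
    if strain == "WT":
        return params.w_wt_mean, params.w_wt_sd
    if kind == "nonpolar":
        return params.w_nonpolar_mean, params.w_nonpolar_sd
    return params.w_polar_mean, params.w_polar_sd


def generate_tracking(
    params: DistParams,
    n_cells: int,
    window_min: float,
    rng: np.random.Generator,
    strain: str = "WT",
    polar_fraction: Optional[float] = None,
    censor: bool = True,
    cluster_noise_sd: float = 0.25,
) -> Tuple[pd.DataFrame, int]:
    """Generate a tracking table for ``n_cells`` founder lineages.

    Each founder is observed from t=0; a division site appears one
    doubling time after birth (growth and replication in synchrony) and
    divides after a class-specific waiting time.  ``polar_fraction`` is
    the probability that an event is polar (default: 0 for WT, the
    observed 77/177 polar share for minB-).  Returns the table and the
    number of right-censored (dropped) events.
    """
    if n_cells < 1:
        raise ValueError(f"n_cells must be >= 1, got {n_cells}")
    if polar_fraction is None:
        polar_fraction = 0.0 if strain == "WT" else 77.0 / 177.0
    blocked = params.n_block_target if strain == "minB" else 0.0

    rows: List[tuple] = []
    censored = 0
    next_id = n_cells

    # stack of (cell_id, parent_id, birth_t, birth_len, Td, t_prev_site)
    stack: List[tuple] = [
        (
            i,
            -1,
            0.0,
            positive_normal(rng, params.L0_mean, params.L0_sd),
            positive_normal(rng, params.Td_mean, params.Td_sd),
            None,
        )
        for i in range(n_cells)
    ]
    stack.reverse()

    while stack:
        cell_id, parent_id, birth_t, birth_len, Td, t_prev = stack.pop()
        t_site = (birth_t if t_prev is None else t_prev) + Td
        if t_site >= window_min:
            continue
        is_polar = rng.random() < polar_fraction
        kind = (
            ("polar_old" if rng.random() < 0.5 else "polar_new")
            if is_polar
            else "nonpolar"
        )
        mean, sd = _waiting_params(params, strain, kind)
        w = rng.normal(mean, sd) if sd > 0 else mean
        division_t = t_site + w
        if division_t < birth_t:
            division_t = birth_t  # waiting drawn deep in the negative tail
        if censor and division_t >= window_min:
            censored += 1
            continue
        division_len = birth_len * 2.0 ** ((division_t - birth_t) / Td)
        n_exp = division_len / params.L0_mean
        n_clusters = int(
            round(max(0.0, n_exp - blocked + rng.normal(0.0, cluster_noise_sd)))
        )
        rows.append(
            (
                cell_id,
                parent_id,
                birth_t,
                division_t,
                birth_len,
                division_len,
                kind,
                t_site,
                n_clusters,
            )
        )
        if is_polar:
            # minicell: the tracked cell continues; next site appears one
            # replication round after the previous one
            stack.append((cell_id, parent_id, birth_t, birth_len, Td, t_site))
        else:
            L1, L2 = split_lengths(division_len, rng, params)
            for L_child in (L1, L2):
                stack.append(
                    (
                        next_id,
                        cell_id,
                        division_t,
                        L_child,
                        positive_normal(rng, params.Td_mean, params.Td_sd),
                        None,
                    )
                )
                next_id += 1

    table = pd.DataFrame(rows, columns=TRACKING_COLUMNS)
    table = table.sort_values("division_t", kind="stable").reset_index(drop=True)
    return table, censored


def generate_cluster_pairs(
    n: int,
    offset: float,
    noise_sd: float,
    rng: np.random.Generator,
    nexp_low: float = 2.5,
    nexp_high: float = 8.0,
) -> pd.DataFrame:
    """Expected/observed cluster-number pairs with a known injected offset.

    ``N_obs = N_exp - offset + normal(0, noise_sd)`` with ``N_exp``
    uniform on ``[nexp_low, nexp_high]`` - the synthetic analogue of the
    cluster-count regression used to quantify the blocking level.
    """
    if n < 2:
        raise ValueError(f"need at least 2 pairs, got {n}")
    n_exp = rng.uniform(nexp_low, nexp_high, size=n)
    n_obs = n_exp - offset + rng.normal(0.0, noise_sd, size=n)
    return pd.DataFrame({"n_exp": n_exp, "n_obs": n_obs})


def generate_snapshot(
    params: DistParams,
    n_cells: int,
    rng: np.random.Generator,
    components: Tuple[Tuple[float, float, float], ...] = (
        (0.7, 3500.0, 900.0),
        (0.3, 7500.0, 2500.0),
    ),
    minicell_fraction: float = 0.0,
) -> pd.DataFrame:
    """Population snapshot with lengths from a normal mixture.

    The default two-component mixture emulates the broad minB- length
    distribution with its filamentous tail.  ``minicell_fraction`` adds
    chromosome-free rows (length set to a nominal 300 nm).
    """
    if n_cells < 1:
        raise ValueError(f"n_cells must be >= 1, got {n_cells}")
    weights = np.array([w for w, _, _ in components], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("mixture weights must sum to a positive value")
    weights = weights / weights.sum()
    comp_idx = rng.choice(len(components), size=n_cells, p=weights)
    lengths = np.array(
        [
            positive_normal(rng, components[i][1], components[i][2])
            for i in comp_idx
        ]
    )
    n_chrom = np.maximum(
        1, np.round(lengths / params.L0_mean - params.n_block_target)
    ).astype(int)
    is_mini = rng.random(n_cells) < minicell_fraction
    lengths = np.where(is_mini, 300.0, lengths)
    n_chrom = np.where(is_mini, 0, n_chrom)
    n_sites = np.maximum(0, n_chrom - 1)
    return pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "parent_id": -1,
            "born_at": 0.0,
            "length_nm": lengths,
            "birth_length_nm": lengths,
            "n_compartments": n_chrom,
            "n_chromosomes": n_chrom,
            "n_blocked_sites": 0,
            "n_active_sites": n_sites,
        }
    )
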