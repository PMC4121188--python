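"""Statistics comparing simulated populations with lineage-tracking data.

All operations consume either simulator output (tracking tables, event
logs, snapshots, the per-step time series) or externally supplied
tracking tables with the same columns, so measured and simulated data
go through identical code paths.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

HISTORY_CATEGORIES = [
    ("polar", "old_pole"),
    ("polar", "nonpolar"),
    ("polar", "new_pole"),
    ("nonpolar", "polar"),
    ("nonpolar", "nonpolar"),
]


@dataclass
class DistributionSummary:
    """Histogram plus summary moments of one observable."""

    counts: np.ndarray
    bin_edges: np.ndarray
    mean: float
    sd: float
    n: int
    empty: bool = False

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _summarize(values: np.ndarray, bin_width: float) -> DistributionSummary:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return DistributionSummary(
            counts=np.zeros(0, dtype=int),
            bin_edges=np.zeros(1),
            mean=float("nan"),
            sd=float("nan"),
            n=0,
            empty=True,
        )
    lo = min(0.0, np.floor(values.min() / bin_width) * bin_width)
    hi = np.ceil(values.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    return DistributionSummary(
        counts=counts,
        bin_edges=edges,
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if values.size > 1 else 0.0,
        n=int(values.size),
    )


def _class_mask(classes: pd.Series, site_class: Optional[str]) -> pd.Series:
    if site_class is None:
        return classes != "none"
    if site_class == "polar":
        return classes.str.startswith("polar")
    return classes == site_class


def waiting_time_distribution(
    table: pd.DataFrame,
    site_class: Optional[str] = None,
    bin_width: float = 5.0,
) -> DistributionSummary:
    """Division waiting times: division time minus site-appearance time.

    For non-polar sites the appearance is the first visible chromosome
    separation; for polar sites it is the formation of the pole, so a
    period spent blocked lengthens the measured (emergent) waiting time.
    ``site_class`` may be ``"nonpolar"``, ``"polar"`` (both pole kinds),
    an exact kind, or ``None`` for all division events.
    """
    mask = _class_mask(table["division_class"], site_class)
    waits = (
        table.loc[mask, "division_t"] - table.loc[mask, "site_appeared_t"]
    ).to_numpy(dtype=float)
    out = _summarize(waits, bin_width)
    if out.empty:
        warnings.warn(f"no division events for class {site_class!r}")
    return out


def interdivision_distribution(
    table: pd.DataFrame, bin_width: float = 5.0
) -> DistributionSummary:
    """Time between a cell's birth and its own division."""
    waits = (table["division_t"] - table["birth_t"]).to_numpy(dtype=float)
    return _summarize(waits, bin_width)


def length_distribution(
    snapshot: pd.DataFrame, bins: int | Sequence[float] = 30
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Histogram and empirical CDF of cell lengths in one snapshot.

    Minicells (zero-chromosome rows) are excluded.  Returns
    ``(counts, bin_edges, sorted_lengths, cdf)`` with a right-continuous
    CDF reaching exactly 1.
    """
    if snapshot.empty:
        raise ValueError("empty snapshot")
    lengths = snapshot["length_nm"]
    if "n_chromosomes" in snapshot.columns:
        lengths = lengths[snapshot["n_chromosomes"] > 0]
    lengths = np.sort(lengths.to_numpy(dtype=float))
    counts, edges = np.histogram(lengths, bins=bins)
    cdf = np.arange(1, lengths.size + 1) / lengths.size
    return counts, edges, lengths, cdf


def classify_division_history(
    table: pd.DataFrame, window: Optional[float] = None
) -> Tuple[pd.DataFrame, int]:
    """Classify successive division pairs into the five history types.

    The first event of a pair is the division that produced (or, for
    polar events, preceded on the same cell) the second; the second is
    classified by its position: at the daughter's old pole, at its new
    pole, or non-polar.  After a non-polar first division the two pole
    identities are pooled into a single "polar" category.  Returns the
    5-row table (counts, percentage within each first-event row, and the
    mean +/- SD inter-event time) plus the number of orphan events (no
    linkable predecessor).
    """
    df = table.copy()
    if window is not None:
        df = df[df["division_t"] <= window]
    df = df.sort_values("division_t", kind="stable").reset_index(drop=True)

    pairs: List[Tuple[str, str, float]] = []
    orphans = 0
    last_event: dict = {}  # cell_id -> (class, division_t)
    for row in df.itertuples(index=False):
        prev = last_event.get(row.cell_id)
        if prev is None and row.parent_id >= 0:
            prev = last_event.get(row.parent_id)
            # only a non-polar parent division creates a new cell
            if prev is not None and not prev[0] == "nonpolar":
                prev = None
        if prev is None:
            orphans += 1
        else:
            first = "nonpolar" if prev[0] == "nonpolar" else "polar"
            if row.division_class == "nonpolar":
                second = "nonpolar"
            elif first == "nonpolar":
                second = "polar"
            elif row.division_class == "polar_old":
                second = "old_pole"
            else:
                second = "new_pole"
            pairs.append((first, second, row.division_t - prev[1]))
        last_event[row.cell_id] = (row.division_class if row.division_class == "nonpolar" else "polar", row.division_t)

    rows = []
    pair_arr = pd.DataFrame(pairs, columns=["first", "second", "dt"])
    for first, second in HISTORY_CATEGORIES:
        sel = pair_arr[(pair_arr["first"] == first) & (pair_arr["second"] == second)]
        n_first = int((pair_arr["first"] == first).sum())
        rows.append(
            (
                first,
                second,
                len(sel),
                100.0 * len(sel) / n_first if n_first else 0.0,
                float(sel["dt"].mean()) if len(sel) else float("nan"),
                float(sel["dt"].std(ddof=1)) if len(sel) > 1 else float("nan"),
            )
        )
    history = pd.DataFrame(
        rows, columns=["first", "second", "n", "pct", "dt_mean", "dt_sd"]
    )
    return history, orphans


def sites_per_length(
    snapshots: Iterable[Tuple[float, pd.DataFrame]]
) -> pd.DataFrame:
    """Active division sites per unit chromosome-containing length over time."""
    rows = []
    for t, snap in snapshots:
        if snap.empty:
            rows.append((t, float("nan")))
            continue
        live = snap
        if "n_chromosomes" in snap.columns:
            live = snap[snap["n_chromosomes"] > 0]
        total_len = float(live["length_nm"].sum())
        n_sites = float(live["n_active_sites"].sum())
        rows.append((t, n_sites / total_len if total_len > 0 else float("nan")))
    return pd.DataFrame(rows, columns=["t_min", "sites_per_nm"])


def expected_cluster_number(L, L0: float):
    """Expected chromosome-cluster count for a cell of length ``L``.

    ``N_exp = L / L0`` with ``L0`` the newborn reference length; values
    below 1 (cells shorter than the reference) trigger a warning but are
    returned as-is.
    """
    if L0 <= 0:
        raise ValueError(f"reference length must be positive, got {L0}")
    L_arr = np.asarray(L, dtype=float)
    out = L_arr / L0
    if np.any(out < 1.0):
        warnings.warn("expected cluster number below 1 for some lengths")
    if np.isscalar(L) or L_arr.ndim == 0:
        return float(out)
    return out


def fit_cluster_offset(n_exp, n_obs) -> float:
    """Fixed-slope least squares of observed on expected cluster numbers.

    Fits ``N_obs = N_exp - b``; with unit slope the least-squares
    solution is exactly the mean residual ``b = mean(N_exp - N_obs)``.
    The fitted ``b`` estimates the average number of potential division
    sites at which segregation did not occur (blocked sites).
    """
    n_exp = np.asarray(n_exp, dtype=float)
    n_obs = np.asarray(n_obs, dtype=float)
    if n_exp.shape != n_obs.shape:
        raise ValueError("expected and observed arrays must have equal shape")
    if n_exp.size < 2:
        raise ValueError(f"need at least 2 pairs, got {n_exp.size}")
    return float(np.mean(n_exp - n_obs))


def bulk_doubling_time(
    timeseries: pd.DataFrame, t_start: float, t_end: Optional[float] = None
) -> float:
    """Culture doubling time from the total-length time series.

    Linear fit of ``log2(total length)`` against time over
    ``[t_start, t_end]``; the doubling time is the inverse slope.
    """
    ts = timeseries
    if t_end is None:
        t_end = float(ts["t_min"].max())
    sel = ts[(ts["t_min"] >= t_start) & (ts["t_min"] <= t_end)]
    if len(sel) < 2:
        raise ValueError("need at least two time points in the fit window")
    t = sel["t_min"].to_numpy(dtype=float)
    y = np.log2(sel["total_length_nm"].to_numpy(dtype=float))
    slope = np.polyfit(t, y, 1)[0]
    return 1.0 / slope
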