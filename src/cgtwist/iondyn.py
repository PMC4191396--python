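"""Ion occupancy, residence-time and multi-ion statistics for a groove region.

Mirrors the per-region bookkeeping of minor-groove cation dynamics: the
occupancy is the fraction of snapshots with at least one ion in the region,
the residence time is the mean length of maximal per-ion runs of
consecutive in-region snapshots (1 ps cadence, no gap tolerance -- a single
snapshot outside the region ends a run), and entry/exit transitions are
counted per ion.  Runs truncated by the ends of the series are included in
the mean (negligible bias when the series is much longer than the mean
residence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .helimap import RegionSpec, assign_region

__all__ = ["OccupancyStats", "MultiIonFractions", "occupancy_stats",
           "multi_ion_fractions", "runs_of_ones"]


@dataclass(frozen=True)
class MultiIonFractions:
    """Fractions of occupied snapshots holding exactly 1, 2 or >=3 ions."""

    f1: float
    f2: float
    f3plus: float
    n_occupied: int
    undefined: bool = False

    def __iter__(self):
        return iter((self.f1, self.f2, self.f3plus))


@dataclass(frozen=True)
class OccupancyStats:
    """Region occupancy and residence statistics at 1 ps sampling."""

    occupancy: float
    mean_residence_ps: float
    residence_ps: np.ndarray
    n_runs: int
    n_entries: int
    n_exits: int
    transitions: int
    multi_ion: MultiIonFractions
    n_snapshots: int
    dt_ps: float = 1.0

    @property
    def occupancy_percent(self) -> float:
        return 100.0 * self.occupancy


def runs_of_ones(mask: np.ndarray):
    """(start, length) pairs of the maximal runs of True in a boolean array."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return np.empty((0, 2), dtype=int)
    padded = np.concatenate(([False], mask, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return np.column_stack([starts, ends - starts])


def _in_region_table(records, spec, region):
    labels = assign_region(records, spec)
    return records.loc[labels == region, ["snapshot", "ion_id"]]


def occupancy_stats(
    records: pd.DataFrame,
    spec: RegionSpec,
    n_snapshots: int,
    *,
    region: str = "inner_minor",
    dt_ps: float = 1.0,
) -> OccupancyStats:
    """Occupancy, residence and transition statistics for one region.

    ``records`` is a curvilinear ion-record stream (one row per ion per
    snapshot); snapshots are assumed uniformly sampled every ``dt_ps``.
    Raises ``ValueError`` if any record's snapshot index is inconsistent
    with ``n_snapshots``.
    """
    snaps = records["snapshot"].to_numpy()
    if len(snaps) and (snaps.min() < 0 or snaps.max() >= n_snapshots):
        raise ValueError(
            f"record snapshot index {snaps.min() if snaps.min() < 0 else snaps.max()} "
            f"inconsistent with n_snapshots={n_snapshots}"
        )
    sub = _in_region_table(records, spec, region).drop_duplicates()

    counts = np.zeros(n_snapshots, dtype=int)
    if len(sub):
        uniq, c = np.unique(sub["snapshot"].to_numpy(), return_counts=True)
        counts[uniq] = c
    occupied = counts > 0
    occupancy = float(occupied.mean())

    run_lengths = []
    n_entries = n_exits = 0
    for _, ion_sub in sub.groupby("ion_id"):
        s = np.sort(ion_sub["snapshot"].to_numpy())
        breaks = np.nonzero(np.diff(s) > 1)[0]
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(s) - 1]))
        for a, b in zip(starts, ends):
            run_lengths.append(b - a + 1)
            if s[a] > 0:
                n_entries += 1
            if s[b] < n_snapshots - 1:
                n_exits += 1
    residence = np.asarray(run_lengths, dtype=float) * dt_ps
    mean_res = float(residence.mean()) if residence.size else 0.0

    occ_counts = counts[occupied]
    if occ_counts.size:
        multi = MultiIonFractions(
            f1=float((occ_counts == 1).mean()),
            f2=float((occ_counts == 2).mean()),
            f3plus=float((occ_counts >= 3).mean()),
            n_occupied=int(occ_counts.size),
        )
    else:
        multi = MultiIonFractions(0.0, 0.0, 0.0, 0, undefined=True)

    return OccupancyStats(
        occupancy=occupancy,
        mean_residence_ps=mean_res,
        residence_ps=residence,
        n_runs=int(residence.size),
        n_entries=n_entries,
        n_exits=n_exits,
        transitions=n_entries + n_exits,
        multi_ion=multi,
        n_snapshots=int(n_snapshots),
        dt_ps=dt_ps,
    )


def multi_ion_fractions(
    records: pd.DataFrame, spec: RegionSpec, n_snapshots: int,
    *, region: str = "inner_minor",
) -> MultiIonFractions:
    """Fractions of occupied snapshots with exactly 1, 2 and >=3 ions.

    Normalized over occupied snapshots; with zero occupied snapshots the
    result is (0, 0, 0) with ``undefined=True`` rather than an error.
    """
    return occupancy_stats(records, spec, n_snapshots, region=region).multi_ion
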