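"""Event-aligned choreography of coupled backbone/ion/twist transitions.

The kinetic picture of CG-step polymorphism is built by detecting zeta
transitions (g-g- -> tt through a single intermediate), aligning arbitrary
per-snapshot observables on the completion time of each transition,
averaging over thousands of events, and reading off when each channel
departs from its baseline (e.g. the minor-groove ion population rises tens
of picoseconds before the zeta flip).

The ion-influence ratio statistic quantifies the same coupling without
event alignment: "states" with or without an ion in a region that last at
least 40 ps are collected, and the per-ps probability of the BII/BII (tt)
label during the last 20 ps of each state is compared between the
with-ion and without-ion classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .iondyn import runs_of_ones

__all__ = [
    "TransitionEvent",
    "EventAlignedProfile",
    "RegionRatio",
    "detect_transitions",
    "event_aligned_average",
    "onset_time",
    "ion_influence_ratio",
]


@dataclass(frozen=True)
class TransitionEvent:
    """One completed substate transition.

    ``index`` is the snapshot at which the target label is first reached;
    ``path`` is the intermediate label traversed (or "direct" for a
    double-flip, flagged); ``duration_ps`` is the dwell between leaving the
    source and reaching the target.
    """

    index: int
    source: str
    target: str
    path: str
    duration_ps: float
    direct: bool = False

    @property
    def direction(self) -> str:
        return f"{self.source}->{self.target}"


def _label_runs(joint):
    """Compress a label series into (label, start, length) runs."""
    joint = np.asarray(joint)
    change = np.nonzero(joint[1:] != joint[:-1])[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(joint)]))
    return [(joint[s], int(s), int(e - s)) for s, e in zip(starts, ends)]


def detect_transitions(
    states,
    source: str = "g-g-",
    target: str = "tt",
    max_path_len: float = 100.0,
    *,
    dt_ps: float = 1.0,
) -> list:
    """Detect source -> target transitions through at most one intermediate.

    An event is recorded at the first snapshot of a ``target`` run that was
    reached from ``source`` either directly (flagged, path "direct") or via
    a single run of one intermediate label whose dwell does not exceed
    ``max_path_len`` ps.  Overlapping candidates resolve to the earliest
    completion because runs are scanned in order.
    """
    if source == target:
        raise ValueError("source and target substates must differ")
    joint = states["joint"].to_numpy() if isinstance(states, pd.DataFrame) else np.asarray(states)
    runs = _label_runs(joint)
    events = []
    for i, (label, start, _length) in enumerate(runs):
        if label != target or i == 0:
            continue
        prev_label, prev_start, prev_len = runs[i - 1]
        if prev_label == source:
            events.append(
                TransitionEvent(index=start, source=source, target=target,
                                path="direct", duration_ps=0.0, direct=True)
            )
        elif i >= 2 and prev_label not in (source, target):
            before_label = runs[i - 2][0]
            dwell = prev_len * dt_ps
            if before_label == source and dwell <= max_path_len:
                events.append(
                    TransitionEvent(index=start, source=source, target=target,
                                    path=str(prev_label), duration_ps=dwell)
                )
    return events


@dataclass(frozen=True)
class EventAlignedProfile:
    """Observables averaged over events as a function of time-to-event.

    ``tau_ps`` runs from -window to 0 for a "before" profile (0 = flip
    completion); ``means``/``ses`` map channel name to per-tau mean and
    standard error over the contributing events.
    """

    tau_ps: np.ndarray
    means: dict
    ses: dict
    n_events: int
    n_dropped: int

    def channel(self, name: str) -> pd.DataFrame:
        return pd.DataFrame(
            {"tau_ps": self.tau_ps, "mean": self.means[name], "se": self.ses[name]}
        )


def event_aligned_average(
    events,
    observables: dict,
    window_ps: float = 250.0,
    direction: str = "before",
    *,
    dt_ps: float = 1.0,
) -> EventAlignedProfile:
    """Average observables over events on a relative-time grid.

    ``observables`` maps channel names to per-snapshot arrays.  For
    ``direction="before"`` the grid is tau in [-window, 0]; events without
    a full window inside the series are dropped and counted.  Raises
    ``ValueError`` when no usable events remain.
    """
    if direction not in ("before", "after"):
        raise ValueError("direction must be 'before' or 'after'")
    if not observables:
        raise ValueError("need at least one observable channel")
    n = len(next(iter(observables.values())))
    for name, arr in observables.items():
        if len(arr) != n:
            raise ValueError(f"observable {name!r} length {len(arr)} != {n}")
    w = int(round(window_ps / dt_ps))
    idx = np.asarray([ev.index for ev in events], dtype=int)
    if direction == "before":
        usable = idx - w >= 0
        offsets = np.arange(-w, 1)
    else:
        usable = idx + w <= n - 1
        offsets = np.arange(0, w + 1)
    kept = idx[usable]
    if kept.size == 0:
        raise ValueError("no events with a full window inside the series")
    gather = kept[:, None] + offsets[None, :]
    means, ses = {}, {}
    for name, arr in observables.items():
        block = np.asarray(arr, dtype=float)[gather]
        means[name] = block.mean(axis=0)
        if kept.size > 1:
            ses[name] = block.std(axis=0, ddof=1) / np.sqrt(kept.size)
        else:
            ses[name] = np.full(offsets.size, np.nan)
    return EventAlignedProfile(
        tau_ps=offsets * dt_ps,
        means=means,
        ses=ses,
        n_events=int(kept.size),
        n_dropped=int((~usable).sum()),
    )


def onset_time(
    profile: EventAlignedProfile,
    channel: str,
    baseline_window=(-250.0, -150.0),
    k_se: float = 3.0,
) -> float | None:
    """Lead time at which a channel departs from its pre-event baseline.

    The baseline mean and scatter (SD of the per-tau profile values inside
    ``baseline_window``) set a threshold baseline + k_se * SD; the onset is
    the earliest tau after the baseline window from which the channel mean
    exceeds the threshold continuously until tau = 0.  Returned as a
    positive lead time in ps, or ``None`` when the threshold is never
    exceeded in a sustained way ("no onset").
    """
    tau = profile.tau_ps
    y = np.asarray(profile.means[channel], dtype=float)
    lo, hi = baseline_window
    base = (tau >= lo) & (tau <= hi)
    if base.sum() < 2:
        raise ValueError("profile does not cover the baseline window")
    mu = y[base].mean()
    sd = y[base].std(ddof=1)
    threshold = mu + k_se * sd
    after = tau > hi
    # earliest tau > hi from which the channel stays above threshold to 0
    ok = np.where(after, y > threshold, False)
    if not ok.any():
        return None
    # suffix of consecutive True ending at the last grid point
    rev = ok[::-1]
    run = np.argmin(rev) if not rev.all() else rev.size
    if run == 0 or not ok[-1]:
        return None
    onset_idx = ok.size - run
    return float(-tau[onset_idx])


@dataclass(frozen=True)
class RegionRatio:
    """Ion-influence statistic for one region.

    ``p_with``/``p_without`` are per-ps probabilities of the tt (BII/BII)
    label during the last ``tail_ps`` of qualifying with-ion/without-ion
    states; ``ratio`` is their quotient (NaN when undefined).
    """

    p_with: float
    p_without: float
    ratio: float
    n_runs_with: int
    n_runs_without: int
    defined: bool


def ion_influence_ratio(
    presence_by_region: dict,
    states,
    min_state_ps: float = 40.0,
    tail_ps: float = 20.0,
    *,
    dt_ps: float = 1.0,
    mode: str = "per_ps",
) -> dict:
    """Influence of regional ion presence on the BII/BII probability.

    ``presence_by_region`` maps region names to aligned 0/1 presence
    series.  For each region, maximal runs of constant presence lasting at
    least ``min_state_ps`` are collected; within the last ``tail_ps``
    snapshots of each run the tt frequency is accumulated separately for
    present and absent runs.  ``mode="per_ps"`` pools tail snapshots
    (per-ps probability, the default reading); ``mode="per_state"``
    averages the tail frequency run by run.  Regions with no qualifying
    runs in a class are flagged ``defined=False``.
    """
    if mode not in ("per_ps", "per_state"):
        raise ValueError("mode must be 'per_ps' or 'per_state'")
    joint = states["joint"].to_numpy() if isinstance(states, pd.DataFrame) else np.asarray(states)
    is_tt = (joint == "tt").astype(float)
    min_len = int(round(min_state_ps / dt_ps))
    tail = int(round(tail_ps / dt_ps))
    out = {}
    for region, presence in presence_by_region.items():
        pres = np.asarray(presence).astype(bool)
        if len(pres) != len(joint):
            raise ValueError(
                f"presence series for {region!r} has length {len(pres)}, "
                f"states have {len(joint)}"
            )
        stats = {}
        for value, mask in ((1, pres), (0, ~pres)):
            runs = runs_of_ones(mask)
            runs = runs[runs[:, 1] >= min_len] if len(runs) else runs
            tt_counts, totals, per_run = [], [], []
            for start, length in runs:
                seg = is_tt[start + length - tail: start + length]
                tt_counts.append(seg.sum())
                totals.append(seg.size)
                per_run.append(seg.mean())
            if totals and sum(totals) > 0:
                if mode == "per_ps":
                    p = float(sum(tt_counts) / sum(totals))
                else:
                    p = float(np.mean(per_run))
            else:
                p = np.nan
            stats[value] = (p, len(runs))
        p1, n1 = stats[1]
        p0, n0 = stats[0]
        defined = n1 > 0 and n0 > 0 and np.isfinite(p0) and np.isfinite(p1) and p0 > 0
        out[region] = RegionRatio(
            p_with=p1,
            p_without=p0,
            ratio=p1 / p0 if defined else np.nan,
            n_runs_with=int(n1),
            n_runs_without=int(n0),
            defined=bool(defined),
        )
    return out
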