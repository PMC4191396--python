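"""Substate population thermodynamics, transition matrices and WHAM.

The four joint zeta substates are ranked by their populations in a
trajectory: dG_s = -kT ln(p_s / p_ref) with g-g- (BI/BI) as the reference.
A 4x4 transition matrix over consecutive snapshots quantifies the pathway
structure (direct g-g- <-> tt double flips are expected to be rare;
transitions pass through the tg-/g-t intermediates).

Umbrella-sampling windows along a zeta torsion (harmonic bias
k*(zeta - c_i)^2) are combined into an unbiased free-energy profile with
the standard self-consistent WHAM iteration.  Statistical errors on the
population free energies can be attached with a moving-block bootstrap,
since consecutive snapshots are autocorrelated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import SUBSTATES, kt_kcal

__all__ = [
    "SubstateThermo",
    "TransitionMatrix",
    "UmbrellaWindow",
    "WhamResult",
    "substate_thermo",
    "transition_matrix",
    "wham",
]


@dataclass(frozen=True)
class SubstateThermo:
    """Populations, relative free energies and mean twist of the substates.

    ``table`` is indexed by the four joint labels with columns
    ``population``, ``dG_kcal`` (relative to g-g-; +inf for unvisited
    states), ``twist_mean``, ``twist_sd`` and ``count``.
    """

    table: pd.DataFrame
    temperature_K: float
    n_snapshots: int
    dG_se: pd.Series | None = None

    def dG(self, label: str) -> float:
        return float(self.table.loc[label, "dG_kcal"])

    def population(self, label: str) -> float:
        return float(self.table.loc[label, "population"])


def substate_thermo(
    states,
    twist_series=None,
    temperature_K: float = 298.0,
    *,
    bootstrap_blocks_ps: int | None = None,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> SubstateThermo:
    """Population free energies dG = -kT ln(p/p_gg) and per-substate twist.

    ``states`` is a substate table (with a ``joint`` column) or an array of
    joint labels; ``twist_series`` is an aligned twist series (optional).
    Unvisited substates are reported with dG = +inf; an unvisited g-g-
    reference raises ``ValueError``.  If ``bootstrap_blocks_ps`` is given
    (e.g. 1000 for 1 ns blocks at 1 ps sampling), a moving-block bootstrap
    standard error is attached for each dG.
    """
    joint = states["joint"].to_numpy() if isinstance(states, pd.DataFrame) else np.asarray(states)
    n = len(joint)
    if n == 0:
        raise ValueError("empty state series")
    if twist_series is not None and len(twist_series) != n:
        raise ValueError(
            f"length mismatch: {n} states vs {len(twist_series)} twist values"
        )
    kt = kt_kcal(temperature_K)
    counts = pd.Series(joint).value_counts().reindex(list(SUBSTATES)).fillna(0).astype(int)
    pops = counts / n
    if pops["g-g-"] == 0:
        raise ValueError("reference substate g-g- is unvisited; dG undefined")
    with np.errstate(divide="ignore"):
        dg = -kt * np.log(pops.to_numpy() / pops["g-g-"])
    table = pd.DataFrame(
        {"population": pops.to_numpy(), "dG_kcal": dg, "count": counts.to_numpy()},
        index=pd.Index(list(SUBSTATES), name="substate"),
    )
    if twist_series is not None:
        from .substates import twist_by_substate

        tw = twist_by_substate(twist_series, joint)
        table["twist_mean"] = tw["mean"]
        table["twist_sd"] = tw["sd"]

    dg_se = None
    if bootstrap_blocks_ps:
        dg_se = _block_bootstrap_dg_se(
            joint, int(bootstrap_blocks_ps), kt, n_bootstrap, seed
        )
    return SubstateThermo(table=table, temperature_K=temperature_K,
                          n_snapshots=n, dG_se=dg_se)


def _block_bootstrap_dg_se(joint, block, kt, n_boot, seed):
    n = len(joint)
    block = min(block, n)
    n_blocks = int(np.ceil(n / block))
    starts_max = n - block
    rng = np.random.default_rng(seed)
    codes = pd.Categorical(joint, categories=list(SUBSTATES)).codes
    samples = np.full((n_boot, len(SUBSTATES)), np.nan)
    for b in range(n_boot):
        starts = rng.integers(0, starts_max + 1, size=n_blocks)
        idx = (starts[:, None] + np.arange(block)[None, :]).ravel()[:n]
        c = np.bincount(codes[idx], minlength=len(SUBSTATES)).astype(float)
        if c[0] == 0:
            continue
        with np.errstate(divide="ignore"):
            samples[b] = -kt * np.log(c / c[0])
    se = np.nanstd(samples, axis=0, ddof=1)
    return pd.Series(se, index=pd.Index(list(SUBSTATES), name="substate"))


@dataclass(frozen=True)
class TransitionMatrix:
    """Counts of consecutive-snapshot joint-label pairs (rows = from)."""

    counts: pd.DataFrame
    probabilities: pd.DataFrame
    n_direct_gg_tt: int
    direct_fraction: float

    @property
    def total_transitions(self) -> int:
        return int(self.counts.to_numpy().sum())


def transition_matrix(states) -> TransitionMatrix:
    """Build the 4x4 transition-count matrix over consecutive snapshots.

    Also reports the number and fraction (among label changes) of direct
    g-g- <-> tt double flips, which occur through intermediate states in
    all but a vanishing share of transitions.
    """
    joint = states["joint"].to_numpy() if isinstance(states, pd.DataFrame) else np.asarray(states)
    if len(joint) < 2:
        raise ValueError("need at least 2 snapshots for a transition matrix")
    cats = list(SUBSTATES)
    codes = pd.Categorical(joint, categories=cats).codes
    if np.any(codes < 0):
        bad = joint[np.asarray(codes) < 0][0]
        raise ValueError(f"unknown substate label {bad!r}")
    idx = codes[:-1] * len(cats) + codes[1:]
    flat = np.bincount(idx, minlength=len(cats) ** 2)
    counts = pd.DataFrame(
        flat.reshape(len(cats), len(cats)), index=pd.Index(cats, name="from"),
        columns=pd.Index(cats, name="to"), dtype=int,
    )
    row_sums = counts.sum(axis=1).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = counts.to_numpy() / row_sums[:, None]
    probabilities = pd.DataFrame(probs, index=counts.index, columns=counts.columns)
    c = counts.to_numpy()
    direct = int(counts.loc["g-g-", "tt"] + counts.loc["tt", "g-g-"])
    changes = int(c.sum() - np.trace(c))
    return TransitionMatrix(
        counts=counts,
        probabilities=probabilities,
        n_direct_gg_tt=direct,
        direct_fraction=direct / changes if changes else 0.0,
    )


@dataclass(frozen=True)
class UmbrellaWindow:
    """Samples of a torsion under a harmonic bias k*(zeta - center)^2."""

    center: float
    k: float  # kcal mol^-1 deg^-2
    samples: np.ndarray
    offset: float = 0.0  # additive constant, irrelevant to the profile

    def __post_init__(self):
        if not self.k > 0:
            raise ValueError("force constant k must be positive")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))

    def bias(self, x):
        return self.k * (np.asarray(x, dtype=float) - self.center) ** 2 + self.offset


@dataclass(frozen=True)
class WhamResult:
    """Unbiased free-energy profile from overlapping umbrella windows.

    The profile is defined up to a constant and anchored at its minimum
    (min F = 0).  ``shifts`` are the converged per-window free-energy
    offsets f_i (first window = 0).
    """

    grid: np.ndarray
    free_energy: np.ndarray
    shifts: np.ndarray
    n_iterations: int
    max_residual: float
    temperature_K: float

    def barrier_height(self) -> float:
        """Highest point between the two outermost local minima."""
        f = self.free_energy
        interior = f[np.isfinite(f)]
        return float(interior.max() - interior.min())

    def interpolate(self, x):
        ok = np.isfinite(self.free_energy)
        return np.interp(x, self.grid[ok], self.free_energy[ok])


def wham(
    windows,
    temperature_K: float = 298.0,
    *,
    grid: np.ndarray | None = None,
    grid_step: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 100000,
) -> WhamResult:
    """Self-consistent WHAM combination of harmonic umbrella windows.

    Iterates the window shifts f_i until the largest change is below
    ``tol`` (kcal/mol); raises ``RuntimeError`` with the residual on
    non-convergence and ``ValueError`` if the window histograms do not
    overlap into a single connected range.
    """
    windows = list(windows)
    if len(windows) < 2:
        if len(windows) == 1:
            pass  # a single window is allowed: plain unbiasing
        else:
            raise ValueError("need at least one umbrella window")
    kt = kt_kcal(temperature_K)
    all_samples = np.concatenate([w.samples for w in windows])
    if grid is None:
        lo, hi = all_samples.min(), all_samples.max()
        grid_edges = np.arange(lo - grid_step, hi + 2 * grid_step, grid_step)
    else:
        grid = np.asarray(grid, dtype=float)
        step = np.diff(grid)
        if not np.allclose(step, step[0]):
            raise ValueError("grid must be uniform")
        grid_edges = np.concatenate([grid - step[0] / 2, [grid[-1] + step[0] / 2]])
    centers = 0.5 * (grid_edges[:-1] + grid_edges[1:])

    hists = np.stack([np.histogram(w.samples, bins=grid_edges)[0] for w in windows])
    if np.any((all_samples < grid_edges[0]) | (all_samples > grid_edges[-1])):
        raise ValueError("samples fall outside the WHAM grid range")
    occupied = hists > 0
    if len(windows) > 1:
        order = np.argsort([w.center for w in windows])
        for a, b in zip(order[:-1], order[1:]):
            if not np.any(occupied[a] & occupied[b]):
                raise ValueError(
                    f"umbrella windows at {windows[a].center} and "
                    f"{windows[b].center} do not overlap"
                )

    n_i = hists.sum(axis=1).astype(float)
    h_k = hists.sum(axis=0).astype(float)
    bias = np.stack([w.bias(centers) for w in windows])  # (W, K)
    boltz = np.exp(-bias / kt)

    f = np.zeros(len(windows))
    resid = np.inf
    for it in range(1, max_iter + 1):
        denom = (n_i * np.exp(f / kt)) @ boltz  # (K,)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, h_k / denom, 0.0)
        z = boltz @ p  # (W,)
        f_new = -kt * np.log(z)
        f_new -= f_new[0]
        resid = float(np.max(np.abs(f_new - f)))
        f = f_new
        if resid < tol:
            break
    else:
        raise RuntimeError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(max shift residual {resid:.3e} kcal/mol)"
        )

    with np.errstate(divide="ignore"):
        free = np.where(p > 0, -kt * np.log(np.where(p > 0, p, 1.0)), np.inf)
    finite = np.isfinite(free)
    free[finite] -= free[finite].min()
    return WhamResult(
        grid=centers,
        free_energy=free,
        shifts=f,
        n_iterations=it,
        max_residual=resid,
        temperature_K=temperature_K,
    )
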