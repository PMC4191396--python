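"""Synthetic coupled ion/backbone/twist dynamics with known ground truth.

Microsecond explicit-solvent trajectories cannot be regenerated at desk
scale, so every downstream stage of the pipeline is exercised on a
discrete-time (1 ps) stochastic emulator of the statistical structure of
CG-step dynamics:

* ion occupancy of the inner minor-groove region is a two-state Markov
  chain whose exit rate is 1/mean_residence and whose entry rate is set by
  detailed balance to reproduce the stationary occupancy;
* the joint zeta substate follows a reversible 4-state Metropolis chain on
  the single-flip graph (g-g- <-> tg-/g-t <-> tt; no direct double flips)
  whose stationary law is the Boltzmann distribution of the substate free
  energies.  While an ion has been continuously present for longer than an
  activation lag, the chain switches to a tilted target law in which the
  g -> t flip hazards are multiplied, raising the BII/BII probability to a
  programmed conditional value;
* twist is emitted from a Gaussian conditioned on the current substate;
  minor-groove width, slide and the C8H8...O3' contact flag are emitted as
  deterministic functions of the substate plus noise.

Only the statistical structure is emulated -- there are no forces, no
explicit water and no real torsion dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .constants import SUBSTATES, N_T_STRANDS, kt_kcal
from .thermo import UmbrellaWindow

__all__ = [
    "SyntheticModelParams",
    "GroundTruth",
    "simulate_coupled_dynamics",
    "simulate_ion_presence",
    "presence_to_ion_records",
    "simulate_conditional_bii_series",
    "scatter_uniform_ions",
    "generate_umbrella_samples",
    "make_toy_fasta",
]

#: Zeta angle emission: (mean, sd, truncation interval) per strand state.
_ZETA_EMISSION = {
    "g-": (270.0, 12.0, (150.0, 315.0)),
    "t": (355.0, 10.0, (315.0, 420.0)),  # reduced mod 360 on output
}

_MGW_BASE = {"g-g-": 4.0, "tg-": 4.8, "g-t": 4.8, "tt": 5.5}  # Angstrom
_SLIDE_BASE = {"g-g-": -0.2, "tg-": 0.3, "g-t": 0.3, "tt": 0.8}  # Angstrom
_CONTACT_P = {"g-g-": 0.05, "tg-": 0.45, "g-t": 0.45, "tt": 0.85}


def _check(cond, name, msg):
    if not cond:
        raise ValueError(f"parameter {name!r}: {msg}")


@dataclass(frozen=True)
class SyntheticModelParams:
    """Ground-truth parameters of the coupled generator.

    Twist-mixture fields (``lt_*``, ``ht_*``) describe the marginal
    two-Gaussian decomposition; ``substate_dG`` (kcal/mol, g-g- = 0) and
    ``substate_twist_mean`` (degrees) set the per-substate thermodynamics
    and twist emission; ion fields set the two-state minor-groove occupancy
    process and the ion -> backbone coupling.  ``p_bii_given_ion`` /
    ``p_bii_given_no_ion`` are the stationary tt probabilities of the
    ion-activated and baseline chain modes (``None`` means the plain
    Boltzmann value of ``substate_dG``); equal values (or a zero attempt
    rate contrast) decouple the backbone from the ions.
    """

    # marginal twist mixture (degrees)
    lt_mean: float = 18.0
    lt_sd: float = 6.7
    lt_weight: float = 0.70
    ht_mean: float = 32.3
    ht_sd: float = 5.0
    # substate thermodynamics and twist emission
    substate_dG: dict = field(
        default_factory=lambda: {"g-g-": 0.0, "tg-": 0.3, "g-t": 0.3, "tt": -0.2}
    )
    substate_twist_mean: dict = field(
        default_factory=lambda: {"g-g-": 33.4, "tg-": 26.2, "g-t": 26.3, "tt": 16.3}
    )
    substate_twist_sd: dict | None = None  # default: ht_sd for g-g-, lt_sd for tt
    # ion occupancy process
    ion_mean_residence_ps: float = 11.3
    ion_occupancy_frac: float = 0.308
    ion_species: str = "K+"
    # ion -> backbone coupling
    ion_lead_time_ps: float = 45.0
    p_bii_given_ion: float | None = 0.80
    p_bii_given_no_ion: float | None = None
    lag_model: str = "deterministic"  # or "exponential"
    zeta_attempt_rate: float = 0.02  # per ps per edge, baseline mode
    zeta_attempt_rate_active: float = 0.45  # per ps per edge, ion-activated mode
    # bookkeeping
    dt_ps: float = 1.0
    temperature_K: float = 298.0
    step_index: int = 6

    def __post_init__(self):
        for name in ("lt_mean", "lt_sd", "lt_weight", "ht_mean", "ht_sd",
                     "ion_mean_residence_ps", "ion_occupancy_frac",
                     "ion_lead_time_ps", "dt_ps", "temperature_K",
                     "zeta_attempt_rate", "zeta_attempt_rate_active"):
            v = getattr(self, name)
            _check(isinstance(v, (int, float)) and math.isfinite(v), name,
                   f"must be finite, got {v!r}")
        _check(0 < self.lt_weight < 1, "lt_weight", "must be in (0, 1)")
        _check(self.lt_sd > 0, "lt_sd", "must be positive")
        _check(self.ht_sd > 0, "ht_sd", "must be positive")
        _check(0 < self.ion_occupancy_frac < 1, "ion_occupancy_frac",
               "must be in (0, 1)")
        _check(self.ion_mean_residence_ps > 0, "ion_mean_residence_ps",
               "must be positive")
        _check(self.dt_ps > 0, "dt_ps", "must be positive")
        _check(self.ion_lead_time_ps >= 0, "ion_lead_time_ps", "must be >= 0")
        _check(set(self.substate_dG) == set(SUBSTATES), "substate_dG",
               f"must map exactly the labels {SUBSTATES}")
        _check(set(self.substate_twist_mean) == set(SUBSTATES),
               "substate_twist_mean", f"must map exactly the labels {SUBSTATES}")
        _check(self.substate_dG["g-g-"] == 0.0, "substate_dG",
               "g-g- is the reference state and must have dG = 0")
        for k, v in self.substate_dG.items():
            _check(math.isfinite(v), "substate_dG", f"dG[{k!r}] must be finite")
        for p_name in ("p_bii_given_ion", "p_bii_given_no_ion"):
            p = getattr(self, p_name)
            if p is not None:
                _check(0 < p < 1, p_name, "must be in (0, 1) or None")
        _check(self.lag_model in ("deterministic", "exponential"), "lag_model",
               "must be 'deterministic' or 'exponential'")
        _check(0 < self.zeta_attempt_rate * self.dt_ps <= 0.5,
               "zeta_attempt_rate", "per-step attempt probability must be in (0, 0.5]")
        _check(0 < self.zeta_attempt_rate_active * self.dt_ps <= 0.5,
               "zeta_attempt_rate_active",
               "per-step attempt probability must be in (0, 0.5]")

    # --- derived quantities -------------------------------------------------
    @property
    def kt(self) -> float:
        return kt_kcal(self.temperature_K)

    def boltzmann_weights(self) -> np.ndarray:
        dg = np.array([self.substate_dG[s] for s in SUBSTATES])
        w = np.exp(-dg / self.kt)
        return w / w.sum()

    def tilt_for(self, p_tt_target: float | None) -> float:
        """Hazard multiplier h so that the tilted stationary law
        pi_i * h^{n_t(i)} has P(tt) = p_tt_target (h = 1 for None)."""
        if p_tt_target is None:
            return 1.0
        pi = self.boltzmann_weights()
        nt = np.array([N_T_STRANDS[s] for s in SUBSTATES])

        def p_tt(log_h):
            w = pi * np.exp(log_h) ** nt
            return w[SUBSTATES.index("tt")] / w.sum() - p_tt_target

        return float(np.exp(brentq(p_tt, -40.0, 40.0, xtol=1e-12)))

    def stationary(self, tilt: float = 1.0) -> np.ndarray:
        pi = self.boltzmann_weights()
        nt = np.array([N_T_STRANDS[s] for s in SUBSTATES])
        w = pi * tilt ** nt
        return w / w.sum()

    def transition_probs(self, attempt_rate: float, tilt: float = 1.0) -> np.ndarray:
        """Per-step Metropolis transition matrix on the single-flip graph
        targeting the (tilted) Boltzmann law."""
        w = self.stationary(tilt)
        q = attempt_rate * self.dt_ps
        n = len(SUBSTATES)
        P = np.zeros((n, n))
        from .constants import SUBSTATE_EDGES

        for a, b in SUBSTATE_EDGES:
            i, j = SUBSTATES.index(a), SUBSTATES.index(b)
            P[i, j] = q * min(1.0, w[j] / w[i])
            P[j, i] = q * min(1.0, w[i] / w[j])
        np.fill_diagonal(P, 1.0 - P.sum(axis=1))
        if np.any(np.diag(P) < 0):
            raise ValueError(
                "parameter 'zeta_attempt_rate': per-step transition "
                "probabilities exceed 1; reduce the attempt rate"
            )
        return P

    def activated_mfpt_ps(self) -> float:
        """Mean first-passage time g-g- -> tt of the ion-activated chain."""
        P = self.transition_probs(self.zeta_attempt_rate_active,
                                  self.tilt_for(self.p_bii_given_ion))
        tt = SUBSTATES.index("tt")
        keep = [i for i in range(len(SUBSTATES)) if i != tt]
        Q = P[np.ix_(keep, keep)]
        tau = np.linalg.solve(np.eye(len(keep)) - Q, np.full(len(keep), self.dt_ps))
        return float(tau[keep.index(SUBSTATES.index("g-g-"))])

    def activation_lag_ps(self) -> float:
        """Lag from ion arrival to hazard activation.  In the deterministic
        model it is the programmed mean lead minus the activated chain's
        mean first-passage time, so the realized arrival-to-flip lead
        averages ``ion_lead_time_ps``."""
        return max(0.0, self.ion_lead_time_ps - self.activated_mfpt_ps())

    def entry_exit_probs(self) -> tuple:
        p_exit = self.dt_ps / self.ion_mean_residence_ps
        occ = self.ion_occupancy_frac
        p_entry = occ * self.dt_ps / ((1.0 - occ) * self.ion_mean_residence_ps)
        if p_exit > 1 or p_entry > 1:
            raise ValueError(
                "parameter 'ion_mean_residence_ps': per-step entry/exit "
                "probability exceeds 1 at this dt_ps"
            )
        return p_entry, p_exit


@dataclass(frozen=True)
class GroundTruth:
    """Hidden sequences realized by the generator (same length/cadence as
    the emitted snapshot series)."""

    params: SyntheticModelParams
    seed: int
    ion_present: np.ndarray
    ion_active: np.ndarray
    zeta_state: np.ndarray
    tilt_active: float
    tilt_baseline: float
    activation_lag_ps: float


def _alternating_runs(n_steps, p_start, p_leave_a, p_leave_b, rng):
    """Boolean series built from alternating geometric runs.

    State A (True) has per-step leave probability ``p_leave_a``; state B
    (False) ``p_leave_b``.  The initial state is True with probability
    ``p_start``.
    """
    out = np.empty(n_steps, dtype=bool)
    pos = 0
    state = bool(rng.random() < p_start)
    while pos < n_steps:
        # draw batches of run lengths (one per state) to limit Python loops
        need = n_steps - pos
        mean_cycle = 1.0 / p_leave_a + 1.0 / p_leave_b
        batch = max(8, int(need / mean_cycle) + 4)
        runs_a = rng.geometric(p_leave_a, size=batch)
        runs_b = rng.geometric(p_leave_b, size=batch)
        for la, lb in zip(runs_a, runs_b):
            first, second = (la, lb) if state else (lb, la)
            end = min(pos + int(first), n_steps)
            out[pos:end] = state
            pos = end
            if pos >= n_steps:
                break
            end = min(pos + int(second), n_steps)
            out[pos:end] = not state
            pos = end
            if pos >= n_steps:
                break
        # full A/B cycles leave `state` unchanged for the next batch
    return out


def simulate_ion_presence(params: SyntheticModelParams, n_steps: int, seed) -> np.ndarray:
    """Two-state (in/out) minor-groove occupancy series at 1 ps cadence."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    p_entry, p_exit = params.entry_exit_probs()
    return _alternating_runs(n_steps, params.ion_occupancy_frac, p_exit, p_entry, rng)


def _activation_series(presence, lag_steps_fn):
    """Activated mask: within each occupied run, True from start+lag to end."""
    from .iondyn import runs_of_ones

    active = np.zeros(presence.size, dtype=bool)
    for start, length in runs_of_ones(presence):
        lag = lag_steps_fn()
        if lag < length:
            active[start + lag: start + length] = True
    return active


def _simulate_zeta_path(P_base, P_active, active, start_state, rng):
    """Sequential simulation of the mode-switching 4-state chain."""
    n = active.size
    # cumulative transition thresholds per (mode, state)
    tables = []
    for P in (P_base, P_active):
        rows = []
        for i in range(P.shape[0]):
            targets = [j for j in range(P.shape[1]) if j != i and P[i, j] > 0]
            cum = np.cumsum([P[i, j] for j in targets])
            rows.append((cum.tolist(), targets))
        tables.append(rows)
    u = rng.random(n).tolist()
    act = active.tolist()
    states = np.empty(n, dtype=np.uint8)
    s = int(start_state)
    for k in range(n):
        cum, targets = tables[1][s] if act[k] else tables[0][s]
        x = u[k]
        for c, j in zip(cum, targets):
            if x < c:
                s = j
                break
        states[k] = s
    return states


def _emit_zeta_angles(strand_states, rng):
    """Truncated-normal zeta angles consistent with the given strand labels."""
    out = np.empty(strand_states.size, dtype=float)
    for label, (mu, sd, (lo, hi)) in _ZETA_EMISSION.items():
        mask = strand_states == label
        k = int(mask.sum())
        if k:
            a, b = (lo - mu) / sd, (hi - mu) / sd
            out[mask] = truncnorm.rvs(a, b, loc=mu, scale=sd, size=k,
                                      random_state=rng)
    return np.mod(out, 360.0)


def simulate_coupled_dynamics(params: SyntheticModelParams, n_steps: int, seed: int):
    """Generate one synthetic trajectory of coupled ion/backbone/twist dynamics.

    Returns ``(snapshots, ions, truth)``: a per-snapshot observable table
    (snapshot, time_ps, twist_deg, zetaW_deg, zetaC_deg, mgw_A, slide_A,
    contact), a curvilinear ion-record stream for the ions occupying the
    inner minor-groove region of the central step, and the
    :class:`GroundTruth` hidden sequences.  Fully reproducible for a fixed
    seed.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)

    presence = simulate_ion_presence(params, n_steps, rng)
    lag_ps = params.activation_lag_ps()
    if params.lag_model == "deterministic":
        lag_steps = int(round(lag_ps / params.dt_ps))
        lag_fn = lambda: lag_steps
    else:
        lag_fn = lambda: int(round(rng.exponential(lag_ps) / params.dt_ps))
    active = _activation_series(presence, lag_fn)

    tilt0 = params.tilt_for(params.p_bii_given_no_ion)
    tilt1 = params.tilt_for(params.p_bii_given_ion)
    P_base = params.transition_probs(params.zeta_attempt_rate, tilt0)
    P_active = params.transition_probs(params.zeta_attempt_rate_active, tilt1)
    start = int(rng.choice(len(SUBSTATES), p=params.stationary(tilt0)))
    codes = _simulate_zeta_path(P_base, P_active, active, start, rng)
    labels = np.asarray(SUBSTATES, dtype="U4")[codes]

    tw_mean = np.array([params.substate_twist_mean[s] for s in SUBSTATES])
    if params.substate_twist_sd is None:
        sd_map = {"g-g-": params.ht_sd, "tt": params.lt_sd,
                  "tg-": 0.5 * (params.ht_sd + params.lt_sd),
                  "g-t": 0.5 * (params.ht_sd + params.lt_sd)}
    else:
        sd_map = params.substate_twist_sd
    tw_sd = np.array([sd_map[s] for s in SUBSTATES])
    twist = rng.normal(tw_mean[codes], tw_sd[codes])

    w_states = np.asarray(["g-" if s in ("g-g-", "g-t") else "t" for s in SUBSTATES])[codes]
    c_states = np.asarray(["g-" if s in ("g-g-", "tg-") else "t" for s in SUBSTATES])[codes]
    zeta_w = _emit_zeta_angles(w_states, rng)
    zeta_c = _emit_zeta_angles(c_states, rng)

    mgw = np.array([_MGW_BASE[s] for s in SUBSTATES])[codes] + rng.normal(0, 0.4, n_steps)
    slide = np.array([_SLIDE_BASE[s] for s in SUBSTATES])[codes] + rng.normal(0, 0.25, n_steps)
    contact = rng.random(n_steps) < np.array([_CONTACT_P[s] for s in SUBSTATES])[codes]

    snapshots = pd.DataFrame(
        {
            "snapshot": np.arange(n_steps),
            "time_ps": np.arange(n_steps) * params.dt_ps,
            "twist_deg": twist,
            "zetaW_deg": zeta_w,
            "zetaC_deg": zeta_c,
            "mgw_A": mgw,
            "slide_A": slide,
            "contact": contact.astype(int),
        }
    )
    ions = presence_to_ion_records(
        presence, step=params.step_index, species=params.ion_species, rng=rng
    )
    truth = GroundTruth(
        params=params,
        seed=seed,
        ion_present=presence,
        ion_active=active,
        zeta_state=labels,
        tilt_active=tilt1,
        tilt_baseline=tilt0,
        activation_lag_ps=lag_ps,
    )
    return snapshots, ions, truth


def presence_to_ion_records(
    presence, step: int = 6, species: str = "K+", rng=None, seed=0
) -> pd.DataFrame:
    """Curvilinear ion records for a 0/1 inner-minor occupancy series.

    Each occupied run becomes one ion (fresh ion id per run) positioned in
    the inner minor-groove region of the given step with small positional
    noise.
    """
    from .iondyn import runs_of_ones

    if rng is None:
        rng = np.random.default_rng(seed)
    presence = np.asarray(presence, dtype=bool)
    runs = runs_of_ones(presence)
    snaps, ids = [], []
    for ion_id, (start, length) in enumerate(runs):
        snaps.append(np.arange(start, start + length))
        ids.append(np.full(length, ion_id))
    if snaps:
        snaps = np.concatenate(snaps)
        ids = np.concatenate(ids)
    else:
        snaps = np.empty(0, dtype=int)
        ids = np.empty(0, dtype=int)
    n = snaps.size
    D = np.clip(step + 0.5 + rng.normal(0, 0.2, n), step - 0.19, step + 1.19)
    R = np.clip(4.0 + rng.normal(0, 1.2, n), 0.3, 10.0)
    A = np.mod(90.0 + rng.normal(0, 15.0, n), 360.0)
    return pd.DataFrame(
        {"snapshot": snaps, "ion_id": ids, "species": species,
         "D": D, "R_A": R, "A_deg": A}
    )


def simulate_conditional_bii_series(
    p_tt_with_ion: float,
    p_tt_without_ion: float,
    mean_run_ps: float,
    n_steps: int,
    seed,
    *,
    dt_ps: float = 1.0,
):
    """Aligned 0/1 ion-presence and joint-substate series with programmed
    per-ps conditional tt probabilities.

    Presence alternates between geometric with/without runs of the given
    mean length; at every snapshot the joint label is ``tt`` with the
    conditional probability of the current presence value, otherwise one of
    the remaining labels (g-g- preferentially).  Returns
    ``(presence, labels)``.
    """
    for name, p in (("p_tt_with_ion", p_tt_with_ion),
                    ("p_tt_without_ion", p_tt_without_ion)):
        if not (0 <= p <= 1):
            raise ValueError(f"parameter {name!r}: must be in [0, 1]")
    if mean_run_ps <= 0 or n_steps < 1:
        raise ValueError("mean_run_ps must be positive and n_steps >= 1")
    rng = np.random.default_rng(seed)
    p_leave = dt_ps / mean_run_ps
    presence = _alternating_runs(n_steps, 0.5, p_leave, p_leave, rng)
    p_tt = np.where(presence, p_tt_with_ion, p_tt_without_ion)
    is_tt = rng.random(n_steps) < p_tt
    others = np.asarray(["g-g-", "tg-", "g-t"])
    labels = others[rng.choice(3, size=n_steps, p=[0.7, 0.15, 0.15])].astype("U4")
    labels[is_tt] = "tt"
    return presence, labels


def scatter_uniform_ions(
    concentration_M: float,
    n_snapshots: int,
    seed,
    *,
    d_range=(0.0, 10.0),
    r_range=(0.0, 15.0),
    rise: float = 3.38,
    species: str = "K+",
) -> pd.DataFrame:
    """Ions placed uniformly in a cylindrical shell at a bulk concentration.

    Per snapshot the ion count is Poisson with mean c * V * 6.022e-4 where
    V is the shell volume in cubic Angstrom; positions are uniform in the
    shell (R sampled with the sqrt law).  Used for molarity calibration.
    """
    if concentration_M <= 0 or n_snapshots < 1:
        raise ValueError("concentration and n_snapshots must be positive")
    rng = np.random.default_rng(seed)
    vol = (rise * (d_range[1] - d_range[0])
           * (r_range[1] ** 2 - r_range[0] ** 2) / 2.0 * 2 * np.pi)
    lam = concentration_M * vol * 6.022e-4
    n_total = rng.poisson(lam * n_snapshots)
    snaps = rng.integers(0, n_snapshots, size=n_total)
    D = rng.uniform(d_range[0], d_range[1], size=n_total)
    R = np.sqrt(rng.uniform(r_range[0] ** 2, r_range[1] ** 2, size=n_total))
    A = rng.uniform(0.0, 360.0, size=n_total)
    return pd.DataFrame(
        {"snapshot": np.sort(snaps), "ion_id": np.arange(n_total),
         "species": species, "D": D, "R_A": R, "A_deg": A}
    )


def generate_umbrella_samples(
    free_energy_fn,
    window_centers,
    k: float = 0.02,
    n_per_window: int = 2000,
    seed=0,
    *,
    temperature_K: float = 298.0,
    grid_pad: float = 25.0,
    grid_step: float = 0.05,
):
    """Draw umbrella-window samples from density ~ exp(-(F + k(x-c)^2)/kT).

    Sampling is exact up to the ``grid_step`` discretization (inverse-CDF on
    a fine grid with within-bin jitter).  Returns a list of
    :class:`cgtwist.thermo.UmbrellaWindow`.
    """
    centers = list(window_centers)
    if not centers:
        raise ValueError("window_centers must not be empty")
    if k <= 0:
        raise ValueError("parameter 'k': force constant must be positive")
    kt = kt_kcal(temperature_K)
    rng = np.random.default_rng(seed)
    lo = min(centers) - grid_pad
    hi = max(centers) + grid_pad
    x = np.arange(lo, hi + grid_step, grid_step)
    F = np.asarray(free_energy_fn(x), dtype=float)
    windows = []
    for c in centers:
        u = F + k * (x - c) ** 2
        w = np.exp(-(u - u.min()) / kt)
        w /= w.sum()
        idx = rng.choice(x.size, size=n_per_window, p=w)
        samples = x[idx] + rng.uniform(-grid_step / 2, grid_step / 2, n_per_window)
        windows.append(UmbrellaWindow(center=float(c), k=float(k), samples=samples))
    return windows


def make_toy_fasta(spec, seed=0, *, line_width: int = 60) -> str:
    """Standard multi-record FASTA text for sequence-counting tests.

    ``spec`` is either a list of explicit sequences or a dict random model
    ``{"n": records, "length": bp, "gc": fraction}``.  Reproducible for a
    fixed seed.
    """
    rng = np.random.default_rng(seed)
    if isinstance(spec, dict):
        n = int(spec.get("n", 1))
        length = int(spec["length"])
        gc = float(spec.get("gc", 0.5))
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        seqs = [
            "".join(np.asarray(list("ACGT"))[rng.choice(4, size=length, p=p)])
            for _ in range(n)
        ]
    else:
        seqs = [str(s).upper() for s in spec]
    lines = []
    for i, s in enumerate(seqs, start=1):
        lines.append(f">seq{i}")
        for j in range(0, len(s), line_width):
            lines.append(s[j: j + line_width])
    return "\n".join(lines) + "\n"
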