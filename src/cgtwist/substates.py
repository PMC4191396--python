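"""BI/BII backbone substate classification and twist mixture decomposition.

The zeta (C3'-O3'-P-O5') torsion at the 3'-junction of a CG step switches
between a canonical g- conformer (centred near 270 deg, the BI backbone
state) and a t conformer (centred near 360 deg, BII).  Considering the two
zeta angles flanking the step (Watson strand first, then Crick) gives four
joint substates: g-g-, tg-, g-t and tt.

Twist distributions of polymorphic CG steps are bimodal; they are
decomposed here into at most two Gaussian components fitted by EM, with the
Bayesian Information Criterion deciding whether one or two components are
warranted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .constants import SUBSTATES

__all__ = [
    "ZETA_G_MINUS_INTERVAL",
    "classify_zeta",
    "joint_state",
    "zeta_state_series",
    "MixtureFit",
    "fit_twist_mixture",
    "weighted_average",
    "twist_by_substate",
]

#: Class boundary for the zeta torsion: g- iff zeta (mod 360) falls in
#: [150, 315).  The upper edge is the midpoint of the g- (270 deg) and
#: t (360 deg) state centres; both edges are configurable per call.
ZETA_G_MINUS_INTERVAL = (150.0, 315.0)


def classify_zeta(zeta, interval=ZETA_G_MINUS_INTERVAL):
    """Classify a zeta torsion (degrees, any real) as ``"g-"`` or ``"t"``.

    Accepts scalars or arrays; angles are reduced modulo 360 first.
    Non-finite values raise ``ValueError``.
    """
    arr = np.asarray(zeta, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("zeta contains non-finite values")
    lo, hi = interval
    reduced = np.mod(arr, 360.0)
    is_g = (reduced >= lo) & (reduced < hi)
    out = np.where(is_g, "g-", "t")
    if arr.ndim == 0:
        return str(out[()])
    return out


def joint_state(zeta_w, zeta_c, interval=ZETA_G_MINUS_INTERVAL):
    """Joint substate label for a (Watson, Crick) zeta pair.

    The Watson-strand label comes first: (350, 270) -> ``"tg-"``.
    """
    w = classify_zeta(zeta_w, interval)
    c = classify_zeta(zeta_c, interval)
    if np.ndim(w) == 0:
        return f"{w}{c}"
    return np.char.add(np.asarray(w, dtype="U2"), np.asarray(c, dtype="U2"))


def zeta_state_series(
    zeta_w, zeta_c, snapshots=None, interval=ZETA_G_MINUS_INTERVAL
) -> pd.DataFrame:
    """Build a per-snapshot substate table from two zeta angle series.

    Returns a DataFrame indexed by snapshot with columns ``w``, ``c``
    (strand labels) and ``joint``.
    """
    zeta_w = np.asarray(zeta_w, dtype=float)
    zeta_c = np.asarray(zeta_c, dtype=float)
    if zeta_w.shape != zeta_c.shape:
        raise ValueError(
            f"zeta series length mismatch: {zeta_w.shape} vs {zeta_c.shape}"
        )
    w = classify_zeta(zeta_w, interval)
    c = classify_zeta(zeta_c, interval)
    joint = np.char.add(np.asarray(w, dtype="U2"), np.asarray(c, dtype="U2"))
    index = np.arange(len(zeta_w)) if snapshots is None else np.asarray(snapshots)
    df = pd.DataFrame({"w": w, "c": c, "joint": joint}, index=pd.Index(index, name="snapshot"))
    return df


@dataclass(frozen=True)
class MixtureFit:
    """A 1- or 2-component Gaussian description of a twist distribution.

    Components are stored low-twist first (ascending mean; ties broken by
    descending weight).  ``bic1``/``bic2`` are the BIC values of the one-
    and two-component fits, whichever was selected.
    """

    n_components: int
    means: tuple
    sds: tuple
    weights: tuple
    log_likelihood: float
    bic1: float
    bic2: float
    n_samples: int = 0

    def __post_init__(self):
        if self.n_components not in (1, 2):
            raise ValueError("n_components must be 1 or 2")
        if len(self.means) != self.n_components:
            raise ValueError("means length must equal n_components")
        if not math.isclose(sum(self.weights), 1.0, abs_tol=1e-9):
            raise ValueError("weights must sum to 1")
        if any(w <= 0 for w in self.weights):
            raise ValueError("weights must be positive")
        if any(s <= 0 for s in self.sds):
            raise ValueError("sds must be positive")

    @property
    def weighted_average(self) -> float:
        """Population-weighted mean twist, sum_i w_i mu_i (degrees)."""
        return float(sum(w * m for w, m in zip(self.weights, self.means)))


def weighted_average(fit: MixtureFit) -> float:
    """Weighted average twist of a mixture fit (degrees)."""
    return fit.weighted_average


def _order_lt_first(means, sds, weights):
    order = sorted(range(len(means)), key=lambda i: (means[i], -weights[i]))
    return (
        tuple(float(means[i]) for i in order),
        tuple(float(sds[i]) for i in order),
        tuple(float(weights[i]) for i in order),
    )


def fit_twist_mixture(
    twist_samples,
    *,
    thin: int = 1,
    n_init: int = 2,
    max_iter: int = 5000,
    tol: float = 1e-8,
    random_state: int = 0,
) -> MixtureFit:
    """Fit 1- and 2-component Gaussian mixtures to a twist series and pick by BIC.

    EM is multi-started (``n_init`` restarts with a fixed seed policy); the
    model with the lower BIC (k_params*ln n - 2 lnL) is selected.  Snapshots
    are treated as independent in the BIC despite trajectory autocorrelation;
    ``thin`` subsamples the series if desired.

    Raises ``ValueError`` for fewer than 50 samples or a degenerate
    (zero-variance) series, and ``RuntimeError`` if EM fails to converge.
    """
    x = np.asarray(twist_samples, dtype=float).ravel()
    if thin > 1:
        x = x[::thin]
    if x.size < 50:
        raise ValueError(f"need at least 50 samples, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("twist samples contain non-finite values")
    if np.std(x) == 0:
        raise ValueError("degenerate twist series: zero variance")

    X = x[:, None]
    fits = {}
    for k in (1, 2):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_init,
            max_iter=max_iter,
            tol=tol,
            random_state=random_state,
            reg_covar=1e-8,
        ).fit(X)
        if not gm.converged_:
            raise RuntimeError(
                f"EM did not converge for k={k} after {n_init} restarts of "
                f"{max_iter} iterations (lower bound {gm.lower_bound_:.6g})"
            )
        fits[k] = gm
    bic = {k: float(gm.bic(X)) for k, gm in fits.items()}
    k_sel = 1 if bic[1] <= bic[2] else 2
    gm = fits[k_sel]
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.reshape(k_sel))
    weights = gm.weights_
    means, sds, weights = _order_lt_first(means, sds, weights)
    return MixtureFit(
        n_components=k_sel,
        means=means,
        sds=sds,
        weights=weights,
        log_likelihood=float(gm.score(X) * x.size),
        bic1=bic[1],
        bic2=bic[2],
        n_samples=int(x.size),
    )


def twist_by_substate(twist_series, states) -> pd.DataFrame:
    """Grouped twist statistics over the four joint substates.

    ``states`` is a substate table from :func:`zeta_state_series` (or any
    object with a ``joint`` column / an array of joint labels) aligned with
    ``twist_series``.  Returns a DataFrame indexed by the four labels with
    columns ``mean``, ``sd`` and ``count``; unvisited substates get count 0
    and NaN statistics.
    """
    twist = np.asarray(twist_series, dtype=float)
    joint = states["joint"].to_numpy() if isinstance(states, pd.DataFrame) else np.asarray(states)
    if len(twist) != len(joint):
        raise ValueError(
            f"length mismatch: {len(twist)} twist values vs {len(joint)} states"
        )
    df = pd.DataFrame({"twist": twist, "joint": joint})
    g = df.groupby("joint")["twist"]
    out = pd.DataFrame(
        {"mean": g.mean(), "sd": g.std(ddof=1), "count": g.count()}
    ).reindex(list(SUBSTATES))
    out["count"] = out["count"].fillna(0).astype(int)
    out.index.name = "substate"
    return out
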