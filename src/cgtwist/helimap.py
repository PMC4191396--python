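"""Curvilinear helicoidal mapping of ion positions around a DNA axis.

Each ion position is expressed in curvilinear cylindrical coordinates with
respect to the (instantaneous) helical axis: D, the position along the axis
in base-pair-level units; R, the radial distance from the axis in Angstrom;
and A, the azimuthal angle in degrees measured from a per-level reference
vector.  The convention required of axis producers is that the centre of
the minor groove maps to A = 90 deg, so the minor groove spans A in
[33, 147) and the major groove is the complement through 0.

Space around a chosen base-pair step N is partitioned into inner
(R < 10.25 A) and outer (10.25 <= R < 15 A) regions of the minor and major
grooves, with the step's axial window D in [N - 0.2, N + 1.2).  Densities
are accumulated on 1D/2D grids over subsets of (D, R, A) and converted to
molarity using the curvilinear bin volume.

All half-open interval conventions are lower-closed/upper-open, so the
five region labels partition space exactly (R = 10.25 A is "outer").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HelicalAxisFrames",
    "RegionSpec",
    "DensityGrid",
    "REGION_LABELS",
    "cartesian_to_curvilinear",
    "emit_cartesian_ions",
    "assign_region",
    "density",
    "filter_records_by_state",
]

#: Conversion between number density (ions per cubic Angstrom) and molarity:
#: molarity = mean count / (V[A^3] * MOLAR_PER_COUNT_A3).
MOLAR_PER_COUNT_A3 = 6.022e-4

REGION_LABELS = ("inner_minor", "inner_major", "outer_minor", "outer_major", "outside")

ION_RECORD_COLUMNS = ("snapshot", "ion_id", "species", "D", "R_A", "A_deg")


@dataclass(frozen=True)
class HelicalAxisFrames:
    """Per-level reference frames of a helical axis.

    ``levels`` are strictly increasing base-pair level indices; for level i
    the frame holds an origin (A), a unit tangent along the axis and a unit
    reference vector (perpendicular to the tangent) defining A = 0.
    """

    levels: np.ndarray
    origins: np.ndarray
    tangents: np.ndarray
    references: np.ndarray

    def __post_init__(self):
        levels = np.asarray(self.levels, dtype=float)
        origins = np.asarray(self.origins, dtype=float)
        tangents = np.asarray(self.tangents, dtype=float)
        references = np.asarray(self.references, dtype=float)
        n = levels.shape[0]
        if n < 2:
            raise ValueError("axis needs at least 2 levels")
        if origins.shape != (n, 3) or tangents.shape != (n, 3) or references.shape != (n, 3):
            raise ValueError("origins/tangents/references must be (n_levels, 3)")
        if not np.all(np.diff(levels) > 0):
            raise ValueError("levels must be strictly increasing")
        tol = 1e-9
        if np.any(np.abs(np.linalg.norm(tangents, axis=1) - 1.0) > tol):
            raise ValueError("tangent vectors must be unit length (within 1e-9)")
        if np.any(np.abs(np.linalg.norm(references, axis=1) - 1.0) > tol):
            raise ValueError("reference vectors must be unit length (within 1e-9)")
        if np.any(np.abs(np.einsum("ij,ij->i", tangents, references)) > 1e-6):
            raise ValueError("reference vectors must be perpendicular to tangents")
        seg = np.diff(origins, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
        bad = np.nonzero(seg_len < 1e-12)[0]
        if bad.size:
            raise ValueError(f"degenerate (zero-length) axis segment at level {levels[bad[0]]}")
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "origins", origins)
        object.__setattr__(self, "tangents", tangents)
        object.__setattr__(self, "references", references)

    @property
    def n_levels(self) -> int:
        return self.levels.shape[0]

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.origins, axis=0), axis=1)

    @classmethod
    def straight(cls, n_levels: int, rise: float = 3.38, level0: int = 0,
                 origin=(0.0, 0.0, 0.0)) -> "HelicalAxisFrames":
        """A straight vertical axis (tangent +z, reference +x), mainly for
        synthetic data and tests."""
        levels = level0 + np.arange(n_levels)
        origins = np.asarray(origin, dtype=float) + np.outer(
            np.arange(n_levels) * rise, np.array([0.0, 0.0, 1.0])
        )
        tangents = np.tile([0.0, 0.0, 1.0], (n_levels, 1))
        references = np.tile([1.0, 0.0, 0.0], (n_levels, 1))
        return cls(levels, origins, tangents, references)

    def frame_at(self, d):
        """Interpolated (point, tangent, reference, binormal) at fractional D.

        Tangent and reference vectors are linearly interpolated between the
        bracketing levels and re-orthonormalized.
        """
        d = np.atleast_1d(np.asarray(d, dtype=float))
        if np.any(d < self.levels[0]) or np.any(d > self.levels[-1]):
            bad = d[(d < self.levels[0]) | (d > self.levels[-1])][0]
            raise ValueError(
                f"D={bad} outside axis level range [{self.levels[0]}, {self.levels[-1]}]"
            )
        idx = np.clip(np.searchsorted(self.levels, d, side="right") - 1, 0, self.n_levels - 2)
        t = (d - self.levels[idx]) / (self.levels[idx + 1] - self.levels[idx])
        return self._frame_on_segment(idx, t)

    def _frame_on_segment(self, idx, t):
        t = t[:, None]
        p = (1 - t) * self.origins[idx] + t * self.origins[idx + 1]
        tan = (1 - t) * self.tangents[idx] + t * self.tangents[idx + 1]
        tan /= np.linalg.norm(tan, axis=1, keepdims=True)
        ref = (1 - t) * self.references[idx] + t * self.references[idx + 1]
        ref -= np.einsum("ij,ij->i", ref, tan)[:, None] * tan
        ref /= np.linalg.norm(ref, axis=1, keepdims=True)
        binorm = np.cross(tan, ref)
        return p, tan, ref, binorm

    def arc_length(self, d_lo: float, d_hi: float) -> float:
        """Arc length along the axis between fractional levels d_lo and d_hi."""
        if d_hi < d_lo:
            raise ValueError("d_hi must be >= d_lo")
        lo = np.clip(d_lo, self.levels[0], self.levels[-1])
        hi = np.clip(d_hi, self.levels[0], self.levels[-1])
        seg_len = self.segment_lengths
        total = 0.0
        for i in range(self.n_levels - 1):
            a, b = self.levels[i], self.levels[i + 1]
            ov_lo, ov_hi = max(lo, a), min(hi, b)
            if ov_hi > ov_lo:
                total += seg_len[i] * (ov_hi - ov_lo) / (b - a)
        return float(total)


def _records_frame(D, R, A, snapshots, ion_ids, species, in_range=None) -> pd.DataFrame:
    n = len(D)
    df = pd.DataFrame(
        {
            "snapshot": np.zeros(n, dtype=int) if snapshots is None else np.asarray(snapshots),
            "ion_id": np.arange(n) if ion_ids is None else np.asarray(ion_ids),
            "species": np.full(n, species) if isinstance(species, str) else np.asarray(species),
            "D": D,
            "R_A": R,
            "A_deg": A,
        }
    )
    if in_range is not None:
        df["in_range"] = in_range
    return df


def cartesian_to_curvilinear(
    xyz,
    axis: HelicalAxisFrames,
    *,
    snapshots=None,
    ion_ids=None,
    species: str = "K+",
    newton_iter: int = 12,
) -> pd.DataFrame:
    """Map Cartesian ion positions to curvilinear (D, R, A) records.

    For each point the bracketing axis segment is found, the fractional
    position t is refined so that the residual vector is perpendicular to
    the interpolated tangent, and the angle A is measured from the
    interpolated reference vector (right-handed about the tangent, in
    [0, 360); A = 0 by convention when R = 0).  Points whose perpendicular
    foot falls outside the axis ends are flagged ``in_range=False`` (their
    coordinates are computed at the clamped end).

    Returns a DataFrame with columns snapshot, ion_id, species, D, R_A,
    A_deg, in_range.
    """
    x = np.atleast_2d(np.asarray(xyz, dtype=float))
    if x.shape[1] != 3:
        raise ValueError("xyz must be (n, 3)")
    o = axis.origins
    seg = np.diff(o, axis=0)
    seg_len2 = np.einsum("ij,ij->i", seg, seg)

    # chord projection onto every segment, clamped; pick the nearest segment
    diff = x[:, None, :] - o[None, :-1, :]
    t_all = np.einsum("nsj,sj->ns", diff, seg) / seg_len2
    t_cl = np.clip(t_all, 0.0, 1.0)
    foot = o[None, :-1, :] + t_cl[:, :, None] * seg[None, :, :]
    dist2 = np.einsum("nsj,nsj->ns", x[:, None, :] - foot, x[:, None, :] - foot)
    best = np.argmin(dist2, axis=1)
    rows = np.arange(x.shape[0])
    t = t_all[rows, best]
    in_range = np.ones(x.shape[0], dtype=bool)
    first, last = best == 0, best == axis.n_levels - 2
    in_range &= ~(first & (t < 0)) & ~(last & (t > 1.0))
    t = np.clip(t, 0.0, 1.0)

    # refine t so that (x - p(t)) is perpendicular to the interpolated
    # tangent; a solution stuck at a segment boundary is handed to the
    # neighboring segment (the chord-projection pick can be off by one near
    # level boundaries of a curved axis)
    for _pass in range(4):
        for _ in range(newton_iter):
            p, tan, _, _ = axis._frame_on_segment(best, t)
            f = np.einsum("nj,nj->n", x - p, tan)
            # p'(t) is the segment chord, so the Newton step is f / (seg . tan)
            denom = np.einsum("nj,nj->n", seg[best], tan)
            denom = np.where(np.abs(denom) < 1e-12, 1e-12, denom)
            t_new = np.clip(t + f / denom, 0.0, 1.0)
            if np.max(np.abs(t_new - t)) < 1e-14:
                t = t_new
                break
            t = t_new
        p, tan, _, _ = axis._frame_on_segment(best, t)
        f = np.einsum("nj,nj->n", x - p, tan)
        move_up = (t >= 1.0) & (f > 1e-12) & (best < axis.n_levels - 2)
        move_dn = (t <= 0.0) & (f < -1e-12) & (best > 0)
        if not (move_up.any() or move_dn.any()):
            break
        best = best + move_up.astype(int) - move_dn.astype(int)
        t = np.where(move_up, 0.0, np.where(move_dn, 1.0, t))

    p, tan, ref, binorm = axis._frame_on_segment(best, t)
    v = x - p
    v_perp = v - np.einsum("nj,nj->n", v, tan)[:, None] * tan
    R = np.linalg.norm(v_perp, axis=1)
    A = np.degrees(np.arctan2(np.einsum("nj,nj->n", v_perp, binorm),
                              np.einsum("nj,nj->n", v_perp, ref)))
    A = np.mod(A, 360.0)
    A[R < 1e-12] = 0.0
    D = axis.levels[best] + t * (axis.levels[best + 1] - axis.levels[best])
    return _records_frame(D, R, A, snapshots, ion_ids, species, in_range=in_range)


def emit_cartesian_ions(records: pd.DataFrame, axis: HelicalAxisFrames) -> np.ndarray:
    """Inverse of :func:`cartesian_to_curvilinear`: rebuild Cartesian points.

    Every record's D must lie within the axis level range; violations raise
    ``ValueError`` naming the offending record.
    """
    D = np.asarray(records["D"], dtype=float)
    R = np.asarray(records["R_A"], dtype=float)
    A = np.radians(np.asarray(records["A_deg"], dtype=float))
    bad = np.nonzero((D < axis.levels[0]) | (D > axis.levels[-1]))[0]
    if bad.size:
        i = bad[0]
        label = records.index[i]
        raise ValueError(
            f"record {label}: D={D[i]} outside axis level range "
            f"[{axis.levels[0]}, {axis.levels[-1]}]"
        )
    p, _, ref, binorm = axis.frame_at(D)
    return p + R[:, None] * (np.cos(A)[:, None] * ref + np.sin(A)[:, None] * binorm)


@dataclass(frozen=True)
class RegionSpec:
    """Groove/region partition around one base-pair step.

    The axial window covers D in [step - 0.2, step + 1.2); the inner region
    is R < ``r_inner`` (10.25 A), the outer shell ``r_inner`` <= R <
    ``r_outer`` (15 A); the minor groove is A in [33, 147) and the major
    groove the angular complement through 0.
    """

    step: int
    d_margin_lo: float = 0.2
    d_margin_hi: float = 1.2
    r_inner: float = 10.25
    r_outer: float = 15.0
    minor_a: tuple = (33.0, 147.0)

    def __post_init__(self):
        if not (0 < self.r_inner < self.r_outer):
            raise ValueError("need 0 < r_inner < r_outer")
        lo, hi = self.minor_a
        if not (0 <= lo < hi < 360):
            raise ValueError("minor groove angular interval must be within [0, 360)")

    @property
    def d_window(self) -> tuple:
        return (self.step - self.d_margin_lo, self.step + self.d_margin_hi)


def assign_region(records, spec: RegionSpec):
    """Assign each ion record one of the five region labels.

    A total, deterministic function: D outside the step window or
    R >= r_outer gives ``"outside"``.  Accepts a records DataFrame (columns
    D, R_A, A_deg) or a single record (Series/dict); returns an array of
    labels or a single label accordingly.
    """
    single = not isinstance(records, pd.DataFrame)
    if single:
        rec = records
        D = np.atleast_1d(float(rec["D"]))
        R = np.atleast_1d(float(rec["R_A"]))
        A = np.atleast_1d(float(rec["A_deg"]))
    else:
        D = records["D"].to_numpy(dtype=float)
        R = records["R_A"].to_numpy(dtype=float)
        A = records["A_deg"].to_numpy(dtype=float)
    d_lo, d_hi = spec.d_window
    in_d = (D >= d_lo) & (D < d_hi)
    a_lo, a_hi = spec.minor_a
    minor = (A >= a_lo) & (A < a_hi)
    inner = R < spec.r_inner
    outer = (R >= spec.r_inner) & (R < spec.r_outer)
    labels = np.full(D.shape, "outside", dtype="U11")
    labels[in_d & inner & minor] = "inner_minor"
    labels[in_d & inner & ~minor] = "inner_major"
    labels[in_d & outer & minor] = "outer_minor"
    labels[in_d & outer & ~minor] = "outer_major"
    if single:
        return str(labels[0])
    return labels


@dataclass(frozen=True)
class DensityGrid:
    """Binned mean ion counts and molarities over curvilinear coordinates.

    ``coords`` is a subset of "DRA" in that order (e.g. "R", "DA");
    ``edges`` maps each coordinate to its bin edges.  ``mean_count`` is the
    per-bin ion count averaged over snapshots; ``molarity`` applies the
    curvilinear bin volume.
    """

    coords: str
    edges: dict
    mean_count: np.ndarray
    molarity: np.ndarray
    volumes: np.ndarray
    n_snapshots: int

    def marginal(self, coord: str) -> "DensityGrid":
        """Marginalize a 2D grid onto one of its coordinates (counts add;
        molarities are recomputed with the summed volumes)."""
        if coord not in self.coords or len(self.coords) != 2:
            raise ValueError("marginal() needs a 2D grid and one of its coords")
        axis = 1 - self.coords.index(coord)
        counts = self.mean_count.sum(axis=axis)
        vols = self.volumes.sum(axis=axis)
        return DensityGrid(
            coords=coord,
            edges={coord: self.edges[coord]},
            mean_count=counts,
            molarity=counts / (vols * MOLAR_PER_COUNT_A3),
            volumes=vols,
            n_snapshots=self.n_snapshots,
        )


def _default_edges(coord, records, n_bins):
    x = records[{"D": "D", "R": "R_A", "A": "A_deg"}[coord]].to_numpy(dtype=float)
    if coord == "A":
        return np.linspace(0.0, 360.0, n_bins + 1)
    lo = 0.0 if coord == "R" else (np.floor(x.min()) if x.size else 0.0)
    hi = x.max() if x.size else 1.0
    return np.linspace(lo, hi + 1e-9, n_bins + 1)


def density(
    records: pd.DataFrame,
    coords: str,
    n_snapshots: int,
    *,
    edges: dict | None = None,
    n_bins: int = 20,
    axis: HelicalAxisFrames | None = None,
    rise: float = 3.38,
    d_range: tuple | None = None,
    r_range: tuple | None = None,
) -> DensityGrid:
    """Accumulate a 1D or 2D ion density grid in molarity units.

    ``coords`` is one of {"D","R","A","DR","DA","RA"}.  The bin volume is
    V = ds * (R2^2 - R1^2)/2 * dA_rad, where ds is the arc length of the
    bin's D interval along the axis (``rise`` Angstrom per level when no
    axis is supplied).  For coordinates not being binned, the volume uses
    ``d_range`` / ``r_range`` (which default to the extent of the supplied
    records) and the full angular circle.

    An empty record stream yields a grid of zeros.
    """
    if n_snapshots < 1:
        raise ValueError("n_snapshots must be >= 1")
    coords = "".join(c for c in "DRA" if c in coords.upper())
    if not coords or len(coords) > 2 or any(c not in "DRA" for c in coords):
        raise ValueError("coords must be a non-empty subset of {D, R, A} (1 or 2 of them)")
    if edges is None:
        edges = {}
    edges = {c: np.asarray(edges[c], dtype=float) if c in edges else _default_edges(c, records, n_bins)
             for c in coords}
    for c, e in edges.items():
        if np.any(np.diff(e) <= 0):
            raise ValueError(f"bin edges for {c} must be strictly increasing")

    colmap = {"D": "D", "R": "R_A", "A": "A_deg"}
    data = [records[colmap[c]].to_numpy(dtype=float) for c in coords]
    if len(records):
        counts, _ = np.histogramdd(np.column_stack(data), bins=[edges[c] for c in coords])
    else:
        counts = np.zeros([len(edges[c]) - 1 for c in coords])
    mean_count = counts / n_snapshots

    # ranges of the unbinned coordinates, for volume computation
    if d_range is None:
        if "D" in coords:
            d_range = (edges["D"][0], edges["D"][-1])
        elif len(records):
            d_range = (records["D"].min(), records["D"].max())
        else:
            d_range = (0.0, 1.0)
    if r_range is None:
        if "R" in coords:
            r_range = (edges["R"][0], edges["R"][-1])
        elif len(records):
            r_range = (0.0, records["R_A"].max())
        else:
            r_range = (0.0, 1.0)

    def arc(d_lo, d_hi):
        if axis is not None:
            return axis.arc_length(d_lo, d_hi)
        return rise * (d_hi - d_lo)

    def vol_1d(c, e):
        if c == "D":
            ds = np.array([arc(a, b) for a, b in zip(e[:-1], e[1:])])
            shell = (r_range[1] ** 2 - r_range[0] ** 2) / 2.0
            return ds * shell * (2 * np.pi)
        if c == "R":
            ds = arc(*d_range)
            return ds * (e[1:] ** 2 - e[:-1] ** 2) / 2.0 * (2 * np.pi)
        ds = arc(*d_range)
        shell = (r_range[1] ** 2 - r_range[0] ** 2) / 2.0
        return ds * shell * np.radians(np.diff(e))

    if len(coords) == 1:
        volumes = vol_1d(coords, edges[coords])
    else:
        # factorized volume: each 1D factor built with the other coord's
        # full range divided out via the outer product of per-bin factors
        c1, c2 = coords
        f1 = _vol_factor(c1, edges[c1], axis, rise, d_range, r_range)
        f2 = _vol_factor(c2, edges[c2], axis, rise, d_range, r_range)
        base = _vol_base(coords, axis, rise, d_range, r_range)
        volumes = base * np.outer(f1, f2)
    molarity = mean_count / (volumes * MOLAR_PER_COUNT_A3)
    return DensityGrid(coords, edges, mean_count, molarity, volumes, int(n_snapshots))


def _vol_factor(c, e, axis, rise, d_range, r_range):
    if c == "D":
        if axis is not None:
            return np.array([axis.arc_length(a, b) for a, b in zip(e[:-1], e[1:])])
        return rise * np.diff(e)
    if c == "R":
        return (e[1:] ** 2 - e[:-1] ** 2) / 2.0
    return np.radians(np.diff(e))


def _vol_base(coords, axis, rise, d_range, r_range):
    base = 1.0
    if "D" not in coords:
        base *= axis.arc_length(*d_range) if axis is not None else rise * (d_range[1] - d_range[0])
    if "R" not in coords:
        base *= (r_range[1] ** 2 - r_range[0] ** 2) / 2.0
    if "A" not in coords:
        base *= 2 * np.pi
    return base


def filter_records_by_state(records: pd.DataFrame, state_series, predicate) -> pd.DataFrame:
    """Keep the ion records whose snapshot satisfies a state predicate.

    ``state_series`` is a per-snapshot table (e.g. from
    :func:`cgtwist.substates.zeta_state_series`) indexed by snapshot, or a
    pandas Series of per-snapshot values.  ``predicate`` receives the state
    table and returns a boolean mask over snapshots; as a convenience a
    string label is matched against the ``joint`` column (or the Series
    values).  Record order is preserved; a record snapshot missing from the
    state series raises ``KeyError``.
    """
    if isinstance(state_series, pd.DataFrame):
        idx = state_series.index
        if callable(predicate):
            mask = np.asarray(predicate(state_series), dtype=bool)
        else:
            mask = (state_series["joint"] == predicate).to_numpy()
    else:
        s = pd.Series(state_series)
        idx = s.index
        mask = np.asarray(predicate(s), dtype=bool) if callable(predicate) else (s == predicate).to_numpy()
    snaps = records["snapshot"].to_numpy()
    missing = ~np.isin(snaps, idx.to_numpy())
    if missing.any():
        raise KeyError(
            f"snapshot {snaps[missing][0]} of the record stream is missing "
            "from the state series"
        )
    keep = pd.Series(mask, index=idx).reindex(snaps).to_numpy(dtype=bool)
    return records.loc[keep].reset_index(drop=True)
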