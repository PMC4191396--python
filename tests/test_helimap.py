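"""Curvilinear transform, region partition and molarity densities."""

import numpy as np
import pandas as pd
import pytest

from cgtwist.helimap import (
    HelicalAxisFrames,
    RegionSpec,
    assign_region,
    cartesian_to_curvilinear,
    density,
    emit_cartesian_ions,
    filter_records_by_state,
)
from cgtwist.substates import zeta_state_series

from conftest import random_records


class TestTransform:
    def test_axis_point_maps_to_zero_radius(self, straight_axis):
        rec = cartesian_to_curvilinear([[0, 0, 2 * 3.38]], straight_axis)
        assert rec.loc[0, "D"] == pytest.approx(2.0)
        assert rec.loc[0, "R_A"] == pytest.approx(0.0, abs=1e-12)
        assert rec.loc[0, "A_deg"] == 0.0  # convention at R = 0

    def test_reference_direction_is_zero_angle(self, straight_axis):
        rec = cartesian_to_curvilinear([[5, 0, 2 * 3.38]], straight_axis)
        assert rec.loc[0, "R_A"] == pytest.approx(5.0)
        assert rec.loc[0, "A_deg"] == pytest.approx(0.0)

    def test_right_handed_angle(self, straight_axis):
        """Reference along +x, tangent +z: +y is A = 90 deg at R = 5."""
        rec = cartesian_to_curvilinear([[0, 5, 3 * 3.38]], straight_axis)
        assert rec.loc[0, "D"] == pytest.approx(3.0)
        assert rec.loc[0, "R_A"] == pytest.approx(5.0)
        assert rec.loc[0, "A_deg"] == pytest.approx(90.0)

    @pytest.mark.parametrize("axis_name", ["straight_axis", "curved_axis"])
    def test_round_trip_identity(self, axis_name, request):
        axis = request.getfixturevalue(axis_name)
        rng = np.random.default_rng(42)
        rec = random_records(rng, 1000, d_range=(0.5, 10.5), r_range=(0.0, 8.0))
        xyz = emit_cartesian_ions(rec, axis)
        back = cartesian_to_curvilinear(xyz, axis)
        assert np.abs(back["D"] - rec["D"]).max() < 1e-6
        assert np.abs(back["R_A"] - rec["R_A"]).max() < 1e-6
        d_ang = np.abs((back["A_deg"] - rec["A_deg"] + 180) % 360 - 180)
        assert d_ang.max() < 1e-6

    def test_rigid_motion_equivariance(self, curved_axis):
        """Rotating + translating points and axis together leaves (D,R,A)
        unchanged."""
        rng = np.random.default_rng(3)
        rec = random_records(rng, 300, d_range=(1.0, 10.0), r_range=(0.0, 9.0))
        xyz = emit_cartesian_ions(rec, curved_axis)
        before = cartesian_to_curvilinear(xyz, curved_axis)
        # random rotation via QR; reflection removed
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        shift = np.array([12.0, -7.0, 4.0])
        moved_axis = HelicalAxisFrames(
            curved_axis.levels,
            curved_axis.origins @ Q.T + shift,
            curved_axis.tangents @ Q.T,
            curved_axis.references @ Q.T,
        )
        after = cartesian_to_curvilinear(xyz @ Q.T + shift, moved_axis)
        for col in ("D", "R_A", "A_deg"):
            np.testing.assert_allclose(after[col], before[col], atol=1e-8)

    def test_points_beyond_ends_flagged(self, straight_axis):
        rec = cartesian_to_curvilinear([[0, 0, -10.0], [0, 0, 200.0]], straight_axis)
        assert not rec["in_range"].any()

    def test_emit_rejects_out_of_range_d(self, straight_axis):
        rec = pd.DataFrame(
            {"snapshot": [0], "ion_id": [7], "species": ["K+"],
             "D": [99.0], "R_A": [1.0], "A_deg": [0.0]}
        )
        with pytest.raises(ValueError, match="level range"):
            emit_cartesian_ions(rec, straight_axis)

    def test_degenerate_axis_segment_rejected(self):
        o = np.zeros((3, 3))
        o[2, 2] = 1.0  # levels 0 and 1 share an origin
        tang = np.tile([0.0, 0.0, 1.0], (3, 1))
        ref = np.tile([1.0, 0.0, 0.0], (3, 1))
        with pytest.raises(ValueError, match="degenerate"):
            HelicalAxisFrames(np.arange(3), o, tang, ref)


class TestRegions:
    SPEC = RegionSpec(step=6)

    @pytest.mark.parametrize(
        "d,r,a,expected",
        [
            (6.5, 5.0, 90.0, "inner_minor"),
            (6.5, 12.0, 270.0, "outer_major"),
            (8.0, 5.0, 90.0, "outside"),  # D window violated
            (6.5, 5.0, 270.0, "inner_major"),
            (6.5, 12.0, 90.0, "outer_minor"),
            (6.5, 16.0, 90.0, "outside"),  # beyond outer shell
            (6.5, 10.25, 90.0, "outer_minor"),  # boundary: lower-closed
            (6.5, 5.0, 33.0, "inner_minor"),
            (6.5, 5.0, 147.0, "inner_major"),  # upper edge open
            (5.8, 5.0, 90.0, "inner_minor"),  # D = N - 0.2 included
        ],
    )
    def test_assign_region(self, d, r, a, expected):
        assert assign_region({"D": d, "R_A": r, "A_deg": a}, self.SPEC) == expected

    def test_partition_is_total(self):
        rng = np.random.default_rng(11)
        rec = random_records(rng, 5000, d_range=(4.0, 9.0), r_range=(0.0, 20.0))
        labels = assign_region(rec, self.SPEC)
        counts = pd.Series(labels).value_counts()
        assert counts.sum() == len(rec)


class TestDensity:
    def test_single_ion_single_bin(self, straight_axis):
        rec = pd.DataFrame(
            {"snapshot": np.arange(100), "ion_id": 0, "species": "K+",
             "D": 2.5, "R_A": 5.0, "A_deg": 90.0}
        )
        grid = density(rec, "R", 100, edges={"R": np.array([0.0, 4.0, 8.0, 12.0])},
                       axis=straight_axis, d_range=(2.0, 3.0))
        np.testing.assert_allclose(grid.mean_count, [0.0, 1.0, 0.0])

    def test_uniform_ions_recover_bulk_molarity(self):
        from cgtwist.synthgen import scatter_uniform_ions

        conc = 0.15
        rec = scatter_uniform_ions(conc, 6000, seed=9, d_range=(0.0, 8.0),
                                   r_range=(0.0, 12.0))
        grid = density(rec, "DR", 6000,
                       edges={"D": np.linspace(0, 8, 4), "R": np.linspace(0, 12, 4)},
                       d_range=(0.0, 8.0), r_range=(0.0, 12.0))
        counts = grid.mean_count * 6000
        se = np.sqrt(np.maximum(counts, 1.0)) / 6000 / (grid.volumes * 6.022e-4)
        assert np.all(np.abs(grid.molarity - conc) < 3 * se)

    def test_molarity_invariant_under_angular_refinement(self):
        from cgtwist.synthgen import scatter_uniform_ions

        rec = scatter_uniform_ions(0.15, 4000, seed=10, d_range=(0.0, 6.0),
                                   r_range=(2.0, 10.0))
        coarse = density(rec, "A", 4000, edges={"A": np.linspace(0, 360, 5)},
                         d_range=(0.0, 6.0), r_range=(2.0, 10.0))
        fine = density(rec, "A", 4000, edges={"A": np.linspace(0, 360, 9)},
                       d_range=(0.0, 6.0), r_range=(2.0, 10.0))
        # refinement leaves the molarity scale unchanged (same mean level)
        assert fine.molarity.mean() == pytest.approx(coarse.molarity.mean(), rel=1e-9)

    def test_marginalizing_2d_reproduces_1d(self):
        rng = np.random.default_rng(13)
        rec = random_records(rng, 3000, d_range=(0.0, 8.0), r_range=(0.0, 12.0))
        e = {"D": np.linspace(0, 8, 5), "R": np.linspace(0, 12, 5)}
        g2 = density(rec, "DR", 50, edges=e, d_range=(0.0, 8.0), r_range=(0.0, 12.0))
        g1 = density(rec, "D", 50, edges={"D": e["D"]}, d_range=(0.0, 8.0),
                     r_range=(0.0, 12.0))
        marg = g2.marginal("D")
        np.testing.assert_allclose(marg.mean_count, g1.mean_count)
        np.testing.assert_allclose(marg.molarity, g1.molarity)

    def test_total_mean_count_identity(self):
        rng = np.random.default_rng(14)
        rec = random_records(rng, 1200, d_range=(0.0, 8.0), r_range=(0.0, 12.0))
        grid = density(rec, "R", 40, edges={"R": np.linspace(0, 12, 7)})
        assert grid.mean_count.sum() == pytest.approx(1200 / 40)

    def test_empty_stream_gives_zero_grid(self):
        rec = pd.DataFrame(columns=["snapshot", "ion_id", "species", "D", "R_A", "A_deg"])
        grid = density(rec, "R", 10, edges={"R": np.linspace(0, 12, 4)},
                       d_range=(0.0, 1.0))
        assert np.all(grid.mean_count == 0) and np.all(grid.molarity == 0)


class TestStateFilter:
    def _states(self, n, rng):
        zw = rng.uniform(0, 360, n)
        zc = rng.uniform(0, 360, n)
        return zeta_state_series(zw, zc)

    def test_always_true_predicate_is_identity(self):
        rng = np.random.default_rng(20)
        rec = random_records(rng, 50)
        rec["snapshot"] = np.arange(50)
        states = self._states(50, rng)
        out = filter_records_by_state(rec, states, lambda s: np.ones(len(s), bool))
        pd.testing.assert_frame_equal(out, rec.reset_index(drop=True))

    def test_label_filter_selects_matching_snapshots(self):
        rng = np.random.default_rng(21)
        rec = random_records(rng, 200)
        rec["snapshot"] = rng.integers(0, 100, 200)
        states = self._states(100, rng)
        out = filter_records_by_state(rec, states, "tt")
        tt_snaps = set(states.index[states["joint"] == "tt"])
        expected = rec[rec["snapshot"].isin(tt_snaps)].reset_index(drop=True)
        pd.testing.assert_frame_equal(out, expected)  # exact rows, stable order

    def test_missing_snapshot_raises(self):
        rng = np.random.default_rng(22)
        rec = random_records(rng, 5)
        rec["snapshot"] = [0, 1, 2, 3, 99]
        states = self._states(10, rng)
        with pytest.raises(KeyError, match="99"):
            filter_records_by_state(rec, states, "tt")

    def test_empty_selection_returns_empty(self):
        rng = np.random.default_rng(23)
        rec = random_records(rng, 10)
        rec["snapshot"] = np.arange(10)
        states = self._states(10, rng)
        out = filter_records_by_state(rec, states, lambda s: np.zeros(len(s), bool))
        assert len(out) == 0

    def test_conditional_density_enrichment(self, tcga_run):
        """Ion density in the inner minor region is higher conditional on
        the tt substate than unconditionally (generator ground truth)."""
        params, snapshots, ions, truth = tcga_run
        states = pd.DataFrame(
            {"joint": truth.zeta_state},
            index=pd.Index(np.arange(len(truth.zeta_state)), name="snapshot"),
        )
        spec = RegionSpec(step=params.step_index)
        labels = assign_region(ions, spec)
        inner = ions.loc[labels == "inner_minor"]
        n = len(truth.zeta_state)
        uncond = len(inner) / n
        tt_recs = filter_records_by_state(inner.reset_index(drop=True), states, "tt")
        n_tt = int((truth.zeta_state == "tt").sum())
        cond = len(tt_recs) / n_tt
        assert cond > uncond
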