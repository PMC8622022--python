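"""Control law, gain construction, error dynamics and synchronization."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import selkovsync as sv
from selkovsync.control import CoupledState, open_loop_error_rhs


@pytest.mark.parametrize(
    "K1, K2, K3, expected",
    [(1, 1, 1, 2.0), (0, 0, 0, 0.0), (4, 1, 4, 16.0)],
)
def test_lipschitz_gain_formula(K1, K2, K3, expected):
    bounds = sv.BoundEstimates(K1=K1, K2=K2, K3=K3, M=max(K1, K2, K3))
    assert sv.lipschitz_gain(bounds) == pytest.approx(expected)


def test_negative_bounds_rejected():
    with pytest.raises(ValueError):
        sv.BoundEstimates(K1=-1, K2=1, K3=1, M=1)


class TestEstimateBounds:
    def _uniform_coupled(self, grid, u1, u2, v1, v2):
        drive = sv.State(grid=grid, u1=np.full(grid.shape, u1),
                         u2=np.full(grid.shape, u2))
        resp = sv.State(grid=grid, u1=np.full(grid.shape, v1),
                        u2=np.full(grid.shape, v2))
        return CoupledState(drive=drive, response=resp)

    def test_sup_of_constants(self, grid_1d):
        snap = self._uniform_coupled(grid_1d, 3.5, 0.28, 1.0, 0.6)
        b = sv.estimate_bounds([snap], margin=1.0)
        assert (b.K1, b.K2, b.K3) == pytest.approx((3.5, 0.28, 1.0))

    def test_margin_inflates(self, grid_1d):
        snap = self._uniform_coupled(grid_1d, 3.5, 0.28, 1.0, 0.6)
        b = sv.estimate_bounds([snap], margin=1.2)
        assert (b.K1, b.K2, b.K3) == pytest.approx((4.2, 0.336, 1.2))
        assert not b.positivity_violation

    def test_negative_sample_flags_positivity(self, grid_1d):
        snap = self._uniform_coupled(grid_1d, 3.5, 0.28, 1.0, -0.1)
        b = sv.estimate_bounds([snap], margin=1.0)
        assert b.positivity_violation
        assert b.K3 == pytest.approx(1.0)  # sup of the field, not |field|

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sv.estimate_bounds([])


class TestControlLaw:
    def test_no_control_at_synchrony(self, ref_params):
        gains = sv.ControlGains.from_K(15.0, ref_params)
        U1, U2 = sv.control_law(np.zeros(5), np.zeros(5), gains)
        assert not U1.any() and not U2.any()

    def test_reference_coefficients(self, ref_params):
        gains = sv.ControlGains.from_K(15.0, ref_params)
        U1, U2 = sv.control_law(np.array([1.0]), np.array([0.0]), gains)
        assert U1[0] == pytest.approx(-29.0)  # -(2K - 1)
        assert U2[0] == pytest.approx(0.0)
        assert gains.is_canonical

    @settings(max_examples=50, derandomize=True)
    @given(
        K=st.floats(min_value=0.5, max_value=100),
        b=st.floats(min_value=0.05, max_value=5),
        seed=st.integers(min_value=0, max_value=2**20),
    )
    def test_closed_loop_identity(self, K, b, seed):
        """Substituting the law into the open-loop error system yields
        uniform damping: b*e2 - e1 + U1 == -2K*e1, -b*e2 + U2 == -2K*e2."""
        params = sv.KineticParams(a=1.0, b=b, d1=1, d2=1)
        gains = sv.ControlGains.from_K(K, params)
        rng = np.random.default_rng(seed)
        e1 = rng.normal(scale=3.0, size=64)
        e2 = rng.normal(scale=3.0, size=64)
        U1, U2 = sv.control_law(e1, e2, gains)
        lhs1 = b * e2 - e1 + U1
        lhs2 = -b * e2 + U2
        scale = 2 * K * max(np.abs(e1).max(), np.abs(e2).max())
        assert np.abs(lhs1 - (-2 * K * e1)).max() < 1e-12 * scale
        assert np.abs(lhs2 - (-2 * K * e2)).max() < 1e-12 * scale

    def test_shape_mismatch_rejected(self, ref_params):
        gains = sv.ControlGains.from_K(1.0, ref_params)
        with pytest.raises(ValueError):
            sv.control_law(np.zeros(3), np.zeros(4), gains)


class TestOpenLoopErrorRhs:
    def test_zero_error_gives_zero_rhs(self, ref_params, grid_1d):
        ic = sv.ic_reference_drive(grid_1d)
        cs = CoupledState(drive=ic, response=ic)
        rhs1, rhs2 = open_loop_error_rhs(cs, ref_params)
        np.testing.assert_array_equal(rhs1, 0.0)
        np.testing.assert_array_equal(rhs2, 0.0)

    def test_cubic_difference_value(self, ref_params, grid_1d):
        # v = (2, 1), u = (1, 1): v1^2 v2 - u1^2 u2 = 4 - 1 = 3
        drive = sv.State(grid=grid_1d, u1=np.ones(51), u2=np.ones(51))
        resp = sv.State(grid=grid_1d, u1=np.full(51, 2.0), u2=np.ones(51))
        cs = CoupledState(drive=drive, response=resp)
        rhs1, rhs2 = open_loop_error_rhs(cs, ref_params)
        # uniform fields: no diffusion; rhs1 = b*0 - 1 + 3, rhs2 = -b*0 - 3
        np.testing.assert_allclose(rhs1, 2.0, atol=1e-13)
        np.testing.assert_allclose(rhs2, -3.0, atol=1e-13)

    def test_one_step_matches_difference_of_trajectories(self, ref_params, grid_1d):
        """Euler-stepping the error system directly equals the difference of
        separately stepped drive and response (linearity of the update)."""
        drive = sv.ic_reference_drive(grid_1d)
        resp = sv.ic_reference_response(grid_1d)
        cs = CoupledState(drive=drive, response=resp)
        dt = 0.01
        rhs1, rhs2 = open_loop_error_rhs(cs, ref_params)
        e1_direct = cs.e1 + dt * rhs1
        e2_direct = cs.e2 + dt * rhs2
        d_next = sv.step_explicit(drive, ref_params, dt)
        r_next = sv.step_explicit(resp, ref_params, dt)
        np.testing.assert_allclose(e1_direct, r_next.u1 - d_next.u1, atol=1e-12)
        np.testing.assert_allclose(e2_direct, r_next.u2 - d_next.u2, atol=1e-12)


class TestVerifyLipschitzBound:
    def _uniform_pair(self, grid, u, v):
        drive = sv.State(grid=grid, u1=np.full(grid.shape, u[0]),
                         u2=np.full(grid.shape, u[1]))
        resp = sv.State(grid=grid, u1=np.full(grid.shape, v[0]),
                        u2=np.full(grid.shape, v[1]))
        return CoupledState(drive=drive, response=resp)

    def test_bound_holds_at_synchrony(self, ref_params, grid_1d):
        ic = sv.ic_reference_drive(grid_1d)
        report = sv.verify_lipschitz_bound([CoupledState(drive=ic, response=ic)], 1.0)
        assert report.holds and report.max_ratio == 0.0

    def test_bound_from_lipschitz_gain(self, grid_1d):
        # u = (1, 1), v = (2, 1): |cubic diff| = 3 <= K * |e1| with
        # K = max(K3^2, K2*(K1+K3)) = max(4, 3) = 4
        snap = self._uniform_pair(grid_1d, (1, 1), (2, 1))
        bounds = sv.BoundEstimates(K1=1, K2=1, K3=2, M=2)
        K = sv.lipschitz_gain(bounds)
        assert K == pytest.approx(4.0)
        assert sv.verify_lipschitz_bound([snap], K).holds

    def test_undersized_gain_reports_violation(self, grid_1d):
        snap = self._uniform_pair(grid_1d, (1, 1), (2, 1))
        report = sv.verify_lipschitz_bound([snap], 1.0)
        assert not report.holds
        assert report.n_violations > 0
        assert report.max_ratio == pytest.approx(3.0)


class TestSynchronize:
    def test_identical_ics_stay_synchronized(self, ref_params, grid_1d):
        ic = sv.ic_reference_drive(grid_1d)
        tcfg = sv.TimeSteppingConfig.from_cfl(ref_params, grid_1d, t_end=8.0)
        gains = sv.ControlGains.from_K(15.0, ref_params)
        snaps, series = sv.synchronize(ic, ic, ref_params, gains, tcfg)
        assert series.l2_error.max() == 0.0
        for snap in snaps:
            np.testing.assert_array_equal(snap.e1, 0.0)

    def test_reference_run_synchronizes(self, controlled_run):
        _, series = controlled_run
        assert series.l2_error[-1] < 1e-6 * series.l2_error[0]

    def test_uncontrolled_pair_does_not_synchronize(self, uncontrolled_run):
        _, series = uncontrolled_run
        assert series.l2_error[-1] > 0.1 * series.l2_error[0]

    def test_swap_symmetry_negates_error(self, ref_params, grid_1d):
        """Swapping the (uncontrolled) drive and response ICs merely
        relabels the two systems, so the error trajectory is exactly
        negated; the control law itself is odd in e, so the same law
        structure applies to -e."""
        a_ic = sv.ic_reference_drive(grid_1d)
        b_ic = sv.ic_reference_response(grid_1d)
        tcfg = sv.TimeSteppingConfig.from_cfl(ref_params, grid_1d, t_end=4.0)
        snaps_ab, _ = sv.synchronize(a_ic, b_ic, ref_params, None, tcfg)
        snaps_ba, _ = sv.synchronize(b_ic, a_ic, ref_params, None, tcfg)
        for sab, sba in zip(snaps_ab, snaps_ba):
            np.testing.assert_array_equal(sab.e1, -sba.e1)
            np.testing.assert_array_equal(sab.e2, -sba.e2)
        gains = sv.ControlGains.from_K(15.0, ref_params)
        e1, e2 = snaps_ab[0].e1, snaps_ab[0].e2
        U1, U2 = sv.control_law(e1, e2, gains)
        W1, W2 = sv.control_law(-e1, -e2, gains)
        np.testing.assert_array_equal(U1, -W1)
        np.testing.assert_array_equal(U2, -W2)

    @pytest.mark.parametrize("a, b", [(1.0, 0.1), (2.5, 0.5), (4.0, 1.0)])
    def test_auto_gain_pipeline_synchronizes(self, a, b, grid_1d):
        """Bound estimation -> Lipschitz gain -> controlled run drives the
        final L2 error below 1e-4 of the initial across the kinetic range."""
        params = sv.KineticParams(a=a, b=b, d1=0.01, d2=1.0)
        tcfg = sv.TimeSteppingConfig.from_cfl(params, grid_1d, t_end=100.0)
        drive_ic = sv.ic_reference_drive(grid_1d)
        resp_ic = sv.ic_reference_response(grid_1d)
        open_snaps, _ = sv.synchronize(drive_ic, resp_ic, params, None, tcfg)
        K = sv.lipschitz_gain(sv.estimate_bounds(open_snaps, margin=1.2))
        gains = sv.ControlGains.from_K(K, params)
        _, series = sv.synchronize(drive_ic, resp_ic, params, gains, tcfg)
        assert series.l2_error[-1] < 1e-4 * series.l2_error[0]
        assert sv.check_monotone_decrease(series).passed

    def test_mismatched_grids_rejected(self, ref_params):
        g1, g2 = sv.build_grid(1, 10, 51), sv.build_grid(1, 10, 41)
        tcfg = sv.TimeSteppingConfig.from_cfl(ref_params, g1, t_end=1.0)
        with pytest.raises(ValueError):
            sv.synchronize(
                sv.ic_reference_drive(g1), sv.ic_reference_drive(g2),
                ref_params, None, tcfg,
            )

    def test_blow_up_names_subsystem(self, ref_params, grid_1d):
        bad = sv.TimeSteppingConfig(
            dt=10 * sv.stable_dt(ref_params, grid_1d, 1.0),
            t_end=50.0, snapshot_interval=4.0,
        )
        with pytest.raises(sv.BlowUpError) as err:
            sv.synchronize(
                sv.ic_reference_drive(grid_1d), sv.ic_reference_response(grid_1d),
                ref_params, None, bad,
            )
        assert err.value.system in ("drive", "response")
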