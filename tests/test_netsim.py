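"""Network construction and dynamics: kernels, drive statistics,
normalization, Euler integration, invariances."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import special

from multicue.circstats import wrap_deg
from multicue.decode import population_vector
from multicue.netsim import (
    CueStimulus,
    Epoch,
    NetworkParams,
    SimulationDiverged,
    build_kernels,
    divisive_normalize,
    feedforward_drive,
    simulate,
    step,
    u0_scale,
)


class TestParams:
    @pytest.mark.parametrize("bad", [
        dict(n=4), dict(dt=0.2), dict(a=-1.0), dict(omega=0.0),
        dict(j_int=0.0), dict(j_int=1.5), dict(j_rp=1.0), dict(j_c=0.0),
    ])
    def test_validation(self, bad):
        with pytest.raises(ValueError):
            NetworkParams(**bad)

    def test_grid_covers_half_open_interval(self):
        th = NetworkParams(n=36).theta_deg
        assert th.min() > -180.0 and th.max() == pytest.approx(180.0)
        assert np.allclose(np.diff(th), 10.0)


class TestU0:
    def test_closed_form(self):
        p = NetworkParams()
        expected = p.j_c * math.exp(1.5) / (
            2 * math.pi * 3e-4 * 1.5 * special.i0(1.5))
        assert u0_scale(p) == pytest.approx(expected, rel=1e-12)

    def test_scalings(self):
        p = NetworkParams()
        assert u0_scale(dataclasses.replace(p, j_c=2 * p.j_c)) == \
            pytest.approx(2 * u0_scale(p))
        assert u0_scale(dataclasses.replace(p, omega=2 * p.omega)) == \
            pytest.approx(0.5 * u0_scale(p))


class TestKernels:
    def test_recurrent_symmetric_circulant_with_peak(self):
        p = NetworkParams()  # n = 180: density weight is exactly 1
        k = build_kernels(p)
        assert np.allclose(k.w_rc, k.w_rc.T, atol=1e-15)
        row_sums = k.w_rc.sum(axis=1)
        assert np.ptp(row_sums) < 1e-12
        peak = p.J_rc * math.exp(p.a) / (2 * math.pi * special.i0(p.a))
        assert np.diag(k.w_rc).max() == pytest.approx(peak, rel=1e-12)

    def test_opposite_kernel_is_shifted_congruent(self):
        p = NetworkParams(n=36)
        k = build_kernels(p)
        assert np.allclose(k.w_rp_o[0], np.roll(k.w_rp_c[0], 18, axis=1),
                           atol=1e-15)
        # maximal at 180 deg offset, with the congruent peak value
        i0 = np.argmin(np.abs(p.theta_deg - 0.0))
        i180 = np.argmin(np.abs(p.theta_deg - 180.0))
        row = k.w_rp_o[0][i0]
        assert np.argmax(row) == i180
        peak = p.J_rp * math.exp(p.a) / (2 * math.pi * special.i0(p.a)) \
            * p.grid_weight
        assert row[i180] == pytest.approx(peak, rel=1e-12)

    def test_jitter_perturbs_reciprocal_only_and_is_seeded(self):
        p = NetworkParams(n=36, jitter=0.9, seed=5)
        k1 = build_kernels(p)
        k2 = build_kernels(p)
        base = build_kernels(dataclasses.replace(p, jitter=0.0))
        assert np.array_equal(k1.w_rp_c, k2.w_rp_c)
        assert np.array_equal(k1.w_rc, base.w_rc)
        assert not np.allclose(k1.w_rp_c, base.w_rp_c)
        assert np.all(k1.w_rp_c >= 0) and np.all(k1.w_rp_o >= 0)
        peak = base.w_rp_c.max()
        assert np.abs(k1.w_rp_c - base.w_rp_c).max() <= 0.9 * peak + 1e-12


class TestDrive:
    def test_mean_profile(self, small_params, rng):
        p = dataclasses.replace(small_params, fano=0.0)
        stim = CueStimulus(0.0, 0.5, module=1)
        drive = feedforward_drive(stim, p, rng, n_steps=3)
        i_peak = np.argmin(np.abs(p.theta_deg))
        assert drive[0, i_peak] == pytest.approx(0.5 * p.u0 + p.i_b)
        i_anti = np.argmin(np.abs(wrap_deg(p.theta_deg - 180.0)))
        assert drive[0, i_anti] == pytest.approx(
            0.5 * p.u0 * math.exp(-p.a) + p.i_b)
        off = feedforward_drive(CueStimulus(0.0, 0.0, module=1), p, rng, 2)
        assert np.allclose(off, p.i_b)

    def test_fano_factor_of_integrated_input(self, small_params, rng):
        # oracle: sample statistics of the generator itself
        p = small_params
        stim = CueStimulus(0.0, 0.8, module=1)
        drive = feedforward_drive(stim, p, rng, n_steps=10_000)
        integrated_var = drive.var(axis=0) * p.dt
        mean = drive.mean(axis=0)
        ratio = integrated_var / mean
        assert np.median(ratio) == pytest.approx(p.fano, rel=0.05)


class TestNormalization:
    def test_rectification_and_pool(self, small_params):
        p = small_params
        u = -np.ones((2, 2, p.n))
        r, d = divisive_normalize(u, p)
        assert np.all(r == 0) and np.all(d == 0)

    def test_pool_includes_other_group(self, small_params):
        p = small_params
        u = np.zeros((2, 2, p.n))
        u[0, 0] = 2.0
        u[0, 1] = 1.0
        r, d = divisive_normalize(u, p)
        s_c = (4.0 * p.n) * p.grid_weight
        s_o = (1.0 * p.n) * p.grid_weight
        assert d[0, 0] == pytest.approx(s_c + p.j_int * s_o)
        assert d[0, 1] == pytest.approx(s_o + p.j_int * s_c)

    def test_uniform_fixed_point_bound(self, small_params):
        # closed form on uniform input: r = u^2 / (1 + omega * W * n * u^2)
        p = small_params
        u = np.zeros((2, 2, p.n))
        u[1, 0] = 5.0
        r, _ = divisive_normalize(u, p)
        expected = 25.0 / (1.0 + p.omega * p.grid_weight * p.n * 25.0)
        assert np.allclose(r[1, 0], expected)


class TestStep:
    def test_zero_state_zero_drive_is_fixed_point(self, small_params):
        p = small_params
        k = build_kernels(p)
        u = np.zeros((2, 2, p.n))
        out = step(u, k, np.zeros_like(u), p)
        assert np.all(out == 0)

    def test_noise_free_convergence_to_stationary_bump(self, small_params):
        p = dataclasses.replace(small_params, fano=0.0)
        k = build_kernels(p)
        u = np.zeros((2, 2, p.n))
        drive = np.zeros_like(u)
        profile = 0.5 * p.u0 * np.exp(p.a * (np.cos(p.theta_rad) - 1) / 2)
        drive[:] = profile + p.i_b
        for _ in range(int(100 / p.dt)):
            u_new = step(u, k, drive, p)
            u = u_new
        residual = np.abs(step(u, k, drive, p) - u).max() / p.dt
        assert residual < 1e-6
        assert u[0, 0].max() > 5 * u[0, 0].min()  # a genuine bump

    def test_non_finite_state_detected(self, small_params):
        p = small_params
        k = build_kernels(p)
        u = np.zeros((2, 2, p.n))
        u[0, 0, 0] = np.nan
        with pytest.raises(SimulationDiverged):
            step(u, k, np.zeros_like(u), p)


class TestSimulate:
    def test_deterministic_given_seed(self, small_params):
        cues = [CueStimulus(-30.0, 0.5, module=1)]
        t1 = simulate(cues, small_params, duration=5.0, burn_in=2.0, seed=9)
        t2 = simulate(cues, small_params, duration=5.0, burn_in=2.0, seed=9)
        assert np.array_equal(t1.r, t2.r)
        t3 = simulate(cues, small_params, duration=5.0, burn_in=2.0, seed=10)
        assert not np.array_equal(t1.r, t3.r)

    def test_sample_count_and_stride(self, small_params):
        cues = [CueStimulus(0.0, 0.5, module=1)]
        tr = simulate(cues, small_params, duration=5.0, burn_in=1.0, stride=4)
        n_steps = int(round(5.0 / small_params.dt))
        assert tr.n_samples == (n_steps + 3) // 4
        assert tr.times[0] > 0

    def test_epoch_concatenation(self, small_params):
        epochs = [Epoch(2.0, (CueStimulus(0.0, 0.5, module=1),)),
                  Epoch(3.0, ())]
        tr = simulate(epochs, small_params, burn_in=1.0)
        assert tr.n_samples == int(round(5.0 / small_params.dt))

    def test_rotation_equivariance(self, small_params):
        # noise-free, jitter off: shifting the cue by a grid multiple
        # shifts every bump profile by exactly that amount
        p = dataclasses.replace(small_params, fano=0.0)
        shift_deg = 3 * (360.0 / p.n)
        t_a = simulate([CueStimulus(0.0, 0.5, module=1)], p,
                       duration=2.0, burn_in=20.0)
        t_b = simulate([CueStimulus(shift_deg, 0.5, module=1)], p,
                       duration=2.0, burn_in=20.0)
        for m in (1, 2):
            for nt in "co":
                rolled = np.roll(t_a.mean_rates(m, nt), 3)
                assert np.allclose(rolled, t_b.mean_rates(m, nt),
                                   rtol=1e-6, atol=1e-9)

    def test_module_symmetry(self, small_params):
        # swapping which module is cued mirrors the traces (noise-free)
        p = dataclasses.replace(small_params, fano=0.0)
        t_a = simulate([CueStimulus(40.0, 0.5, module=1)], p, duration=2.0,
                       burn_in=20.0)
        t_b = simulate([CueStimulus(40.0, 0.5, module=2)], p, duration=2.0,
                       burn_in=20.0)
        for nt in "co":
            assert np.allclose(t_a.mean_rates(1, nt), t_b.mean_rates(2, nt),
                               rtol=1e-6, atol=1e-9)

    def test_opposite_group_geometry(self, small_params):
        # direct-cue module: both bumps at the cue; other module: congruent
        # bump at the cue, opposite bump antipodal
        p = small_params
        tr = simulate([CueStimulus(-30.0, 0.5, module=1)], p, duration=30.0,
                      burn_in=30.0, seed=2)
        th = p.theta_deg
        pos = {(m, nt): population_vector(tr.mean_rates(m, nt), th)
               for m in (1, 2) for nt in "co"}
        grid = 360.0 / p.n
        assert abs(wrap_deg(pos[(1, "c")] - (-30.0))) < 2 * grid
        assert abs(wrap_deg(pos[(1, "o")] - (-30.0))) < 2 * grid
        assert abs(wrap_deg(pos[(2, "c")] - (-30.0))) < 2 * grid
        assert abs(wrap_deg(pos[(2, "o")] - 150.0)) < 2 * grid

    def test_no_winner_take_all_under_combined_cues(self, small_params):
        tr = simulate([CueStimulus(-30.0, 0.5, module=1),
                       CueStimulus(30.0, 0.5, module=2)], small_params,
                      duration=30.0, burn_in=30.0, seed=3)
        for nt in "co":
            assert tr.mean_rates(1, nt).max() > 1.0

    def test_grid_invariance_of_decoded_mean(self, default_params):
        # halving the grid leaves the noise-free bump position and height
        # essentially unchanged (density-weighted sums)
        p180 = dataclasses.replace(default_params, fano=0.0)
        p90 = dataclasses.replace(default_params, n=90, fano=0.0)
        cues = [CueStimulus(-30.0, 0.5, module=1)]
        a = simulate(cues, p180, duration=1.0, burn_in=30.0)
        b = simulate(cues, p90, duration=1.0, burn_in=30.0)
        pa = population_vector(a.mean_rates(1, "c"), p180.theta_deg)
        pb = population_vector(b.mean_rates(1, "c"), p90.theta_deg)
        assert abs(wrap_deg(pa - pb)) < 0.5
        assert a.mean_rates(1, "c").max() == pytest.approx(
            b.mean_rates(1, "c").max(), rel=0.05)
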