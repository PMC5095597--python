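"""Bloch-McConnell propagation: generator structure, propagator algebra,
steady states, pulse trains, and spectral invariants."""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings
from hypothesis import strategies as st

from cestkit import (ExchangePool, InvalidInputError, SaturationScheme,
                     SpinSystem, cw_equivalent_b1, default_scheme,
                     simulate_pulse_train, simulate_zspectrum, water_pool)
from cestkit.bloch import (_expm_batch, _simulate_offsets, build_generator,
                           build_generators, cw_steady_state, propagate,
                           train_propagators)
from cestkit.saturation import gaussian_segments
from cestkit.spinsystem import GAMMA_HZ_PER_UT


class TestGenerator:
    def test_water_only_no_saturation_is_pure_relaxation(self, water_system):
        A = build_generator(water_system, 0.0, 0.0)
        # z-row: dMz/dt = -Mz/T1 + M0/T1
        assert A[2, 2] == pytest.approx(-1 / 1.7)
        assert A[2, -1] == pytest.approx(1 / 1.7)
        assert A[2, 1] == 0.0  # no B1 coupling

    def test_b1_zero_decouples_transverse_longitudinal(self, three_pool_system):
        A = build_generator(three_pool_system, 0.0, 2.8)
        for i in range(three_pool_system.n_pools):
            assert A[3 * i + 1, 3 * i + 2] == 0.0
            assert A[3 * i + 2, 3 * i + 1] == 0.0

    def test_detailed_balance_exchange_entries(self, two_pool_system):
        A = build_generator(two_pool_system, 0.0, 0.0)
        pool = two_pool_system.pools[1]
        # water z gains from pool z at the pool->water rate; pool z gains
        # from water z at rate * fraction
        assert A[2, 5] == pytest.approx(pool.rate)
        assert A[5, 2] == pytest.approx(pool.rate * pool.fraction)

    def test_nonfinite_parameters_rejected(self, water_system):
        with pytest.raises(InvalidInputError):
            build_generator(water_system, np.nan, 0.0)
        with pytest.raises(InvalidInputError):
            build_generator(water_system, -0.1, 0.0)

    def test_smallest_eigenvalue_matches_time_stepped_decay(self, two_pool_system):
        """The slowest generator mode must match a brute-force explicit
        Runge-Kutta integration of the same system."""
        from scipy.integrate import solve_ivp

        A = build_generator(two_pool_system, 0.8, 2.8)
        state0 = two_pool_system.equilibrium_state()

        def rhs(t, y):
            return A @ y

        sol = solve_ivp(rhs, (0, 30.0), state0, t_eval=[20.0, 25.0, 30.0],
                        rtol=1e-10, atol=1e-12)
        mz = sol.y[2]
        ss = cw_steady_state(two_pool_system, 0.8, [2.8])[0]
        # decay rate of the residual toward steady state
        rate_num = -np.log(abs(mz[2] - ss) / abs(mz[0] - ss)) / 10.0
        eig = np.linalg.eigvals(A[:-1, :-1])
        slowest = -max(e.real for e in eig if e.real < -1e-12)
        assert rate_num == pytest.approx(slowest, rel=5e-2)


class TestPropagate:
    def test_zero_duration_is_identity(self, water_system, rng):
        A = build_generator(water_system, 0.5, 1.0)
        state = rng.normal(size=4)
        assert np.array_equal(propagate(A, 0.0, state), state)

    def test_long_time_relaxation_limit(self, water_system):
        A = build_generator(water_system, 0.0, 0.0)
        state = np.array([0.0, 0.0, 0.0, 1.0])  # Mz = 0
        out = propagate(A, 50 * 1.7, state)
        assert out[2] == pytest.approx(1.0, abs=1e-6)

    def test_composition_property(self, three_pool_system, rng):
        A = build_generator(three_pool_system, 0.8, 2.8)
        state = three_pool_system.equilibrium_state()
        once = propagate(A, 0.37, state)
        stepped = state
        for _ in range(10):
            stepped = propagate(A, 0.037, stepped)
        assert np.allclose(once, stepped, rtol=1e-10, atol=1e-12)

    def test_negative_duration_rejected(self, water_system):
        A = build_generator(water_system, 0.0, 0.0)
        with pytest.raises(InvalidInputError):
            propagate(A, -1.0, water_system.equilibrium_state())


class TestExpmBatch:
    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_scipy_expm(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(scale=3.0, size=(4, 7, 7))
        t = float(rng.uniform(0.01, 2.0))
        P = _expm_batch(A, t)
        ref = np.stack([scipy.linalg.expm(a * t) for a in A])
        assert np.allclose(P, ref, rtol=1e-9, atol=1e-9)

    def test_large_norm_grouping(self, three_pool_system):
        # reference offsets at +/-100 ppm force extra squarings for a few
        # batch members only
        offs = np.array([0.0, 2.8, -100.0, 100.0])
        A = build_generators(three_pool_system, np.full(4, 0.7), offs)
        P = _expm_batch(A, 0.013)
        ref = np.stack([scipy.linalg.expm(a * 0.013) for a in A])
        assert np.allclose(P, ref, rtol=1e-9, atol=1e-10)


class TestSteadyState:
    def test_cw_steady_state_matches_propagation(self, three_pool_system):
        ss = cw_steady_state(three_pool_system, 0.42, [2.8])[0]
        A = build_generator(three_pool_system, 0.42, 2.8)
        out = propagate(A, 60.0, three_pool_system.equilibrium_state())
        assert ss == pytest.approx(out[2], abs=1e-8)

    def test_oracle_equivalence_random_systems(self, rng):
        """Null-space linear solve vs long-time propagation for randomized
        2- and 3-pool systems."""
        for _ in range(10):
            pools = [water_pool(rng.uniform(0.5, 2.5), rng.uniform(0.04, 0.2))]
            for i in range(int(rng.integers(1, 3))):
                pools.append(ExchangePool(
                    f"p{i}", rng.uniform(-4, 4), rng.uniform(20, 3000),
                    rng.uniform(1e-4, 5e-3), rng.uniform(0.5, 1.5),
                    rng.uniform(0.003, 0.03)))
            system = SpinSystem(tuple(pools))
            offset = float(rng.uniform(-5, 5))
            b1 = float(rng.uniform(0.2, 1.5))
            ss = cw_steady_state(system, b1, [offset])[0]
            A = build_generator(system, b1, offset)
            t_long = 60.0 * max(p.t1 for p in pools)
            prop = propagate(A, t_long, system.equilibrium_state())[2]
            assert ss == pytest.approx(prop, abs=1e-8)


class TestPulseTrain:
    def test_zero_power_limit(self, three_pool_system, short_scheme):
        tiny = short_scheme.replace(flip_angle=1e-4)
        z = simulate_pulse_train(three_pool_system, tiny, 2.8)
        assert z == pytest.approx(1.0, abs=1e-4)

    def test_far_off_resonance_reference_near_unity(self, three_pool_system,
                                                    full_scheme):
        for off in (-100.0, 100.0):
            z = simulate_pulse_train(three_pool_system, full_scheme, off)
            assert abs(z - 1.0) < 0.01

    def test_pulsed_agrees_with_cw_at_equivalent_power(self, full_scheme):
        """Saturation-transfer difference under the train vs CW at the
        rms-equivalent B1, within 15% relative (exact agreement is not
        expected between waveforms)."""
        amine = ExchangePool("amine", 2.8, 1000.0, 5e-4, 1.0, 0.01)
        water = water_pool(1.7, 0.14)
        with_pool = SpinSystem((water, amine))
        without = SpinSystem((water,))
        dz_train = (simulate_pulse_train(without, full_scheme, 2.8)
                    - simulate_pulse_train(with_pool, full_scheme, 2.8))
        b1 = cw_equivalent_b1(full_scheme)
        dz_cw = (cw_steady_state(without, b1, [2.8])[0]
                 - cw_steady_state(with_pool, b1, [2.8])[0])
        assert dz_train == pytest.approx(dz_cw, rel=0.15)

    def test_train_propagator_equals_explicit_segment_product(
            self, two_pool_system):
        scheme = SaturationScheme(
            mode="gaussian_train", n_pulses=3, pulse_duration=0.026,
            flip_angle=180.0, duty_cycle=0.5, n_segments=8,
            offsets=(2.8,))
        P = train_propagators(two_pool_system, scheme, [2.8])[0]
        amps, dt = gaussian_segments(scheme)
        step = np.eye(7)
        for a in amps:
            A = build_generator(two_pool_system, a, 2.8)
            step = scipy.linalg.expm(A * dt) @ step
        gap = scipy.linalg.expm(
            build_generator(two_pool_system, 0.0, 2.8) * scheme.gap)
        ref = np.linalg.matrix_power(gap @ step, 3)
        assert np.allclose(P, ref, rtol=1e-9, atol=1e-11)


class TestZSpectrum:
    def test_water_only_spectrum_symmetric(self, water_system, short_scheme):
        spec = simulate_zspectrum(water_system, short_scheme)
        assert np.abs(spec.signals - spec.signals[::-1]).max() <= 1e-9

    def test_all_pools_at_zero_ppm_symmetric(self, short_scheme):
        pools = (water_pool(1.7, 0.14),
                 ExchangePool("x", 0.0, 500.0, 1e-3, 1.0, 0.01))
        spec = simulate_zspectrum(SpinSystem(pools), short_scheme)
        assert np.abs(spec.signals - spec.signals[::-1]).max() <= 1e-9

    def test_null_pool_equals_water_only(self, water_system, short_scheme):
        pools = (water_system.pools[0],
                 ExchangePool("amine", 2.8, 1000.0, 0.0, 1.0, 0.01))
        with_null = simulate_zspectrum(SpinSystem(pools), short_scheme)
        base = simulate_zspectrum(water_system, short_scheme)
        assert np.abs(with_null.signals - base.signals).max() <= 1e-12

    def test_three_pool_spectrum_structure(self, three_pool_system, full_scheme):
        spec = simulate_zspectrum(three_pool_system, full_scheme)
        assert spec.offsets[np.argmin(spec.signals)] == pytest.approx(0.0)
        z28 = spec.interp(2.8)
        zref = 0.5 * (spec.interp(1.4) + spec.interp(4.2))
        assert z28 < spec.interp(-2.8) + 0.05  # amine dip present
        assert z28 < zref

    def test_monotone_in_fraction(self, short_scheme):
        z_prev = None
        for frac in (1e-4, 5e-4, 2e-3, 5e-3):
            pools = (water_pool(1.7, 0.14),
                     ExchangePool("amine", 2.8, 1000.0, frac, 1.0, 0.01))
            z = simulate_pulse_train(SpinSystem(pools), short_scheme, 2.8)
            if z_prev is not None:
                assert z < z_prev
            z_prev = z

    def test_segment_convergence_at_default(self, three_pool_system):
        """Doubling the acquisition-grade discretization changes no
        simulated Z value by more than 1e-4."""
        offs = np.linspace(-10, 10, 85)
        base = default_scheme()
        z1 = _simulate_offsets(three_pool_system, base, offs)
        z2 = _simulate_offsets(three_pool_system,
                               base.replace(n_segments=256), offs)
        assert np.abs(z1 - z2).max() <= 1e-4

    def test_empty_offsets_rejected(self, water_system):
        scheme = SaturationScheme(mode="cw", b1=0.5, duration=5.0, offsets=())
        with pytest.raises(InvalidInputError):
            simulate_zspectrum(water_system, scheme)


class TestCwEquivalentB1:
    def test_cw_scheme_returns_own_b1(self):
        s = SaturationScheme(mode="cw", b1=0.8, duration=5.0, offsets=(0.0,))
        assert cw_equivalent_b1(s) == 0.8

    def test_rectangular_pulse_closed_form(self):
        # near-rectangular envelope: huge n_segments with a flat cap is
        # emulated by comparing against the analytic flip-angle amplitude
        s = SaturationScheme(mode="gaussian_train", n_pulses=1,
                             pulse_duration=0.026, flip_angle=180.0,
                             duty_cycle=1.0, n_segments=64, offsets=(0.0,))
        # a rectangular 180 deg / 26 ms pulse has B1 = 0.5 / (gamma * 0.026)
        b1_rect = 0.5 / (GAMMA_HZ_PER_UT * 0.026)
        assert b1_rect == pytest.approx(0.452, abs=2e-3)
        # the Gaussian's rms exceeds the rectangular amplitude at equal duty
        assert cw_equivalent_b1(s) > b1_rect

    def test_default_scheme_equivalent_power(self):
        """The 300 x 26 ms / 180 deg / 50% duty train: rms-equivalent CW
        power, logged as a diagnostic against the protocol's nominal value."""
        b1 = cw_equivalent_b1(default_scheme())
        assert b1 == pytest.approx(0.4166, abs=2e-3)
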