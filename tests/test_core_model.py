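"""Unit tests for the coupled-oscillator virtual player."""

import math

import numpy as np
import pytest

from mirrorgame import (
    EstimationError,
    HandParams,
    ModelConfig,
    angular_accel,
    estimate_params,
    perlin_noise,
    position_of,
    radius_at,
    simulate_virtual,
    step,
    wrap_phase,
)
from mirrorgame.core_model import OscillatorState, initial_state

from conftest import whole_period_circle


class TestPerlinNoise:
    @pytest.mark.parametrize("t", [0.0, 1.0, 7.0, 59.0])
    @pytest.mark.parametrize("seed", [0, 1, 12345])
    def test_vanishes_at_lattice_nodes(self, t, seed):
        assert perlin_noise(t, seed, 0.085) == 0.0

    def test_zero_amplitude_is_zero(self):
        t = np.linspace(0, 60, 777)
        assert np.all(perlin_noise(t, 3, 0.0) == 0.0)

    def test_bounded_and_continuous_on_dense_scan(self):
        # 1 kHz scan over a full trial: values stay inside +/-amplitude
        # and step-to-step jumps are small (continuity), with the jump
        # bound taken from the scan itself at double resolution.
        amp = 0.085
        t = np.arange(0, 60, 0.001)
        v = perlin_noise(t, 99, amp)
        assert np.max(np.abs(v)) <= amp
        jumps = np.abs(np.diff(v))
        # oracle bound: a half-step scan caps the local slope, so 1 ms
        # jumps can be at most ~2x the 0.5 ms jumps
        t2 = np.arange(0, 60, 0.0005)
        jumps2 = np.abs(np.diff(perlin_noise(t2, 99, amp)))
        assert np.max(jumps) <= 2.2 * np.max(jumps2)
        # crude absolute continuity bound: < 1% of the range per ms
        assert np.max(jumps) < 0.01 * 2 * amp

    def test_deterministic_and_seed_dependent(self):
        t = np.linspace(0, 10, 501)
        a = perlin_noise(t, 7, 0.085)
        b = perlin_noise(t, 7, 0.085)
        c = perlin_noise(t, 8, 0.085)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            perlin_noise(0.5, 0, -1.0)


class TestRadius:
    def test_zero_noise_returns_radius0(self, hands):
        cfg = ModelConfig(noise_amplitude=0.0)
        t = np.linspace(0, 60, 301)
        assert np.all(radius_at(hands[0], t, cfg, 5) == 0.163)

    def test_bounds_from_amplitude(self, hands):
        cfg = ModelConfig()
        t = np.linspace(0, 60, 3001)
        r = radius_at(hands[1], t, cfg, 11)
        assert np.all(r >= 0.161 - 0.085) and np.all(r <= 0.161 + 0.085)

    def test_independent_streams_per_seed_and_side(self, hands):
        cfg = ModelConfig()
        t = np.linspace(0, 60, 3001)
        a = radius_at(hands[0], t, cfg, 1)
        b = radius_at(hands[0], t, cfg, 2)
        assert not np.array_equal(a, b)
        left = HandParams(hands[0].center, 0.163, 2.695, "left")
        c = radius_at(left, t, cfg, 1)
        assert not np.array_equal(a, c)


class TestKinematics:
    def test_right_hand_phase_zero(self, hands):
        pos = position_of(hands[0], 0.0, 0.2)
        np.testing.assert_allclose(pos, hands[0].center + [0, 0, 0.2])

    def test_left_hand_phase_zero_flips_lateral(self, hands):
        pos = position_of(hands[1], 0.0, 0.2)
        np.testing.assert_allclose(pos, hands[1].center - [0, 0, 0.2])

    @pytest.mark.parametrize("side", ["right", "left"])
    def test_on_circle_identity(self, side):
        hand = HandParams([0.1, 1.0, -0.3], 0.15, 2.7, side)
        for theta in np.linspace(-math.pi, math.pi, 37):
            pos = position_of(hand, theta, 0.2)
            assert abs(np.linalg.norm(pos - hand.center) - 0.2) < 1e-12

    def test_position_stays_in_movement_plane(self, hands):
        for theta in np.linspace(-3, 3, 11):
            pos = position_of(hands[0], theta, 0.1)
            assert pos[0] == hands[0].center[0]


class TestCouplingDynamics:
    def _state(self, tr=0.0, tl=0.0):
        return OscillatorState(tr, tl, 2.695, 2.698, 0.0, 0)

    def test_zero_gains_zero_accel(self):
        cfg = ModelConfig(k_inter=0.0, k_intra=0.0)
        assert angular_accel(self._state(), 1.0, 2.0, cfg) == (0.0, 0.0)

    def test_aligned_phases_zero_accel(self):
        cfg = ModelConfig(k_inter=0.0075, k_intra=0.005)
        acc_r, _ = angular_accel(self._state(0.7, 0.7), 0.3, 0.7, cfg)
        assert acc_r == pytest.approx(0.0, abs=1e-15)

    def test_quarter_cycle_lead_gives_full_gain(self):
        cfg = ModelConfig(k_inter=0.0075, k_intra=0.0)
        acc_r, _ = angular_accel(self._state(0.0, 0.0), 0.0, math.pi / 2, cfg)
        assert acc_r == pytest.approx(0.0075)

    def test_decoupled_ignores_nan_human_phases(self):
        cfg = ModelConfig(k_inter=0.0, k_intra=0.005)
        acc = angular_accel(self._state(0.2, 0.9), math.nan, math.nan, cfg)
        assert all(math.isfinite(a) for a in acc)


class TestStep:
    def test_velocity_increment_arithmetic(self, hands):
        # acceleration k_inter * sin(pi/2) = 0.0075 over dt = 0.02
        cfg = ModelConfig(k_inter=0.0075, k_intra=0.0, noise_amplitude=0.0)
        state = initial_state(hands, 0)
        new, _, _ = step(state, 0.0, math.pi / 2, hands, cfg)
        assert new.omega_right - state.omega_right == pytest.approx(
            0.0075 * 0.02
        )

    def test_rejects_nonfinite_human_phase_when_coupled(self, hands):
        cfg = ModelConfig(k_inter=0.0075, noise_amplitude=0.0)
        with pytest.raises(ValueError):
            step(initial_state(hands, 0), math.nan, 0.0, hands, cfg)

    def test_constant_omega_circle(self, hands, quiet_config):
        # no coupling, no noise: omega frozen, phase advances linearly,
        # so the trajectory is a perfect circle with period 2*pi/omega
        tr, _ = simulate_virtual(hands, quiet_config, seed=0)
        radial = np.linalg.norm(tr.positions - hands[0].center, axis=1)
        np.testing.assert_allclose(radial, 0.163, atol=1e-12)
        y = tr.positions[:, 1] - hands[0].center[1]
        z = tr.positions[:, 2] - hands[0].center[2]
        theta = np.unwrap(np.arctan2(y, z))
        omega_emp = np.diff(theta) / quiet_config.dt
        np.testing.assert_allclose(omega_emp, 2.695, atol=1e-9)
        assert 2 * math.pi / 2.695 == pytest.approx(2.331, abs=5e-4)

    def test_iterated_steps_match_simulate_bitwise(self, hands):
        cfg = ModelConfig(k_inter=0.0, duration=5.0)
        tr, tl = simulate_virtual(hands, cfg, seed=42)
        state = initial_state(hands, 42)
        pos_r = [position_of(hands[0], 0.0,
                             radius_at(hands[0], 0.0, cfg, 42))]
        for _ in range(cfg.n_samples - 1):
            state, pr, pl = step(state, math.nan, math.nan, hands, cfg)
            pos_r.append(pr)
        assert np.array_equal(np.asarray(pos_r), tr.positions)


class TestSimulateVirtual:
    def test_sample_count_60s_at_50hz(self, hands):
        tr, tl = simulate_virtual(hands, ModelConfig(k_inter=0.0), seed=0)
        assert len(tr.times) == len(tl.times) == 3001

    def test_decoupled_output_invariant_to_phase_source(self, hands):
        cfg = ModelConfig(k_inter=0.0)
        a = simulate_virtual(hands, cfg, lambda t: (0.0, 0.0), seed=9)
        b = simulate_virtual(
            hands, cfg, lambda t: (math.sin(31 * t), -2.9), seed=9
        )
        assert np.array_equal(a[0].positions, b[0].positions)
        assert np.array_equal(a[1].positions, b[1].positions)

    def test_coupled_requires_phase_source(self, hands):
        with pytest.raises(ValueError):
            simulate_virtual(hands, ModelConfig(k_inter=0.0075), seed=0)

    def test_deterministic_given_seed(self, hands):
        cfg = ModelConfig(k_inter=0.0, duration=10.0)
        a = simulate_virtual(hands, cfg, seed=3)
        b = simulate_virtual(hands, cfg, seed=3)
        c = simulate_virtual(hands, cfg, seed=4)
        assert np.array_equal(a[0].positions, b[0].positions)
        assert not np.array_equal(a[0].positions, c[0].positions)

    def test_left_right_mirror_symmetry(self, quiet_config):
        # identical parameters and no noise: left and right positions are
        # mirror images through the plane z = c_z
        center = np.array([0.343, 1.3, 0.0])
        hands = (
            HandParams(center, 0.163, 2.695, "right"),
            HandParams(center, 0.163, 2.695, "left"),
        )
        tr, tl = simulate_virtual(hands, quiet_config, seed=0)
        np.testing.assert_allclose(
            tr.positions[:, 1], tl.positions[:, 1], atol=1e-12
        )
        np.testing.assert_allclose(
            tr.positions[:, 2] - center[2],
            -(tl.positions[:, 2] - center[2]),
            atol=1e-12,
        )

    def test_frequency_conserved_without_coupling_or_noise(
        self, hands, quiet_config
    ):
        tr, _ = simulate_virtual(hands, quiet_config, seed=0)
        y = tr.positions[:, 1] - hands[0].center[1]
        z = tr.positions[:, 2] - hands[0].center[2]
        omega = np.diff(np.unwrap(np.arctan2(y, z))) / quiet_config.dt
        assert np.ptp(omega) < 1e-9

    @pytest.mark.parametrize(
        "detuning,should_lock", [(0.10, True), (0.25, False)]
    )
    def test_phase_lock_vs_detuning(self, hands, detuning, should_lock):
        # second-order Kuramoto: lock iff |detuning| < 2*sqrt(k_inter)
        # (= 0.173 rad/s at the default gain); full separatrix sweep in
        # the acceptance suite
        cfg = ModelConfig(
            k_inter=0.0075, k_intra=0.0, noise_amplitude=0.0, duration=120.0
        )
        omega_h = 2.695 + detuning
        tr, _ = simulate_virtual(
            hands, cfg, lambda t: (omega_h * t, omega_h * t), seed=0
        )
        y = tr.positions[:, 1] - hands[0].center[1]
        z = tr.positions[:, 2] - hands[0].center[2]
        theta = np.unwrap(np.arctan2(y, z))
        phi = omega_h * tr.times - theta
        locked = np.max(np.abs(phi - phi[0])) < math.pi
        assert locked == should_lock


class TestEstimateParams:
    def test_exact_recovery_on_noiseless_circles(self):
        right, omega_r = whole_period_circle(side="right")
        left, omega_l = whole_period_circle(
            center=(0.343, 1.3, -0.25), radius=0.161, cycles=25, side="left"
        )
        hr, hl = estimate_params(right, left)
        np.testing.assert_allclose(hr.center, [0.343, 1.3, 0.25], atol=1e-9)
        assert hr.radius0 == pytest.approx(0.163, abs=1e-9)
        assert hr.omega0 == pytest.approx(omega_r, abs=1e-9)
        assert hl.radius0 == pytest.approx(0.161, abs=1e-9)
        assert hl.omega0 == pytest.approx(omega_l, abs=1e-9)

    def test_recovery_under_position_noise(self):
        # 5 mm Gaussian position noise, 60 s: radius within 2 mm and
        # omega within 0.02 rad/s on every one of 25 replicates (the
        # 100-replicate study runs in the acceptance suite)
        for seed in range(25):
            rng = np.random.default_rng(seed)
            right, omega = whole_period_circle(rng=rng, noise_sd=0.005)
            left, _ = whole_period_circle(
                center=(0.343, 1.3, -0.25), side="left", rng=rng,
                noise_sd=0.005,
            )
            hr, _ = estimate_params(right, left)
            assert abs(hr.radius0 - 0.163) < 0.002
            assert abs(hr.omega0 - omega) < 0.02

    def test_degenerate_trajectory_raises(self):
        from mirrorgame import HandTrajectory

        times = np.arange(150) / 50.0
        pos = np.tile([0.3, 1.2, 0.0], (150, 1))
        pos += np.random.default_rng(0).normal(0, 0.001, pos.shape)
        traj = HandTrajectory("right", times, pos)
        with pytest.raises(EstimationError):
            estimate_params(traj, traj)

    def test_too_short_training_raises(self):
        right, _ = whole_period_circle(duration=1.0, cycles=1)
        with pytest.raises(EstimationError):
            estimate_params(right, right)

    def test_realistic_partner_estimates_in_plausible_band(self):
        # a drifting synthetic partner should yield training estimates of
        # the observed magnitudes: r around 0.16 m, omega around 2.7 rad/s
        from mirrorgame import ModelConfig, simulate_human
        from mirrorgame.dyad_simulator import default_profile

        tr_r, tr_l = simulate_human(default_profile(seed=2), ModelConfig())
        hr, hl = estimate_params(tr_r, tr_l)
        assert 0.10 < hr.radius0 < 0.25
        assert 1.5 < hr.omega0 < 4.0
        assert 0.10 < hl.radius0 < 0.25


class TestWrapPhase:
    def test_interval_is_left_open(self):
        assert wrap_phase(math.pi) == pytest.approx(math.pi)
        assert wrap_phase(-math.pi) == pytest.approx(math.pi)
        assert wrap_phase(3 * math.pi) == pytest.approx(math.pi)

    def test_idempotent_on_wrapped_values(self):
        x = np.linspace(-3.1, 3.1, 101)
        np.testing.assert_allclose(wrap_phase(x), x, atol=1e-15)
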