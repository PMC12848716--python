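"""Simulator oracles: step statistics, MSD laws, confinement, mixing."""

import numpy as np
import pytest

from sptmotion import (
    MsdCurve,
    SimulationConfig,
    empirical_msd,
    generate_dataset,
    simulate_ad,
    simulate_cd,
    simulate_dm,
    simulate_mm,
    simulate_nd,
    theoretical_msd,
)
from sptmotion.simulate import InvalidParameterError


def _ensemble_msd(pos_stack: np.ndarray, lags: np.ndarray) -> np.ndarray:
    return np.array(
        [np.mean(np.sum((pos_stack[:, k:] - pos_stack[:, :-k]) ** 2, axis=2)) for k in lags]
    )


class TestNormalDiffusion:
    def test_zero_diffusivity_limit_stays_at_origin(self, rng):
        traj = simulate_nd(100, 0.01, 1e-30, rng)
        assert np.max(np.linalg.norm(traj.pos, axis=1)) < 1e-10

    def test_step_variance_matches_2_d_dt(self, rng):
        D, dt = 1.0, 0.01
        steps = np.concatenate(
            [np.diff(simulate_nd(100, dt, D, rng).pos, axis=0) for _ in range(2000)]
        )
        assert np.var(steps) == pytest.approx(2 * D * dt, rel=0.03)

    def test_ensemble_msd_follows_6_d_t(self, rng):
        D, dt = 1.0, 0.01
        P = np.array([simulate_nd(100, dt, D, rng).pos for _ in range(2000)])
        lags = np.arange(1, 11)
        msd = _ensemble_msd(P, lags)
        assert np.allclose(msd, 6 * D * lags * dt, rtol=0.05)

    def test_per_axis_isotropy(self, rng):
        steps = np.concatenate(
            [np.diff(simulate_nd(100, 0.05, 0.5, rng).pos, axis=0) for _ in range(2000)]
        )
        per_axis = steps.var(axis=0)
        assert np.ptp(per_axis) / per_axis.mean() < 0.05

    def test_invalid_parameters_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            simulate_nd(100, 0.01, -1.0, rng)
        with pytest.raises(InvalidParameterError):
            simulate_nd(100, 0.0, 1.0, rng)


class TestDirectedMotion:
    def test_noise_free_limit_is_a_straight_line(self, rng):
        s, dt = 3.0, 0.05
        traj = simulate_dm(50, dt, 1e-30, (5, 20), rng, angular_noise=0.0, speed=s)
        steps = np.linalg.norm(np.diff(traj.pos, axis=0), axis=1)
        assert np.allclose(steps, s * dt, atol=1e-9)
        # collinearity: cross products of consecutive steps vanish
        v = np.diff(traj.pos, axis=0)
        assert np.allclose(np.cross(v[:-1], v[1:]), 0, atol=1e-9)

    def test_ballistic_net_displacement(self, rng):
        D, dt, n = 0.5, 0.05, 100
        speed = 15 * D
        nets = [
            np.linalg.norm(
                simulate_dm(n, dt, D, (15, 15), rng, angular_noise=0.05).pos[-1]
            )
            for _ in range(500)
        ]
        assert np.mean(nets) == pytest.approx(speed * (n - 1) * dt, rel=0.15)

    def test_msd_grows_superlinearly(self, rng):
        P = np.array(
            [simulate_dm(100, 0.05, 0.5, (5, 20), rng).pos for _ in range(400)]
        )
        lags = np.arange(1, 26)
        slope = np.polyfit(np.log(lags), np.log(_ensemble_msd(P, lags)), 1)[0]
        assert slope > 1.3


class TestAnomalousDiffusion:
    def test_phase_free_wm_series_is_deterministic_and_zero_at_origin(self):
        from sptmotion.simulate import wm_function

        phases = np.zeros(57)
        w = wm_function(np.array([0.0, 0.3, 0.7]), 0.5, phases)
        assert w[0] == pytest.approx(0.0, abs=1e-12)
        w2 = wm_function(np.array([0.0, 0.3, 0.7]), 0.5, phases)
        assert np.array_equal(w, w2)

    @pytest.mark.parametrize("alpha", [0.3, 0.5, 0.7])
    def test_ensemble_msd_slope_recovers_alpha(self, alpha):
        rng = np.random.default_rng(99)
        P = np.array([simulate_ad(100, 0.05, 1.0, alpha, rng).pos for _ in range(600)])
        lags = np.arange(1, 26)
        slope = np.polyfit(np.log(lags), np.log(_ensemble_msd(P, lags)), 1)[0]
        assert slope == pytest.approx(alpha, abs=0.1)

    def test_slope_monotone_in_alpha(self, rng):
        slopes = []
        for alpha in (0.3, 0.9):
            P = np.array(
                [simulate_ad(100, 0.05, 1.0, alpha, rng).pos for _ in range(300)]
            )
            lags = np.arange(1, 26)
            slopes.append(np.polyfit(np.log(lags), np.log(_ensemble_msd(P, lags)), 1)[0])
        assert slopes[1] > slopes[0]

    def test_alpha_outside_unit_interval_rejected(self, rng):
        for alpha in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(InvalidParameterError):
                simulate_ad(100, 0.05, 1.0, alpha, rng)


class TestConfinedDiffusion:
    def test_hard_confinement_no_violations(self, rng):
        # 1000 trajectories x 100 frames = 1e5 recorded positions, all inside
        violations = 0
        for _ in range(1000):
            D = float(rng.uniform(0.1, 1.0))
            B = float(rng.uniform(1.0, 10.0))
            traj = simulate_cd(100, 0.05, D, B, rng)
            r = (D * B) ** (1 / 3)
            violations += int(np.any(np.linalg.norm(traj.pos, axis=1) > r + 1e-12))
        assert violations == 0

    def test_unit_radius_bound(self, rng):
        traj = simulate_cd(100, 0.05, 1.0, 1.0, rng)
        assert np.max(np.linalg.norm(traj.pos, axis=1)) <= 1.0 + 1e-12

    def test_msd_plateau_at_uniform_ball_level(self, rng):
        D, B, dt = 1.0, 8.0, 0.05
        r = (D * B) ** (1 / 3)
        P = np.array([simulate_cd(60, dt, D, B, rng).pos for _ in range(400)])
        lags = np.array([20, 40])
        msd = _ensemble_msd(P, lags)
        assert 0.8 <= msd[1] / msd[0] <= 1.25
        assert msd[1] == pytest.approx(6 * r * r / 5, rel=0.30)

    def test_weak_confinement_reduces_to_free_diffusion(self, rng):
        D, dt = 1.0, 0.05
        steps = np.concatenate(
            [np.diff(simulate_cd(100, dt, D, 1e6, rng).pos, axis=0) for _ in range(300)]
        )
        # recorded steps aggregate 100 sub-steps of variance 2 D ddt each
        assert np.var(steps) == pytest.approx(2 * D * dt, rel=0.05)


class TestMixedMotion:
    def test_forced_segment_layout_and_continuity(self, rng):
        cfg = SimulationConfig()
        traj = simulate_mm(
            100, 0.05, cfg, rng, segment_labels=["ND", "CD"], segment_lengths=[50, 50]
        )
        assert list(traj.labels[:50]) == ["ND"] * 50
        assert list(traj.labels[50:]) == ["CD"] * 50
        # continuity: the junction step is an ordinary diffusion step, not a
        # teleport (segment 2 starts exactly at segment 1's endpoint)
        gaps = np.linalg.norm(np.diff(traj.pos, axis=0), axis=1)
        assert gaps[49] < 10 * np.median(gaps)
        assert traj.n_frames == 100

    def test_every_mixed_trajectory_switches_labels(self, rng):
        cfg = SimulationConfig()
        for _ in range(200):
            traj = simulate_mm(100, 0.05, cfg, rng)
            assert len(set(traj.labels)) >= 2

    def test_label_run_lengths_respect_segment_range(self, rng):
        # adjacent same-type segments merge, so a run is a sum of one or
        # more segments: every run except the (possibly truncated) final
        # one must be at least the minimum segment length
        cfg = SimulationConfig()
        lo, _ = cfg.mm_segment_range
        for _ in range(200):
            labels = simulate_mm(100, 0.05, cfg, rng).labels
            runs, cur = [], 1
            for a, b in zip(labels[:-1], labels[1:]):
                if a == b:
                    cur += 1
                else:
                    runs.append(cur)
                    cur = 1
            runs.append(cur)
            assert all(r >= lo for r in runs[:-1])


class TestDatasetGeneration:
    def test_total_data_points_and_class_mix(self):
        cfg = SimulationConfig(n_trajectories=100, seed=3)
        trajs = generate_dataset(cfg)
        assert sum(t.n_frames for t in trajs) == 100 * 100
        classes = [t.motion_class for t in trajs]
        assert classes.count("MM") == 28
        assert classes.count("ND") == 18

    def test_identical_seeds_reproduce_bitwise(self):
        cfg = SimulationConfig(n_trajectories=20, seed=11)
        a = generate_dataset(cfg)
        b = generate_dataset(cfg)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.pos, tb.pos)
        c = generate_dataset(cfg.replace(seed=12))
        assert not np.array_equal(a[0].pos, c[0].pos)

    def test_pure_mix_yields_single_label(self):
        cfg = SimulationConfig(
            n_trajectories=10, seed=5,
            class_mix={"DM": 0, "ND": 1.0, "AD": 0, "CD": 0, "MM": 0},
        )
        for traj in generate_dataset(cfg):
            assert set(traj.labels) == {"ND"}


class TestMsd:
    def test_collinear_unit_steps_exact(self):
        pos = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        msd = empirical_msd(pos, 3)
        assert np.array_equal(msd.values, [1.0, 4.0, 9.0])

    def test_stationary_point_is_zero(self):
        pos = np.zeros((10, 3))
        assert np.all(empirical_msd(pos, 5).values == 0)

    def test_lag_bound_enforced(self):
        with pytest.raises(InvalidParameterError):
            empirical_msd(np.zeros((5, 3)), 5)

    def test_theoretical_closed_forms(self):
        nd = theoretical_msd("ND", {"D": 1.0}, [1], 1.0)
        assert nd.values[0] == pytest.approx(6.0)
        dm = theoretical_msd("DM", {"D": 0.0, "v": 2.0}, [3], 1.0)
        assert dm.values[0] == pytest.approx(36.0)
        ad = theoretical_msd("AD", {"D": 1.0, "alpha": 0.5}, [4], 1.0)
        assert ad.values[0] == pytest.approx(12.0)
        with pytest.raises(InvalidParameterError):
            theoretical_msd("XX", {}, [1], 1.0)

    def test_msd_ordering_directed_vs_normal_vs_anomalous(self, rng):
        D, dt, lag = 0.5, 0.05, 50
        msds = {}
        for name, gen in {
            "DM": lambda: simulate_dm(100, dt, D, (10, 10), rng),
            "ND": lambda: simulate_nd(100, dt, D, rng),
            "AD": lambda: simulate_ad(100, dt, D, 0.5, rng),
        }.items():
            P = np.array([gen().pos for _ in range(300)])
            msds[name] = np.mean(np.sum((P[:, lag:] - P[:, :-lag]) ** 2, axis=2))
        assert msds["DM"] > msds["ND"] > msds["AD"]


def test_msd_curve_invariants_enforced():
    with pytest.raises(InvalidParameterError):
        MsdCurve(np.array([2, 1]), np.array([1.0, 2.0]))
    with pytest.raises(InvalidParameterError):
        MsdCurve(np.array([1, 2]), np.array([1.0, -2.0]))
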