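"""Feature oracles: closed forms on constructed paths, statistical checks
on simulated ensembles, invariance and boundedness properties."""

import math

import numpy as np
import pytest

from sptmotion import MsdCurve, SimulationConfig, generate_dataset, simulate_nd
from sptmotion.features import (
    FEATURE_NAMES,
    angular_gaussianity,
    asymmetry,
    avg_msd_ratio,
    compute_feature_table,
    compute_features,
    excursion_stats,
    fit_alpha,
    fractal_dimension,
    gaussianity,
    jump_length,
    kurtosis_projected,
    straightness_efficiency,
    trappedness,
    velocity_autocorrelation,
)
from sptmotion.segment import segment_dataset


def _line(n=29, step=1.0):
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(n) * step
    return pos


def _nd_windows(n_traj=300, D=1.0, dt=0.05, seed=4):
    rng = np.random.default_rng(seed)
    return np.array([simulate_nd(29, dt, D, rng).pos for _ in range(n_traj)])


class TestClosedForms:
    def test_straight_line_limits(self):
        f = compute_features(_line(), dt=0.05)
        assert f["straightness"] == pytest.approx(1.0)
        assert f["efficiency"] == pytest.approx(1.0)
        assert f["fractal_dimension"] == pytest.approx(1.0)
        assert f["velocity_autocorrelation"] == pytest.approx(1.0)
        assert f["jump_length"] == pytest.approx(1.0)
        assert f["alpha"] == pytest.approx(2.0, abs=1e-9)  # ballistic MSD ~ t^2

    def test_stationary_window_fallbacks(self):
        f = compute_features(np.zeros((29, 3)), dt=0.05)
        assert f["jump_length"] == 0.0
        assert f["trappedness"] == 1.0  # degenerate point is maximally trapped
        assert f["straightness"] == 0.0 and f["efficiency"] == 0.0
        assert f["fractal_dimension"] == 1.0
        assert np.isfinite(f.to_numpy()).all()

    def test_fit_alpha_on_exact_power_laws(self):
        lags = np.arange(1, 15)
        dt = 0.05
        for a in (1.0, 0.5):
            msd = MsdCurve(lags, 6 * (lags * dt) ** a)
            assert fit_alpha(msd, dt) == pytest.approx(a, abs=1e-12)

    def test_avg_msd_ratio_signatures(self):
        lags = np.arange(1, 6)
        assert avg_msd_ratio(MsdCurve(lags, 3.0 * lags)) == pytest.approx(0.0)
        assert avg_msd_ratio(MsdCurve(np.array([1, 2]), np.array([1.0, 4.0]))) == pytest.approx(-0.25)
        assert avg_msd_ratio(MsdCurve(np.array([1, 2]), np.array([2.0, 2.0]))) == pytest.approx(0.5)

    def test_right_angle_straightness_efficiency(self):
        pos = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0]], dtype=float)
        s, e = straightness_efficiency(pos, dt=1.0)
        assert s == pytest.approx(math.sqrt(2) / 2)
        assert e == pytest.approx(0.5)

    def test_closed_loop_has_zero_net_motion(self):
        pos = np.array(
            [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [0, 0, 0]], dtype=float
        )
        s, e = straightness_efficiency(pos, dt=1.0)
        assert s == 0.0 and e == 0.0

    def test_planar_isotropic_asymmetry_value(self):
        # lambda3 = 0, lambda1 = lambda2  ->  -ln(1 - 2 l^2 / 8 l^2) = -ln(3/4)
        theta = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        pos = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(100)])
        assert asymmetry(pos, dt=1.0) == pytest.approx(-math.log(0.75), rel=1e-6)

    def test_collinear_window_hits_asymmetry_cap(self):
        assert asymmetry(_line(), dt=1.0) == pytest.approx(10.0)

    def test_trappedness_root_and_reference_point(self):
        # construct a window whose Dhat*T/r0^2 hits the exponent's root
        # directly through the scalar formula
        from sptmotion.features import TRAP_A, TRAP_B

        x = TRAP_A / TRAP_B
        assert 1 - math.exp(TRAP_A - TRAP_B * x) == pytest.approx(0.0, abs=1e-12)
        assert 1 - math.exp(TRAP_A - TRAP_B * 10) == pytest.approx(0.9004, abs=1e-4)

    def test_velocity_autocorrelation_limits(self):
        assert velocity_autocorrelation(_line()) == pytest.approx(1.0)
        zigzag = np.zeros((20, 3))
        zigzag[1::2, 0] = 1.0
        assert velocity_autocorrelation(zigzag) == pytest.approx(-1.0)

    def test_angular_gaussianity_deterministic_angle(self):
        # planar regular polygon walk: every turning angle equal and nonzero
        theta = 0.3
        steps = np.column_stack(
            [np.cos(theta * np.arange(20)), np.sin(theta * np.arange(20)), np.zeros(20)]
        )
        pos = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        assert angular_gaussianity(pos, dt=1.0) == pytest.approx(-2 / 3, rel=1e-9)

    def test_angular_gaussianity_straight_line_fallback(self):
        assert angular_gaussianity(_line(), dt=1.0) == 0.0

    def test_kurtosis_two_point_and_uniform(self):
        pos = np.zeros((4, 3))
        pos[:, 0] = [-1, -1, 1, 1]
        assert kurtosis_projected(pos, dt=1.0) == pytest.approx(1.0)
        assert kurtosis_projected(_line(1000), dt=1.0) == pytest.approx(1.8, abs=0.01)

    def test_gaussianity_fixed_magnitude_displacements(self):
        # all displacement magnitudes equal -> <r^4> = <r^2>^2 -> 3/5 - 1
        f = compute_features(_line(), dt=1.0)
        assert f["gaussianity"] == pytest.approx(-0.4, abs=0.05)

    def test_running_max_dominates_its_mean(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            pos = np.cumsum(rng.normal(size=(29, 3)), axis=0)
            me, mme = excursion_stats(pos, dt=1.0)
            assert mme <= me + 1e-12


class TestEnsembleStatistics:
    def test_normal_diffusion_moments(self):
        P = _nd_windows(3000)
        from sptmotion.features import _batch_features

        feats = _batch_features(P.copy(), 0.05, 3)
        # the windowed time-average estimator carries a small negative
        # finite-sample bias (~-0.11 at W=29, K=14 lags); the ensemble mean
        # must sit just below zero, not far from it
        assert -0.2 < np.mean(feats["gaussianity"]) < 0.0
        assert abs(np.mean(feats["velocity_autocorrelation"])) < 0.05
        assert np.mean(feats["fractal_dimension"]) == pytest.approx(2.0, abs=0.3)
        # mean 3D step length: Maxwell mean = sqrt(8 sigma^2 / pi) * ... =
        # 2 sigma sqrt(2/pi) with sigma^2 = 2 D dt
        expect = 2 * math.sqrt(2 * 1.0 * 0.05) * math.sqrt(2 / math.pi)
        assert np.mean(feats["jump_length"]) == pytest.approx(expect, rel=0.05)

    def test_gaussianity_matches_in_2d_projection(self):
        from sptmotion.features import _batch_features

        P = _nd_windows(3000)
        feats2 = _batch_features(P[:, :, :2].copy(), 0.05, 2)
        assert -0.2 < np.mean(feats2["gaussianity"]) < 0.0

    def test_gaussian_kurtosis(self):
        rng = np.random.default_rng(8)
        pos = np.zeros((5000, 3))
        pos[:, 0] = rng.normal(size=5000)
        assert kurtosis_projected(pos, dt=1.0) == pytest.approx(3.0, abs=0.3)


class TestInvariance:
    def test_rigid_rotation_and_translation_leave_features_unchanged(self):
        from scipy.spatial.transform import Rotation

        from sptmotion.features import _batch_features

        rng = np.random.default_rng(21)
        P = np.array([np.cumsum(rng.normal(size=(29, 3)), axis=0) for _ in range(40)])
        base = _batch_features(P.copy(), 0.05, 3)
        R = Rotation.random(random_state=5).as_matrix()
        shifted = P @ R.T + np.array([3.0, -7.0, 11.0])
        rot = _batch_features(shifted, 0.05, 3)
        for name in FEATURE_NAMES:
            assert np.allclose(base[name], rot[name], atol=1e-9), name

    def test_bounded_features_stay_in_range(self):
        from sptmotion.features import _batch_features

        rng = np.random.default_rng(31)
        # heterogeneous fuzz: mixed scales, near-degenerate and wild windows
        P = rng.normal(size=(20000, 29, 3)) * rng.lognormal(0, 2, size=(20000, 1, 1))
        P[:5000] = np.cumsum(P[:5000] * 0.05, axis=1)
        P[5000:6000, :, :] = 0.0
        feats = _batch_features(P, 0.05, 3)
        for name in ("straightness", "efficiency", "trappedness"):
            assert np.all((feats[name] >= 0) & (feats[name] <= 1)), name
        v = feats["velocity_autocorrelation"]
        assert np.all((v >= -1 - 1e-12) & (v <= 1 + 1e-12))
        for name in FEATURE_NAMES:
            assert np.all(np.isfinite(feats[name])), name

    def test_planar_trajectory_2d_projection_consistency(self):
        # a z=const window: dimension-free features agree between dim tags
        rng = np.random.default_rng(41)
        pos = np.cumsum(rng.normal(size=(29, 3)), axis=0)
        pos[:, 2] = 5.0
        f3 = compute_features(pos, dim=3, dt=0.05)
        f2 = compute_features(pos, dim=2, dt=0.05)
        for name in ("jump_length", "straightness", "efficiency",
                     "fractal_dimension", "velocity_autocorrelation", "alpha",
                     "avg_msd_ratio", "kurtosis"):
            assert f3[name] == pytest.approx(f2[name], rel=1e-9), name


class TestSeparability:
    def test_class_conditioned_feature_ordering(self, small_table):
        means = small_table.groupby("center_label")[
            ["trappedness", "straightness", "alpha"]
        ].mean()
        assert means.loc["CD", "trappedness"] > means.loc["ND", "trappedness"]
        assert means.loc["DM", "straightness"] > means.loc["ND", "straightness"]
        assert means.loc["AD", "alpha"] < means.loc["ND", "alpha"]

    def test_feature_table_shape_and_finiteness(self, small_table):
        assert list(small_table.columns[3:17]) == list(FEATURE_NAMES)
        assert small_table[list(FEATURE_NAMES)].notna().all().all()
        assert small_table.attrs["dim_tag"] == "3D"
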