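import math

import numpy as np
import pandas as pd
import pytest

from streamrelay import metrics
from streamrelay.fixtures import make_fixture_ou_tracks


def straight_tracks(n_cells=5, n_frames=20, dt=0.02, direction=(0.0, 1.0)):
    rows = []
    for cid in range(n_cells):
        for f in range(n_frames):
            rows.append((cid, f, f * dt, 0.1 * cid + direction[0] * f * dt,
                         direction[1] * f * dt))
    return pd.DataFrame(rows, columns=["cell_id", "frame", "t", "x", "y"])


class TestMotionAngles:
    def test_straight_up_gives_zero_angle(self):
        ang = metrics.motion_angles(straight_tracks())
        assert np.allclose(ang["theta"], 0.0)

    def test_straight_lateral_gives_right_angle(self):
        ang = metrics.motion_angles(straight_tracks(direction=(1.0, 0.0)))
        assert np.allclose(ang["theta"], math.pi / 2)

    def test_lag_and_slow_filter(self):
        tr = straight_tracks(n_cells=1, n_frames=10)
        ang = metrics.motion_angles(tr, lag_frames=3)
        assert len(ang) == 7
        # freeze the cell: all displacements drop below the slow filter
        tr2 = tr.copy()
        tr2[["x", "y"]] = 0.0
        ang2 = metrics.motion_angles(tr2)
        assert len(ang2) == 0
        assert ang2.attrs["n_dropped"] == 9

    def test_periodic_direction_uses_minimum_image(self):
        tr = pd.DataFrame({
            "cell_id": [0, 0], "frame": [0, 1], "t": [0.0, 0.1],
            "x": [0.49, 0.01], "y": [0.0, 0.08]})
        ang = metrics.motion_angles(tr, width=0.5)
        # dx = +0.02 across the wall, not -0.48
        assert ang["theta"].iloc[0] == pytest.approx(math.atan2(0.02, 0.08))


class TestAutocorrelation:
    def test_constant_angle_gives_unit_correlation(self):
        ang = metrics.motion_angles(straight_tracks())
        ac = metrics.angle_autocorrelation(ang, region=None)
        assert np.allclose(ac["C"], 1.0)

    def test_iid_angles_decorrelate(self, rng):
        rows = []
        for cid in range(40):
            th = rng.uniform(-math.pi, math.pi, 80)
            for f in range(80):
                rows.append((cid, f, f * 0.1, 0.5, th[f]))
        ang = pd.DataFrame(rows, columns=["cell_id", "frame", "t", "y",
                                          "theta"])
        ac = metrics.angle_autocorrelation(ang, region=None,
                                           quantity="cos_theta")
        c_pos = ac["C"].iloc[1:]
        n = ac["n_pairs"].iloc[1:]
        # <cos^2>=1/2 per sample; se of the mean product ~ 1/(2 sqrt n)
        assert np.all(np.abs(c_pos) <= 3.0 / (2.0 * np.sqrt(n)) + 0.02)

    def test_cos_theta_zero_lag_is_mean_square(self, rng):
        ang = pd.DataFrame({
            "cell_id": np.zeros(50, dtype=int), "frame": np.arange(50),
            "t": np.arange(50) * 0.1, "y": np.full(50, 0.7),
            "theta": rng.normal(0, 0.5, 50)})
        ac = metrics.angle_autocorrelation(ang, region=None,
                                           quantity="cos_theta")
        assert ac["C"].iloc[0] == pytest.approx(
            np.mean(np.cos(ang["theta"]) ** 2), rel=1e-12)
        assert ac["C"].iloc[0] <= 1.0

    def test_empty_region_raises(self):
        ang = metrics.motion_angles(straight_tracks(n_frames=5))
        with pytest.raises(ValueError):
            metrics.angle_autocorrelation(ang, region=(0.99, 1.0))


class TestFitExponential:
    def test_recovers_noiseless_generator(self):
        tau = np.linspace(0, 10, 40)
        fit = metrics.fit_exponential(tau, 0.8 * np.exp(-tau / 2.0))
        assert fit.A == pytest.approx(0.8, abs=1e-6)
        assert fit.T == pytest.approx(2.0, abs=1e-6)
        assert fit.B == pytest.approx(0.0, abs=1e-6)

    def test_constant_reports_infinite_time(self):
        fit = metrics.fit_exponential(np.linspace(0, 5, 10), np.ones(10))
        assert math.isinf(fit.T)

    def test_paper_mode_pins_plateau_to_zero(self):
        tau = np.linspace(0, 6, 30)
        fit = metrics.fit_exponential(tau, 0.5 * np.exp(-tau / 1.5),
                                      mode="paper")
        assert fit.B == 0.0
        assert fit.T == pytest.approx(1.5, abs=1e-6)

    def test_scale_equivariance(self):
        tau = np.linspace(0, 8, 25)
        c = 0.6 * np.exp(-tau / 3.0) + 0.2
        f1 = metrics.fit_exponential(tau, c)
        f2 = metrics.fit_exponential(tau, 5.0 * c)
        assert f2.A == pytest.approx(5 * f1.A, rel=1e-6)
        assert f2.B == pytest.approx(5 * f1.B, rel=1e-6)
        assert f2.T == pytest.approx(f1.T, rel=1e-6)

    def test_ou_fixture_recovers_response_time(self):
        """End to end: synthetic walkers -> motion angles -> vector
        autocorrelation -> exponential fit recovers T within 15%."""
        T, sigma = 0.02, math.sqrt(2 * 0.02 / 10)   # kappa = 10
        tr = make_fixture_ou_tracks(T, sigma, n_cells=400, n_frames=500,
                                    dt=T / 20, seed=5)
        ang = metrics.motion_angles(tr)
        ac = metrics.angle_autocorrelation(ang, region=None,
                                           max_lag_frames=80)
        fit = metrics.fit_exponential(ac)
        assert fit.T == pytest.approx(T, rel=0.15)


class TestVarianceVsY:
    def test_zero_for_straight_tracks(self):
        ang = metrics.motion_angles(straight_tracks(n_frames=40))
        prof = metrics.angle_variance_vs_y(ang, y_bins=4, min_count=2)
        filled = prof.dropna()
        assert len(filled) > 0
        assert np.allclose(filled["var"], 0.0)

    def test_flat_profile_at_stationarity(self):
        T, sigma = 0.02, math.sqrt(2 * 0.02 / 20)   # kappa = 20
        tr = make_fixture_ou_tracks(T, sigma, n_cells=300, n_frames=400,
                                    dt=T / 10, seed=7)
        tr["y"] = np.mod(tr["y"], 1.0)   # fold onto chamber bins
        ang = metrics.motion_angles(tr)
        prof = metrics.angle_variance_vs_y(ang, y_bins=5).dropna()
        expected = sigma**2 / (2 * T)
        assert np.all(np.abs(prof["var"] - expected) <= 0.1 * expected)

    def test_invariant_to_id_relabeling(self, rng):
        tr = straight_tracks(n_cells=6, n_frames=30)
        ang1 = metrics.angle_variance_vs_y(metrics.motion_angles(tr))
        relabeled = tr.copy()
        relabeled["cell_id"] = 17 - relabeled["cell_id"]
        ang2 = metrics.angle_variance_vs_y(metrics.motion_angles(relabeled))
        pd.testing.assert_frame_equal(ang1, ang2)


class TestMeanProgression:
    def test_straight_up_unity(self):
        prog = metrics.mean_progression(straight_tracks(n_frames=40))
        assert prog.u_final == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(prog.by_time["u"].dropna(), 1.0)

    def test_isotropic_orientations_average_to_zero(self, rng):
        rows = []
        for cid in range(100):
            th = rng.uniform(0, 2 * math.pi)
            x, y = 0.0, 0.5
            for f in range(30):
                rows.append((cid, f, f * 0.01, x, y))
                x += 0.01 * math.sin(th)
                y += 0.01 * math.cos(th)
        tr = pd.DataFrame(rows, columns=["cell_id", "frame", "t", "x", "y"])
        prog = metrics.mean_progression(tr, region=(0.0, 1.0))
        se = 1.0 / math.sqrt(100)
        assert abs(prog.u_final) <= 3 * se

    def test_region_excludes_entry_strip(self):
        # cells below y=0.25 move up, cells above stand... cannot stand
        # (unit speed) - they move laterally instead
        rows = []
        for cid in range(10):
            for f in range(20):
                rows.append((cid, f, f * 0.01, f * 0.01, 0.5))  # lateral
        for cid in range(10, 20):
            for f in range(20):
                rows.append((cid, f, f * 0.01, 0.0, 0.01 + f * 0.002))
        tr = pd.DataFrame(rows, columns=["cell_id", "frame", "t", "x", "y"])
        prog = metrics.mean_progression(tr, region=(0.25, 1.0))
        assert prog.u_final == pytest.approx(0.0, abs=1e-12)
        prog_full = metrics.mean_progression(tr, region=(0.0, 1.0))
        assert prog_full.u_final > 0.05


class TestDensityProfile:
    def test_uniform_positions_flat(self, rng):
        n = 4000
        tr = pd.DataFrame({
            "cell_id": np.arange(n), "frame": np.zeros(n, dtype=int),
            "t": np.zeros(n), "x": rng.uniform(0, 0.5, n),
            "y": rng.uniform(0, 1, n)})
        prof, rho_max = metrics.density_profile(tr, y_bins=10)
        assert np.all(np.abs(prof["rho"] - 1.0) <= 3 * math.sqrt(10.0 / n)
                      + 0.05)

    def test_concentrated_bin_normalization(self):
        n = 100
        tr = pd.DataFrame({
            "cell_id": np.arange(n), "frame": np.zeros(n, dtype=int),
            "t": np.zeros(n), "x": np.zeros(n), "y": np.full(n, 0.35)})
        prof, rho_max = metrics.density_profile(tr, y_bins=10)
        assert rho_max == pytest.approx(10.0)
        assert prof["rho"].iloc[3] == pytest.approx(10.0)
        assert prof["rho"].sum() == pytest.approx(10.0)  # mean is exactly 1

    def test_profile_mean_is_one(self, rng):
        n = 137
        tr = pd.DataFrame({
            "cell_id": np.arange(n), "frame": np.zeros(n, dtype=int),
            "t": np.zeros(n), "x": np.zeros(n), "y": rng.uniform(0, 1, n)})
        prof, _ = metrics.density_profile(tr, y_bins=8)
        assert prof["rho"].mean() == pytest.approx(1.0, rel=1e-12)

    def test_no_positions_raises(self):
        empty = pd.DataFrame(columns=["cell_id", "frame", "t", "x", "y"])
        with pytest.raises(ValueError):
            metrics.density_profile(empty)


class TestClassifyRegime:
    @pytest.mark.parametrize("u, rho, label", [
        (0.05, 8.0, "clumping"),
        (0.9, 1.1, "uncorrelated"),
        (0.4, 3.0, "streaming"),
        (0.05, 1.0, "streaming"),   # slow but dilute: between the boxes
        (0.9, 6.0, "streaming"),
    ])
    def test_threshold_boxes(self, u, rho, label):
        assert metrics.classify_regime(u, rho) == label

    def test_missing_inputs_rejected(self):
        with pytest.raises(ValueError):
            metrics.classify_regime(math.nan, 3.0)
        with pytest.raises(ValueError):
            metrics.classify_regime(0.5, math.inf)


class TestInvariances:
    def test_metrics_invariant_to_x_shift(self, rng):
        """Rigid shifts along the periodic direction change nothing."""
        T, sigma = 0.05, 0.2
        tr = make_fixture_ou_tracks(T, sigma, n_cells=30, n_frames=60,
                                    dt=0.005, seed=3)
        tr["y"] = np.mod(tr["y"], 1.0)
        shifted = tr.copy()
        shifted["x"] = np.mod(shifted["x"] + 0.123, 0.5)
        for table in (tr, shifted):
            table.attrs.clear()
        a1 = metrics.motion_angles(tr, width=0.5)
        a2 = metrics.motion_angles(shifted, width=0.5)
        assert np.allclose(a1["theta"], a2["theta"], atol=1e-9)
        p1 = metrics.mean_progression(tr, region=(0, 1)).u_final
        p2 = metrics.mean_progression(shifted, region=(0, 1)).u_final
        assert p1 == pytest.approx(p2, rel=1e-12)
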