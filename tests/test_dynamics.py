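"""MSD analysis, population splitting and tension-stress inversion."""

import warnings

import numpy as np
import pytest

from ermech.chains import FiberChain
from ermech.constants import K_B
from ermech.dynamics import (
    MSDCurve,
    TransverseTrack,
    classify_tracks,
    compute_msd,
    ensemble_msd,
    estimate_stress,
    fit_power_law,
    track_transverse,
    transverse_msd_model,
)


def brute_force_msd(h, dt, max_lag):
    """Naive double-loop MSD: enumerate every overlapping pair per lag."""
    lags, msd, n_pairs = [], [], []
    for k in range(1, max_lag + 1):
        sq = []
        for t in range(len(h) - k):
            sq.append((h[t + k] - h[t]) ** 2)
        lags.append(k * dt)
        msd.append(np.mean(np.array(sq)))
        n_pairs.append(len(sq))
    return np.array(lags), np.array(msd), np.array(n_pairs)


class TestTrackTransverse:
    def setup_method(self):
        x = np.linspace(0.0, 4.0, 41)
        self.chain = FiberChain(np.stack([x, np.zeros_like(x)], 1), 0.1)
        self.times = np.arange(50) * 0.1

    def test_perpendicular_motion_passes_through(self):
        h = 0.05 * np.sin(self.times)
        pos = np.stack([np.full_like(h, 2.0), h], 1)
        tr = track_transverse(self.times, pos, self.chain)
        np.testing.assert_allclose(tr.displacement, h, atol=1e-12)

    def test_axial_motion_projects_to_zero(self):
        pos = np.stack([2.0 + 0.05 * np.sin(self.times), np.zeros_like(self.times)], 1)
        tr = track_transverse(self.times, pos, self.chain)
        assert np.allclose(tr.displacement, 0.0, atol=1e-12)
        assert tr.longitudinal_fraction == np.inf

    def test_diagonal_motion_splits_variance(self):
        wob = 0.05 * np.sin(self.times)
        pos = np.stack([2.0 + wob, wob], 1)
        tr = track_transverse(self.times, pos, self.chain)
        total = 2 * np.var(wob)
        assert np.var(tr.displacement) == pytest.approx(total / 2, rel=1e-9)
        assert tr.longitudinal_fraction == pytest.approx(1.0, rel=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            track_transverse([0.0], np.array([[0.0, 0.0]]), self.chain)


class TestComputeMsd:
    def test_constant_track_zero(self):
        tr = TransverseTrack(np.arange(20) * 0.1, np.full(20, 1.23))
        assert np.allclose(compute_msd(tr).msd, 0.0)

    def test_linear_drift_exact(self):
        v, dt = 0.7, 0.05
        t = np.arange(200) * dt
        tr = TransverseTrack(t, v * t)
        curve = compute_msd(tr)
        np.testing.assert_allclose(curve.msd, v**2 * curve.lags**2, rtol=1e-12)

    def test_equals_brute_force_oracle_exactly(self):
        rng = np.random.default_rng(17)
        h = np.cumsum(rng.normal(0.0, 0.1, 100))
        tr = TransverseTrack(np.arange(100) * 0.2, h)
        curve = compute_msd(tr, max_lag_fraction=0.25)
        lags, msd, n_pairs = brute_force_msd(h, 0.2, len(curve.lags))
        np.testing.assert_array_equal(curve.msd, msd)
        np.testing.assert_array_equal(curve.n_pairs, n_pairs)
        np.testing.assert_allclose(curve.lags, lags, rtol=1e-12)

    def test_random_walk_diffusive_scaling(self):
        rng = np.random.default_rng(23)
        dt, step = 0.01, 0.05
        h = np.cumsum(rng.normal(0.0, step, 100_000))
        tr = TransverseTrack(np.arange(100_000) * dt, h)
        curve = compute_msd(tr, max_lag_fraction=0.0002)
        D = step**2 / (2 * dt)
        np.testing.assert_allclose(curve.msd, 2 * D * curve.lags, rtol=0.05)

    def test_pairs_non_increasing(self):
        tr = TransverseTrack(np.arange(50) * 0.1, np.sin(np.arange(50)))
        curve = compute_msd(tr)
        assert np.all(np.diff(curve.n_pairs) <= 0)


class TestFitPowerLaw:
    def test_exact_half_power(self):
        tau = np.linspace(0.1, 10, 50)
        curve = MSDCurve(tau, 3.0 * tau**0.5, np.full(50, 100))
        fit = fit_power_law(curve, (0.1, 10))
        assert fit.alpha == pytest.approx(0.5, abs=1e-12)
        assert fit.prefactor == pytest.approx(3.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_linear_msd(self):
        tau = np.linspace(0.1, 10, 50)
        fit = fit_power_law(MSDCurve(tau, tau, np.full(50, 10)), (0.1, 10))
        assert fit.alpha == pytest.approx(1.0, abs=1e-12)

    def test_too_few_points_rejected(self):
        tau = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            fit_power_law(MSDCurve(tau, tau, np.ones(3, int)), (1.0, 3.0))


class TestClassifyTracks:
    @staticmethod
    def make_track(kind, seed, duration=12.0, dt=0.02):
        rng = np.random.default_rng(seed)
        t = np.arange(int(duration / dt) + 1) * dt
        noise = rng.normal(0.0, 0.002, t.size)  # measurement noise
        if kind == "active":
            h = 0.2 * t**1.5 + noise  # super-diffusive, sub-ballistic
        else:
            # bounded (equilibrium-like) wobble saturates at long lags
            h = 0.05 * np.sin(2 * np.pi * t / 3.0) + noise
        return TransverseTrack(t, h, track_id=f"{kind}-{seed}")

    def test_short_tracks_excluded(self):
        tracks = [
            TransverseTrack(np.arange(30) * 0.1, np.random.default_rng(s).normal(size=30),
                            track_id=f"s{s}")
            for s in range(3)
        ]
        with pytest.raises(ValueError):
            classify_tracks(tracks, short_cutoff=5.0)

    def test_passive_only_has_no_superdiffusive(self):
        tracks = [self.make_track("passive", s) for s in range(6)]
        split = classify_tracks(tracks)
        assert "superdiffusive" not in split.ensembles
        assert all(lbl == "subdiffusive" for lbl in split.labels.values())

    def test_mixture_recovers_labels(self):
        tracks = [self.make_track("passive", s) for s in range(8)]
        tracks += [self.make_track("active", 100 + s) for s in range(8)]
        split = classify_tracks(tracks)
        for tr in tracks:
            want = "superdiffusive" if tr.track_id.startswith("active") else "subdiffusive"
            assert split.labels[tr.track_id] == want

    def test_every_track_labelled_once(self):
        tracks = [self.make_track("passive", s) for s in range(4)]
        tracks.append(TransverseTrack(np.arange(30) * 0.1, np.zeros(30) + 0.1,
                                      track_id="short"))
        split = classify_tracks(tracks)
        assert set(split.labels) == {t.track_id for t in tracks}
        assert split.labels["short"] == "excluded_short"


class TestEstimateStress:
    def make_curve(self, sigma=58.3, L_p=3.03, eta=1e-3, T=298.0):
        tau = np.geomspace(0.1, 10.0, 40)
        msd = transverse_msd_model(tau, sigma, L_p, eta, T)
        return MSDCurve(tau, msd, np.full(tau.size, 100))

    def test_analytic_round_trip(self):
        est = estimate_stress(self.make_curve(58.3), 3.03, 1e-3, 298.0)
        assert est.sigma_Pa == pytest.approx(58.3, rel=1e-6)

    def test_prefactor_scaling_exponent(self):
        # sigma ~ A^{-4/3}: scaling A by 2^{3/4} halves sigma
        curve = self.make_curve(58.3)
        scaled = MSDCurve(curve.lags, curve.msd * 2**0.75, curve.n_pairs)
        est1 = estimate_stress(curve, 3.03, 1e-3, 298.0)
        est2 = estimate_stress(scaled, 3.03, 1e-3, 298.0)
        assert est2.sigma_Pa == pytest.approx(est1.sigma_Pa / 2, rel=1e-9)

    def test_viscosity_scaling_exponent(self):
        curve = self.make_curve(58.3)
        est1 = estimate_stress(curve, 3.03, 1e-3, 298.0)
        est2 = estimate_stress(curve, 3.03, 2e-3, 298.0)
        assert est2.sigma_Pa == pytest.approx(est1.sigma_Pa * 2 ** (-2.0 / 3.0), rel=1e-9)

    def test_tension_length_and_force_convention(self):
        est = estimate_stress(self.make_curve(58.3), 3.03, 1e-3, 298.0,
                              radius_nm=44.1)
        f_expected = est.sigma_Pa * np.pi * (44.1e-9) ** 2
        assert est.tension_force_N == pytest.approx(f_expected, rel=1e-9)
        kappa = 3.03e-6 * K_B * 298.0
        assert est.tension_length_m == pytest.approx(np.sqrt(kappa / f_expected), rel=1e-9)

    def test_validity_bound_reported(self):
        est = estimate_stress(self.make_curve(58.3), 3.03, 1e-3, 298.0,
                              contour_length_um=3.0)
        expected = K_B * 298.0 * 3.03e-6 / (3.0e-6) ** 2
        assert est.validity_sigma_min_Pa == pytest.approx(expected, rel=1e-9)
        assert est.sigma_Pa > est.validity_sigma_min_Pa

    def test_warns_off_regime(self):
        tau = np.geomspace(0.1, 10.0, 20)
        curve = MSDCurve(tau, 0.01 * tau**1.5, np.full(tau.size, 10))
        with pytest.warns(UserWarning, match="regime"):
            estimate_stress(curve, 3.03, 1e-3, 298.0)


def test_ensemble_msd_weighting():
    tau = np.arange(1, 6) * 0.1
    a = MSDCurve(tau, np.ones(5), np.full(5, 10))
    b = MSDCurve(tau, 3 * np.ones(5), np.full(5, 30))
    eq = ensemble_msd([a, b])
    wt = ensemble_msd([a, b], weight_by_pairs=True)
    assert np.allclose(eq.msd, 2.0)
    assert np.allclose(wt.msd, (10 * 1 + 30 * 3) / 40)
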