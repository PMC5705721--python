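"""Generators: WLC chains, networks, renderings, localizations, Langevin."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

from ermech.chains import FiberChain
from ermech.synthetic import (
    FluctuationParams,
    RenderParams,
    WLCParams,
    generate_branched_network,
    generate_localizations,
    generate_track_population,
    generate_wlc_chain,
    generate_wlc_ensemble,
    midpoint_msd_expected,
    render_image,
    simulate_transverse_fluctuations,
    tube_profile,
    wlc_mean_square_end_to_end,
)


class TestWLC:
    def test_rigid_rod_limit(self):
        p = WLCParams(1e6, 10.0, 0.1, "3D", seed=0)
        chain = generate_wlc_chain(p)
        assert chain.end_to_end() == pytest.approx(10.0, rel=1e-3)

    def test_segment_spacing_uniform(self):
        p = WLCParams(2.0, 5.0, 0.05, "3D", seed=1)
        chain = generate_wlc_chain(p)
        assert np.allclose(chain.segment_lengths, 0.05, rtol=1e-9)

    @pytest.mark.parametrize("dim", ["2D", "3D"])
    @pytest.mark.parametrize("ratio", [0.1, 1.0, 10.0])
    def test_mean_square_end_to_end_matches_closed_form(self, dim, ratio):
        # both conventions have tangent correlation exp(-s/L_p), so the
        # Kratky-Porod closed form applies to each
        Lp, Lc = 1.0, ratio
        p = WLCParams(Lp, Lc, min(0.02, Lc / 10), dim, seed=hash((dim, ratio)) % 2**31)
        v = generate_wlc_ensemble(p, 2000)
        r2 = ((v[:, -1] - v[:, 0]) ** 2).sum(axis=1)
        expected = wlc_mean_square_end_to_end(Lc, Lp)
        se = r2.std(ddof=1) / np.sqrt(len(r2))
        assert abs(r2.mean() - expected) < 3 * se

    def test_kratky_porod_value_at_unity(self):
        # closed form at L_c = L_p = 1: 2(1 - (1 - 1/e)) = 0.7357588823
        assert wlc_mean_square_end_to_end(1.0, 1.0) == pytest.approx(
            0.7357588823, abs=1e-9
        )
        p = WLCParams(1.0, 1.0, 0.01, "3D", seed=12)
        v = generate_wlc_ensemble(p, 2000)
        r2 = ((v[:, -1] - v[:, 0]) ** 2).sum(axis=1)
        se = r2.std(ddof=1) / np.sqrt(len(r2))
        assert abs(r2.mean() - 0.7357588823) < 3 * se

    def test_fixed_seed_reproducible(self):
        p = WLCParams(3.0, 6.0, 0.05, "3D", seed=7)
        a = generate_wlc_chain(p).vertices
        b = generate_wlc_chain(p).vertices
        np.testing.assert_array_equal(a, b)

    def test_tangent_autocorrelation_decay(self):
        p = WLCParams(3.0, 9.0, 0.06, "3D", seed=3)
        v = generate_wlc_ensemble(p, 2000)
        tang = np.diff(v, axis=1)
        tang /= np.linalg.norm(tang, axis=2, keepdims=True)
        ks = np.arange(1, 60)
        corr = [np.mean((tang[:, :-k] * tang[:, k:]).sum(axis=2)) for k in ks]
        slope = np.polyfit(ks * 0.06, np.log(corr), 1)[0]
        assert -1.0 / slope == pytest.approx(3.0, rel=0.05)

    def test_projected_chain_is_planar_and_uniform(self):
        p = WLCParams(2.0, 6.0, 0.05, "3D-projected", seed=9)
        chain = generate_wlc_chain(p)
        assert chain.vertices.shape[1] == 2
        sl = chain.segment_lengths
        assert (sl.max() - sl.min()) < 0.01 * sl.mean()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            WLCParams(1.0, 0.01, 0.05, "3D")  # L_c < segment
        with pytest.raises(ValueError):
            WLCParams(-1.0, 1.0, 0.05, "3D")


class TestBranchedNetwork:
    def test_edge_lengths_in_range(self):
        net = generate_branched_network(4, (1.0, 5.0), 3.03, seed=11)
        lengths = [c.contour_length() for c in net.chains]
        assert min(lengths) >= 1.0 and max(lengths) <= 5.0

    def test_interior_junction_degree_three(self):
        net = generate_branched_network(4, (1.0, 5.0), 3.03, seed=2)
        assert len(net.junctions) > 0
        assert all(deg == 3 for _, _, deg in net.junctions)

    def test_empty_and_deterministic(self):
        assert generate_branched_network(0, (1, 5), 3.0, 0).n_chains == 0
        a = generate_branched_network(2, (1, 5), 3.0, seed=4)
        b = generate_branched_network(2, (1, 5), 3.0, seed=4)
        np.testing.assert_array_equal(a.chains[0].vertices, b.chains[0].vertices)

    def test_bad_range_rejected(self):
        with pytest.raises(ValueError):
            generate_branched_network(1, (5.0, 1.0), 3.0, 0)


class TestRenderImage:
    def test_line_source_profile_is_psf_gaussian(self, straight_chain):
        params = RenderParams(
            pixel_size=0.05, psf_sigma=0.125, tube_outer_radius=0.0,
            wall_thickness=0.0, photon_peak=1000, background=0, noise_model="none",
        )
        img, gt = render_image(straight_chain, params)
        col = img[:, img.shape[1] // 2].astype(float)
        rows = np.arange(col.size) * params.pixel_size
        mu = (rows * col).sum() / col.sum()
        var = ((rows - mu) ** 2 * col).sum() / col.sum()
        assert np.sqrt(var) == pytest.approx(0.125, rel=0.02)

    def test_hollow_tube_widens_profile(self, straight_chain):
        # numeric second-moment oracle: annular projection adds R^2/2
        base = dict(pixel_size=0.01, psf_sigma=0.01, wall_thickness=0.0,
                    photon_peak=5000, background=0, noise_model="none")
        d = np.linspace(-0.15, 0.15, 2001)
        second = {}
        for R in (0.0, 44.1):
            prof = tube_profile(d, R, 0.0, 0.01)
            second[R] = (d**2 * prof).sum() / prof.sum()
            img, _ = render_image(straight_chain, RenderParams(tube_outer_radius=R, **base))
            col = img[:, img.shape[1] // 2].astype(float)
            rows = np.arange(col.size) * 0.01
            mu = (rows * col).sum() / col.sum()
            var = ((rows - mu) ** 2 * col).sum() / col.sum()
            assert var == pytest.approx(second[R], rel=0.05)
        expected_gain = (44.1e-3) ** 2 / 2.0
        assert second[44.1] - second[0.0] == pytest.approx(expected_gain, rel=0.05)

    def test_intensity_linear_in_photon_peak(self, straight_chain):
        base = dict(pixel_size=0.1, psf_sigma=0.125, tube_outer_radius=44.1,
                    wall_thickness=0.0, background=0, noise_model="none")
        img1, _ = render_image(straight_chain, RenderParams(photon_peak=100, **base))
        img2, _ = render_image(straight_chain, RenderParams(photon_peak=200, **base))
        hot = img1 > 10
        assert np.allclose(img2[hot], 2 * img1[hot], atol=1.0)

    def test_pixel_size_must_fit_fov(self, straight_chain):
        with pytest.raises(ValueError):
            render_image(
                straight_chain,
                RenderParams(pixel_size=1.0),
                fov_um=((0.0, 0.5), (0.0, 0.5)),
            )

    def test_ground_truth_centerline_in_pixels(self, straight_chain):
        params = RenderParams(noise_model="none")
        img, gt = render_image(straight_chain, params)
        cl = np.array(gt["centerlines_px"][0])
        # brightest row of a middle column should match the centerline row
        j = img.shape[1] // 2
        row_at_mid = np.interp(j, cl[:, 0], cl[:, 1])
        assert abs(np.argmax(img[:, j]) - row_at_mid) <= 1.0


class TestLocalizations:
    def test_offsets_bounded_by_radius_without_noise(self, straight_chain):
        locs = generate_localizations(straight_chain, 44.1, 0.0, 500.0, seed=1)
        assert np.all(np.abs(locs["y [nm]"]) <= 44.1 + 1e-9)

    def test_count_follows_poisson_mean(self, straight_chain):
        density, L = 800.0, straight_chain.contour_length()
        counts = [
            len(generate_localizations(straight_chain, 44.1, 10.0, density, seed=s))
            for s in range(20)
        ]
        mean = density * L
        se = np.sqrt(mean / len(counts))
        assert abs(np.mean(counts) - mean) < 4 * se

    def test_deterministic(self, straight_chain):
        a = generate_localizations(straight_chain, 44.1, 10.0, 200.0, seed=5)
        b = generate_localizations(straight_chain, 44.1, 10.0, 200.0, seed=5)
        assert a.equals(b)


class TestFluctuationSimulator:
    def test_equipartition_of_mode_amplitudes(self):
        params = FluctuationParams(
            filament_length=2.0, dt=1e-3, duration=10.0, n_modes=3,
            tension_stress=58.3, seed=5,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, modes = simulate_transverse_fluctuations(params, return_modes=True)
        emp = modes["amplitudes_m"].var(axis=0)
        expected = modes["equilibrium_variance_m2"]
        assert np.all(np.abs(emp / expected - 1.0) < 0.05)

    def test_strict_dt_names_offending_mode(self):
        params = FluctuationParams(
            filament_length=10.0, dt=0.1, duration=1.0, n_modes=20, seed=0
        )
        with pytest.raises(ValueError, match="mode"):
            simulate_transverse_fluctuations(params, strict_dt=True)
        with pytest.warns(UserWarning, match="unresolved"):
            simulate_transverse_fluctuations(params)

    def test_ballistic_limit_of_active_drift(self):
        v = 0.5  # um/s
        params = FluctuationParams(
            filament_length=5.0, dt=0.01, duration=20.0, n_modes=10,
            tension_stress=500.0, active_drift=v, seed=8,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            track = simulate_transverse_fluctuations(params)
        tau = 10.0
        k = int(tau / params.dt)
        msd_tau = np.mean((track.displacement[k:] - track.displacement[:-k]) ** 2)
        assert msd_tau / tau**2 == pytest.approx(v**2, rel=0.05)

    def test_expected_msd_mode_sum_matches_simulation(self):
        params = FluctuationParams(
            filament_length=20.0, dt=1e-3, duration=4.0, n_modes=40,
            tension_stress=100.0,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tracks = [
                simulate_transverse_fluctuations(replace(params, seed=s))
                for s in range(16)
            ]
        lags = np.array([0.01, 0.05, 0.2])
        expected = midpoint_msd_expected(params, lags)
        for lag, exp in zip(lags, expected):
            k = int(round(lag / params.dt))
            vals = [
                np.mean((t.displacement[k:] - t.displacement[:-k]) ** 2)
                for t in tracks
            ]
            assert np.mean(vals) == pytest.approx(exp, rel=0.15)


class TestTrackPopulation:
    def test_pure_populations_labelled(self):
        params = FluctuationParams(
            filament_length=5.0, dt=0.05, duration=6.0, n_modes=10, seed=0
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, labels_p = generate_track_population(5, 0, params, seed=1)
            _, labels_a = generate_track_population(0, 5, params, seed=2)
        assert set(labels_p) == {"passive"} and set(labels_a) == {"active"}

    def test_deterministic(self):
        params = FluctuationParams(
            filament_length=5.0, dt=0.05, duration=6.0, n_modes=10, seed=0
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a, _ = generate_track_population(2, 2, params, seed=3)
            b, _ = generate_track_population(2, 2, params, seed=3)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.displacement, tb.displacement)

    def test_durations_at_least_default_filter(self):
        params = FluctuationParams(
            filament_length=5.0, dt=0.05, duration=6.0, n_modes=10, seed=0
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tracks, _ = generate_track_population(3, 0, params, seed=4)
        assert all(t.duration >= 5.0 for t in tracks)
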