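"""Generator contracts: geometry sampling, rendering, time series, traces."""

from __future__ import annotations

import numpy as np
import pytest
from shapely.geometry import LineString

from macnet import synthgen as sg
from macnet.synthgen import ContractionParams, SynthParams


def minimal_params(**kw) -> SynthParams:
    base = dict(
        image_size_px=(128, 128),
        pixel_size_um=0.2,
        n_filaments=15,
        seed=11,
        poisson_noise=False,
        read_noise_sd=0.0,
    )
    base.update(kw)
    return SynthParams(**base)


class TestFilamentSampling:
    def test_empty_field(self):
        truth, geom = sg.sample_filament_field(minimal_params(n_filaments=0))
        assert truth.filaments == [] and geom == []
        assert truth.node_coords.shape == (0, 2)

    def test_determinism_same_seed(self):
        p = minimal_params()
        t1, g1 = sg.sample_filament_field(p)
        t2, g2 = sg.sample_filament_field(p)
        for a, b in zip(t1.filaments, t2.filaments):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(t1.multiplicities, t2.multiplicities)

    def test_filament_count_and_bounds(self):
        p = minimal_params(n_filaments=40)
        truth, geom = sg.sample_filament_field(p)
        assert len(geom) == 40
        w, h = p.field_um
        for poly, _ in geom:
            assert np.all(poly[:, 0] >= -1e-9) and np.all(poly[:, 0] <= w + 1e-9)
            assert np.all(poly[:, 1] >= -1e-9) and np.all(poly[:, 1] <= h + 1e-9)

    def test_orientations_in_halfturn(self):
        truth, _ = sg.sample_filament_field(minimal_params(n_filaments=50))
        assert np.all(truth.orientations >= 0) and np.all(truth.orientations < np.pi)

    def test_high_concentration_collapses_on_director(self):
        """kappa = 1e6 with one domain at 30 deg: circular SD < 0.01 rad."""
        p = minimal_params(
            n_filaments=200,
            orientation_kappa=1e6,
            n_director_domains=1,
            domain_directors=(np.deg2rad(30.0),),
        )
        truth, _ = sg.sample_filament_field(p)
        z = np.exp(2j * truth.orientations)
        # circular stats on the doubled angle; SD of theta is half that of 2 theta
        R = abs(z.mean())
        circ_sd = np.sqrt(-2.0 * np.log(R)) / 2.0
        assert circ_sd < 0.01
        mean_dir = (np.angle(z.mean()) / 2.0) % np.pi
        assert abs(mean_dir - np.deg2rad(30.0)) < 0.01

    def test_kappa_zero_is_uniform(self):
        """Rayleigh-style check: resultant of 2 theta is small for uniform angles."""
        p = minimal_params(n_filaments=400, orientation_kappa=0.0)
        truth, _ = sg.sample_filament_field(p)
        R = abs(np.exp(2j * truth.orientations).mean())
        assert R < 3.0 / np.sqrt(truth.orientations.size)

    def test_node_truth_matches_independent_geometry_oracle(self):
        """Pairwise crossings reproduced exactly by a shapely oracle."""
        truth, geom = sg.sample_filament_field(minimal_params(n_filaments=25, seed=3))
        oracle = []
        lines = [LineString(poly) for poly, _ in geom]
        for i in range(len(lines)):
            for j in range(i + 1, len(lines)):
                inter = lines[i].intersection(lines[j])
                if inter.is_empty:
                    continue
                if inter.geom_type == "Point":
                    oracle.append([inter.x, inter.y])
        oracle = np.asarray(sorted(map(tuple, oracle)))
        got = np.asarray(sorted(map(tuple, truth.node_coords.tolist())))
        assert got.shape == oracle.shape
        np.testing.assert_allclose(got, oracle, atol=1e-9)

    def test_analytic_order_monotone_in_kappa(self):
        """Mean cos 2(theta - director) rises with concentration (MC, 2 SE)."""
        rng = np.random.default_rng(42)
        n = 20000
        means, ses = [], []
        for kappa in (0.0, 1.0, 2.0, 4.0, 8.0):
            vals = np.array(
                [np.cos(2.0 * (sg._sample_orientation(rng, 0.3, kappa) - 0.3)) for _ in range(n)]
            )
            means.append(vals.mean())
            ses.append(vals.std(ddof=1) / np.sqrt(n))
        for k in range(1, len(means)):
            assert means[k] - means[k - 1] > -2.0 * np.hypot(ses[k], ses[k - 1])
        assert means[-1] > means[0] + 0.5


class TestRendering:
    def test_background_only(self):
        p = minimal_params(n_filaments=0, background=10.0)
        img = sg.render_micrograph([], p)
        np.testing.assert_allclose(img.pixels, 10.0)

    def test_multiplicity_linearity(self):
        p = minimal_params(n_filaments=0, background=0.0)
        poly = np.array([[5.0, 12.0], [20.0, 12.0]])
        one = sg.render_micrograph([(poly, 1)], p).pixels
        two = sg.render_micrograph([(poly, 2)], p).pixels
        peak1, peak2 = one.max(), two.max()
        assert peak2 / peak1 == pytest.approx(2.0, abs=1e-6)

    def test_horizontal_ridge_gaussian_profile(self):
        """Cross-section matches the closed-form Gaussian of SD psf/pixel."""
        p = minimal_params(n_filaments=0, background=0.0, psf_sigma_um=0.3)
        y0 = 12.0  # um, on a pixel center (row 60)
        poly = np.array([[2.0, y0], [23.0, y0]])
        img = sg.render_micrograph([(poly, 1)], p).pixels
        ys = np.arange(img.shape[0]) * p.pixel_size_um
        expected = p.line_amplitude * np.exp(-((ys - y0) ** 2) / (2.0 * p.psf_sigma_um**2))
        for col in (30, 50, 64, 90):
            np.testing.assert_allclose(img[:, col], expected, atol=1e-6)

    def test_noise_keeps_pixels_non_negative(self):
        p = minimal_params(poisson_noise=True, read_noise_sd=50.0, background=1.0)
        img = sg.render_micrograph(sg.sample_filament_field(p)[1], p)
        assert np.all(img.pixels >= 0)

    def test_seeded_noise_reproducible(self):
        p = minimal_params(poisson_noise=True, read_noise_sd=2.0)
        _, geom = sg.sample_filament_field(p)
        a = sg.render_micrograph(geom, p).pixels
        b = sg.render_micrograph(geom, p).pixels
        np.testing.assert_array_equal(a, b)


class TestContractionSeries:
    def test_mode_none_static_without_noise_or_bleach(self):
        p = minimal_params(n_filaments=10)
        cp = ContractionParams(
            n_frames=4, mode="none", aster_centers=(), bleach_rate_per_frame=0.0, seed=1
        )
        actin, _, flows = sg.generate_contraction_series(
            sg.sample_filament_field(p)[1], cp, p
        )
        for f in actin.frames[1:]:
            np.testing.assert_array_equal(f.pixels, actin.frames[0].pixels)
        for fl in flows:
            assert np.all(fl.u_um_s == 0) and np.all(fl.v_um_s == 0)

    def test_mode_none_forces_zero_speed(self):
        cp = ContractionParams(mode="none", aster_centers=(), v0_um_per_s=5.0)
        assert cp.v0_um_per_s == 0.0

    def test_vertex_distance_to_aster_non_increasing(self):
        p = minimal_params(n_filaments=12)
        w, h = p.field_um
        aster = (w / 2, h / 2)
        cp = ContractionParams(
            n_frames=8, aster_centers=(aster,), v0_um_per_s=0.3,
            capture_radius_um=60.0, mode="global", seed=2,
        )
        _, geom = sg.sample_filament_field(p)
        polys0 = [poly.copy() for poly, _ in geom]
        actin, _, _ = sg.generate_contraction_series(geom, cp, p)
        # re-run the kinematics independently: mean distance decreases frame on frame
        dists = []
        polys = [poly.copy() for poly in polys0]
        for _ in range(cp.n_frames):
            all_pts = np.concatenate(polys)
            dists.append(np.hypot(all_pts[:, 0] - aster[0], all_pts[:, 1] - aster[1]).mean())
            for poly in polys:
                step = sg._imposed_velocity(poly, cp, w / 2) * cp.frame_interval_s
                # do not overshoot the aster center
                to_aster = np.hypot(poly[:, 0] - aster[0], poly[:, 1] - aster[1])
                mag = np.hypot(step[:, 0], step[:, 1])
                over = mag > to_aster
                step[over] *= (to_aster[over] / mag[over])[:, None]
                poly += step
        assert all(d2 <= d1 + 1e-9 for d1, d2 in zip(dists, dists[1:]))

    def test_partial_mode_untouched_half_has_zero_flow(self):
        p = minimal_params(n_filaments=10)
        w, h = p.field_um
        cp = ContractionParams(
            n_frames=3, aster_centers=((w / 4, h / 2),), v0_um_per_s=0.3,
            capture_radius_um=100.0, mode="partial", seed=3,
        )
        _, _, flows = sg.generate_contraction_series(sg.sample_filament_field(p)[1], cp, p)
        for fl in flows:
            right = fl.x_um >= w / 2
            assert np.all(fl.u_um_s[right] == 0) and np.all(fl.v_um_s[right] == 0)

    def test_intensity_conservation_under_contraction(self):
        """No noise, no bleach: total signal is conserved within 1%."""
        p = minimal_params(n_filaments=25, background=0.0, seed=6)
        w, h = p.field_um
        cp = ContractionParams(
            n_frames=10, aster_centers=((w / 2, h / 2),), v0_um_per_s=0.2,
            capture_radius_um=60.0, bleach_rate_per_frame=0.0, seed=6,
        )
        actin, _, _ = sg.generate_contraction_series(sg.sample_filament_field(p)[1], cp, p)
        totals = np.array([f.pixels.sum() for f in actin.frames])
        # the first step pulls border-clipped ridge tails onto the grid
        # (border clipping is excepted from conservation); afterwards the
        # compaction-compensated rendering conserves total signal
        moved = totals[1:]
        assert np.max(np.abs(moved - moved[0])) / moved[0] < 0.01
        assert np.max(np.abs(totals - totals[0])) / totals[0] < 0.02

    def test_requires_asters_unless_none(self):
        with pytest.raises(ValueError):
            ContractionParams(mode="global", aster_centers=())


class TestScalarTraces:
    def test_frap_immobile_one_has_no_recovery(self):
        tr = sg.generate_frap_trace(3.0, 5.0, 1.0, 0.25, 100, 0.0, seed=0)
        post = tr.spot_intensity[tr.bleach_index :]
        np.testing.assert_allclose(post, post[0], atol=1e-12)

    def test_frap_fast_diffusion_recovers_within_first_frame(self):
        tr = sg.generate_frap_trace(1e4, 2.0, 0.0, 1.0, 50, 0.0, seed=0)
        assert tr.spot_intensity[tr.bleach_index + 1] > 0.99

    def test_frap_matches_finite_difference_diffusion(self):
        """Closed-form recovery vs an explicit-Euler diffusion oracle, 1% RMS."""
        D, radius = 3.0, 5.0
        n_frames, dt_frame = 80, 0.25
        tr = sg.generate_frap_trace(D, radius, 0.0, dt_frame, n_frames, 0.0,
                                    bleach_depth=1.0, n_prebleach=0)
        # fine-grid explicit diffusion of the bleach profile
        L, dx = 60.0, 0.25
        n = int(L / dx)
        xs = (np.arange(n) + 0.5) * dx - L / 2
        X, Y = np.meshgrid(xs, xs)
        disc = X**2 + Y**2 <= radius**2
        c = np.where(disc, 0.0, 1.0)
        dt = 0.2 * dx**2 / D
        steps_per_frame = dt_frame / dt
        oracle = [c[disc].mean()]
        acc = 0.0
        t_needed = (n_frames - 1) * dt_frame
        n_steps = int(np.ceil(t_needed / dt))
        frame_times = np.arange(1, n_frames) * dt_frame
        next_frame = 0
        for step in range(1, n_steps + 1):
            lap = (
                np.roll(c, 1, 0) + np.roll(c, -1, 0) + np.roll(c, 1, 1) + np.roll(c, -1, 1)
                - 4 * c
            ) / dx**2
            c = c + D * dt * lap
            c[0, :] = c[-1, :] = c[:, 0] = c[:, -1] = 1.0  # far-field reservoir
            t = step * dt
            while next_frame < frame_times.size and t >= frame_times[next_frame] - 1e-12:
                oracle.append(c[disc].mean())
                next_frame += 1
        oracle = np.asarray(oracle[:n_frames])
        rms = np.sqrt(np.mean((tr.spot_intensity - oracle) ** 2))
        assert rms < 0.01

    def test_rifs_constant_and_step(self):
        flat = sg.generate_rifs_trace([(50.0, 2.0)], 0.0)
        np.testing.assert_allclose(flat.dOT_nm, 2.0)
        step = sg.generate_rifs_trace([(50.0, 0.0), (50.0, 6.0)], 0.0)
        assert step.dOT_nm[-1] - step.dOT_nm[0] == pytest.approx(6.0)

    def test_rifs_noise_sd_within_chi_square_bounds(self):
        tr = sg.generate_rifs_trace([(500.0, 3.0)], 0.1, seed=5)
        sd = tr.dOT_nm.std(ddof=1)
        assert 0.08 < sd < 0.12
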