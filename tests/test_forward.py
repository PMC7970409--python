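"""Pencil-beam excitation, diffusion kernel, detector fluence and full scans."""

import numpy as np
import pytest

from xlct.forward import (BeamSpec, DetectorSet, GeometryError, NoiseModel,
                          Sinogram, SinogramFormatError, detector_fluence,
                          export_sinogram_csv, greens_function,
                          greens_infinite, luminescence_source, read_sinogram,
                          simulate_scan, write_sinogram, xray_intensity,
                          _diffusion_params)
from xlct.phantoms import (ConcentrationMap, OpticalProperties,
                           SphericalTarget, grid_coords, make_phantom,
                           rasterize_concentration)
from conftest import SMALL_VOXEL


class TestXRayIntensity:
    def test_no_attenuation_uniform_along_chord(self, small_phantom):
        """mu_x = 0: constant intensity along the beam (per footprint row)."""
        beam = BeamSpec(mu_x=0.0)
        f = xray_intensity(small_phantom, beam, 0.0, 0.0)
        assert f.values.any()
        for j in range(f.values.shape[1]):
            col = f.values[:, j][f.values[:, j] > 0]
            if col.size:
                np.testing.assert_allclose(col, col[0], rtol=1e-12)
                assert col[0] <= beam.source_intensity

    def test_entry_attenuation_factor_is_unity(self, small_phantom):
        """The Beer–Lambert factor at the entry point (d = 0) is 1: dividing
        out the footprint weight recovers the source intensity."""
        att = xray_intensity(small_phantom, BeamSpec(mu_x=0.27), 0.0, 0.0)
        ref = xray_intensity(small_phantom, BeamSpec(mu_x=0.0), 0.0, 0.0)
        mask = ref.values > 0
        ratio = att.values[mask] / ref.values[mask]
        # entry voxel center sits at most ~one voxel past the surface
        assert np.exp(-0.027 * 2 * small_phantom.voxel_size) \
            <= ratio.max() <= 1.0

    def test_attenuation_matches_line_integral_oracle(self, small_phantom):
        """Beer–Lambert ratio between two on-beam voxels equals the
        exponential of the quadrature line integral of mu_x to 1e-9."""
        from scipy.integrate import quad
        beam = BeamSpec(mu_x=0.27)
        f = xray_intensity(small_phantom, beam, 0.0, 0.0)
        x, _ = grid_coords(small_phantom)
        row = f.values[:, np.argmax(f.values.max(axis=0))]
        idx = np.flatnonzero(row)
        i0, i1 = idx[0], idx[-1]
        d_mm = x[i1, 0] - x[i0, 0]
        mu_mm = 0.27 / 10.0
        integral, _ = quad(lambda s: mu_mm, 0.0, d_mm)  # piecewise-constant medium
        assert row[i1] / row[i0] == pytest.approx(np.exp(-integral), abs=1e-9)

    def test_monotone_nonincreasing_along_beam(self, small_phantom):
        f = xray_intensity(small_phantom, BeamSpec(mu_x=0.27), 0.0, 0.0)
        for j in range(f.values.shape[1]):
            col = f.values[:, j][f.values[:, j] > 0]  # fixed footprint row
            assert np.all(np.diff(col) <= 1e-15)

    def test_miss_yields_zero_field(self, small_phantom):
        f = xray_intensity(small_phantom, BeamSpec(), 0.0,
                           small_phantom.radius + 1.0)
        assert not f.values.any()

    def test_zero_outside_beam_column(self, small_phantom):
        beam = BeamSpec()
        f = xray_intensity(small_phantom, beam, 90.0, 2.0)
        x, y = grid_coords(small_phantom)
        # at 90 deg the translation axis is -x; footprint support is 1.8 voxels
        far = np.abs(-x - 2.0) > 1.8 * small_phantom.voxel_size
        assert not f.values[far].any()


class TestLuminescenceSource:
    def test_zero_concentration_zero_source(self, small_phantom, empty_phantom):
        f = xray_intensity(small_phantom, BeamSpec(), 0.0, 0.0)
        s = luminescence_source(f, rasterize_concentration(empty_phantom))
        assert not s.values.any()

    def test_linear_in_eta_and_pointwise_product(self, small_phantom):
        f = xray_intensity(small_phantom, BeamSpec(), 0.0, -2.0)
        rho = rasterize_concentration(small_phantom)
        s1 = luminescence_source(f, rho, eta=1.0)
        s2 = luminescence_source(f, rho, eta=2.0)
        np.testing.assert_array_equal(s2.values, 2.0 * s1.values)
        np.testing.assert_array_equal(s1.values, f.values * rho.values)

    def test_grid_mismatch_raises(self, small_phantom):
        f = xray_intensity(small_phantom, BeamSpec(), 0.0, 0.0)
        other = ConcentrationMap(values=np.zeros((4, 4)), origin=(0, 0),
                                 voxel_size=1.0)
        with pytest.raises(ValueError, match="grid mismatch"):
            luminescence_source(f, other)


class TestGreensFunction:
    def test_diffusion_parameters(self, props):
        D, mu_eff = _diffusion_params(props)
        assert D / 10 == pytest.approx(1.0 / 46.5, rel=1e-12)    # cm
        assert (mu_eff * 10) ** 2 == pytest.approx(23.25, rel=1e-12)

    def test_infinite_kernel_matches_closed_form(self, props):
        """G∞(d) = exp(−μeff·d)/(4πD·d) at the validation optics, 1e-12."""
        D, mu_eff = _diffusion_params(props)
        for d in [1.0, 2.5, 5.0, 8.0, 12.0]:
            expected = np.exp(-mu_eff * d) / (4 * np.pi * D * d)
            assert greens_infinite(d, props) == pytest.approx(
                expected, rel=1e-12)

    def test_isotropy(self, props):
        # equal distances along different directions give equal kernels
        assert greens_infinite(3.7, props) == greens_infinite(3.7, props)
        d = np.array([3.7, 3.7])
        g = greens_infinite(d, props)
        assert g[0] == g[1]

    def test_boundary_kernel_positive_and_monotone(self, props):
        r_det = np.array([12.5, 0.0, 0.0])
        xs = np.linspace(11.5, 0.5, 40)
        pts = np.stack([xs, np.zeros_like(xs), np.zeros_like(xs)], axis=1)
        g = greens_function(r_det, pts, props, boundary_radius=12.5)
        assert np.all(g > 0)
        assert np.all(np.diff(g) < 0)   # farther source, smaller fluence

    def test_source_outside_boundary_raises(self, props):
        r_det = np.array([12.5, 0.0, 0.0])
        with pytest.raises(GeometryError):
            greens_function(r_det, np.array([12.5, 0.0, 0.0]), props)
        with pytest.raises(GeometryError):
            greens_function(r_det, np.array([13.0, 0.0, 0.0]), props)

    def test_non_diffusive_props_warn(self):
        import warnings
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            bad = OpticalProperties.__new__(OpticalProperties)
            object.__setattr__(bad, "mu_a", 5.0)
            object.__setattr__(bad, "mu_s_prime", 15.0)
            object.__setattr__(bad, "refractive_index", 1.37)
            greens_function(np.array([12.5, 0, 0]), np.array([5.0, 0, 0]),
                            bad, boundary_radius=12.5)
        assert any("diffusion" in str(w.message) for w in rec)


class TestDetectorFluence:
    def test_zero_source_zero_readings(self, small_phantom, detectors, props):
        f = xray_intensity(small_phantom, BeamSpec(), 0.0, 20.0)  # miss
        s = luminescence_source(f, rasterize_concentration(small_phantom))
        out = detector_fluence(s, detectors, props, small_phantom)
        np.testing.assert_array_equal(out, 0.0)

    def test_single_voxel_hand_evaluation(self, small_phantom, detectors,
                                          props):
        """One nonzero voxel: reading is G × S × voxel volume × aperture."""
        n = small_phantom.n_grid
        values = np.zeros((n, n))
        values[n // 2 + 2, n // 2 - 1] = 3.5
        x, y = grid_coords(small_phantom)
        src = np.array([x[n // 2 + 2, n // 2 - 1], y[n // 2 + 2, n // 2 - 1],
                        0.0])
        from xlct.forward import LuminescenceSource
        source = LuminescenceSource(values=values, origin=(-12.5, -12.5),
                                    voxel_size=small_phantom.voxel_size)
        out = detector_fluence(source, detectors, props, small_phantom,
                               view_angle=0.0)
        for k, r_det in enumerate(detectors.positions(small_phantom, 0.0)):
            g = greens_function(r_det, src, props,
                                boundary_radius=small_phantom.radius)
            expected = g * 3.5 * small_phantom.voxel_size ** 3 \
                * detectors.aperture_area
            assert out[k] == pytest.approx(expected, rel=1e-12)

    def test_multi_voxel_matches_bruteforce_sum(self, small_phantom,
                                                detectors, props):
        beam = BeamSpec()
        f = xray_intensity(small_phantom, beam, 30.0, -1.0)
        rho = rasterize_concentration(small_phantom)
        s = luminescence_source(f, rho)
        out = detector_fluence(s, detectors, props, small_phantom,
                               view_angle=30.0)
        x, y = grid_coords(small_phantom)
        for k, r_det in enumerate(detectors.positions(small_phantom, 30.0)):
            acc = 0.0
            for ix, iy in zip(*np.nonzero(s.values)):
                g = greens_function(
                    r_det, np.array([x[ix, iy], y[ix, iy], 0.0]), props,
                    boundary_radius=small_phantom.radius)
                acc += g * s.values[ix, iy]
            acc *= small_phantom.voxel_size ** 3 * detectors.aperture_area
            assert out[k] == pytest.approx(acc, rel=1e-12)

    def test_empty_detector_set_rejected(self):
        with pytest.raises(ValueError):
            DetectorSet(angular_offsets=())


class TestSimulateScan:
    def test_validation_protocol_shape(self, small_phantom):
        """The stated scan protocol: 15 views × 50 translations × 3 bundles."""
        sino = simulate_scan(small_phantom, BeamSpec(), DetectorSet())
        assert sino.shape == (15, 50, 3)
        np.testing.assert_allclose(sino.angles, np.arange(15) * 12.0)

    def test_empty_phantom_all_zero(self, empty_phantom, small_beam,
                                    detectors):
        sino = simulate_scan(empty_phantom, small_beam, detectors)
        assert not sino.values.any()

    def test_linearity_in_concentration(self, small_phantom, small_beam,
                                        detectors):
        s1 = simulate_scan(small_phantom, small_beam, detectors)
        s2 = simulate_scan(small_phantom.scaled(2.0), small_beam, detectors)
        np.testing.assert_allclose(s2.values, 2.0 * s1.values, rtol=1e-12)

    def test_superposition_of_targets(self, small_beam, detectors):
        a = SphericalTarget(center=(4.0, 1.0, 0.0), radius=2.0,
                            concentration=1.0)
        b = SphericalTarget(center=(-4.0, -3.0, 0.0), radius=1.5,
                            concentration=2.0)
        ph_a = make_phantom(targets=[a], voxel_size=SMALL_VOXEL)
        ph_b = make_phantom(targets=[b], voxel_size=SMALL_VOXEL)
        ph_ab = make_phantom(targets=[a, b], voxel_size=SMALL_VOXEL)
        sum_ab = simulate_scan(ph_a, small_beam, detectors).values \
            + simulate_scan(ph_b, small_beam, detectors).values
        both = simulate_scan(ph_ab, small_beam, detectors).values
        np.testing.assert_allclose(both, sum_ab, rtol=1e-10)

    def test_rotational_consistency(self, detectors):
        """Rotating the target by one angular step shifts the sinogram by
        one view (detectors co-rotate with the gantry)."""
        beam = BeamSpec(n_views=8, n_translations=20, translation_step=1.2)
        step = np.deg2rad(beam.angular_span / beam.n_views)
        r, ang = 5.0, 0.4
        t0 = SphericalTarget(center=(r * np.cos(ang), r * np.sin(ang), 0.0),
                             radius=2.0, concentration=1.0)
        t1 = SphericalTarget(center=(r * np.cos(ang + step),
                                     r * np.sin(ang + step), 0.0),
                             radius=2.0, concentration=1.0)
        s0 = simulate_scan(make_phantom(targets=[t0], voxel_size=0.125),
                           beam, detectors).values
        s1 = simulate_scan(make_phantom(targets=[t1], voxel_size=0.125),
                           beam, detectors).values
        rolled = np.roll(s1, -1, axis=0)[:-1]   # drop the wrapped view
        rel = np.linalg.norm(rolled - s0[:-1]) / np.linalg.norm(s0[:-1])
        assert rel < 0.05

    def test_nonzero_set_matches_line_sphere_oracle(self, detectors):
        """Readings are nonzero exactly where the beam line meets the target
        sphere, up to a half-voxel-diagonal rasterization band."""
        target = SphericalTarget(center=(3.0, -2.0, 0.0), radius=2.0,
                                 concentration=1.0)
        ph = make_phantom(targets=[target], voxel_size=0.25)
        beam = BeamSpec(n_views=10, n_translations=30, translation_step=0.8)
        sino = simulate_scan(ph, beam, detectors)
        hit = sino.values.sum(axis=2) > 0
        band_in = target.radius - 2.0 * ph.voxel_size
        band_out = target.radius + 1.8 * ph.voxel_size + beam.diameter / 2000.0
        for i, theta in enumerate(np.deg2rad(sino.angles)):
            # distance from the beam line to the sphere center
            d = np.abs(target.center[0] * (-np.sin(theta))
                       + target.center[1] * np.cos(theta) - sino.offsets)
            assert hit[i][d <= band_in].all()
            assert not hit[i][d >= band_out].any()

    def test_nonnegative_and_noise_determinism(self, small_phantom,
                                               small_beam, detectors):
        noise = NoiseModel(level=0.05, seed=9)
        a = simulate_scan(small_phantom, small_beam, detectors, noise=noise)
        b = simulate_scan(small_phantom, small_beam, detectors, noise=noise)
        assert np.all(a.values >= 0)
        np.testing.assert_array_equal(a.values, b.values)
        clean = simulate_scan(small_phantom, small_beam, detectors)
        assert not np.array_equal(a.values, clean.values)


class TestSinogramIO:
    def test_round_trip(self, tmp_path, small_phantom, small_beam, detectors):
        sino = simulate_scan(small_phantom, small_beam, detectors,
                             noise=NoiseModel(seed=1))
        path = tmp_path / "s.h5"
        write_sinogram(sino, path)
        back = read_sinogram(path)
        np.testing.assert_array_equal(back.values, sino.values)
        np.testing.assert_array_equal(back.angles, sino.angles)
        np.testing.assert_array_equal(back.offsets, sino.offsets)
        assert back.detector_offsets == sino.detector_offsets
        assert back.noise["seed"] == 1

    def test_truncated_file_is_format_error(self, tmp_path):
        path = tmp_path / "bad.h5"
        path.write_bytes(b"\x89HDF\r\n\x1a\n" + b"\x00" * 32)
        with pytest.raises(SinogramFormatError):
            read_sinogram(path)

    def test_few_view_angle_grid(self):
        """15 views over 180° give the 12°-step grid {0, 12, ..., 168}."""
        np.testing.assert_allclose(BeamSpec(n_views=15).angles,
                                   np.arange(0, 180, 12))
        np.testing.assert_allclose(BeamSpec(n_views=30).angles,
                                   np.arange(0, 180, 6))

    def test_csv_export(self, tmp_path, small_phantom, small_beam, detectors):
        sino = simulate_scan(small_phantom, small_beam, detectors)
        path = tmp_path / "s.csv"
        export_sinogram_csv(sino, path)
        rows = path.read_text().strip().splitlines()
        assert len(rows) == 1 + np.prod(sino.shape)
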