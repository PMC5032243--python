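"""Array geometry, angular-spectrum propagation, Q, aberration correction
and the closed-form focused-bowl oracle."""

import numpy as np
import pytest
from scipy.integrate import quad

from fusmrt import acoustics, phantoms
from fusmrt.acoustics import (build_array, calibrate_aperture, compute_q,
                              field_at_points, geometric_steer, has_propagate,
                              oneil_axial_oracle, source_plane)
from fusmrt.phantoms import MaterialProperties, build_homogeneous_phantom

WATER = MaterialProperties(c=1482.0, attenuation=0.0, rho=1000.0)


def water_medium(shape, spacing, z0):
    origin = (-(shape[0] - 1) / 2 * spacing[0],
              -(shape[1] - 1) / 2 * spacing[1], z0)
    return build_homogeneous_phantom(shape, spacing, gel_props=WATER,
                                     water_props=WATER, gel_z_extent=-1.0,
                                     origin=origin)


class TestBuildArray:
    def test_elements_on_sphere_about_focus(self):
        arr = build_array(256, roc=0.13, frequency=1e6, aperture_diameter=0.12)
        d = np.linalg.norm(arr.element_positions - np.array(arr.focus_center),
                           axis=1)
        assert np.allclose(d, 0.13, atol=1e-9)
        assert arr.n_elements == 256

    def test_single_element_on_axis(self):
        arr = build_array(1, roc=0.1, aperture_diameter=0.05)
        assert np.allclose(arr.element_positions[0], [0.0, 0.0, 0.0], atol=1e-12)

    def test_layout_deterministic_given_seed(self):
        a = build_array(64, layout_seed=5)
        b = build_array(64, layout_seed=5)
        assert np.array_equal(a.element_positions, b.element_positions)

    def test_aperture_too_large_rejected(self):
        with pytest.raises(ValueError):
            build_array(16, roc=0.1, aperture_diameter=0.3)


class TestGeometricSteer:
    def test_zero_phase_at_center_of_curvature(self):
        arr = build_array(64, roc=0.13, aperture_diameter=0.1)
        ph = geometric_steer(arr, arr.focus_center, 1482.0)
        assert np.allclose(ph, 0.0, atol=1e-6)

    def test_steered_phases_match_path_lengths(self):
        arr = build_array(32, roc=0.13, aperture_diameter=0.1)
        target = (5e-3, 0.0, 0.13)
        ph = geometric_steer(arr, target, 1500.0)
        d = np.linalg.norm(arr.element_positions - np.asarray(target), axis=1)
        expected = -(2 * np.pi * 1e6 / 1500.0) * (d - 0.13)
        assert np.allclose(ph, expected)

    def test_doubling_speed_halves_phases(self):
        arr = build_array(16, roc=0.1, aperture_diameter=0.06)
        ph1 = geometric_steer(arr, (2e-3, 0, 0.1), 1000.0)
        ph2 = geometric_steer(arr, (2e-3, 0, 0.1), 2000.0)
        assert np.allclose(ph2, ph1 / 2)

    def test_nonpositive_speed_rejected(self):
        arr = build_array(4, roc=0.1, aperture_diameter=0.06)
        with pytest.raises(ValueError):
            geometric_steer(arr, (0, 0, 0.1), 0.0)


class TestSourcePlane:
    def test_single_element_inverse_distance(self):
        arr = build_array(1, roc=0.1, aperture_diameter=0.05, element_radius=0.0)
        p = field_at_points(arr, [(0, 0, 0.02), (0, 0, 0.04)], 1482.0)
        assert abs(p[0]) / abs(p[1]) == pytest.approx(2.0, rel=1e-12)

    def test_power_normalization(self):
        med = water_medium((64, 64, 8), (0.7e-3, 0.7e-3, 1e-3), 0.05)
        arr = build_array(64, roc=0.13, aperture_diameter=0.08)
        sp = source_plane(arr, 0.05, med, watts=3.0)
        zi = sp.z_index
        I = np.abs(sp.p) ** 2 / (2 * med.rho[:, :, zi] * med.c[:, :, zi])
        total = I.sum() * med.spacing[0] * med.spacing[1]
        assert total == pytest.approx(3.0, rel=5e-3)

    def test_matches_bruteforce_double_loop(self):
        med = water_medium((6, 5, 4), (1e-3, 1e-3, 1e-3), 0.03)
        arr = build_array(8, roc=0.1, aperture_diameter=0.06, element_radius=0.0)
        sp = source_plane(arr, 0.03, med)
        k = 2 * np.pi * 1e6 / 1482.0
        xs, ys = med.axis_coords(0), med.axis_coords(1)
        expected = np.zeros((6, 5), dtype=complex)
        for i, x in enumerate(xs):
            for j, y in enumerate(ys):
                for e in range(arr.n_elements):
                    r = np.linalg.norm(np.array([x, y, sp.z])
                                       - arr.element_positions[e])
                    expected[i, j] += np.exp(1j * k * r) / r
        assert np.allclose(sp.p, expected, rtol=1e-10)

    def test_plane_intersecting_array_rejected(self):
        med = water_medium((8, 8, 8), (1e-3, 1e-3, 1e-3), 0.0)
        arr = build_array(16, roc=0.1, aperture_diameter=0.08)
        with pytest.raises(ValueError):
            source_plane(arr, 0.0, med)


class TestHasPropagate:
    def test_spectral_power_conserved_lossless(self):
        """Plane-integrated propagating spectral power is conserved
        plane-to-plane in a lossless homogeneous medium (unitary propagator,
        evanescent-free beam)."""
        med = water_medium((64, 64, 40), (0.7e-3, 0.7e-3, 1e-3), 0.0)
        xs, ys = med.axis_coords(0), med.axis_coords(1)
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        p0 = np.exp(-(X ** 2 + Y ** 2) / (2 * (4e-3) ** 2)).astype(complex)
        sp = acoustics.SourcePlane(p=p0, z_index=0, z=0.0,
                                   spacing=med.spacing[:2])
        pf = has_propagate(sp, med)
        power = [np.sum(np.abs(np.fft.fft2(pf.p[:, :, j])) ** 2)
                 for j in range(1, med.shape[2])]
        power = np.asarray(power)
        assert np.max(np.abs(np.diff(power)) / power[0]) < 1e-3

    def test_beer_lambert_slab_decay(self):
        """Uniform plane wave through a 0.1 m slab of 6 Np/m absorber:
        amplitude ratio exp(-0.6) = 0.5488."""
        gel = MaterialProperties(c=1553.0, attenuation=0.06, rho=1057.0)
        shape = (8, 8, 101)
        med = build_homogeneous_phantom(shape, (0.7e-3, 0.7e-3, 1e-3),
                                        gel_props=gel, water_props=gel,
                                        gel_z_extent=-1.0,
                                        origin=(0.0, 0.0, 0.0))
        sp = acoustics.SourcePlane(p=np.ones((8, 8), dtype=complex),
                                   z_index=0, z=0.0, spacing=med.spacing[:2])
        pf = has_propagate(sp, med)
        ratio = np.abs(pf.p[4, 4, 100]) / np.abs(pf.p[4, 4, 0])
        assert ratio == pytest.approx(np.exp(-0.6), abs=1e-3)

    def test_axial_field_matches_oneil(self):
        """On-axis HAS pressure of a focused bowl in lossless water agrees
        with the O'Neil closed form within 5 % of the focal peak over
        0.8-1.2 times the radius of curvature."""
        roc, ap = 0.05, 0.03
        shape = (128, 128, 110)
        spacing = (0.55e-3, 0.55e-3, 0.5e-3)
        med = water_medium(shape, spacing, 10e-3)
        arr = build_array(2048, roc=roc, frequency=1e6, aperture_diameter=ap)
        sp = source_plane(arr, 10e-3, med, watts=1.0)
        pf = has_propagate(sp, med)
        z = med.axis_coords(2)
        axial = np.abs(pf.p[shape[0] // 2, shape[1] // 2, :])
        sel = (z >= 0.8 * roc) & (z <= 1.2 * roc)
        oneil = oneil_axial_oracle(roc, ap, 1e6, 1482.0, 1000.0, z[sel])
        a = axial[sel] / axial[sel].max()
        o = oneil / oneil.max()
        assert np.max(np.abs(a - o)) < 0.05

    def test_source_linearity_in_power(self):
        med = water_medium((32, 32, 16), (0.7e-3, 0.7e-3, 1e-3), 0.04)
        arr = build_array(32, roc=0.13, aperture_diameter=0.06)
        p1 = has_propagate(source_plane(arr, 0.04, med, watts=1.0), med).p
        p4 = has_propagate(source_plane(arr, 0.04, med, watts=4.0), med).p
        assert np.allclose(np.abs(p4), 2.0 * np.abs(p1), rtol=1e-6)

    def test_spacing_guard(self):
        med = water_medium((8, 8, 8), (2e-3, 2e-3, 1e-3), 0.04)
        sp = acoustics.SourcePlane(p=np.ones((8, 8), dtype=complex),
                                   z_index=0, z=0.04, spacing=med.spacing[:2])
        with pytest.raises(ValueError):
            has_propagate(sp, med, spacing_check="raise")


class TestComputeQ:
    def test_plane_wave_hand_value(self):
        """|p| = 0.5 MPa in gelatin: I = 7.615e4 W/m^2, Q = 9.14e5 W/m^3."""
        gel = MaterialProperties(c=1553.0, attenuation=0.06, rho=1057.0)
        med = build_homogeneous_phantom((4, 4, 4), (1e-3,) * 3, gel_props=gel,
                                        water_props=gel, gel_z_extent=-1.0)
        pf = acoustics.PressureField(p=np.full(med.shape, 0.5e6, dtype=complex),
                                     frequency=1e6, spacing=med.spacing,
                                     origin=med.origin)
        q = compute_q(pf, med)
        assert q.q[0, 0, 0] == pytest.approx(9.138e5, rel=1e-3)

    def test_zero_attenuation_gives_zero_q(self):
        med = water_medium((4, 4, 4), (1e-3,) * 3, 0.0)
        pf = acoustics.PressureField(p=np.ones(med.shape, dtype=complex),
                                     frequency=1e6, spacing=med.spacing,
                                     origin=med.origin)
        assert np.all(compute_q(pf, med).q == 0.0)

    def test_absorbed_power_bounded_by_emitted(self, homogeneous_result):
        res = homogeneous_result
        emitted = res.array.total_acoustic_power
        assert res.q.total_power <= emitted * 1.01


class TestAberrationCorrection:
    def _setup(self, nz=64):
        shape = (48, 48, nz)
        spacing = (0.7e-3, 0.7e-3, 1e-3)
        med = water_medium(shape, spacing, 20e-3)
        arr = build_array(12, roc=0.08, frequency=1e6, aperture_diameter=0.03)
        return med, arr

    def test_homogeneous_matches_geometric(self):
        med, arr = self._setup()
        focus = (0.0, 0.0, 0.08)
        corrected = acoustics.aberration_correct(arr, med, focus)
        fi = med.index_of(focus)  # compare at the snapped voxel center
        snapped = tuple(med.axis_coords(a)[fi[a]] for a in range(3))
        geo = geometric_steer(arr, snapped, 1482.0)
        diff = np.angle(np.exp(1j * (corrected - geo)))
        diff -= diff.mean()  # global constant is irrelevant
        assert np.max(np.abs(diff)) < 0.05

    def test_correction_never_decreases_focal_pressure(self):
        med, arr = self._setup()
        # an aberrating off-center fast inclusion
        med.c[10:30, 10:30, 20:30] = 2000.0
        med.rho[10:30, 10:30, 20:30] = 1100.0
        focus = (0.0, 0.0, 0.08)
        fi = med.index_of(focus)
        corrected, diag = acoustics.aberration_correct(
            arr, med, focus, return_diagnostics=True)
        p_corr = np.abs(np.sum(diag["p_focus"] * np.exp(1j * corrected)))
        p_zero = np.abs(np.sum(diag["p_focus"]))
        assert p_corr >= p_zero - 1e-12

    def test_imposed_delays_are_negated(self):
        """Shifting each element toward the focus by d_i shortens its path
        by d_i; the recovered correction shifts by +k*d_i element-wise."""
        med, arr = self._setup()
        focus = (0.0, 0.0, 0.08)
        base = acoustics.aberration_correct(arr, med, focus)
        rng = np.random.default_rng(3)
        d = rng.uniform(0, 0.3e-3, arr.n_elements)
        arr2 = acoustics.TransducerArray(
            n_elements=arr.n_elements,
            element_positions=arr.element_positions + d[:, None] * arr.element_normals,
            element_normals=arr.element_normals, frequency=arr.frequency,
            roc=arr.roc, aperture_diameter=arr.aperture_diameter,
            focus_center=arr.focus_center, drive=arr.drive.copy(),
            element_radius=arr.element_radius)
        shifted = acoustics.aberration_correct(arr2, med, focus)
        k = 2 * np.pi * 1e6 / 1482.0
        diff = np.angle(np.exp(1j * (shifted - base - k * d)))
        assert np.max(np.abs(diff - diff.mean())) < 0.05


class TestOneilOracle:
    def test_peak_near_roc_for_high_gain(self):
        z = np.linspace(0.02, 0.12, 400)
        p = oneil_axial_oracle(0.06, 0.04, 1.5e6, 1482.0, 1000.0, z)
        assert abs(z[np.argmax(p)] - 0.06) < 0.006

    def test_matches_rayleigh_quadrature(self):
        """Closed form vs direct numerical Rayleigh integration over the cap
        (independent quadrature oracle)."""
        roc, ap, f, c, rho = 0.05, 0.03, 1e6, 1482.0, 1000.0
        k = 2 * np.pi * f / c
        a = ap / 2
        theta_max = np.arcsin(a / roc)

        def axial_rayleigh(z):
            def integrand(theta, part):
                R = np.sqrt(z * z + 2 * roc * (roc - z) * (1 - np.cos(theta)))
                val = np.exp(1j * k * R) / R * np.sin(theta)
                return val.real if part == 0 else val.imag
            re = quad(lambda t: integrand(t, 0), 0, theta_max, limit=200)[0]
            im = quad(lambda t: integrand(t, 1), 0, theta_max, limit=200)[0]
            return rho * c * k * roc ** 2 * abs(complex(re, im))

        for z in (0.035, 0.045, 0.052, 0.06):
            closed = oneil_axial_oracle(roc, ap, f, c, rho, z)
            assert closed == pytest.approx(axial_rayleigh(z), rel=0.01)

    def test_nonphysical_geometry_rejected(self):
        with pytest.raises(ValueError):
            oneil_axial_oracle(0.05, 0.2, 1e6, 1482.0, 1000.0, 0.05)


class TestCalibrateAperture:
    def test_fwhm_monotone_in_aperture(self):
        f1 = acoustics._lateral_fwhm_direct(build_array(64, aperture_diameter=0.08), 1482.0)
        f2 = acoustics._lateral_fwhm_direct(build_array(64, aperture_diameter=0.12), 1482.0)
        assert f2 < f1

    def test_reproduces_target_fwhm(self):
        d = calibrate_aperture(2.0e-3, n_elements=256)
        arr = build_array(256, aperture_diameter=d)
        fwhm = acoustics._lateral_fwhm_direct(arr, 1482.0)
        assert fwhm == pytest.approx(2.0e-3, rel=0.05)

    def test_deterministic(self):
        assert calibrate_aperture(2.5e-3, n_elements=64) == \
            calibrate_aperture(2.5e-3, n_elements=64)
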