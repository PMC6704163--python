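"""Spectrum sampling, fiber coupling, A-scan reconstruction and B-scan properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octsim import (
    FiberMode,
    Polarisation,
    SpectralCoupling,
    build_spectrum,
    coupling_amplitude,
    integrated_error,
    make_cylinder_cluster,
    make_single_cylinder,
    max_visible_depth,
    reconstruct_ascan,
    run_ascan,
    run_bscan,
)
from octsim.optics import SPEED_OF_LIGHT, angular_quadrature
from octsim.scenes import PhantomSpec
from octsim.spectral import (
    _reference_alpha,
    back_propagate_to_fiber,
    detect_from_far_field,
)

C = SPEED_OF_LIGHT


class TestSpectrum:
    def test_temporal_width_matches_published_rounding(self):
        sp = build_spectrum(1300e-9, 170e-9)
        assert np.isclose(sp.b, 1.8e-14, rtol=0.025)  # 2 significant figures

    def test_peak_and_cutoff_samples(self):
        sp = build_spectrum(1300e-9, 170e-9, 1e-3, 161)  # odd N puts w0 on grid
        assert np.isclose(sp.S.max(), sp.b / np.sqrt(2), rtol=1e-12)
        assert np.isclose(sp.S[0], sp.epsilon * sp.S.max(), rtol=1e-12)
        assert np.isclose(sp.S[-1], sp.epsilon * sp.S.max(), rtol=1e-12)

    def test_sampled_range_inverts_the_gaussian(self):
        sp = build_spectrum(1300e-9, 170e-9, 1e-4, 64)
        span = sp.omega[-1] - sp.omega[0]
        assert np.isclose(span, (4 / sp.b) * np.sqrt(np.log(1 / sp.epsilon)),
                          rtol=1e-12)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            build_spectrum(1.3e-6, 170e-9, epsilon=2.0)
        with pytest.raises(ValueError):
            build_spectrum(1.3e-6, 170e-9, N=1)


class TestCoupling:
    def test_gaussian_overlap_closed_form(self, mode):
        y = np.linspace(-8 * mode.w0, 8 * mode.w0, 4001)
        val = coupling_amplitude(y, np.exp(-(y**2) / mode.w0**2), mode)
        assert abs(val - mode.w0 * np.sqrt(np.pi / 2)) / abs(val) < 1e-8

    def test_odd_field_couples_to_zero(self, mode):
        y = np.linspace(-8 * mode.w0, 8 * mode.w0, 4001)
        val = coupling_amplitude(y, y / mode.w0 * np.exp(-(y**2) / mode.w0**2),
                                 mode)
        assert abs(val) < 1e-12 * mode.w0

    def test_quadrature_converged_for_smooth_field(self, mode):
        field = lambda y: np.exp(-(y / (3 * mode.w0)) ** 2) * np.cos(
            2e5 * y) * (1 + y / (9 * mode.w0))  # noqa: E731
        coarse = np.linspace(-8 * mode.w0, 8 * mode.w0, 2001)
        fine = np.linspace(-8 * mode.w0, 8 * mode.w0, 20001)
        va = coupling_amplitude(coarse, field(coarse), mode)
        vb = coupling_amplitude(fine, field(fine), mode)
        assert abs(va - vb) / abs(vb) < 1e-8

    def test_narrow_range_warns(self, mode):
        y = np.linspace(-2 * mode.w0, 2 * mode.w0, 101)
        with pytest.warns(UserWarning):
            coupling_amplitude(y, np.ones_like(y), mode)


class TestMaxVisibleDepth:
    def test_reference_configuration(self):
        sp = build_spectrum(1300e-9, 170e-9, 1e-3, 160)
        depth = max_visible_depth(160, sp.b, 1e-3, 1.35)
        assert np.isclose(depth, 92e-6, atol=2e-6)

    def test_agrees_with_wavenumber_spacing_estimate(self):
        """Closed form tracks pi/(2 dk) within 2% at N = 160."""
        sp = build_spectrum(1300e-9, 170e-9, 1e-3, 160)
        dk = sp.delta_omega / C
        est = np.pi / (2 * dk) / 1.35
        assert abs(max_visible_depth(160, sp.b, 1e-3, 1.35) - est) / est < 0.02

    def test_monotone_in_samples(self):
        sp = build_spectrum(1300e-9, 170e-9, 1e-3, 160)
        depths = [max_visible_depth(n, sp.b, 1e-3, 1.35)
                  for n in (8, 16, 64, 160, 320)]
        assert np.all(np.diff(depths) > 0)

    def test_odd_n_rejected(self):
        with pytest.raises(ValueError):
            max_visible_depth(161, 1.8e-14, 1e-3, 1.35)


def _delay_coupling(spectrum, tau):
    ref = np.ones(spectrum.N, dtype=complex)
    return SpectralCoupling(spectrum.k, ref * np.exp(1j * spectrum.omega * tau),
                            ref)


class TestReconstruction:
    n_med = 1.35

    def test_pure_delay_peaks_at_its_depth(self):
        sp = build_spectrum(1300e-9, 170e-9, 1e-3, 160)
        x0 = 30e-6
        asc = reconstruct_ascan(_delay_coupling(sp, 2 * self.n_med * x0 / C),
                                sp, self.n_med)
        assert abs(asc.peak_depth() - x0) <= asc.depth_bin

    def test_zero_delay_mirror_case(self):
        """alpha_sca = alpha_ref: unit peak at zero depth and, outside the
        coherence envelope around it, a floor far below -60 dB with no
        mirror or autocorrelation peaks."""
        sp = build_spectrum(1300e-9, 170e-9, 1e-3, 160)
        asc = reconstruct_ascan(_delay_coupling(sp, 0.0), sp, self.n_med)
        i0 = int(np.argmax(asc.intensity))
        assert asc.depth[i0] == 0.0
        assert np.isclose(asc.intensity[i0], 1.0, rtol=1e-12)
        outside = np.ones(sp.N, dtype=bool)
        outside[max(0, i0 - 10):i0 + 11] = False
        assert np.all(asc.intensity[outside] < 1e-6)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(m=st.integers(1, 400))
    def test_alias_bin_arithmetic(self, m):
        """A delay of m time bins lands exactly at the DFT-wrapped bin."""
        sp = build_spectrum(1300e-9, 170e-9, 1e-3, 64)
        dt = 2 * np.pi / (sp.N * sp.delta_omega)
        asc = reconstruct_ascan(_delay_coupling(sp, m * dt), sp, self.n_med)
        expected_bin = ((m + sp.N // 2) % sp.N) - sp.N // 2
        got_bin = int(np.argmax(asc.intensity)) - sp.N // 2
        assert got_bin == expected_bin

    def test_target_beyond_max_depth_aliases(self):
        sp = build_spectrum(1300e-9, 170e-9, 1e-3, 64)
        ct_max = max_visible_depth(64, sp.b, 1e-3, self.n_med)
        dt = 2 * np.pi / (sp.N * sp.delta_omega)
        m = sp.N // 2 + 5  # five bins past the unambiguous edge
        asc = reconstruct_ascan(_delay_coupling(sp, m * dt), sp, self.n_med)
        x_true = m * dt * C / (2 * self.n_med)
        assert x_true > ct_max
        assert asc.peak_depth() < 0  # wrapped to the negative branch

    def test_parseval_energy_identity(self):
        sp = build_spectrum(1300e-9, 170e-9, 1e-3, 96)
        rng = np.random.default_rng(7)
        coup = SpectralCoupling(sp.k,
                                rng.normal(size=96) + 1j * rng.normal(size=96),
                                np.ones(96, complex))
        asc = reconstruct_ascan(coup, sp, self.n_med, normalization=1.0)
        weighted = sp.S**2 * coup.alpha_sca * np.conj(coup.alpha_ref)
        lhs = np.sum(np.abs(asc.complex_signal) ** 2)
        rhs = (sp.delta_omega / (2 * np.pi)) ** 2 * sp.N * np.sum(
            np.abs(weighted) ** 2)
        assert np.isclose(lhs, rhs, rtol=1e-12)

    def test_length_mismatch_rejected(self):
        sp = build_spectrum(1300e-9, 170e-9, 1e-3, 32)
        coup = _delay_coupling(build_spectrum(1300e-9, 170e-9, 1e-3, 64), 0.0)
        with pytest.raises(ValueError):
            reconstruct_ascan(coup, sp, self.n_med)


class TestIntegratedError:
    def test_identical_and_scaled_images(self):
        rng = np.random.default_rng(0)
        img = rng.random((20, 13))
        assert integrated_error(img, img) == 0.0
        assert np.isclose(integrated_error(img, 2 * img), 1.0, rtol=1e-12)

    def test_matches_direct_double_sum(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((9, 7)), rng.random((9, 7))
        num = den = 0.0
        for i in range(9):
            for j in range(7):
                num += abs(a[i, j] - b[i, j]) ** 2
                den += abs(a[i, j]) ** 2
        assert np.isclose(integrated_error(a, b), np.sqrt(num) / np.sqrt(den),
                          rtol=1e-14)

    def test_resampling_preserves_constant_images(self):
        a = np.ones((16, 16))
        b = np.ones((31, 9))
        assert integrated_error(a, b) < 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            integrated_error(np.zeros((0, 2)), np.zeros((0, 2)))


class TestDetection:
    def test_reciprocity_form_matches_explicit_back_chain(self, sysm, mode, k0):
        """The angular-weight detection functional and the full numeric
        Fresnel + Debye-Wolf back-propagation agree up to one k-dependent
        constant, independent of the angular pattern."""
        from octsim.optics import beam_angular_amplitude

        theta, wq = angular_quadrature(sysm, 201)
        w = beam_angular_amplitude(theta, k0, mode, sysm)
        patterns = [w, w * np.cos(3 * theta), w * (1 + 0.3 * np.sin(5 * theta))]
        ratios = []
        for pat in patterns:
            ratios.append(back_propagate_to_fiber(pat, theta, k0, mode, sysm)
                          / detect_from_far_field(pat, theta, wq, k0, mode, sysm))
        ratios = np.array(ratios)
        assert np.all(np.abs(ratios / ratios[0] - 1) < 0.01)
        # a laterally displaced source (linear phase tilt) stays within a few %
        tilted = w * np.exp(1j * k0 * 1.35 * np.sin(theta) * 3e-6)
        r_t = (back_propagate_to_fiber(tilted, theta, k0, mode, sysm)
               / detect_from_far_field(tilted, theta, wq, k0, mode, sysm))
        assert abs(r_t / ratios[0] - 1) < 0.05


class TestBScans:
    sp_small = build_spectrum(1300e-9, 170e-9, 1e-3, 64)

    def test_echo_distance_law_across_radii(self, sysm, mode):
        """Front/back echo separation is 2 a n_cyl/n_med within one bin."""
        sp = build_spectrum(1300e-9, 170e-9, 1e-3, 160)
        for a in (2e-6, 5e-6, 10e-6):
            scene = make_single_cylinder(a, 1.42, 1.35)
            # amplitude weighting keeps the axial resolution fine enough to
            # separate the 4.2 um echo pair of the smallest cylinder
            asc = run_ascan(scene, sysm, mode, sp, weighting="amplitude")
            idx = np.argsort(asc.intensity)[::-1]
            # two strongest local peaks
            peaks = []
            for i in idx:
                if 0 < i < len(asc.intensity) - 1 and \
                        asc.intensity[i] >= asc.intensity[i - 1] and \
                        asc.intensity[i] >= asc.intensity[i + 1]:
                    peaks.append(i)
                if len(peaks) == 2:
                    break
            sep = abs(asc.depth[peaks[0]] - asc.depth[peaks[1]])
            assert abs(sep - 2 * a * 1.42 / 1.35) <= asc.depth_bin

    def test_symmetric_scene_gives_symmetric_bscan(self, sysm, mode):
        scene = make_single_cylinder(2e-6, 1.42, 1.35)
        ys = np.linspace(-4e-6, 4e-6, 5)
        tomo = run_bscan(scene, sysm, mode, self.sp_small, y_positions=ys)
        img = tomo.image
        assert np.linalg.norm(img - img[:, ::-1]) / np.linalg.norm(img) < 1e-6

    def test_normalization_invariant_under_source_power(self, sysm):
        scene = make_single_cylinder(2e-6, 1.42, 1.35)
        t1 = run_bscan(scene, sysm, FiberMode(E0=1.0), self.sp_small)
        t2 = run_bscan(scene, sysm, FiberMode(E0=2.0), self.sp_small)
        assert np.allclose(t1.image, t2.image, rtol=1e-10)

    def test_mirror_equivalent_sample_reads_unity(self, sysm, mode):
        """Feeding the reference response through the sample channel yields a
        flat bright line of normalized intensity 1 at depth zero."""
        sp = self.sp_small
        theta, wq = angular_quadrature(sysm, 201)
        alpha_ref = np.array([_reference_alpha(theta, wq, k, mode, sysm, 1.0)
                              for k in sp.k])
        coup = SpectralCoupling(sp.k, alpha_ref, alpha_ref)
        asc = reconstruct_ascan(coup, sp, sysm.n_med)
        assert asc.depth[np.argmax(asc.intensity)] == 0.0
        assert np.isclose(asc.intensity.max(), 1.0, rtol=1e-10)

    def test_grid_solver_reproduces_analytic_ascan(self, sysm, mode):
        """End-to-end oracle: Born-series B-scan matches the series path."""
        sp = build_spectrum(1300e-9, 170e-9, 1e-3, 24)
        scene = make_single_cylinder(1e-6, 1.42, 1.35, margin=2e-6)
        a_ana = run_ascan(scene, sysm, mode, sp)
        with pytest.warns(UserWarning):
            a_grid = run_ascan(scene, sysm, mode, sp, solver="grid",
                               dx=1.3e-6 / 13, boundary_width=6e-6)
        rel = (np.linalg.norm(a_ana.intensity - a_grid.intensity)
               / np.linalg.norm(a_ana.intensity))
        assert rel < 0.05
        assert a_ana.peak_depth() == a_grid.peak_depth()

    def test_polarisation_sensitivity_of_cluster_vs_single_interface(
            self, sysm, mode):
        """Multi-cylinder phantoms separate the channels; a single cylinder
        leaves them nearly identical."""
        sp = build_spectrum(1300e-9, 170e-9, 1e-8, 40)
        spec = PhantomSpec(83, ("disc", 0.0, 0.0, 10e-6), 0.5e-6, 1.42, seed=1)
        cluster = make_cylinder_cluster(spec)
        ys = np.linspace(-12e-6, 12e-6, 7)
        img_pe = run_bscan(cluster, sysm, mode, sp,
                           Polarisation.PERPENDICULAR, ys).image
        img_pa = run_bscan(cluster, sysm, mode, sp,
                           Polarisation.PARALLEL, ys).image
        assert integrated_error(img_pe, img_pa) > 0.05
        single = make_single_cylinder(5e-6, 1.42, 1.35)
        a_pe = run_ascan(single, sysm, mode, sp, Polarisation.PERPENDICULAR)
        a_pa = run_ascan(single, sysm, mode, sp, Polarisation.PARALLEL)
        assert integrated_error(a_pe.intensity[None, :],
                                a_pa.intensity[None, :]) < 0.05
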