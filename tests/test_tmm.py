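"""Transfer-matrix engine: closed-form oracles, conservation laws, and the
GIF forward model's qualitative band structure."""

import dataclasses

import numpy as np
import pytest

from naagif.bands import locate_band_max
from naagif.errors import InvalidParameterError, StructuralError
from naagif.materials import Material, MaterialSet, default_materials
from naagif.structure import GifDesign
from naagif.tmm import (
    OpticalStack,
    bragg_wavelengths,
    compute_reflectance,
    compute_reflectance_transmittance,
    simulate_gif_spectrum,
)

WL = np.arange(400.0, 901.0, 5.0)


def uniform_stack(thicknesses, indices, n_in=1.33, n_out=1.33, wl=WL):
    idx = np.array([[n] * wl.size for n in indices], dtype=complex)
    return OpticalStack(wl, np.asarray(thicknesses, float), idx, n_in, n_out)


def airy_reflectance(n0, n1, n2, d, wl):
    """Single-film closed form: r = (r01 + r12 e^{2i beta})/(1 + r01 r12 e^{2i beta})."""
    r01 = (n0 - n1) / (n0 + n1)
    r12 = (n1 - n2) / (n1 + n2)
    beta = 2 * np.pi * n1 * d / wl
    r = (r01 + r12 * np.exp(2j * beta)) / (1 + r01 * r12 * np.exp(2j * beta))
    return np.abs(r) ** 2


class TestOracles:
    def test_zero_contrast_stack_reflects_nothing(self):
        stack = uniform_stack([100.0, 200.0], [1.33, 1.33])
        R = compute_reflectance(stack).values
        np.testing.assert_allclose(R, 0.0, atol=1e-12)

    def test_bare_interface_fresnel(self):
        stack = uniform_stack([], [], n_in=1.33, n_out=1.66)
        R = compute_reflectance(stack).values
        expected = ((1.33 - 1.66) / (1.33 + 1.66)) ** 2
        np.testing.assert_allclose(R, expected, atol=1e-12)
        assert expected == pytest.approx(0.01218, abs=5e-5)

    def test_single_film_matches_airy_formula(self):
        n0, n1, n2, d = 1.0, 2.3, 1.52, 180.0
        stack = uniform_stack([d], [n1], n_in=n0, n_out=n2)
        R = compute_reflectance(stack).values
        np.testing.assert_allclose(R, airy_reflectance(n0, n1, n2, d, WL),
                                   atol=1e-10)

    def test_single_absorbing_film_matches_airy(self):
        n0, n1, n2, d = 1.33, 1.6 + 0.02j, 1.33, 500.0
        stack = uniform_stack([d], [n1], n_in=n0, n_out=n2)
        R = compute_reflectance(stack).values
        np.testing.assert_allclose(R, airy_reflectance(n0, n1, n2, d, WL),
                                   atol=1e-10)


class TestConservationAndSymmetry:
    def test_energy_conservation_lossless(self):
        rng = np.random.default_rng(7)
        thick = rng.uniform(50, 300, size=12)
        idx = rng.uniform(1.3, 2.4, size=12)
        stack = uniform_stack(thick, idx, n_in=1.0, n_out=1.52)
        for pol in ("s", "p", "unpolarized"):
            for angle in (0.0, 8.0, 30.0):
                R, T = compute_reflectance_transmittance(stack, angle, pol)
                np.testing.assert_allclose(R + T, 1.0, atol=1e-9)

    def test_absorbing_stack_dissipates(self):
        stack = uniform_stack([300.0, 200.0], [1.6 + 0.05j, 1.5], 1.33, 1.33)
        R, T = compute_reflectance_transmittance(stack)
        assert np.all(R + T < 1.0)
        assert np.all(R >= 0) and np.all(T >= 0)

    def test_reciprocity_lossless_normal_incidence(self):
        rng = np.random.default_rng(11)
        thick = rng.uniform(40, 250, size=9)
        idx = rng.uniform(1.3, 2.2, size=9)
        stack = uniform_stack(thick, idx, n_in=1.0, n_out=1.7)
        R_fwd = compute_reflectance(stack).values
        R_bwd = compute_reflectance(stack.reversed()).values
        np.testing.assert_allclose(R_fwd, R_bwd, atol=1e-10)

    def test_s_and_p_coincide_at_normal_incidence(self):
        stack = uniform_stack([120.0, 90.0], [2.0, 1.4], 1.0, 1.52)
        Rs, _ = compute_reflectance_transmittance(stack, 0.0, "s")
        Rp, _ = compute_reflectance_transmittance(stack, 0.0, "p")
        np.testing.assert_allclose(Rs, Rp, atol=1e-12)

    def test_misaligned_grids_rejected(self):
        with pytest.raises(StructuralError):
            OpticalStack(WL, [100.0], [[1.5] * (WL.size - 1)], 1.0, 1.0)

    def test_bad_angle_rejected(self):
        stack = uniform_stack([100.0], [1.5])
        with pytest.raises(InvalidParameterError):
            compute_reflectance(stack, angle_of_incidence=90.0)


class TestGifForwardModel:
    def test_two_stopbands_near_bragg_positions(self, small_design, materials,
                                                coarse_grid):
        spectrum = simulate_gif_spectrum(small_design, materials, coarse_grid)
        lam_top, lam_bottom = bragg_wavelengths(small_design, materials)
        # one band per stack, within half a bandwidth of the Bragg condition
        sig = locate_band_max(spectrum, (lam_top - 40, lam_top + 40))
        ref = locate_band_max(spectrum, (lam_bottom - 40, lam_bottom + 40))
        assert abs(sig.peak_wavelength - lam_top) < 20
        assert abs(ref.peak_wavelength - lam_bottom) < 20
        # the two bands dominate everything else in the spectrum
        mask = np.ones(coarse_grid.size, bool)
        for lam in (lam_top, lam_bottom):
            mask &= np.abs(coarse_grid - lam) > 40
        background = spectrum.values[mask].max()
        assert sig.peak_height > 3 * background
        assert ref.peak_height > 3 * background

    def test_signal_band_decreases_faster_with_loading(self, small_design,
                                                       materials, coarse_grid):
        lam_top, lam_bottom = bragg_wavelengths(small_design, materials)
        sig_win = (lam_top - 40, lam_top + 40)
        ref_win = (lam_bottom - 40, lam_bottom + 40)
        sig, ref = [], []
        for f in (0.0, 0.025, 0.050, 0.075):
            s = simulate_gif_spectrum(small_design.with_drug_fraction(f),
                                      materials, coarse_grid)
            sig.append(locate_band_max(s, sig_win).peak_height)
            ref.append(locate_band_max(s, ref_win).peak_height)
        assert np.all(np.diff(sig) < 0), "signal band must lose height monotonically"
        # relative loss of the signal band exceeds that of the reference band
        assert sig[-1] / sig[0] < ref[-1] / ref[0]

    def test_grid_refinement_convergence(self, materials, coarse_grid):
        """Richardson check: halving the discretization step converges the
        band maximum at second order, and the doubled-resolution result is
        within 1% of converged.

        (Staircasing a sinusoid into m steps scales its fundamental
        Fourier amplitude by sinc(pi/m), so the 8-layer default carries a
        ~2% coupling deficit that halves-squared on refinement.)
        """
        base = GifDesign(n_periods_top=25, n_periods_bottom=25,
                         layers_per_period=8)
        lam_top, _ = bragg_wavelengths(base, materials)
        win = (lam_top - 40, lam_top + 40)
        heights = {}
        for m in (8, 16, 32):
            design = dataclasses.replace(base, layers_per_period=m)
            heights[m] = locate_band_max(
                simulate_gif_spectrum(design, materials, coarse_grid), win
            ).peak_height
        step1 = abs(heights[16] - heights[8])
        step2 = abs(heights[32] - heights[16])
        assert step2 < step1 / 2          # at least first-order contraction
        assert step1 / heights[16] < 0.03  # 8 layers already adequate
        assert step2 / heights[32] < 0.01  # 16 layers converged to < 1%

    def test_wetting_redshift_positive(self, small_design, materials, coarse_grid):
        wet = simulate_gif_spectrum(small_design, materials, coarse_grid)
        dry = simulate_gif_spectrum(small_design.with_medium_index(1.0),
                                    materials, coarse_grid)
        lam_top, _ = bragg_wavelengths(small_design, materials)
        win = (lam_top - 60, lam_top + 40)
        shift = (locate_band_max(wet, win).peak_wavelength
                 - locate_band_max(dry, win).peak_wavelength)
        assert shift > 0

    def test_medium_material_overrides_design_index(self, small_design,
                                                    coarse_grid):
        base = default_materials()
        with_medium = MaterialSet(host=base.host, drug=base.drug,
                                  medium=Material.constant(1.33))
        a = simulate_gif_spectrum(small_design, base, coarse_grid)
        b = simulate_gif_spectrum(small_design, with_medium, coarse_grid)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)
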