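import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from destreak.filtering import moving_average_row
from destreak.metrics import (
    central_vertical_band_energy,
    fwhm,
    line_profile,
    mtf_curves,
    mtf_image,
    nps_image,
    ssd,
)
from destreak.phantoms import make_phantom


class TestSSD:
    def test_identical_images_give_zero(self, random_image):
        assert ssd(random_image, random_image) == 0.0

    def test_doubled_image_gives_half(self, random_image):
        assert ssd(random_image.values, 2.0 * random_image.values) == pytest.approx(0.5, rel=1e-12)

    def test_hand_computed_two_by_two(self):
        a = np.array([[1.0, 0.0], [0.0, 1.0]])
        b = np.array([[0.0, 1.0], [1.0, 0.0]])
        # numerator 4, denominator sqrt(2)*sqrt(2) = 2
        assert ssd(a, b) == pytest.approx(2.0)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        arrays(np.float64, (8, 8), elements=st.floats(-5, 5)),
        arrays(np.float64, (8, 8), elements=st.floats(-5, 5)),
    )
    def test_symmetry(self, a, b):
        if np.all(a == 0) or np.all(b == 0):
            return
        assert ssd(a, b) == pytest.approx(ssd(b, a), rel=1e-12, abs=1e-15)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ssd(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            ssd(np.zeros((4, 4)), np.zeros((4, 4)))


class TestNPS:
    def test_identical_images_give_constant_zero(self, random_image):
        assert np.all(nps_image(random_image, random_image) == 0.0)

    def test_impulse_difference_gives_flat_spectrum(self):
        a = np.zeros((16, 16))
        b = a.copy()
        b[5, 9] = 1.0
        np.testing.assert_allclose(nps_image(a, b), 1.0, atol=1e-12)

    def test_matches_bruteforce_dft(self, rng):
        a = rng.random((16, 16))
        b = rng.random((16, 16))
        nps = nps_image(a, b)
        d = a - b
        n = 16
        brute = np.empty((n, n))
        for u in range(n):
            for v in range(n):
                s = 0.0j
                for i in range(n):
                    for j in range(n):
                        s += d[i, j] * np.exp(-2j * np.pi * (u * i + v * j) / n)
                brute[u, v] = abs(s)
        np.testing.assert_allclose(nps, np.fft.fftshift(brute), atol=1e-8)

    def test_vertical_band_energy_counts_central_columns(self):
        nps = np.zeros((16, 16))
        nps[:, 8] = 2.0  # central column (fx = 0)
        nps[:, 0] = 9.0  # far column, outside the band
        assert central_vertical_band_energy(nps, half_width=3) == pytest.approx(16 * 4.0)


class TestMTF:
    def test_identity_when_output_equals_input(self, random_image):
        np.testing.assert_allclose(mtf_image(random_image, random_image), 1.0)

    def test_zero_output_bounded_by_one(self, random_image):
        out = mtf_image(random_image, np.zeros((64, 64)))
        assert np.all(out <= 1.0) and np.all(out > 0.0)

    def test_box_blur_cross_section_tracks_dirichlet_magnitude(self):
        # blur along rows with the 13-tap box; the fy=0 cross-section of the
        # MTF follows |sin(pi f k)/(k sin(pi f))| where the input spectrum
        # dominates epsilon
        n, k = 128, 13
        phantom = make_phantom("torso", n).values
        blurred = np.array([moving_average_row(r, k) for r in phantom])
        mtf = mtf_image(phantom, blurred)
        input_mag = np.abs(np.fft.fftshift(np.fft.fft2(phantom)))
        row = n // 2  # fy = 0
        f = (np.arange(n) - n // 2) / n
        with np.errstate(divide="ignore", invalid="ignore"):
            dirichlet = np.abs(np.sin(np.pi * f * k) / (k * np.sin(np.pi * f)))
        dirichlet[n // 2] = 1.0
        strong = input_mag[row] > 100 * 0.1
        assert strong.sum() > 10
        np.testing.assert_allclose(mtf[row, strong], dirichlet[strong], atol=0.05)

    def test_curves_of_constant_image_are_one(self):
        curves = mtf_curves(np.ones((64, 64)))
        for c in (curves.curve_0deg, curves.curve_45deg, curves.curve_90deg):
            np.testing.assert_allclose(c, 1.0, atol=1e-12)

    def test_curves_agree_for_radially_symmetric_mtf(self):
        n = 128
        fy, fx = np.mgrid[-n // 2 : n // 2, -n // 2 : n // 2]
        mtf = np.exp(-(np.hypot(fx, fy) ** 2) / (2 * 20.0**2))
        curves = mtf_curves(mtf)
        np.testing.assert_allclose(curves.curve_0deg, curves.curve_45deg, rtol=0.01, atol=0.01)
        np.testing.assert_allclose(curves.curve_0deg, curves.curve_90deg, rtol=0.01, atol=0.01)

    def test_horizontal_blur_dips_only_the_0deg_curve(self):
        # a separable box blur along rows: the 90-degree wedge (frequencies
        # along fy) stays near 1, the 0-degree wedge follows the box response
        n, k = 128, 13
        rng = np.random.default_rng(4)
        base = rng.random((n, n))
        blurred = np.array([moving_average_row(r, k) for r in base])
        eps = 1e-6  # tiny epsilon: the ratio is the pure transfer magnitude
        curves = mtf_curves(mtf_image(base, blurred, epsilon=eps))
        # closed-form oracle: wedge-average of the separable transfer |D(f cos a)|
        radii = np.arange(n // 2)
        angles = np.radians(np.arange(-16.0, 17.0))

        def dirichlet(f):
            out = np.ones_like(f)
            nz = f != 0
            out[nz] = np.abs(np.sin(np.pi * f[nz] * k) / (k * np.sin(np.pi * f[nz])))
            return out

        fx_0 = np.abs(radii[None, :] * np.cos(angles)[:, None]) / n
        fx_90 = np.abs(radii[None, :] * np.cos(angles + np.pi / 2)[:, None]) / n
        oracle_0 = dirichlet(fx_0).mean(axis=0)
        oracle_90 = dirichlet(fx_90).mean(axis=0)
        sel = radii < int(0.7 * n / k)  # below the first transfer null
        np.testing.assert_allclose(curves.curve_0deg[sel], oracle_0[sel], atol=0.05)
        np.testing.assert_allclose(curves.curve_90deg[sel], oracle_90[sel], atol=0.05)
        # the blur acts along rows: the 0-degree wedge reads the blurred axis
        mid = (radii > 4) & sel
        assert np.all(curves.curve_90deg[mid] > curves.curve_0deg[mid] + 0.05)

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            mtf_curves(np.ones((16, 16)))


class TestLineProfileAndFWHM:
    def test_constant_image_profile(self):
        img = np.full((32, 32), 3.0)
        np.testing.assert_array_equal(line_profile(img, 10, 4, 20), np.full(16, 3.0))

    def test_disk_profile_has_plateau_between_zeros(self):
        img = make_phantom("disk", 64)
        profile = line_profile(img, 32, 0, 64)
        assert profile[0] == 0.0 and profile[-1] == 0.0
        assert profile[32] == 1.0

    def test_matches_direct_indexing(self, random_image):
        np.testing.assert_array_equal(
            line_profile(random_image, 7, 3, 50), random_image.values[7, 3:50]
        )

    def test_out_of_bounds_rejected(self):
        img = np.zeros((32, 32))
        with pytest.raises(IndexError):
            line_profile(img, 40, 0, 10)
        with pytest.raises(IndexError):
            line_profile(img, 5, 10, 40)

    def test_gaussian_fwhm_closed_form(self):
        x = np.arange(61, dtype=float)
        profile = np.exp(-((x - 30.0) ** 2) / (2 * 3.0**2))
        assert fwhm(profile) == pytest.approx(2 * np.sqrt(2 * np.log(2)) * 3.0, abs=0.1)

    def test_rectangle_fwhm_is_its_width(self):
        profile = np.zeros(50)
        profile[20:28] = 1.0
        profile[23] += 1e-9  # unique maximum
        assert fwhm(profile) == pytest.approx(8.0, abs=1.0)

    def test_triangle_fwhm_is_half_the_base(self):
        base = 24
        profile = np.concatenate([np.linspace(0, 1, base // 2 + 1), np.linspace(1, 0, base // 2 + 1)[1:]])
        assert fwhm(profile) == pytest.approx(base / 2.0, abs=0.1)

    def test_affine_invariance(self):
        x = np.arange(41, dtype=float)
        profile = np.exp(-((x - 20.0) ** 2) / (2 * 2.5**2))
        assert fwhm(5.0 * profile + 3.0) == pytest.approx(fwhm(profile), abs=1e-9)

    def test_degenerate_profiles_rejected(self):
        with pytest.raises(ValueError):
            fwhm(np.ones(10))
        with pytest.raises(ValueError):
            fwhm(np.array([0.0, 1.0, 1.0, 0.0]))
        with pytest.raises(ValueError):
            fwhm(np.array([2.0, 1.0, 0.0, 0.5]))
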