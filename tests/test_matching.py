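import numpy as np
import pytest
from scipy import ndimage
from scipy.special import erf

from cherimatch.calibrate import PixelScale
from cherimatch.matching import (
    DEFAULT_MATCH_ROI,
    FlatProfileError,
    IntensityProfile,
    MatchingConfig,
    RectROI,
    compose_reference,
    compose_shifted,
    difference_image,
    extract_profile,
    measure_matching,
    profile_fwhm,
)
from cherimatch.simulate import SIGMA_EDGE_MM, simulate_condition
from cherimatch.specs import AcquisitionSpec, FieldImage, ShiftSpec

from conftest import simulate_shifted


def img(arr, scale=1.0, **meta):
    return FieldImage(np.asarray(arr, dtype=float), scale, dict(meta))


class TestCompose:
    def test_additive_identity(self, rng):
        a = img(rng.uniform(0, 100, (6, 6)))
        zero = img(np.zeros((6, 6)))
        out = compose_reference(a, zero)
        np.testing.assert_array_equal(out.pixels, a.pixels)

    def test_disjoint_fields_union_preserves_max(self):
        a = np.zeros((4, 8)); a[:, :4] = 200.0
        b = np.zeros((4, 8)); b[:, 4:] = 150.0
        out = compose_reference(img(a), img(b))
        assert out.pixels.max() == 200.0
        assert (out.pixels > 0).all()

    def test_8bit_clipping_flagged(self):
        a = img(np.full((3, 3), 200.0))
        b = img(np.full((3, 3), 200.0))
        out = compose_reference(a, b, max_value=255.0)
        np.testing.assert_array_equal(out.pixels, 255.0)
        assert out.metadata["clip_fraction"] == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes differ"):
            compose_reference(img(np.zeros((3, 3))), img(np.zeros((3, 4))))

    def test_zero_shift_composite_equals_reference(self, noiseless_pair):
        sp, se = noiseless_pair
        from cherimatch.preprocess import preprocess_stack

        p, e = preprocess_stack(sp), preprocess_stack(se)
        ref = compose_reference(p, e)
        shifted = compose_shifted(p, e, shifted_field="photon")
        np.testing.assert_array_equal(ref.pixels, shifted.pixels)
        assert shifted.metadata["shifted_field"] == "photon"

    def test_difference_support_localised_to_moved_edges(self, noiseless_pair, photon_beam, yellow):
        """Shifting only the photon field changes the composite near the
        junction band and the far photon edge; everywhere else the
        difference vanishes."""
        from cherimatch.preprocess import preprocess_stack

        sp, se = noiseless_pair
        p, e = preprocess_stack(sp), preprocess_stack(se)
        shifted_stack = simulate_shifted(photon_beam, yellow, 10.0, "inferior", seed=3)
        ps = preprocess_stack(shifted_stack)
        diff = difference_image(
            compose_shifted(ps, e, shifted_field="photon"), compose_reference(p, e)
        )
        x = diff.x_mm()
        # junction band [0, 10] mm and far edge band [-50, -40] mm, +- penumbra
        moved = ((x > -54.0) & (x < -36.0)) | ((x > -4.0) & (x < 14.0))
        untouched = diff.pixels[:, ~moved]
        assert untouched.max() < 1e-4 * diff.pixels.max()


class TestDifferenceImage:
    def test_identical_inputs_zero(self, rng):
        a = img(rng.uniform(0, 50, (5, 5)))
        np.testing.assert_array_equal(difference_image(a, a).pixels, 0.0)

    def test_sharp_step_shift_band_width_equals_shift(self):
        n = 100
        ref = np.zeros((10, n)); ref[:, :50] = 1000.0
        for k in (3, 7):
            sh = np.zeros((10, n)); sh[:, :50 + k] = 1000.0
            d = difference_image(img(sh), img(ref))
            band = (d.pixels[0] > 0).sum()
            assert band == k

    @pytest.mark.parametrize("k_px", [3.0, 6.0, 9.0, 15.0, 36.0])
    def test_erf_band_fwhm_matches_numerical_oracle(self, k_px):
        """The FWHM of the difference of two erf edges separated by k px must
        match a 1-D numerical convolution oracle; for k >= 4 sigma it is
        within 1 px of k itself."""
        sigma_px = SIGMA_EDGE_MM["photon"] * 3.6
        n = 200
        x = np.arange(n, dtype=float)
        edge = lambda c: 0.5 * (1 + erf((x - c) / (sigma_px * np.sqrt(2))))

        band = np.abs(edge(80.0 + k_px) - edge(80.0)) * 1000.0
        width, _, _ = profile_fwhm(IntensityProfile(x, band))

        # oracle: box of width k convolved with a unit Gaussian, on a fine grid
        sub = 20
        xf = np.arange(n * sub) / sub
        box = ((xf >= 80.0) & (xf < 80.0 + k_px)).astype(float)
        smooth = ndimage.gaussian_filter1d(box, sigma_px * sub)
        half = smooth.max() / 2
        above = np.flatnonzero(smooth >= half)
        oracle = (above[-1] - above[0] + 1) / sub

        assert width == pytest.approx(oracle, abs=0.15)
        if k_px >= 4 * sigma_px:
            assert width == pytest.approx(k_px, abs=1.0)


class TestExtractProfile:
    def test_constant_image(self):
        image = img(np.full((40, 60), 3.0), scale=1.0)
        roi = RectROI.centered(0, 0, 20, 10)
        profile = extract_profile(image, roi)
        np.testing.assert_array_equal(profile.values, 3.0)
        assert len(profile.values) == 20

    def test_single_bright_column_fraction(self):
        arr = np.zeros((40, 60))
        arr[18:22, 30] = 1.0  # 4 bright rows at column 30
        roi = RectROI.centered(0, 0, 20, 10)  # rows 15..25 (10 rows)
        profile = extract_profile(img(arr), roi)
        peak_col = int(profile.positions_px[np.argmax(profile.values)])
        assert peak_col == 30
        assert profile.values.max() == pytest.approx(4 / 10)

    def test_matches_brute_force_double_loop(self, rng):
        arr = rng.uniform(0, 100, (30, 40))
        image = img(arr, scale=2.0)
        roi = RectROI(-5.0, -4.0, 9.0, 7.0)
        profile = extract_profile(image, roi)
        rows, cols = roi.to_pixel_bounds(image)
        expected = []
        for j in range(cols.start, cols.stop):
            acc = 0.0
            for i in range(rows.start, rows.stop):
                acc += arr[i, j]
            expected.append(acc / (rows.stop - rows.start))
        np.testing.assert_allclose(profile.values, expected)

    def test_out_of_bounds_roi_suggests_clipping(self):
        image = img(np.zeros((20, 20)), scale=1.0)
        with pytest.raises(ValueError, match="nearest valid bounds"):
            extract_profile(image, RectROI.centered(0, 0, 60, 10))


class TestProfileFWHM:
    def test_rectangular_pulse(self):
        v = np.zeros(120); v[40:76] = 100.0  # 36 samples wide
        width, peak, half = profile_fwhm(IntensityProfile(np.arange(120.0), v))
        assert width == pytest.approx(36.0, abs=1e-9)
        assert peak == 100.0
        # 36 px at 3.6 px/mm is the 10 mm worked example
        assert width / 3.6 == pytest.approx(10.0)

    def test_triangular_pulse_half_base(self):
        x = np.arange(41.0)
        v = np.maximum(0.0, 10.0 - np.abs(x - 20.0))  # base width 20
        width, _, _ = profile_fwhm(IntensityProfile(x, v))
        assert width == pytest.approx(10.0, abs=1e-9)

    def test_flat_profile_rejected(self):
        with pytest.raises(FlatProfileError):
            profile_fwhm(IntensityProfile(np.arange(10.0), np.full(10, 5.0)))

    def test_noisy_erf_bands_match_threshold_count_oracle(self):
        """Against a brute-force oracle that counts samples at or above the
        half level, interpolated widths agree within 1 px over 100 noisy
        band profiles."""
        rng = np.random.default_rng(42)
        sigma, k, n = 2.5, 18.0, 120
        x = np.arange(n, dtype=float)
        edge = lambda c: 0.5 * (1 + erf((x - c) / (sigma * np.sqrt(2))))
        clean = np.abs(edge(50.0 + k) - edge(50.0)) * 1000.0
        for _ in range(100):
            noisy = clean + rng.normal(0, 15.0, n)
            profile = IntensityProfile(x, noisy)
            width, _, half = profile_fwhm(profile)
            count = int((noisy >= half).sum())
            assert width == pytest.approx(count, abs=1.0)


class TestMeasureMatching:
    def test_noiseless_electron_shift_recovered(self, noiseless_pair, electron_beam, yellow):
        sp, se = noiseless_pair
        sh = simulate_shifted(electron_beam, yellow, 5.0, "superior", seed=2)
        r = measure_matching(sp, se, electron_stack_shifted=sh)
        assert r.detectable
        assert r.measured_matching_mm == pytest.approx(5.0, abs=0.3)
        assert r.introduced_shift_mm == -5.0

    def test_noiseless_zero_shift_null(self, noiseless_pair):
        sp, se = noiseless_pair
        r = measure_matching(sp, se)
        assert r.measured_matching_mm == 0.0
        assert r.discrepancy_mm == 0.0

    def test_direction_symmetry_noiseless(self, noiseless_pair, photon_beam, yellow):
        sp, se = noiseless_pair
        measured = {}
        for d in ("superior", "inferior"):
            sh = simulate_shifted(photon_beam, yellow, 5.0, d, seed=4)
            measured[d] = measure_matching(sp, se, photon_stack_shifted=sh).measured_matching_mm
        assert measured["superior"] == pytest.approx(measured["inferior"], abs=1e-9)

    def test_monotone_in_shift_magnitude_noiseless(self, noiseless_pair, photon_beam, yellow):
        sp, se = noiseless_pair
        values = []
        for mag in (0.0, 2.0, 5.0, 10.0):
            sh = simulate_shifted(photon_beam, yellow, mag, "inferior", seed=5)
            values.append(measure_matching(sp, se, photon_stack_shifted=sh).measured_matching_mm)
        assert values == sorted(values)

    def test_black_tissue_not_detectable(self, photon_beam, electron_beam, black):
        """Dark tissue absorbs the visible Cherenkov emission: even a 10 mm
        shift leaves no band above the noise, so matching is unmonitorable."""
        acq_p = AcquisitionSpec.default_for(photon_beam, black)
        acq_e = AcquisitionSpec.default_for(electron_beam, black)
        sp = simulate_condition(photon_beam, black, acq_p, None, 10)
        se = simulate_condition(electron_beam, black, acq_e, None, 11)
        sh = simulate_condition(photon_beam, black, acq_p,
                                ShiftSpec(10.0, "inferior", "photon"), 12)
        r = measure_matching(sp, se, photon_stack_shifted=sh)
        assert not r.detectable
        assert r.measured_matching_mm is None
        assert r.discrepancy_mm is None

    def test_yellow_tissue_detectable_at_default_noise(self, photon_beam, electron_beam, yellow):
        acq_p = AcquisitionSpec.default_for(photon_beam, yellow)
        acq_e = AcquisitionSpec.default_for(electron_beam, yellow)
        sp = simulate_condition(photon_beam, yellow, acq_p, None, 10)
        se = simulate_condition(electron_beam, yellow, acq_e, None, 11)
        sh = simulate_condition(photon_beam, yellow, acq_p,
                                ShiftSpec(10.0, "inferior", "photon"), 12)
        r = measure_matching(sp, se, photon_stack_shifted=sh)
        assert r.detectable
        assert r.snr > 2.0

    def test_systematic_offset_correction(self, noiseless_pair, photon_beam, yellow):
        sp, se = noiseless_pair
        sh = simulate_shifted(photon_beam, yellow, 5.0, "inferior", seed=6)
        plain = measure_matching(sp, se, photon_stack_shifted=sh)
        corrected = measure_matching(
            sp, se, photon_stack_shifted=sh,
            config=MatchingConfig(apply_offset_correction=True),
        )
        assert corrected.measured_matching_mm == pytest.approx(
            plain.measured_matching_mm - 0.55
        )

    def test_both_shifted_stacks_rejected(self, noiseless_pair):
        sp, se = noiseless_pair
        with pytest.raises(ValueError, match="at most one"):
            measure_matching(sp, se, photon_stack_shifted=sp, electron_stack_shifted=se)

    def test_explicit_scale_used_for_conversion(self, noiseless_pair, photon_beam, yellow):
        sp, se = noiseless_pair
        sh = simulate_shifted(photon_beam, yellow, 5.0, "inferior", seed=8)
        r = measure_matching(sp, se, photon_stack_shifted=sh,
                             scale=PixelScale(px_per_mm=3.6))
        assert r.measured_matching_mm == pytest.approx(5.0, abs=0.3)
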