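"""NOAC normalization, filtering, directional differences and NAD maps."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

import octnad as on
from octnad.nad import DegenerateNormalizationError
from octnad.oac import OACMap
from octnad.octio import ValidationError


def oac_map_from(values):
    return OACMap(value=np.asarray(values, float), depth_um=0.0, window_px=40)


FULL_ROI = on.EnfaceROI(x0=0, x1=7, y0=0, y1=7)


class TestNormalize:
    def test_midpoint_maps_to_half(self):
        v = np.full((4, 4), 3.0)
        v[0, 0], v[0, 1] = 2.0, 4.0
        out = on.normalize_map(oac_map_from(v), on.EnfaceROI(x0=0, x1=1, y0=0, y1=1))
        assert out.value[2, 2] == pytest.approx(0.5)
        assert (out.min_roi, out.max_roi) == (2.0, 4.0)

    def test_roi_endpoints_map_to_zero_and_one(self):
        rng = np.random.default_rng(0)
        v = rng.random((8, 8))
        out = on.normalize_map(oac_map_from(v), FULL_ROI)
        assert out.value.min() == 0.0
        assert out.value.max() == 1.0

    def test_constant_roi_is_degenerate(self):
        with pytest.raises(DegenerateNormalizationError):
            on.normalize_map(oac_map_from(np.ones((8, 8))), FULL_ROI)

    def test_masked_roi_is_degenerate(self):
        v = np.full((8, 8), np.nan)
        with pytest.raises(DegenerateNormalizationError):
            on.normalize_map(oac_map_from(v), FULL_ROI)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        v=hnp.arrays(np.float64, (8, 8), elements=st.floats(-5, 5)),
        a=st.floats(0.1, 10),
        b=st.floats(-3, 3),
    )
    def test_invariant_under_affine_rescaling(self, v, a, b):
        roi = on.EnfaceROI(x0=1, x1=5, y0=2, y1=6)
        base = v[roi.slices()]
        if base.max() - base.min() < 1e-6:
            return
        out1 = on.normalize_map(oac_map_from(v), roi)
        out2 = on.normalize_map(oac_map_from(a * v + b), roi)
        np.testing.assert_allclose(out1.value, out2.value, atol=1e-9)

    def test_roi_range_held_at_every_depth_of_tumor_stack(
        self, glioma_flat, tumor_roi
    ):
        spec, flat, truth = glioma_flat
        sx, sy = tumor_roi.slices()
        for d in (405.0, 450.0, 495.0):
            noac = on.normalize_map(
                on.enface_oac_map(flat, d), tumor_roi
            )
            roi_vals = noac.value[sx, sy]
            assert np.nanmin(roi_vals) == 0.0
            assert np.nanmax(roi_vals) == 1.0
            assert noac.max_roi > noac.min_roi


def noac_from(values):
    return on.NOACMap(value=np.asarray(values, float), depth_um=0.0,
                      roi=FULL_ROI, min_roi=0.0, max_roi=1.0)


class TestLowpass:
    def test_sigma_zero_is_identity(self):
        rng = np.random.default_rng(1)
        m = noac_from(rng.random((9, 9)))
        np.testing.assert_array_equal(on.lowpass_filter(m, 0.0).value, m.value)

    def test_constant_map_unchanged(self):
        m = noac_from(np.full((9, 9), 0.7))
        np.testing.assert_allclose(on.lowpass_filter(m, 3.0).value, 0.7)

    def test_impulse_response_is_gaussian_kernel(self):
        n, sigma = 33, 2.0
        imp = np.zeros((n, n))
        imp[n // 2, n // 2] = 1.0
        out = on.lowpass_filter(noac_from(imp), sigma).value
        r = int(4 * sigma + 0.5)
        k = np.exp(-np.arange(-r, r + 1) ** 2 / (2 * sigma**2))
        k /= k.sum()
        expected = np.outer(k, k)
        got = out[n // 2 - r : n // 2 + r + 1, n // 2 - r : n // 2 + r + 1]
        np.testing.assert_allclose(got, expected, atol=1e-6)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)

    def test_masked_pixels_stay_masked_and_excluded(self):
        m = np.full((9, 9), 2.0)
        m[4, 4] = np.nan
        out = on.lowpass_filter(noac_from(m), 1.5).value
        assert np.isnan(out[4, 4])
        # normalized convolution: remaining constant field is preserved
        np.testing.assert_allclose(out[~np.isnan(out)], 2.0, atol=1e-12)


class TestDifferencesAndNAD:
    def test_constant_map_all_zero(self):
        dx, dy = on.directional_differences(noac_from(np.full((6, 5), 0.3)))
        assert not dx.any() and not dy.any()
        assert dx.shape == dy.shape == (5, 4)

    def test_linear_ramp(self):
        i = np.arange(7)[:, None] * np.ones(6)[None, :]
        dx, dy = on.directional_differences(noac_from(0.25 * i))
        np.testing.assert_allclose(dx, 0.25)
        np.testing.assert_allclose(dy, 0.0)

    def test_column_step(self):
        v = np.zeros((6, 6))
        v[3:, :] = 1.5
        dx, dy = on.directional_differences(noac_from(v))
        np.testing.assert_allclose(dx[2], 1.5)
        assert np.count_nonzero(dx) == dx.shape[1]
        assert not dy.any()

    def test_difference_touching_mask_is_masked(self):
        v = np.ones((4, 4))
        v[1, 1] = np.nan
        dx, dy = on.directional_differences(noac_from(v))
        assert np.isnan(dx[0, 1]) and np.isnan(dx[1, 1])
        assert np.isnan(dy[1, 0]) and np.isnan(dy[1, 1])

    def test_too_small_map_rejected(self):
        with pytest.raises(ValidationError):
            on.directional_differences(noac_from(np.ones((1, 5))))

    def test_pythagorean_combination(self):
        m = on.nad_map(np.full((2, 2), 3.0), np.full((2, 2), 4.0))
        np.testing.assert_allclose(m.value, 5.0)
        np.testing.assert_allclose(on.nad_map(np.zeros((2, 2)), np.zeros((2, 2))).value, 0.0)
        np.testing.assert_allclose(
            on.nad_map(np.full((2, 2), 0.7), np.zeros((2, 2))).value, 0.7
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            on.nad_map(np.zeros((2, 3)), np.zeros((3, 2)))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(v=hnp.arrays(
        np.float64, (6, 6),
        # hundredths grid: keeps squares well above the underflow threshold,
        # where the zero-iff-flat equivalence genuinely holds
        elements=st.integers(-200, 200).map(lambda k: k / 100.0),
    ))
    def test_nad_nonnegative_and_zero_iff_flat(self, v):
        dx, dy = on.directional_differences(noac_from(v))
        nadm = on.nad_map(dx, dy)
        assert np.all(nadm.value >= 0)
        zero = nadm.value == 0
        np.testing.assert_array_equal(zero, (dx == 0) & (dy == 0))


def brute_force_nad(oac, roi):
    """Per-pixel reimplementation of the normalization, the two directional
    differences and their RMS, with explicit loops."""
    sx, sy = roi.slices()
    lo = oac[sx, sy].min()
    hi = oac[sx, sy].max()
    nx, ny = oac.shape
    noac = np.empty_like(oac)
    for i in range(nx):
        for j in range(ny):
            noac[i, j] = (oac[i, j] - lo) / (hi - lo)
    out = np.empty((nx - 1, ny - 1))
    for i in range(nx - 1):
        for j in range(ny - 1):
            dxv = noac[i + 1, j] - noac[i, j]
            dyv = noac[i, j + 1] - noac[i, j]
            out[i, j] = np.sqrt(dxv * dxv + dyv * dyv)
    return out


class TestOracleEquivalence:
    def test_pipeline_matches_brute_force_bitwise(self):
        rng = np.random.default_rng(2024)
        roi = on.EnfaceROI(x0=2, x1=5, y0=2, y1=5)
        for _ in range(100):
            v = rng.random((8, 8)) * 4.0
            noac = on.normalize_map(oac_map_from(v), roi)
            dx, dy = on.directional_differences(noac)
            got = on.nad_map(dx, dy).value
            expected = brute_force_nad(v, roi)
            np.testing.assert_array_equal(got, expected)


class TestNadVolume:
    def test_homogeneous_speckled_nad_is_flat(self, homogeneous_speckled):
        spec, vol, truth = homogeneous_speckled
        flat = on.flatten(vol, on.detect_surface(vol))
        roi = on.EnfaceROI(x0=30, x1=60, y0=30, y1=60)
        # the fixture's surface sits at 375 µm, so only shallow windows fit
        stack = on.nad_volume(flat, roi, [0.0, 50.0, 100.0])
        for m in stack.maps:
            v = m.value[np.isfinite(m.value)]
            # no boundary: after normalization to the ROI's speckle range
            # and smoothing, neighbour differences are a small fraction of it
            assert np.median(v) < 0.05
            assert np.quantile(v, 0.99) < 0.2

    def test_depth_axis_strictly_increasing_and_provenance(
        self, glioma_flat, tumor_roi
    ):
        spec, flat, truth = glioma_flat
        stack = on.nad_volume(flat, tumor_roi, [405.0, 450.0, 495.0])
        assert np.all(np.diff(stack.depths_um) > 0)
        assert len(stack.roi_minmax) == 3
        assert all(hi > lo for lo, hi in stack.roi_minmax)
        assert stack.as_array().shape == (3, 95, 95)
        assert len(stack.config_hash) == 16

    def test_default_depth_list_covers_shallow_depths(self, homogeneous_speckled):
        spec, vol, truth = homogeneous_speckled
        flat = on.flatten(vol, on.detect_surface(vol))
        roi = on.EnfaceROI(x0=30, x1=60, y0=30, y1=60)
        stack = on.nad_volume(flat, roi)
        assert stack.depths_um[0] == 0.0
        assert len(stack.maps) > 10
        # default list stops where the fit window loses half its coverage
        assert stack.depths_um[-1] <= (flat.nz - 40) * flat.dz

    def test_unordered_depths_rejected(self, glioma_flat, tumor_roi):
        spec, flat, truth = glioma_flat
        with pytest.raises(ValidationError):
            on.nad_volume(flat, tumor_roi, [450.0, 405.0])


class TestBoundaryExtraction:
    def test_zero_map_gives_empty_mask(self):
        m = on.NADMap(value=np.zeros((8, 8)), depth_um=0.0)
        with pytest.warns(UserWarning):
            mask = on.extract_boundary(m, method="threshold", level=0.9)
        assert not mask.any()

    def test_ideal_ring_thresholds_to_ring(self):
        v = np.zeros((21, 21))
        ii, jj = np.meshgrid(np.arange(21), np.arange(21), indexing="ij")
        ring = np.abs(np.sqrt((ii - 10.0) ** 2 + (jj - 10.0) ** 2) - 6.0) < 0.6
        v[ring] = 1.0
        m = on.NADMap(value=v, depth_um=0.0)
        mask = on.extract_boundary(m, method="threshold", level=0.9)
        np.testing.assert_array_equal(mask, ring)

    def test_ridge_recovers_circle_radius(self):
        # synthetic circular NAD ridge of known radius
        n, r0 = 41, 9.0
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        r = np.sqrt((ii - 20.0) ** 2 + (jj - 20.0) ** 2)
        m = on.NADMap(value=np.exp(-((r - r0) ** 2) / 2.0), depth_um=0.0)
        radii, _ = on.ridge_radii(m, (20.5, 20.5))
        assert np.nanmean(np.abs(radii - r0)) <= 0.5
        mask = on.extract_boundary(m, method="ridge", seed_px=(20.5, 20.5))
        assert mask.any()
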