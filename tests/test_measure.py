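"""Cross-section resampling, 2-D lumen segmentation and extremes."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stenoquant import (
    ImageVolume,
    ThresholdSet,
    ared,
    dred,
    measure_mask,
    resample_plane,
    segment_cross_section,
    summarize_segment,
)
from stenoquant.measure import CrossSection, SegmentProfile


def disc_image(radius_mm=2.0, step=0.1, size_mm=8.0, value=300.0, background=60.0):
    n = int(round(size_mm / step)) + 1
    c = (n - 1) / 2 * step
    yy, xx = np.meshgrid(np.arange(n) * step, np.arange(n) * step, indexing="ij")
    img = np.full((n, n), background)
    img[np.hypot(yy - c, xx - c) <= radius_mm] = value
    return img


@pytest.fixture
def band():
    return ThresholdSet(300.0, 60.0, 140.0, 320.0)


class TestResamplePlane:
    def test_uniform_region_gives_constant_plane(self):
        vol = ImageVolume(np.full((20, 20, 20), 42.0), spacing=(1, 1, 1))
        img = resample_plane(vol, (10.0, 10.0, 10.0), (0.3, 0.6, 0.74), fov_mm=6, step_mm=0.2)
        np.testing.assert_allclose(img, 42.0)

    def test_axis_aligned_tube_yields_disc(self):
        zz, yy, xx = np.meshgrid(*[np.arange(s) * 0.5 for s in (40, 40, 40)], indexing="ij")
        vals = np.where(np.hypot(zz - 10, yy - 10) <= 3.0, 300.0, 60.0)
        vol = ImageVolume(vals, spacing=(0.5, 0.5, 0.5))
        img = resample_plane(vol, (10.0, 10.0, 10.0), (0.0, 0.0, 1.0), fov_mm=10, step_mm=0.1)
        c = (img.shape[0] - 1) / 2 * 0.1
        yy2, xx2 = np.meshgrid(np.arange(img.shape[0]) * 0.1, np.arange(img.shape[1]) * 0.1, indexing="ij")
        r = np.hypot(yy2 - c, xx2 - c)
        assert img[r < 2.5].min() > 250.0
        assert img[r > 3.6].max() < 110.0

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        vol = ImageVolume(rng.uniform(0, 100, (15, 15, 15)), spacing=(1, 0.7, 0.7))
        args = (vol, (7.0, 5.0, 5.0), (0.2, 0.5, 0.84))
        np.testing.assert_array_equal(resample_plane(*args), resample_plane(*args))

    def test_degenerate_tangent_rejected(self):
        vol = ImageVolume(np.zeros((5, 5, 5)), spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="tangent"):
            resample_plane(vol, (2.0, 2.0, 2.0), (0.0, 0.0, 0.0))


class TestCrossSectionSegmentation:
    def test_clean_disc_recovered(self, band):
        img = disc_image(radius_mm=2.0, step=0.1)
        mask = segment_cross_section(img, band, step_mm=0.1)
        truth = img >= 300.0
        dice = 2 * np.sum(mask & truth) / (mask.sum() + truth.sum())
        assert dice >= 0.98

    def test_noise_holes_closed(self, band):
        rng = np.random.default_rng(1)
        img = disc_image(radius_mm=2.0, step=0.1)
        holes = rng.choice(np.flatnonzero(img == 300.0), size=15, replace=False)
        img.ravel()[holes] = 80.0  # single-pixel dropouts inside the lumen
        mask = segment_cross_section(img, band, curvature_scale=10, step_mm=0.1)
        from scipy.ndimage import binary_fill_holes

        assert np.array_equal(mask, binary_fill_holes(mask))  # no holes survive
        assert mask.sum() >= (disc_image() >= 300).sum() * 0.95

    def test_plaque_crescent_excluded(self, band):
        img = disc_image(radius_mm=2.0, step=0.1)
        n = img.shape[0]
        c = (n - 1) / 2 * 0.1
        yy, xx = np.meshgrid(np.arange(n) * 0.1, np.arange(n) * 0.1, indexing="ij")
        r = np.hypot(yy - c, xx - c)
        crescent = (r > 1.4) & (r <= 2.0) & (xx - c > 0.5)
        img[crescent] = 800.0  # calcification brighter than UT
        mask = segment_cross_section(img, band, step_mm=0.1)
        assert not np.any(mask & crescent)
        assert mask[int(c / 0.1), int(c / 0.1)]

    def test_seed_out_of_band_gives_empty_mask(self, band):
        img = np.full((41, 41), 60.0)
        mask = segment_cross_section(img, band, step_mm=0.1)
        assert mask.sum() == 0


class TestMeasureMask:
    def test_digital_disc(self):
        mask = disc_image(radius_mm=2.0, step=0.1) >= 300.0
        area, diameter = measure_mask(mask, 0.1)
        assert area == pytest.approx(np.pi * 4.0, rel=0.02)
        assert diameter == pytest.approx(4.0, abs=0.1)

    def test_ellipse_shortest_is_minor_axis(self):
        step = 0.05
        yy, xx = np.meshgrid(np.arange(241) * step, np.arange(241) * step, indexing="ij")
        mask = ((yy - 6) / 1.5) ** 2 + ((xx - 6) / 3.0) ** 2 <= 1.0
        area, diameter = measure_mask(mask, step)
        assert area == pytest.approx(np.pi * 3.0 * 1.5, rel=0.02)
        assert diameter == pytest.approx(3.0, abs=0.1)

    def test_single_pixel(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 4] = True
        area, diameter = measure_mask(mask, 0.2)
        assert area == pytest.approx(0.04)
        assert diameter == pytest.approx(0.2)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            measure_mask(np.zeros((5, 5), dtype=bool), 0.1)

    def test_rotation_invariance_of_min_feret(self):
        from scipy.ndimage import rotate

        mask = np.zeros((121, 121), dtype=bool)
        mask[40:80, 30:90] = True  # 8 mm x 12 mm rectangle at 0.2 mm pixels
        _, d0 = measure_mask(mask, 0.2)
        rot = rotate(mask.astype(float), 30, reshape=True, order=0) > 0.5
        _, d30 = measure_mask(rot, 0.2)
        assert d30 == pytest.approx(d0, abs=0.25)


class TestReductions:
    @pytest.mark.parametrize("mn,mx,expected", [(2.5, 5.0, 50.0), (3.0, 3.0, 0.0)])
    def test_dred_examples(self, mn, mx, expected):
        assert dred(mn, mx) == pytest.approx(expected)

    def test_circular_consistency(self):
        # Dred 50 % on a circular lumen implies Ared 75 %
        min_a, max_a = np.pi * 1.25**2, np.pi * 2.5**2
        assert ared(min_a, max_a) == pytest.approx(75.0)

    def test_noise_inversion_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamp"):
            assert dred(5.1, 5.0) == 0.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            dred(1.0, 0.0)
        with pytest.raises(ValueError):
            ared(1.0, 0.0)


def profile_from_arrays(arcs, diameters, areas, eligible, valid=None):
    valid = [True] * len(arcs) if valid is None else valid
    sections = [
        CrossSection(a, ar if v else None, d if v else None, e)
        for a, d, ar, e, v in zip(arcs, diameters, areas, eligible, valid)
    ]
    return SegmentProfile(1, 1, sections, step_mm=float(arcs[1] - arcs[0]) if len(arcs) > 1 else 1.0)


class TestSummarizeSegment:
    def test_constant_profile_zero_reduction(self):
        p = profile_from_arrays(
            np.arange(0, 31.0), [4.0] * 31, [12.0] * 31, [s >= 10 for s in range(31)]
        )
        s = summarize_segment(p)
        assert s.dred_pct == 0.0 and s.ared_pct == 0.0
        assert not s.fallback_used

    def test_direct_substitution(self):
        p = profile_from_arrays(
            [0.0, 10.0, 20.0], [5.0, 5.0, 2.5], [19.6, 19.6, 4.9], [False, True, True]
        )
        s = summarize_segment(p)
        assert s.min_d_mm == 2.5 and s.max_d_mm == 5.0
        assert s.dred_pct == pytest.approx(50.0)

    def test_global_max_near_bifurcation_ignored(self):
        """The global maximum 3 mm from the bifurcation is ineligible; the
        reported MaxD is the largest among eligible stations."""
        arcs = np.arange(0.0, 21.0)
        diam = np.full(21, 4.0)
        diam[18] = 6.0  # 3 mm before the bifurcation at 21 mm -> ineligible
        diam[12] = 5.0  # eligible maximum
        eligible = [(10.0 <= s <= 16.0) for s in arcs]
        s = summarize_segment(profile_from_arrays(arcs, diam, np.pi * (diam / 2) ** 2, eligible))
        assert s.max_d_mm == 5.0

    def test_fallback_when_nothing_eligible(self):
        p = profile_from_arrays([0.0, 1.0, 2.0], [4.0, 3.0, 5.0], [12, 7, 19], [False] * 3)
        s = summarize_segment(p)
        assert s.fallback_used
        assert s.max_d_mm == 5.0

    def test_all_invalid_marks_non_measurable(self):
        p = profile_from_arrays([0.0, 1.0], [0, 0], [0, 0], [True, True], valid=[False, False])
        s = summarize_segment(p)
        assert not s.measurable

    @given(data=st.data())
    def test_matches_bruteforce_over_eligible_set(self, data):
        """Property: summarize_segment equals an explicit scan over the
        flagged index set on random profiles."""
        n = data.draw(st.integers(min_value=1, max_value=25))
        diam = data.draw(
            st.lists(st.floats(0.5, 8.0), min_size=n, max_size=n)
        )
        areas = data.draw(st.lists(st.floats(0.3, 40.0), min_size=n, max_size=n))
        eligible = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        p = profile_from_arrays(np.arange(n, dtype=float), diam, areas, eligible)
        s = summarize_segment(p)
        assert s.min_d_mm == min(diam)
        assert s.min_a_mm2 == min(areas)
        idx = [i for i in range(n) if eligible[i]]
        if idx:
            assert s.max_d_mm == max(max(diam[i] for i in idx), min(diam))
            assert s.max_a_mm2 == max(max(areas[i] for i in idx), min(areas))
            assert not s.fallback_used
        else:
            assert s.fallback_used
            assert s.max_d_mm == max(diam)


class TestProfileSegment:
    def test_station_count_and_eligibility_rules(self, recovery_runs):
        """A ~36 mm segment at 0.5 mm steps: stations inside 10 mm of the
        aorta are flagged ineligible, the rest eligible (no bifurcation)."""
        run = recovery_runs[("CTA", 50.0)]
        profile = run["profiles"][0]
        arcs = profile.arc_lengths
        assert len(arcs) == int(np.floor((arcs[-1] - arcs[0]) / 0.5)) + 1
        for c in profile.cross_sections:
            assert c.eligible_for_max == (c.arc_length >= 10.0)

    def test_halving_step_never_increases_min_diameter(self, recovery_runs):
        from stenoquant import profile_segment

        run = recovery_runs[("CTA", 50.0)]
        seg = run["segments"][0]
        vol = ImageVolume.load(run["out_dir"] + "/volume.nii.gz")
        coarse = summarize_segment(profile_segment(vol, seg, run["thresholds"], step_mm=2.0))
        fine = summarize_segment(profile_segment(vol, seg, run["thresholds"], step_mm=1.0))
        assert fine.min_d_mm <= coarse.min_d_mm + 1e-9
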