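"""Measurement protocol: projection, dip rule, distances, areas, triage."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.draw import disk

from karyodot.measure import (
    ChromosomeBlob,
    Configuration,
    LineProfile,
    UnclassifiableProfileError,
    classify_configuration,
    classify_dot_out,
    compute_3d_distance,
    estimate_background,
    max_intensity_projection,
    measure_area,
    proportion_out,
    segment_blobs,
    xy_distance,
    z_offset_sections,
)
from karyodot.stack import ConfocalStack
from karyodot.synthetic import SimulationParams, generate_oocyte_stack


def brute_force_dip_out(samples, background, dip_threshold=0.5, min_peak_fraction=0.1):
    """Independent O(n^2) scan of the dip rule over every interior sample."""
    bgsub = [s - background for s in samples]
    floor = min_peak_fraction * max(bgsub)
    any_valid = False
    decided = False
    for v in range(1, len(samples) - 1):
        left = max(bgsub[:v])
        right = max(bgsub[v + 1 :])
        if left > 0 and right > 0 and left >= floor and right >= floor:
            any_valid = True
            if bgsub[v] <= (1.0 - dip_threshold) * min(left, right):
                decided = True
    if not any_valid:
        raise UnclassifiableProfileError("no two detectable peaks")
    return decided


def make_profile(samples, background):
    return LineProfile(np.asarray(samples, float), (0, 0), (0, len(samples)), background)


class TestProjection:
    def test_single_section_is_identity(self, rng):
        data = rng.random((1, 8, 9))
        stack = ConfocalStack(data)
        np.testing.assert_array_equal(max_intensity_projection(stack), data[0])

    def test_zero_section_does_not_contribute(self, rng):
        plane = rng.random((8, 9))
        stack = ConfocalStack(np.stack([np.zeros_like(plane), plane]))
        np.testing.assert_array_equal(max_intensity_projection(stack), plane)

    def test_projection_dominates_every_voxel(self, rng):
        data = rng.random((6, 10, 12))
        proj = max_intensity_projection(ConfocalStack(data))
        for s in range(6):  # brute force over all voxels
            assert (proj >= data[s]).all()


class TestBackground:
    def test_constant_input_returns_that_constant(self):
        assert estimate_background(np.full((20, 20), 37.0)) == 37.0

    def test_flat_tails_with_bright_interior(self):
        profile = np.concatenate([np.full(10, 20.0), np.full(80, 200.0), np.full(10, 20.0)])
        assert estimate_background(profile) == 20.0

    def test_all_zero_input(self):
        assert estimate_background(np.zeros(50)) == 0.0


class TestDipClassifier:
    def test_worked_example_37_percent_remaining_is_out(self):
        # bg 20; dot peak 180; adjacent peak 220; valley 80:
        # bg-subtracted valley 60 vs reference 160 -> 37.5% remaining -> out.
        p = make_profile([180, 120, 80, 150, 220], background=20)
        assert classify_dot_out(p) is True

    def test_no_dip_is_not_out(self):
        p = make_profile([180, 180, 180, 180, 180], background=20)
        assert classify_dot_out(p) is False

    def test_full_dip_to_background_is_out(self):
        p = make_profile([180, 20, 220], background=20)
        assert classify_dot_out(p) is True

    def test_exactly_fifty_percent_dip_counts_as_out(self):
        # reference peak bg-sub 160; valley bg-sub exactly 80.
        p = make_profile([180, 100, 220], background=20)
        assert classify_dot_out(p) is True

    def test_just_above_fifty_percent_is_not_out(self):
        p = make_profile([180, 101, 220], background=20)
        assert classify_dot_out(p) is False

    def test_single_peak_profile_is_unclassifiable(self):
        p = make_profile([200, 100, 30, 20, 20], background=20)
        with pytest.raises(UnclassifiableProfileError):
            classify_dot_out(p)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        samples=st.lists(st.integers(0, 255), min_size=3, max_size=50),
        bg_frac=st.floats(0.0, 1.0),
    )
    def test_matches_brute_force_scan(self, samples, bg_frac):
        background = bg_frac * max(samples)
        p = make_profile(samples, background)
        try:
            expected = brute_force_dip_out(samples, background)
        except UnclassifiableProfileError:
            with pytest.raises(UnclassifiableProfileError):
                classify_dot_out(p)
            return
        assert classify_dot_out(p) == expected

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        peak_a=st.integers(60, 255),
        peak_b=st.integers(60, 255),
        valley=st.integers(0, 255),
        drop=st.integers(1, 50),
    )
    def test_lowering_the_valley_never_flips_out_to_not_out(
        self, peak_a, peak_b, valley, drop
    ):
        bg = 10
        valley = min(valley, min(peak_a, peak_b))
        before = classify_dot_out(make_profile([peak_a, bg + valley, peak_b], bg))
        after = classify_dot_out(
            make_profile([peak_a, max(0, bg + valley - drop), peak_b], bg)
        )
        if before:
            assert after

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        peak_a=st.integers(100, 255),
        peak_b=st.integers(100, 255),
        valley=st.integers(20, 99),
        bump=st.integers(1, 15),
    )
    def test_raising_background_never_flips_out_to_not_out(
        self, peak_a, peak_b, valley, bump
    ):
        samples = [peak_a, valley, peak_b]
        before = classify_dot_out(make_profile(samples, background=0))
        after = classify_dot_out(make_profile(samples, background=bump))
        if before:
            assert after


class TestSegmentation:
    @staticmethod
    def draw(shape, disks, value=200.0, bg=10.0):
        img = np.full(shape, bg)
        for center, radius in disks:
            rr, cc = disk(center, radius, shape=shape)
            img[rr, cc] = value
        return img

    def test_single_disk_centroid_and_count(self):
        img = self.draw((100, 100), [((40, 60), 9)])
        blobs = segment_blobs(img)
        assert len(blobs) == 1
        assert blobs[0].centroid[0] == pytest.approx(40, abs=0.5)
        assert blobs[0].centroid[1] == pytest.approx(60, abs=0.5)

    def test_blank_image_gives_empty_list(self):
        assert segment_blobs(np.zeros((50, 50))) == []

    def test_two_disks_recover_drawn_areas(self):
        img = self.draw((120, 120), [((30, 30), 12), ((80, 80), 5)])
        n_big = disk((30, 30), 12, shape=img.shape)[0].size
        n_small = disk((80, 80), 5, shape=img.shape)[0].size
        blobs = segment_blobs(img)
        assert len(blobs) == 2
        assert blobs[0].area_px == pytest.approx(n_big, rel=0.10)
        assert blobs[1].area_px == pytest.approx(n_small, rel=0.10)
        assert blobs[1].is_dot  # ~25/144 of largest < 25% -> dot candidate

    def test_dot_candidate_rule_uses_area_fraction(self):
        img = self.draw((200, 200), [((50, 50), 20), ((150, 150), 12)])
        big, small = segment_blobs(img)
        # 12^2/20^2 = 36% of the largest: not a dot candidate
        assert not small.is_dot


def blob_from_pixels(pixels, shape=(200, 200), px=0.054):
    img = np.zeros(shape)
    pixels = np.asarray(pixels)
    img[pixels[:, 0], pixels[:, 1]] = 1.0
    return ChromosomeBlob.from_pixels(pixels, img, px)


class TestXYDistance:
    def test_two_single_pixels_outer_edge_convention(self):
        a = blob_from_pixels([[50, 10]])
        b = blob_from_pixels([[50, 110]])
        # 100 px between centers + one pixel per side = 102 px.
        assert xy_distance(a, b, 0.054) == pytest.approx(102 * 0.054)

    def test_identical_blob_returns_zero_with_warning(self):
        a = blob_from_pixels([[10, 10], [10, 11]])
        with pytest.warns(UserWarning, match="overlap"):
            assert xy_distance(a, a, 0.054) == 0.0

    def test_drawn_disks_match_construction(self):
        shape = (120, 160)
        r1, r2 = 6, 8
        c1, c2 = (60, 30), (60, 120)
        img = np.zeros(shape)
        blobs = []
        for c, r in [(c1, r1), (c2, r2)]:
            rr, cc = disk(c, r, shape=shape)
            blobs.append(ChromosomeBlob.from_pixels(np.column_stack([rr, cc]), img, 0.054))
        # outer pixel edge to outer pixel edge along the centroid line
        expected_px = (c2[1] - c1[1]) + r1 + r2 + 1
        measured_px = xy_distance(blobs[0], blobs[1], 1.0)
        assert measured_px == pytest.approx(expected_px, abs=1.0)

    def test_symmetric_in_blob_order(self):
        a = blob_from_pixels([[50, 10], [51, 10]])
        b = blob_from_pixels([[50, 110], [49, 111]])
        assert xy_distance(a, b, 0.054) == pytest.approx(xy_distance(b, a, 0.054))


class TestZOffset:
    @staticmethod
    def stack_with_bright_sections(sa, sb, n_sections=24):
        data = np.zeros((n_sections, 40, 40))
        pix_a = [[10, 10], [10, 11]]
        pix_b = [[30, 30], [30, 31]]
        for r, c in pix_a:
            data[sa, r, c] = 100
        for r, c in pix_b:
            data[sb, r, c] = 100
        stack = ConfocalStack(data)
        img = data.max(axis=0)
        a = ChromosomeBlob.from_pixels(np.array(pix_a), img, 0.054)
        b = ChromosomeBlob.from_pixels(np.array(pix_b), img, 0.054)
        return stack, a, b

    def test_sections_ten_and_eighteen_give_eight(self):
        stack, a, b = self.stack_with_bright_sections(10, 18)
        assert z_offset_sections(stack, a, b) == 8

    def test_same_section_gives_zero(self):
        stack, a, b = self.stack_with_bright_sections(12, 12)
        assert z_offset_sections(stack, a, b) == 0

    def test_generator_truth_z_two_microns_gives_four_sections(self):
        params = SimulationParams(
            shape=(20, 192, 192),
            true_separation_3d=6.0,
            z_offset_sections=4,
            section_thickness_z=0.5,
            seed=1,
        )
        stack, truth = generate_oocyte_stack(params)
        assert truth.z_um == pytest.approx(2.0)
        from karyodot.measure import measure_oocyte

        m = measure_oocyte(stack)
        assert m.z_sections == 4


class TestDistanceFormula:
    def test_three_four_five_triangle(self):
        assert compute_3d_distance(3.0, 8, 0.5) == pytest.approx(5.0)

    def test_zero_z_returns_d(self):
        assert compute_3d_distance(4.2, 0, 0.7) == pytest.approx(4.2)

    def test_direct_formula(self):
        assert compute_3d_distance(6.0, 5, 0.4) == pytest.approx(math.sqrt(40.0))

    @pytest.mark.parametrize(
        "d, k, dz", [(-1.0, 2, 0.5), (3.0, -1, 0.5), (3.0, 2, 0.0)]
    )
    def test_invalid_inputs_rejected(self, d, k, dz):
        with pytest.raises(ValueError):
            compute_3d_distance(d, k, dz)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        d=st.floats(0, 50),
        k=st.integers(0, 40),
        dz=st.floats(0.1, 2.0),
    )
    def test_distance_dominates_both_components(self, d, k, dz):
        dist = compute_3d_distance(d, k, dz)
        assert dist >= max(d, k * dz) - 1e-12
        assert dist <= d + k * dz + 1e-12


class TestArea:
    def test_single_pixel_at_standard_zoom(self):
        blob = blob_from_pixels([[5, 5]])
        assert measure_area(blob, 0.054) == pytest.approx(0.054**2)

    def test_drawn_disk_radius_ten(self):
        img = np.full((64, 64), 10.0)
        rr, cc = disk((32, 32), 10, shape=img.shape)
        img[rr, cc] = 200.0
        (blob,) = segment_blobs(img, pixel_size_xy=0.054)
        assert measure_area(blob, 0.054) == pytest.approx(
            math.pi * 100 * 0.054**2, rel=0.10
        )

    def test_doubling_pixel_size_quadruples_area(self):
        blob = blob_from_pixels([[1, 1], [1, 2], [2, 1]])
        assert measure_area(blob, 0.108) == pytest.approx(4 * measure_area(blob, 0.054))


class TestConfigurationTriage:
    @staticmethod
    def dots_at(rows):
        return [blob_from_pixels([[r, 50]]) for r in rows]

    def test_opposite_sides_both_out(self):
        dots = self.dots_at([20, 80])
        cfg = classify_configuration(dots, [True, True], mass_centroid=(50, 50))
        assert cfg is Configuration.BOTH_OUT
        assert cfg.distance_eligible and cfg.counts_as_out

    def test_same_side_excluded_but_counts_as_out(self):
        dots = self.dots_at([20, 30])
        cfg = classify_configuration(dots, [True, True], mass_centroid=(50, 50))
        assert cfg is Configuration.BOTH_SAME_SIDE
        assert not cfg.distance_eligible
        assert cfg.counts_as_out

    def test_no_out_flags(self):
        dots = self.dots_at([45, 55])
        cfg = classify_configuration(dots, [False, False], mass_centroid=(50, 50))
        assert cfg is Configuration.NONE_OUT
        assert not cfg.counts_as_out

    def test_extra_nonexchange_chromosome(self):
        dots = self.dots_at([20, 80, 30])
        cfg = classify_configuration(dots, [True, True, True], mass_centroid=(50, 50))
        assert cfg is Configuration.EXTRA_NONEXCHANGE
        assert not cfg.distance_eligible

    def test_lone_out_dot_without_partner_is_abnormal(self):
        dots = self.dots_at([20])
        cfg = classify_configuration(dots, [True], mass_centroid=(50, 50))
        assert cfg is Configuration.ABNORMAL

    def test_one_out_with_locatable_partner(self):
        dots = self.dots_at([20, 52])
        cfg = classify_configuration(dots, [True, False], mass_centroid=(50, 50))
        assert cfg is Configuration.ONE_OUT_OTHER_LOCATABLE
        assert cfg.distance_eligible


class TestProportionOut:
    def test_melanogaster_counts(self):
        assert proportion_out(71, 147) == pytest.approx(0.483, abs=5e-4)
        assert round(proportion_out(71, 147), 2) == 0.48

    def test_willistoni_counts(self):
        assert proportion_out(14, 115) == pytest.approx(0.122, abs=5e-4)
        assert round(100 * proportion_out(14, 115)) == 12

    def test_zero_numerator(self):
        assert proportion_out(0, 99) == 0.0

    def test_complement_identity(self):
        n_out, n_total = 37, 160
        assert proportion_out(n_out, n_total) == pytest.approx(
            1 - proportion_out(n_total - n_out, n_total)
        )

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            proportion_out(0, 0)

    def test_out_count_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            proportion_out(10, 5)
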