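"""Bone masking, contour closing with chord bridging, area and volume."""

import math
from dataclasses import replace

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from orbitovol import (
    NoEnclosingBoneError,
    PartialMeasurementError,
    ProtocolConfig,
    SegmentationError,
    Slice2D,
    UnclosableContourError,
    ValidationError,
    bone_mask,
    close_boundary,
    estimate_volume,
    fill_and_measure,
    generate_phantom,
    measure_orbit,
)
from orbitovol.imaging import extract_coronal_slice
from orbitovol.measure import volume_bone_threshold
from orbitovol.phantom import LABEL_BONE, label_volume

PIX = 0.3  # mm
PIXEL_AREA = PIX * PIX


def annulus_mask(n=200, r_in_mm=18.0, thick_mm=3.0, gap_deg=None, gap_width_mm=0.0):
    """Synthetic bone ring; optional angular sector cut through the wall."""
    c = n // 2
    i, j = np.mgrid[0:n, 0:n].astype(float)
    r = np.hypot(i - c, j - c) * PIX
    mask = (r >= r_in_mm) & (r <= r_in_mm + thick_mm)
    if gap_deg is not None:
        theta = np.arctan2(j - c, i - c)
        half_ang = (gap_width_mm / 2.0) / r_in_mm
        dtheta = np.angle(np.exp(1j * (theta - math.radians(gap_deg))))
        mask &= ~(np.abs(dtheta) <= half_ang)
    return mask, (c, c)


class TestBoneMask:
    def test_noiseless_slice_reproduces_label_plane(self, small_spec):
        spec0 = replace(small_spec, noise_sd=0.0)
        vol, _ = generate_phantom(spec0)
        labels, _, origin = label_volume(spec0)
        s = extract_coronal_slice(vol, -9.6)
        j = int(round((s.plane_position - origin[1]) / 0.3))
        assert np.array_equal(bone_mask(s, 650.0), labels[:, j, :] == LABEL_BONE)

    def test_auto_threshold_on_noisy_slice_matches_labels(
        self, default_phantom, default_labels
    ):
        vol, _ = default_phantom
        labels, _, origin = default_labels
        thr = volume_bone_threshold(vol)
        s = extract_coronal_slice(vol, -9.6)
        j = int(round((s.plane_position - origin[1]) / 0.3))
        agreement = (bone_mask(s, thr) == (labels[:, j, :] == LABEL_BONE)).mean()
        assert agreement >= 0.99

    def test_auto_on_constant_slice_raises(self):
        s = Slice2D(np.full((10, 10), 7.0), (PIX, PIX), 0.0)
        with pytest.raises(SegmentationError, match="histogram"):
            bone_mask(s, "auto")


class TestCloseBoundary:
    def test_complete_ring_needs_no_bridging(self):
        mask, seed = annulus_mask()
        contour, bridges, region = close_boundary(mask, seed, 10.0, (PIX, PIX))
        assert bridges == []
        area = region.sum() * PIXEL_AREA
        assert area == pytest.approx(math.pi * 18.0**2, rel=0.01)

    def test_four_mm_gap_bridged_by_single_matching_chord(self):
        mask0, seed = annulus_mask()
        mask1, _ = annulus_mask(gap_deg=40.0, gap_width_mm=4.0)
        _, b0, r0 = close_boundary(mask0, seed, 10.0, (PIX, PIX))
        _, b1, r1 = close_boundary(mask1, seed, 10.0, (PIX, PIX))
        assert len(b1) == 1
        # oracle: brute-force nearest bone-pixel pair across the opening
        i, j = np.argwhere(mask1).T
        theta = np.degrees(np.arctan2(j - seed[1], i - seed[0]))
        r = np.hypot(i - seed[0], j - seed[1]) * PIX
        near = r < 18.0 + 2 * PIX  # inner-boundary pixels only
        a_side = np.c_[i, j][near & (theta < 40.0) & (theta > 20.0)]
        b_side = np.c_[i, j][near & (theta > 40.0) & (theta < 60.0)]
        d = np.hypot(*(a_side[:, None, :] - b_side[None, :, :]).transpose(2, 0, 1))
        shortest = d.min() * PIX
        assert b1[0].length_mm == pytest.approx(shortest, abs=1e-9)
        # and the digital opening spans about the nominal 4 mm gap width
        assert 4.0 - 0.45 <= shortest <= 4.0 + 2 * 0.45
        a0, a1 = r0.sum() * PIXEL_AREA, r1.sum() * PIXEL_AREA
        assert abs(a1 - a0) / a0 < 0.005

    def test_gap_exceeding_limit_is_unclosable_and_reports_size(self):
        mask, seed = annulus_mask(gap_deg=-90.0, gap_width_mm=15.0)
        with pytest.raises(UnclosableContourError, match="exceeds") as exc:
            close_boundary(mask, seed, 10.0, (PIX, PIX))
        assert exc.value.gap_mm == pytest.approx(15.0, abs=1.0)

    def test_no_bone_anywhere_raises(self):
        with pytest.raises(NoEnclosingBoneError):
            close_boundary(np.zeros((50, 50), bool), (25, 25), 10.0, (PIX, PIX))

    def test_seed_on_bone_raises(self):
        mask, _ = annulus_mask()
        on_ring = (100 + int(19.5 / PIX), 100)
        with pytest.raises(SegmentationError, match="bone"):
            close_boundary(mask, on_ring, 10.0, (PIX, PIX))

    def test_contour_is_closed_and_contains_seed(self):
        mask, seed = annulus_mask(gap_deg=120.0, gap_width_mm=5.0)
        contour, _, _ = close_boundary(mask, seed, 10.0, (PIX, PIX))
        assert np.allclose(contour[0], contour[-1])
        assert Polygon(contour).contains(Point(seed))


class TestFillAndMeasure:
    def test_disc_area_matches_brute_force_polygon_oracle(self):
        # 10 mm radius disc as a fine polygon on a 0.3 mm pixel grid
        r_px = 10.0 / PIX
        ang = np.linspace(0, 2 * np.pi, 721)
        contour = np.column_stack(
            [50 + r_px * np.cos(ang), 50 + r_px * np.sin(ang)]
        )
        filled, area = fill_and_measure(contour, (PIX, PIX), shape=(101, 101))
        assert area == pytest.approx(math.pi * 100.0, rel=0.01)
        # oracle: count pixel centers covered by the polygon (boundary incl.)
        poly = Polygon(contour)
        count = sum(
            poly.covers(Point(i, j)) for i in range(101) for j in range(101)
        )
        assert filled.sum() == count
        assert area == count * PIXEL_AREA

    def test_area_is_exactly_pixel_count_times_pixel_area(self):
        contour = np.array([[2, 2], [2, 8], [8, 8], [8, 2], [2, 2]], float)
        filled, area = fill_and_measure(contour, (PIX, PIX), shape=(12, 12))
        assert area == filled.sum() * PIXEL_AREA
        assert filled.sum() == 7 * 7  # centers inside-or-on a 6x6 px square

    def test_single_pixel_region(self):
        contour = np.array(
            [[5.5, 5.0], [5.0, 5.5], [4.5, 5.0], [5.0, 4.5], [5.5, 5.0]]
        )
        _, area = fill_and_measure(contour, (PIX, PIX), shape=(10, 10))
        assert area == pytest.approx(PIXEL_AREA)

    def test_open_contour_rejected(self):
        contour = np.array([[0, 0], [0, 5], [5, 5]], float)
        with pytest.raises(ValidationError, match="closed"):
            fill_and_measure(contour, (PIX, PIX))


class TestMeasureOrbit:
    def test_slice_areas_track_analytic_cone_areas(self, measured_pair, default_phantom):
        _, gt = default_phantom
        for side, m in measured_pair.items():
            for s in m.slices:
                expect = gt.area(side, -s.plane_position)
                assert s.area_mm2 == pytest.approx(expect, rel=0.02)

    def test_area_equals_mask_count_exactly(self, measured_pair):
        for m in measured_pair.values():
            for s in m.slices:
                assert s.area_mm2 == s.filled_mask.sum() * PIXEL_AREA

    def test_areas_strictly_decrease_toward_apex(self, measured_pair):
        for m in measured_pair.values():
            areas = m.areas_mm2
            assert all(a > b for a, b in zip(areas, areas[1:]))

    def test_bridged_segments_within_gap_limit(self, measured_pair):
        for m in measured_pair.values():
            for s in m.slices:
                for b in s.bridged_segments:
                    assert b.length_mm <= 10.0

    def test_volume_is_cavalieri_sum(self, measured_pair):
        for m in measured_pair.values():
            assert m.volume_mm3 == pytest.approx(4.8 * sum(m.areas_mm2), abs=1e-9)

    def test_noiseless_symmetric_phantom_measures_equal_sides(self, small_spec):
        vol, _ = generate_phantom(replace(small_spec, noise_sd=0.0))
        ml = measure_orbit(vol, "left", (-16.0, 0.0, 0.0))
        mr = measure_orbit(vol, "right", (16.0, 0.0, 0.0))
        assert ml.areas_mm2 == mr.areas_mm2

    def test_gaps_change_areas_by_under_one_percent(self, small_spec):
        from orbitovol import GapSpec

        gapped = replace(
            small_spec,
            right=replace(
                small_spec.right,
                gaps=(
                    GapSpec(5.0, 18.0, -60.0, 3.0),
                    GapSpec(6.0, 18.0, 70.0, 2.0),
                ),
            ),
        )
        m0 = measure_orbit(generate_phantom(small_spec)[0], "right", (16.0, 0, 0))
        m1 = measure_orbit(generate_phantom(gapped)[0], "right", (16.0, 0, 0))
        for a0, a1 in zip(m0.areas_mm2, m1.areas_mm2):
            assert abs(a1 - a0) / a0 < 0.01

    def test_scale_law_under_similarity(self, measured_pair, shrunk_phantom):
        _, vol, _ = shrunk_phantom
        s = 0.9
        cfg = ProtocolConfig(interval_mm=4.8 * s)
        m_small = measure_orbit(vol, "left", (-25.0 * 1.0, 0.0, 0.0), cfg)
        m_ref = measured_pair["left"]
        assert m_small.areas_mm2[0] == pytest.approx(s**2 * m_ref.areas_mm2[0], rel=0.02)
        assert m_small.volume_mm3 == pytest.approx(s**3 * m_ref.volume_mm3, rel=0.05)

    def test_slices_beyond_apex_raise_partial_result(self, small_phantom):
        vol, _ = small_phantom
        cfg = ProtocolConfig(n_slices=9)
        with pytest.raises(PartialMeasurementError) as exc:
            measure_orbit(vol, "right", (16.0, 0.0, 0.0), cfg)
        assert len(exc.value.completed) >= 5
        assert exc.value.slice_index == len(exc.value.completed) + 1

    def test_seed_outside_volume_rejected(self, small_phantom):
        vol, _ = small_phantom
        with pytest.raises(ValidationError, match="seed"):
            measure_orbit(vol, "right", (500.0, 0.0, 0.0))


class TestEstimateVolume:
    def test_arithmetic(self):
        assert estimate_volume([100, 80, 60, 40, 20], 4.8) == pytest.approx(1440.0)

    def test_single_area(self):
        assert estimate_volume([123.0], 4.8) == pytest.approx(4.8 * 123.0)

    def test_all_zero(self):
        assert estimate_volume([0, 0, 0], 4.8) == 0.0

    def test_negative_area_rejected(self):
        with pytest.raises(ValidationError):
            estimate_volume([10, -1], 4.8)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            estimate_volume([], 4.8)
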