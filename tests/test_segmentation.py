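"""Offset partitioning: oracle equivalence, exactness, monotonicity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thyrovasc import segmentation
from thyrovasc.segmentation import (
    boundary_mask,
    partition_regions,
    partition_to_labels,
    region_areas,
)

from conftest import disk_mask


def oracle_central_mask(roi: np.ndarray, offset_fraction: float) -> np.ndarray:
    """Exhaustive per-pixel distance to the nearest boundary pixel.

    The boundary is the set of ROI pixels 4-adjacent to background (frame
    edges count as background). Independent of the EDT-based code path.
    """
    h, w = roi.shape
    boundary = []
    for r in range(h):
        for c in range(w):
            if not roi[r, c]:
                continue
            neighbours = [
                roi[r - 1, c] if r > 0 else False,
                roi[r + 1, c] if r < h - 1 else False,
                roi[r, c - 1] if c > 0 else False,
                roi[r, c + 1] if c < w - 1 else False,
            ]
            if not all(neighbours):
                boundary.append((r, c))
    boundary = np.array(boundary)
    rows, cols = np.nonzero(roi)
    d = np.zeros(roi.shape)
    for r, c in zip(rows, cols):
        d[r, c] = np.sqrt(((boundary - (r, c)) ** 2).sum(axis=1).min())
    d_max = d[roi].max()
    return roi & (d >= offset_fraction * d_max)


@pytest.mark.parametrize("fraction", [0.1, 0.22, 0.5, 0.9])
@pytest.mark.parametrize("roi_fixture", ["circle_roi_small", "two_lobe_roi"])
def test_distance_partition_matches_exhaustive_oracle(request, roi_fixture, fraction):
    roi = request.getfixturevalue(roi_fixture)
    part = partition_regions(roi, fraction)
    expected = oracle_central_mask(roi, fraction)
    np.testing.assert_array_equal(part.central_mask, expected)


def test_random_masks_match_oracle():
    rng = np.random.default_rng(42)
    for _ in range(5):
        blob = disk_mask((48, 48), rng.integers(16, 32, 2), rng.integers(8, 14))
        blob |= disk_mask((48, 48), rng.integers(16, 32, 2), rng.integers(5, 10))
        fraction = rng.uniform(0.05, 0.95)
        part = partition_regions(blob, fraction)
        np.testing.assert_array_equal(
            part.central_mask, oracle_central_mask(blob, fraction)
        )


def test_offset_zero_maps_whole_roi_to_central(circle_roi_small):
    part = partition_regions(circle_roi_small, 0.0)
    np.testing.assert_array_equal(part.central_mask, circle_roi_small)
    assert not part.peripheral_mask.any()
    assert region_areas(part) == (int(circle_roi_small.sum()), 0)


def test_offset_one_keeps_deepest_pixels(circle_roi_small):
    part = partition_regions(circle_roi_small, 1.0)
    assert part.central_mask.any()
    d = segmentation.distance_to_boundary(circle_roi_small)
    assert np.all(d[part.central_mask] == d[circle_roi_small].max())


def test_circle_central_area_fraction(circle_roi_large):
    """At a 22% offset a disk keeps a central core of ~(1-0.22)^2 area."""
    part = partition_regions(circle_roi_large, 0.22)
    area_c, area_p = region_areas(part)
    assert area_c + area_p == int(circle_roi_large.sum())
    assert area_c / (area_c + area_p) == pytest.approx(0.78**2, abs=0.01)


@pytest.mark.parametrize("method", ["distance_fraction", "contour_scale"])
@pytest.mark.parametrize("fraction", [0.0, 0.22, 0.7])
def test_partition_is_exact(two_lobe_roi, method, fraction):
    part = partition_regions(two_lobe_roi, fraction, method=method)
    np.testing.assert_array_equal(part.central_mask | part.peripheral_mask, two_lobe_roi)
    assert not (part.central_mask & part.peripheral_mask).any()


def test_central_area_monotone_in_offset(two_lobe_roi):
    areas = [
        region_areas(partition_regions(two_lobe_roi, f))[0]
        for f in np.linspace(0, 1, 11)
    ]
    assert all(a >= b for a, b in zip(areas, areas[1:]))


def test_partition_is_deterministic(circle_roi_small):
    a = partition_regions(circle_roi_small, 0.22)
    b = partition_regions(circle_roi_small, 0.22)
    np.testing.assert_array_equal(a.central_mask, b.central_mask)


def test_contour_scale_identity_and_degenerate(circle_roi_small):
    part0 = partition_regions(circle_roi_small, 0.0, method="contour_scale")
    np.testing.assert_array_equal(part0.central_mask, circle_roi_small)
    part1 = partition_regions(circle_roi_small, 1.0, method="contour_scale")
    assert part1.central_mask.sum() == 1


def test_invalid_inputs_rejected(circle_roi_small):
    with pytest.raises(ValueError, match="empty"):
        partition_regions(np.zeros((8, 8), dtype=bool), 0.22)
    with pytest.raises(ValueError, match="offset_fraction"):
        partition_regions(circle_roi_small, 1.5)
    with pytest.raises(ValueError, match="method"):
        partition_regions(circle_roi_small, 0.2, method="nope")


def test_multi_component_mask_warns():
    mask = disk_mask((64, 64), (16, 16), 8) | disk_mask((64, 64), (48, 48), 8)
    with pytest.warns(UserWarning, match="connected components"):
        partition_regions(mask, 0.22)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    height=st.integers(2, 24),
    width=st.integers(2, 24),
    fraction=st.floats(0.0, 1.0),
)
def test_partition_exact_on_arbitrary_rectangles(height, width, fraction):
    """Union/disjointness hold for every rectangle and offset fraction."""
    roi = np.zeros((32, 32), dtype=bool)
    roi[4 : 4 + height, 4 : 4 + width] = True
    part = partition_regions(roi, fraction)
    np.testing.assert_array_equal(part.central_mask | part.peripheral_mask, roi)
    assert not (part.central_mask & part.peripheral_mask).any()
    assert part.central_mask.any()  # >= convention keeps the argmax set


def test_boundary_includes_frame_edge():
    mask = np.ones((8, 8), dtype=bool)
    border = boundary_mask(mask)
    assert border[0].all() and border[-1].all()
    assert not border[1:-1, 1:-1].any()


def test_label_export(circle_roi_small):
    part = partition_regions(circle_roi_small, 0.22)
    labels = partition_to_labels(part)
    assert set(np.unique(labels)) == {0, 1, 2}
    np.testing.assert_array_equal(labels == 2, part.central_mask)
    np.testing.assert_array_equal(labels == 0, ~circle_roi_small)
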