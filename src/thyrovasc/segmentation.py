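"""Central/peripheral partitioning of a nodule ROI by the offsetting principle.

A nodule region of interest (ROI) is split into a *central* core and a
*peripheral* rim by contracting the ROI inward by a fraction of its depth
(the "offset"). The default offset of 22% is the value established as
diagnostically optimal for thyroid nodule regional vascularity segmentation.

Two geometries are provided:

``distance_fraction`` (default)
    A pixel belongs to the central region when its Euclidean distance to the
    ROI boundary is at least ``offset_fraction`` times the maximum such
    distance over the ROI. Robust for arbitrary, including non-convex,
    shapes.

``contour_scale``
    The ROI contour is shrunk toward its centroid by the factor
    ``1 - offset_fraction``; intended for sensitivity analysis only.

Conventions: coordinates are row-major, 0-based, pixel-centre. The ROI
boundary is the set of ROI pixels 4-adjacent to background (pixels on the
image frame edge count as adjacent to background). Threshold ties go to the
central region (``>=``), so an offset of 0 maps the whole ROI to central.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "RegionPartition",
    "boundary_mask",
    "distance_to_boundary",
    "partition_regions",
    "region_areas",
    "partition_to_labels",
]

_METHODS = ("distance_fraction", "contour_scale")


@dataclass(frozen=True)
class RegionPartition:
    """Exact two-way split of an ROI into central and peripheral masks.

    Invariants: ``central | peripheral`` equals the ROI and the two masks
    are disjoint.
    """

    central_mask: np.ndarray
    peripheral_mask: np.ndarray
    offset_fraction: float
    method: str

    @property
    def roi_mask(self) -> np.ndarray:
        return self.central_mask | self.peripheral_mask


def _validate_roi(roi: np.ndarray) -> np.ndarray:
    roi = np.asarray(roi).astype(bool)
    if roi.ndim != 2:
        raise ValueError(f"ROI mask must be 2-D, got shape {roi.shape}")
    if not roi.any():
        raise ValueError("ROI mask is empty")
    _, n_components = ndimage.label(roi)
    if n_components > 1:
        warnings.warn(
            f"ROI mask has {n_components} connected components; "
            "processing as a single mask",
            stacklevel=3,
        )
    return roi


def boundary_mask(roi: np.ndarray) -> np.ndarray:
    """ROI pixels 4-adjacent to background (frame edges count as background)."""
    roi = np.asarray(roi).astype(bool)
    interior = ndimage.binary_erosion(
        roi, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return roi & ~interior


def distance_to_boundary(roi: np.ndarray) -> np.ndarray:
    """Euclidean distance from every pixel to the nearest ROI boundary pixel.

    Boundary pixels themselves are at distance 0. The distance is computed
    to boundary *pixels* (not to the background), so a disk of radius r has
    a maximum distance of roughly r - 1 at its centre.
    """
    border = boundary_mask(roi)
    return ndimage.distance_transform_edt(~border)


def partition_regions(
    roi: np.ndarray,
    offset_fraction: float = 0.22,
    method: str = "distance_fraction",
) -> RegionPartition:
    """Partition an ROI into central and peripheral regions at an offset.

    Parameters
    ----------
    roi
        2-D boolean mask; True marks nodule pixels. Must be non-empty.
    offset_fraction
        Fraction in [0, 1] by which the ROI is contracted to form the
        central region. 0 assigns the whole ROI to central; 1 leaves only
        the deepest pixel(s).
    method
        ``distance_fraction`` or ``contour_scale``.
    """
    roi = _validate_roi(roi)
    if not 0.0 <= offset_fraction <= 1.0:
        raise ValueError(f"offset_fraction must be in [0, 1], got {offset_fraction}")
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {_METHODS}")

    if method == "distance_fraction":
        d = distance_to_boundary(roi)
        d_max = d[roi].max()
        central = roi & (d >= offset_fraction * d_max)
    else:
        central = _contour_scale_central(roi, offset_fraction)

    peripheral = roi & ~central
    return RegionPartition(
        central_mask=central,
        peripheral_mask=peripheral,
        offset_fraction=float(offset_fraction),
        method=method,
    )


def _contour_scale_central(roi: np.ndarray, offset_fraction: float) -> np.ndarray:
    """Central mask by shrinking the ROI toward its centroid by 1 - offset."""
    scale = 1.0 - offset_fraction
    rows, cols = np.nonzero(roi)
    cr, cc = rows.mean(), cols.mean()
    if scale == 0.0:
        # degenerate limit: keep the ROI pixel nearest the centroid
        idx = np.argmin((rows - cr) ** 2 + (cols - cc) ** 2)
        central = np.zeros_like(roi)
        central[rows[idx], cols[idx]] = True
        return central
    # pixel p is central iff its pre-image under the shrink lies in the ROI
    src_r = np.rint(cr + (rows - cr) / scale).astype(int)
    src_c = np.rint(cc + (cols - cc) / scale).astype(int)
    inside = (
        (src_r >= 0)
        & (src_r < roi.shape[0])
        & (src_c >= 0)
        & (src_c < roi.shape[1])
    )
    keep = np.zeros(rows.shape, dtype=bool)
    keep[inside] = roi[src_r[inside], src_c[inside]]
    central = np.zeros_like(roi)
    central[rows[keep], cols[keep]] = True
    return central


def region_areas(partition: RegionPartition) -> tuple[int, int]:
    """Pixel counts (central, peripheral); their sum is the ROI area."""
    return int(partition.central_mask.sum()), int(partition.peripheral_mask.sum())


def partition_to_labels(partition: RegionPartition) -> np.ndarray:
    """3-label image: 0 = background, 1 = peripheral, 2 = central."""
    labels = np.zeros(partition.central_mask.shape, dtype=np.uint8)
    labels[partition.peripheral_mask] = 1
    labels[partition.central_mask] = 2
    return labels
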