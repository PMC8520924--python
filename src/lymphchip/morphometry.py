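"""Morphometry of cell and sprout masks.

Quantifications of the imaging readouts: per-cell shape metrics
(area, perimeter, circularity 4*pi*A/P^2, equivalent-ellipse aspect
ratio and orientation), polar orientation histograms with circular
statistics for axial data, and sprout-front measurements (perpendicular
sprouting distance from the gel interface, sprout area, direction
angles) with interface-disconnected objects counted separately as
single-cell migration events.

Perimeter uses a smoothed subpixel contour-length estimator (Gaussian
sigma 1.5 px, marching-squares contour at the 0.5 level): plain
pixel-edge counting biases circularity low for smooth shapes, while
this estimator recovers both a disk (circularity ~1.00) and a square
(~0.785) to a few percent.  Circularity is clamped at 1 against
discretization overshoot.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.measure import find_contours, label as sk_label, regionprops

from .device_model import ValidationError

__all__ = [
    "ShapeMetrics",
    "SproutMetrics",
    "shape_metrics",
    "orientation_histogram",
    "sprout_quantification",
    "contour_perimeter",
]

#: Minimum component area (px) considered a real object, not noise.
MIN_COMPONENT_AREA = 20
_PERIMETER_SIGMA = 1.5


@dataclass(frozen=True)
class ShapeMetrics:
    """Shape descriptors of one connected component."""

    label: int
    area: float            # physical units^2 (pixel_size applied)
    perimeter: float
    circularity: float     # 4 pi A / P^2, in (0, 1]
    aspect_ratio: float    # major/minor axis of the moment ellipse, >= 1
    orientation: float     # deg in [-90, 90), from +x (column) axis
    centroid: tuple[float, float]  # (x, y) physical units
    touches_border: bool = False


@dataclass(frozen=True)
class SproutMetrics:
    """Sprout-front measurements for one gel-region mask."""

    distances: tuple[float, ...]       # per-sprout perpendicular extent
    max_distance: float
    mean_distance: float
    sprout_area: float
    direction_angles: tuple[float, ...]  # deg, from interface normal (+x)
    n_sprouts: int
    n_single_cells: int                # interface-disconnected objects
    metadata: dict = field(default_factory=dict, compare=False)


def contour_perimeter(mask: np.ndarray, sigma: float = _PERIMETER_SIGMA) -> float:
    """Subpixel perimeter: contour length of the smoothed 0.5-level set."""
    m = np.pad(np.asarray(mask, float), 4)
    if sigma > 0:
        m = gaussian_filter(m, sigma)
    total = 0.0
    for contour in find_contours(m, 0.5):
        d = np.diff(contour, axis=0)
        total += float(np.hypot(d[:, 0], d[:, 1]).sum())
    return total


def _orientation_from_x(props) -> float:
    """Regionprops orientation -> degrees from the +x (column) axis, [-90, 90)."""
    ang = 90.0 + math.degrees(props.orientation)
    return (ang + 90.0) % 180.0 - 90.0


def shape_metrics(
    mask: np.ndarray,
    pixel_size: float = 1.0,
    min_area: int = MIN_COMPONENT_AREA,
) -> list[ShapeMetrics]:
    """Per-object shape metrics from a binary or labeled mask.

    An unlabeled (boolean/0-1) mask is connected-component labeled
    (8-connectivity) first.  Components below ``min_area`` pixels are
    ignored; components touching the image border are flagged.  An empty
    mask yields an empty list with a warning.
    """
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValidationError("mask must be 2D")
    if arr.max() <= 1:
        lab = sk_label(arr > 0, connectivity=2)
    else:
        lab = arr.astype(int)
    out: list[ShapeMetrics] = []
    h, w = lab.shape
    for props in regionprops(lab):
        if props.area < min_area:
            continue
        # bbox-cropped object view keeps the subpixel contour cheap
        perim_px = contour_perimeter(props.image)
        area_px = float(props.area)
        circ = 4.0 * math.pi * area_px / perim_px**2 if perim_px > 0 else 0.0
        circ = min(circ, 1.0)
        minor = props.axis_minor_length
        ar = props.axis_major_length / minor if minor > 0 else math.inf
        r0, c0, r1, c1 = props.bbox
        touches = r0 == 0 or c0 == 0 or r1 == h or c1 == w
        cy, cx = props.centroid
        out.append(
            ShapeMetrics(
                label=int(props.label),
                area=area_px * pixel_size**2,
                perimeter=perim_px * pixel_size,
                circularity=circ,
                aspect_ratio=float(ar),
                orientation=_orientation_from_x(props),
                centroid=(cx * pixel_size, cy * pixel_size),
                touches_border=touches,
            )
        )
    if not out:
        warnings.warn("mask contains no component above the minimum area", stacklevel=2)
    return out


def orientation_histogram(
    angles,
    n_bins: int = 12,
    range_mode: str = "half-circle",
):
    """Polar histogram plus circular statistics of orientation data.

    ``range_mode="half-circle"`` treats angles as axial (180-degree
    periodic, e.g. cell long-axis orientations): angles are doubled
    before computing the circular mean and resultant length, and the
    histogram covers [-90, 90).  ``"full-circle"`` treats them as
    directional over [-180, 180).

    Returns ``(counts, bin_edges, circular_mean_deg, resultant_length)``.
    Counts always sum to the number of input angles.
    """
    if n_bins < 4:
        raise ValidationError(f"n_bins must be >= 4, got {n_bins}")
    a = np.asarray(list(angles), dtype=float)
    if a.size == 0:
        raise ValidationError("angles must be non-empty")
    if range_mode == "half-circle":
        lo, hi, period = -90.0, 90.0, 180.0
    elif range_mode == "full-circle":
        lo, hi, period = -180.0, 180.0, 360.0
    else:
        raise ValidationError(f"unknown range_mode {range_mode!r}")

    if np.any((a < lo) | (a >= hi)):
        warnings.warn("angles outside declared range were wrapped", stacklevel=2)
        a = (a - lo) % period + lo

    counts, edges = np.histogram(a, bins=n_bins, range=(lo, hi))

    mult = 2.0 if range_mode == "half-circle" else 1.0
    z = np.exp(1j * np.deg2rad(a * mult))
    r = abs(z.mean())
    mean = math.degrees(np.angle(z.mean())) / mult
    return counts, edges, mean, float(r)


def sprout_quantification(
    gel_mask: np.ndarray,
    interface_position: int,
    pixel_size: float = 1.0,
    min_area: int = MIN_COMPONENT_AREA,
    direction: int = +1,
) -> SproutMetrics:
    """Measure sprouting from a binary gel-region mask.

    ``interface_position`` is the column index of the gel interface
    line; the gel lies toward ``direction`` (+1: increasing column
    index).  8-connected foreground structures touching the interface
    (within one pixel) are sprouts: their distance is the maximum
    perpendicular extent from the interface, and their direction angle
    is the angle of the base-centroid-to-tip vector relative to the
    interface normal.  Structures not connected to the interface are
    counted as single-cell migration events and excluded from distances.
    """
    arr = np.asarray(gel_mask) > 0
    if arr.ndim != 2:
        raise ValidationError("gel_mask must be 2D")
    h, w = arr.shape
    if not 0 <= interface_position < w:
        raise ValidationError("interface position must lie inside the image")

    # work in a gel-frame view: column 0 is the interface, columns grow into the gel
    gel = arr[:, interface_position:] if direction >= 0 else arr[:, interface_position::-1]

    lab = sk_label(gel, connectivity=2)
    distances: list[float] = []
    angles: list[float] = []
    sprout_area_px = 0
    n_single = 0
    for props in regionprops(lab):
        if props.area < min_area:
            continue
        rows, cols = np.nonzero(lab == props.label)
        if cols.min() <= 1:  # connected to the interface line
            dist_px = float(cols.max())
            distances.append(dist_px * pixel_size)
            sprout_area_px += int(props.area)
            # direction: base centroid -> tip (farthest pixel)
            base_rows = rows[cols <= 1]
            base_r = float(base_rows.mean())
            tip_i = int(np.argmax(cols))
            dy = float(rows[tip_i]) - base_r
            dx = float(cols[tip_i])
            angles.append(math.degrees(math.atan2(-dy, dx)))  # +y up convention
        else:
            n_single += 1

    distances_t = tuple(distances)
    return SproutMetrics(
        distances=distances_t,
        max_distance=max(distances_t) if distances_t else 0.0,
        mean_distance=float(np.mean(distances_t)) if distances_t else 0.0,
        sprout_area=sprout_area_px * pixel_size**2,
        direction_angles=tuple(angles),
        n_sprouts=len(distances_t),
        n_single_cells=n_single,
        metadata={"interface_position": interface_position, "pixel_size": pixel_size},
    )
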