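"""Per-cell axis measurement, elongation index, and gradient alignment.

Axes are measured in the single largest-area z plane of a cell: the long
axis is the maximum Feret chord of the (optionally protrusion-stripped)
body outline, the short axis is the body's maximal extent orthogonal to
the long axis.  The elongation index is ``(a_long - a_short) /
(a_long + a_short)``; orientation to a gradient is the folded angle
``arccos(|<axis, gradient>|)`` in degrees on [0, 90].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage.morphology import opening

from .errors import ComputationError, ConfigurationError
from .segmentation import SegmentedObject

__all__ = [
    "CellMeasurement", "largest_plane", "measure_axes", "elongation_index",
    "orientation_angle", "measure_object",
]


@dataclass
class CellMeasurement:
    a_long: float                 # um
    a_short: float                # um
    ei: float
    long_axis_dir: np.ndarray     # unit vector (y, x) in the measurement plane
    plane_index: int | None = None  # z index of largest cross-section (3D only)
    theta_deg: float | None = None  # angle to gradient, when one is declared


def largest_plane(obj: SegmentedObject) -> int:
    """Z index of the object's largest cross-section.

    Ties are broken toward the plane nearest the object's centroid (and
    then toward the smaller index, for determinism).
    """
    if obj.n_voxels == 0:
        raise ComputationError("cannot find the largest plane of an empty object")
    zs = obj.coords[:, 0]
    areas = np.bincount(zs)
    best = areas.max()
    candidates = np.flatnonzero(areas == best)
    centroid_z = obj.centroid[0] / obj.voxel_size[0] - 0.5
    return int(candidates[np.argmin(np.abs(candidates - centroid_z))])


def _anisotropic_disk(r_um: float, voxel_size_yx: tuple[float, float]
                      ) -> np.ndarray:
    ry = max(1, int(math.floor(r_um / voxel_size_yx[0])))
    rx = max(1, int(math.floor(r_um / voxel_size_yx[1])))
    dy = np.arange(-ry, ry + 1)[:, None] * voxel_size_yx[0]
    dx = np.arange(-rx, rx + 1)[None, :] * voxel_size_yx[1]
    return dy * dy + dx * dx <= r_um * r_um + 1e-12


#: angular resolution of the rotating-calipers direction sweep
_N_DIRECTIONS = 720


def measure_axes(plane_mask: np.ndarray,
                 voxel_size_yx: tuple[float, float] = (1.0, 1.0),
                 exclude_protrusions: bool = False,
                 r_open: float = 1.0) -> tuple[float, float, np.ndarray]:
    """Long axis, orthogonal short axis (um), and long-axis direction.

    With ``exclude_protrusions`` the mask is reduced to the cell body by
    morphological opening with a physical-radius ``r_open`` disk before
    measurement, discarding filopodia-like spurs.

    Extents are convex-hull widths of the pixel centres, swept by rotating
    calipers over a fine angular grid; for a digitized ellipse the extreme
    pixel centres sit on the outline, so centre widths are unbiased to
    within voxel quantization.  Directions in which the centre width is
    degenerate (single pixel, one-pixel-wide line) fall back to the pixel
    footprint's support, so no mask yields a zero axis.  Anisotropic
    pixels are handled throughout.
    """
    plane_mask = np.asarray(plane_mask, dtype=bool)
    if plane_mask.ndim != 2 or not plane_mask.any():
        raise ComputationError("measure_axes needs a nonempty 2D mask")
    if exclude_protrusions:
        body = opening(plane_mask,
                       footprint=_anisotropic_disk(r_open, voxel_size_yx))
        if not body.any():
            raise ComputationError(
                f"cell body vanished after opening with r_open={r_open} um"
            )
        plane_mask = body

    sy, sx = float(voxel_size_yx[0]), float(voxel_size_yx[1])
    centers = np.argwhere(plane_mask) * np.array([sy, sx])
    if len(centers) >= 3:
        try:
            centers = centers[ConvexHull(centers).vertices]
        except QhullError:  # collinear pixel centres
            pass

    theta = np.linspace(0.0, math.pi, _N_DIRECTIONS, endpoint=False)
    dirs = np.column_stack([np.sin(theta), np.cos(theta)])  # (y, x)
    proj = centers @ dirs.T
    center_widths = proj.max(axis=0) - proj.min(axis=0)
    support = sy * np.abs(dirs[:, 0]) + sx * np.abs(dirs[:, 1])
    widths = np.where(center_widths > 0, center_widths, support)
    i = int(np.argmax(widths))
    a_long = float(widths[i])
    direction = dirs[i]
    j = (i + _N_DIRECTIONS // 2) % _N_DIRECTIONS  # orthogonal direction
    a_short = float(widths[j])
    return a_long, a_short, direction


def elongation_index(a_long: float, a_short: float) -> float:
    """``(a_long - a_short) / (a_long + a_short)``; 0 for round cells."""
    if a_short <= 0:
        raise ConfigurationError(f"a_short must be > 0, got {a_short}")
    if a_long < a_short:
        raise ConfigurationError(
            f"a_long ({a_long}) must be >= a_short ({a_short})"
        )
    return (a_long - a_short) / (a_long + a_short)


def orientation_angle(long_axis_dir: np.ndarray,
                      gradient_axis: np.ndarray) -> float:
    """Folded angle (degrees, [0, 90]) between two undirected axes.

    Invariant to a sign flip of either vector.  Vectors of any matching
    dimension are accepted.
    """
    u = np.asarray(long_axis_dir, dtype=float).ravel()
    v = np.asarray(gradient_axis, dtype=float).ravel()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ConfigurationError("axis vectors must be nonzero")
    if u.shape != v.shape:
        raise ConfigurationError(
            f"axis dimensions differ: {u.shape} vs {v.shape}"
        )
    c = abs(float(np.dot(u, v))) / (nu * nv)
    return math.degrees(math.acos(min(c, 1.0)))


def measure_object(obj: SegmentedObject,
                   exclude_protrusions: bool = False,
                   r_open: float = 1.0,
                   gradient_axis: np.ndarray | None = None
                   ) -> CellMeasurement:
    """Full morphometry of a segmented 3D object in its largest plane."""
    z = largest_plane(obj)
    in_plane = obj.coords[obj.coords[:, 0] == z][:, 1:]
    lo = in_plane.min(axis=0)
    mask = np.zeros(in_plane.max(axis=0) - lo + 1, dtype=bool)
    mask[tuple((in_plane - lo).T)] = True
    vs_yx = (obj.voxel_size[1], obj.voxel_size[2])
    a_long, a_short, direction = measure_axes(
        mask, vs_yx, exclude_protrusions=exclude_protrusions, r_open=r_open
    )
    theta = None
    if gradient_axis is not None:
        theta = orientation_angle(direction, gradient_axis)
    return CellMeasurement(
        a_long=a_long,
        a_short=a_short,
        ei=elongation_index(a_long, a_short),
        long_axis_dir=direction,
        plane_index=z,
        theta_deg=theta,
    )
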