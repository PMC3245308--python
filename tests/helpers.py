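"""Shared construction helpers for the test suite."""

from __future__ import annotations

import numpy as np

from stackquant import IntensityStack, SegmentedObject


def make_stack(arr, channels=("cells",), voxel_size=(1.0, 1.0, 1.0)):
    """Wrap a 3D array (or dict of channel -> 3D array) as an IntensityStack."""
    if isinstance(arr, dict):
        channels = list(arr)
        data = np.stack([np.asarray(arr[ch], dtype=float) for ch in channels])
    else:
        data = np.asarray(arr, dtype=float)[None]
        channels = list(channels)
    return IntensityStack(data, channels, voxel_size)


def make_object(volume, label=1, voxel_size=(1.0, 1.0, 1.0), coords=None):
    """A SegmentedObject with a prescribed volume (coords are placeholders)."""
    if coords is None:
        coords = np.array([[0, 0, 0]])
    return SegmentedObject(
        label=label,
        coords=np.asarray(coords),
        volume=float(volume),
        centroid=np.zeros(3),
        mean_intensity={},
        voxel_size=voxel_size,
    )


def ellipse_mask(a_um, b_um, pixel_um=0.5, pad=6, angle_deg=0.0,
                 shape=None, center=None):
    """Binary 2D mask of a filled ellipse with semi-axes in um."""
    if shape is None:
        half = int(np.ceil(max(a_um, b_um) / pixel_um)) + pad
        shape = (2 * half + 1, 2 * half + 1)
    if center is None:
        center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    yy, xx = np.mgrid[0: shape[0], 0: shape[1]].astype(float)
    dy = (yy - center[0]) * pixel_um
    dx = (xx - center[1]) * pixel_um
    t = np.radians(angle_deg)
    u = dx * np.cos(t) + dy * np.sin(t)
    v = -dx * np.sin(t) + dy * np.cos(t)
    return (u / a_um) ** 2 + (v / b_um) ** 2 <= 1.0


def ellipsoid_mask(shape, center, semi_axes, rotation=None,
                   voxel_size=(1.0, 1.0, 1.0)):
    """Binary 3D mask of a filled ellipsoid; semi-axes and center in voxels
    scaled by voxel_size."""
    zz, yy, xx = np.mgrid[0:shape[0], 0:shape[1], 0:shape[2]].astype(float)
    d = np.stack([
        (zz - center[0]) * voxel_size[0],
        (yy - center[1]) * voxel_size[1],
        (xx - center[2]) * voxel_size[2],
    ])
    if rotation is not None:
        d = np.einsum("ji,jzyx->izyx", np.asarray(rotation), d)
    q = sum((d[k] / semi_axes[k]) ** 2 for k in range(3))
    return q <= 1.0
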