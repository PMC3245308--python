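"""Multi-channel 3D intensity stacks and their TIFF representation.

A stack is stored as a ``(C, Z, Y, X)`` float array with an ordered list of
channel role labels and physical voxel dimensions in micrometres, axis order
``(z, y, x)``.  On disk a stack is a multi-page TIFF (pages in C-then-Z
order) accompanied by a small YAML sidecar recording channels and voxel
size, so the pairing survives tools that strip TIFF tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import yaml

from .errors import ConfigurationError, InputError

SIDECAR_SUFFIX = ".yaml"


@dataclass
class IntensityStack:
    voxels: np.ndarray  # (C, Z, Y, X), finite, >= 0
    channels: list[str]
    voxel_size: tuple[float, float, float]  # um per (z, y, x)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 4:
            raise ConfigurationError(
                f"stack must be (C, Z, Y, X); got shape {self.voxels.shape}"
            )
        if len(self.channels) != self.voxels.shape[0]:
            raise ConfigurationError(
                f"{len(self.channels)} channel labels for "
                f"{self.voxels.shape[0]} channel planes"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ConfigurationError(f"duplicate channel labels: {self.channels}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ConfigurationError(
                f"voxel_size must be three positive values (z, y, x); "
                f"got {self.voxel_size}"
            )
        if not np.all(np.isfinite(self.voxels)) or np.any(self.voxels < 0):
            raise InputError("stack intensities must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial shape (Z, Y, X)."""
        return self.voxels.shape[1:]

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in um^3."""
        return float(np.prod(self.voxel_size))

    def channel(self, role: str) -> np.ndarray:
        """Return the 3D array for a channel role."""
        try:
            idx = self.channels.index(role)
        except ValueError:
            raise ConfigurationError(
                f"channel {role!r} not present; available: {self.channels}"
            ) from None
        return self.voxels[idx]


def sidecar_path(tiff_path: str | Path) -> Path:
    p = Path(tiff_path)
    return p.with_suffix(p.suffix + SIDECAR_SUFFIX)


def write_stack(stack: IntensityStack, tiff_path: str | Path) -> Path:
    """Write stack as multi-page TIFF plus a YAML sidecar; returns sidecar path."""
    tiff_path = Path(tiff_path)
    tiff_path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        tiff_path,
        stack.voxels.astype(np.float32),
        photometric="minisblack",
        metadata={"axes": "CZYX"},
    )
    meta = {
        "channels": list(stack.channels),
        "voxel_size_um": {"z": stack.voxel_size[0],
                          "y": stack.voxel_size[1],
                          "x": stack.voxel_size[2]},
        "shape_czyx": list(stack.voxels.shape),
    }
    side = sidecar_path(tiff_path)
    side.write_text(yaml.safe_dump(meta, sort_keys=True))
    return side


def read_stack(
    tiff_path: str | Path,
    channels: Sequence[str] | None = None,
    voxel_size: Sequence[float] | None = None,
) -> IntensityStack:
    """Read a stack written by :func:`write_stack`.

    ``channels`` and ``voxel_size`` override the sidecar; both must be given
    when no sidecar exists.
    """
    tiff_path = Path(tiff_path)
    if not tiff_path.exists():
        raise InputError(f"stack file not found: {tiff_path}")
    try:
        data = tifffile.imread(tiff_path)
    except Exception as exc:  # malformed TIFF
        raise InputError(f"could not read TIFF {tiff_path}: {exc}") from exc

    side = sidecar_path(tiff_path)
    meta = {}
    if side.exists():
        try:
            meta = yaml.safe_load(side.read_text()) or {}
        except yaml.YAMLError as exc:
            raise InputError(f"malformed sidecar {side}: {exc}") from exc

    if channels is None:
        channels = meta.get("channels")
    if channels is None:
        raise InputError(
            f"no channel labels: provide them or supply sidecar {side}"
        )
    if voxel_size is None:
        vs = meta.get("voxel_size_um")
        if vs is not None:
            voxel_size = (vs["z"], vs["y"], vs["x"])
    if voxel_size is None:
        raise InputError(
            f"no voxel size: provide it or supply sidecar {side}"
        )

    data = np.asarray(data, dtype=np.float64)
    if data.ndim == 3 and len(channels) == 1:
        data = data[None]
    elif data.ndim == 3 and data.shape[0] == len(channels):
        # single-plane multi-channel written as (C, Y, X)
        data = data[:, None]
    if data.ndim != 4:
        raise InputError(
            f"TIFF {tiff_path} has shape {data.shape}; expected (C, Z, Y, X)"
        )
    return IntensityStack(voxels=data, channels=list(channels),
                          voxel_size=tuple(voxel_size))
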