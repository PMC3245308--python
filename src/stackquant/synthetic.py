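"""Ground-truthed synthetic fluorescence scenes.

Two generators are provided:

``generate_stack``
    A 3D multi-channel confocal-like stack of ellipsoidal cells, isolated
    or placed in touching clusters, with marker-positive subsets, Gaussian
    blur, and additive noise.

``generate_culture_field``
    A single-plane field of elongated cells whose long-axis orientations
    follow an axial (period-180 deg) von Mises distribution about a declared
    gradient axis.

Both are deterministic functions of ``(SceneConfig, seed)`` and return the
rendered :class:`~stackquant.stack.IntensityStack` together with a
:class:`GroundTruthScene` truth table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError, PlacementError
from .stack import IntensityStack

#: placement attempts allowed per cell before giving up
PLACEMENT_ATTEMPTS_PER_CELL = 200


@dataclass
class SceneConfig:
    """Parameters of a synthetic scene.

    Lengths are micrometres, volumes um^3, intensities arbitrary units.
    ``stack_shape`` is in voxels, axis order ``(z, y, x)``; for culture
    fields the z extent must be 1.
    """

    stack_shape: tuple[int, int, int] = (40, 128, 128)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_cells: int = 50
    cell_volume_mean: float = 300.0
    cell_volume_cv: float = 0.2
    cell_volume_range: tuple[float, float] | None = None  # hard clip, um^3
    axis_ratio_max: float = 1.6
    cluster_fraction: float = 0.0
    cluster_size_range: tuple[int, int] = (2, 3)
    marker_positive_fraction: Mapping[str, float] = field(default_factory=dict)
    ei_distribution: tuple[float, float] = (0.2, 0.08)
    orientation_concentration: float = 0.0
    gradient_axis: tuple[float, float] = (0.0, 1.0)  # in-plane (y, x)
    cell_channel: str = "cells"
    foreground_level: float = 1000.0
    background_level: float = 100.0
    noise_sd: float = 20.0
    blur_sigma: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 0:
            raise ConfigurationError(f"n_cells must be >= 0, got {self.n_cells}")
        if len(self.stack_shape) != 3 or any(s < 1 for s in self.stack_shape):
            raise ConfigurationError(f"bad stack_shape {self.stack_shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ConfigurationError(
                f"voxel_size must be strictly positive, got {self.voxel_size}"
            )
        if self.cell_volume_mean <= 0 or self.cell_volume_cv < 0:
            raise ConfigurationError("cell volume mean must be > 0, cv >= 0")
        if self.cell_volume_range is not None:
            lo, hi = self.cell_volume_range
            if not 0 < lo <= hi:
                raise ConfigurationError(
                    f"cell_volume_range must satisfy 0 < lo <= hi, "
                    f"got {self.cell_volume_range}"
                )
        if not 0.0 <= self.cluster_fraction <= 1.0:
            raise ConfigurationError(
                f"cluster_fraction must be in [0, 1], got {self.cluster_fraction}"
            )
        lo, hi = self.cluster_size_range
        if not (2 <= lo <= hi):
            raise ConfigurationError(
                f"cluster_size_range must satisfy 2 <= min <= max, "
                f"got {self.cluster_size_range}"
            )
        for ch, frac in self.marker_positive_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(
                    f"marker fraction for {ch!r} must be in [0, 1], got {frac}"
                )
        if self.orientation_concentration < 0:
            raise ConfigurationError(
                "orientation_concentration (kappa) must be >= 0, got "
                f"{self.orientation_concentration}"
            )
        if self.axis_ratio_max < 1.0:
            raise ConfigurationError("axis_ratio_max must be >= 1")
        if self.noise_sd < 0 or self.blur_sigma < 0 or self.background_level < 0:
            raise ConfigurationError("noise, blur and background must be >= 0")
        if self.foreground_level <= self.background_level:
            raise ConfigurationError(
                "foreground_level must exceed background_level"
            )
        g = np.asarray(self.gradient_axis, dtype=float)
        if g.shape != (2,) or not np.linalg.norm(g) > 0:
            raise ConfigurationError(f"bad gradient_axis {self.gradient_axis}")

    def to_yaml(self, path: str | Path) -> None:
        d = {
            **{k: getattr(self, k) for k in (
                "n_cells", "cell_volume_mean", "cell_volume_cv",
                "axis_ratio_max", "cluster_fraction", "cell_channel",
                "orientation_concentration", "foreground_level",
                "background_level", "noise_sd", "blur_sigma", "seed")},
            "stack_shape": list(self.stack_shape),
            "voxel_size": list(self.voxel_size),
            "cluster_size_range": list(self.cluster_size_range),
            "marker_positive_fraction": dict(self.marker_positive_fraction),
            "ei_distribution": list(self.ei_distribution),
            "gradient_axis": list(self.gradient_axis),
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SceneConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        for k in ("stack_shape", "voxel_size", "cluster_size_range",
                  "ei_distribution", "gradient_axis"):
            if k in d:
                d[k] = tuple(d[k])
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class CellRecord:
    """Ground truth for one synthetic cell."""

    cell_id: int
    centroid: np.ndarray       # (z, y, x) um
    semi_axes: np.ndarray      # (a, b, c) um, descending
    orientation: np.ndarray    # unit vector of the long axis, (z, y, x)
    markers: dict[str, bool]
    cluster_id: int | None = None

    @property
    def volume(self) -> float:
        """Analytic ellipsoid volume 4/3*pi*a*b*c in um^3."""
        return float(4.0 / 3.0 * math.pi * np.prod(self.semi_axes))


@dataclass
class GroundTruthScene:
    cells: list[CellRecord]
    gradient_axis: np.ndarray | None = None  # (y, x), culture fields only

    def __len__(self) -> int:
        return len(self.cells)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            row = {
                "cell_id": c.cell_id,
                "centroid_z_um": c.centroid[0],
                "centroid_y_um": c.centroid[1],
                "centroid_x_um": c.centroid[2],
                "semi_axis_a_um": c.semi_axes[0],
                "semi_axis_b_um": c.semi_axes[1],
                "semi_axis_c_um": c.semi_axes[2],
                "orient_z": c.orientation[0],
                "orient_y": c.orientation[1],
                "orient_x": c.orientation[2],
                "volume_um3": c.volume,
                "cluster_id": -1 if c.cluster_id is None else c.cluster_id,
            }
            for ch, flag in c.markers.items():
                row[f"marker_{ch}"] = bool(flag)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def sample_axial_deviation(n: int, kappa: float, rng: np.random.Generator
                           ) -> np.ndarray:
    """Signed deviations (degrees, in (-90, 90]) of an axis from a reference.

    Axial data have period 180 deg, so the doubled angle is drawn from a von
    Mises distribution with concentration ``kappa`` and halved.  ``kappa=0``
    gives deviations uniform on (-90, 90], i.e. folded angles uniform on
    [0, 90).
    """
    if kappa < 0:
        raise ConfigurationError(f"kappa must be >= 0, got {kappa}")
    if kappa == 0:
        return rng.uniform(-90.0, 90.0, size=n)
    doubled = rng.vonmises(0.0, kappa, size=n)  # radians in (-pi, pi]
    return np.degrees(doubled) / 2.0


def _quaternion_rotation(q: np.ndarray) -> np.ndarray:
    """Rotation matrix from a unit quaternion (w, x, y, z)."""
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _sample_volumes(cfg: SceneConfig, rng: np.random.Generator, n: int
                    ) -> np.ndarray:
    vol = rng.normal(cfg.cell_volume_mean,
                     cfg.cell_volume_cv * cfg.cell_volume_mean, size=n)
    vol = np.clip(vol, 0.2 * cfg.cell_volume_mean, None)
    if cfg.cell_volume_range is not None:
        vol = np.clip(vol, *cfg.cell_volume_range)
    return vol


def _sample_shapes(cfg: SceneConfig, rng: np.random.Generator, n: int
                   ) -> np.ndarray:
    """Sample (n, 3) descending semi-axes matching the target volume stats."""
    vol = _sample_volumes(cfg, rng, n)
    ratios = rng.uniform(1.0, cfg.axis_ratio_max, size=(n, 2))
    semi = np.empty((n, 3))
    for i in range(n):
        p, q = sorted(ratios[i], reverse=True)
        scale = (3.0 * vol[i] / (4.0 * math.pi * p * q)) ** (1.0 / 3.0)
        semi[i] = scale * np.array([p, q, 1.0])
    return semi


def _partition_clusters(cfg: SceneConfig, rng: np.random.Generator
                        ) -> list[int | None]:
    """Cluster id per cell (None = isolated), honouring cluster_fraction."""
    n = cfg.n_cells
    n_clustered = int(round(cfg.cluster_fraction * n))
    if n_clustered < 2:
        return [None] * n
    ids: list[int | None] = []
    cid = 0
    lo, hi = cfg.cluster_size_range
    remaining = n_clustered
    while remaining >= 2:
        size = int(rng.integers(lo, hi + 1))
        size = min(size, remaining)
        if size < 2:
            break
        ids.extend([cid] * size)
        cid += 1
        remaining -= size
    ids.extend([None] * (n - len(ids)))
    return ids


def _place_cells(cfg: SceneConfig, rng: np.random.Generator,
                 semi: np.ndarray, cluster_ids: list[int | None],
                 planar: bool) -> np.ndarray:
    """Rejection-sample cell centroids (um) with collision constraints.

    Cells of distinct clusters (or isolated) keep bounding spheres separated
    by ``clearance``; cells sharing a cluster are placed overlapping so their
    rendered masks form one connected component.
    """
    n = len(semi)
    extent = np.array(cfg.stack_shape, dtype=float) * np.array(cfg.voxel_size)
    clearance = 2.0 * cfg.blur_sigma + 2.0
    centers = np.zeros((n, 3))
    rmax = semi[:, 0]
    rmin = semi[:, 2]
    budget = PLACEMENT_ATTEMPTS_PER_CELL * max(n, 1)
    attempts = 0
    placed: list[int] = []

    lo = rmax[:, None] + cfg.blur_sigma
    hi = extent[None, :] - rmax[:, None] - cfg.blur_sigma
    if planar:
        lo[:, 0] = 0.0
        hi[:, 0] = extent[0]
    if np.any(hi <= lo):
        ext = tuple(round(float(e), 2) for e in extent)
        raise PlacementError(
            f"stack extent {ext} um cannot contain cells of radius up to "
            f"{float(rmax.max()):.1f} um (placement budget "
            f"{PLACEMENT_ATTEMPTS_PER_CELL} attempts per cell never started)"
        )

    def collides(i: int, pos: np.ndarray) -> bool:
        for j in placed:
            if cluster_ids[i] is not None and cluster_ids[i] == cluster_ids[j]:
                continue
            if np.linalg.norm(pos - centers[j]) < rmax[i] + rmax[j] + clearance:
                return True
        return False

    for i in range(n):
        anchor = None
        if cluster_ids[i] is not None:
            siblings = [j for j in placed if cluster_ids[j] == cluster_ids[i]]
            if siblings:
                anchor = siblings[-1]
        while True:
            attempts += 1
            if attempts > budget:
                raise PlacementError(
                    f"could not place cell {i} of {n} within the attempt "
                    f"budget of {budget} ({PLACEMENT_ATTEMPTS_PER_CELL} per "
                    f"cell); enlarge the stack or reduce n_cells"
                )
            if anchor is None:
                pos = rng.uniform(lo[i], hi[i])
            else:
                d = rng.normal(size=3)
                if planar:
                    d[0] = 0.0
                nrm = np.linalg.norm(d)
                if nrm == 0:
                    continue
                dist = 0.9 * (rmin[i] + rmin[anchor])
                pos = centers[anchor] + d / nrm * dist
                if np.any(pos < lo[i]) or np.any(pos > hi[i]):
                    continue
            if planar:
                pos[0] = 0.5 * cfg.voxel_size[0]
            if not collides(i, pos):
                centers[i] = pos
                placed.append(i)
                break
    return centers


def _rasterize_ellipsoid(shape: tuple[int, int, int],
                         voxel_size: tuple[float, float, float],
                         center: np.ndarray, semi: np.ndarray,
                         rot: np.ndarray) -> tuple[tuple[slice, ...], np.ndarray]:
    """Boolean sub-array (plus its slices) of voxels inside the ellipsoid.

    Voxel centres are at ``(index + 0.5) * voxel_size``; a voxel belongs to
    the cell when its centre satisfies the ellipsoid inequality.
    """
    vs = np.asarray(voxel_size)
    r = semi[0] + 1e-6
    lo = np.maximum(np.floor((center - r) / vs - 0.5).astype(int), 0)
    hi = np.minimum(np.ceil((center + r) / vs - 0.5).astype(int) + 1,
                    np.asarray(shape))
    if np.any(hi <= lo):
        return (slice(0, 0),) * 3, np.zeros((0, 0, 0), dtype=bool)
    axes = [
        (np.arange(lo[k], hi[k]) + 0.5) * vs[k] - center[k] for k in range(3)
    ]
    dz = axes[0][:, None, None]
    dy = axes[1][None, :, None]
    dx = axes[2][None, None, :]
    # body-frame coordinates: rot columns are the ellipsoid axes
    q = np.zeros((len(axes[0]), len(axes[1]), len(axes[2])))
    for k in range(3):
        comp = (dz * rot[0, k] + dy * rot[1, k] + dx * rot[2, k]) / semi[k]
        q += comp * comp
    inside = q <= 1.0
    slices = tuple(slice(int(lo[k]), int(hi[k])) for k in range(3))
    return slices, inside


def _render(cfg: SceneConfig, rng: np.random.Generator,
            scene: GroundTruthScene, rotations: list[np.ndarray]
            ) -> IntensityStack:
    channels = [cfg.cell_channel] + [
        ch for ch in cfg.marker_positive_fraction if ch != cfg.cell_channel
    ]
    shape = tuple(cfg.stack_shape)
    data = np.full((len(channels),) + shape, cfg.background_level, dtype=float)

    masks = []
    for cell, rot in zip(scene.cells, rotations):
        masks.append(_rasterize_ellipsoid(shape, cfg.voxel_size,
                                          cell.centroid, cell.semi_axes, rot))
    for ci, ch in enumerate(channels):
        plane = data[ci]
        for cell, (slices, inside) in zip(scene.cells, masks):
            if ch != cfg.cell_channel and not cell.markers.get(ch, False):
                continue
            sub = plane[slices]
            sub[inside] = cfg.foreground_level
    if cfg.blur_sigma > 0:
        sigma_vox = cfg.blur_sigma / np.asarray(cfg.voxel_size)
        if shape[0] == 1:
            sigma_vox[0] = 0.0
        for ci in range(len(channels)):
            data[ci] = gaussian_filter(data[ci], sigma=sigma_vox)
    if cfg.noise_sd > 0:
        data += rng.normal(0.0, cfg.noise_sd, size=data.shape)
    np.clip(data, 0.0, None, out=data)
    return IntensityStack(voxels=data, channels=channels,
                          voxel_size=tuple(cfg.voxel_size))


def _draw_markers(cfg: SceneConfig, rng: np.random.Generator, n: int
                  ) -> list[dict[str, bool]]:
    flags = {
        ch: rng.random(n) < frac
        for ch, frac in cfg.marker_positive_fraction.items()
        if ch != cfg.cell_channel
    }
    return [{ch: bool(v[i]) for ch, v in flags.items()} for i in range(n)]


def generate_stack(config: SceneConfig) -> tuple[IntensityStack, GroundTruthScene]:
    """Render a 3D multi-channel stack of ellipsoidal cells with ground truth.

    Identical ``config`` (including ``seed``) reproduces the output
    bit-for-bit.  Raises :class:`PlacementError` when the stack cannot hold
    the requested cells within the placement-attempt budget.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cells

    semi = _sample_shapes(config, rng, n)
    cluster_ids = _partition_clusters(config, rng)
    quats = rng.normal(size=(n, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True) if n else 1.0
    rotations = [_quaternion_rotation(q) for q in quats]
    markers = _draw_markers(config, rng, n)
    centers = _place_cells(config, rng, semi, cluster_ids, planar=False)

    cells = [
        CellRecord(
            cell_id=i,
            centroid=centers[i],
            semi_axes=semi[i],
            orientation=rotations[i][:, 0].copy(),
            markers=markers[i],
            cluster_id=cluster_ids[i],
        )
        for i in range(n)
    ]
    scene = GroundTruthScene(cells=cells)
    stack = _render(config, rng, scene, rotations)
    return stack, scene


def generate_culture_field(config: SceneConfig
                           ) -> tuple[IntensityStack, GroundTruthScene]:
    """Render a single-plane field of elongated cells aligned to a gradient.

    Long-axis orientations deviate from ``config.gradient_axis`` by axial
    von Mises draws with concentration ``orientation_concentration``; target
    elongation indices come from ``ei_distribution``.  Cell areas equal the
    equatorial cross-section of a sphere with the configured cell volume.
    """
    config.validate()
    if config.stack_shape[0] != 1:
        raise ConfigurationError(
            f"culture fields are single-plane; stack_shape[0] must be 1, "
            f"got {config.stack_shape[0]}"
        )
    rng = np.random.default_rng(config.seed)
    n = config.n_cells

    vol = _sample_volumes(config, rng, n)
    radius = (3.0 * vol / (4.0 * math.pi)) ** (1.0 / 3.0)
    ei = np.clip(rng.normal(*config.ei_distribution, size=n), 0.0, 0.9)
    a = radius * np.sqrt((1.0 + ei) / (1.0 - ei))
    b = radius * np.sqrt((1.0 - ei) / (1.0 + ei))

    g = np.asarray(config.gradient_axis, dtype=float)
    g = g / np.linalg.norm(g)
    base_angle = math.atan2(g[0], g[1])  # (y, x) components
    dev = sample_axial_deviation(n, config.orientation_concentration, rng)
    psi = base_angle + np.radians(dev)

    half_z = 0.5 * config.voxel_size[0]
    semi = np.column_stack([a, b, np.full(n, half_z)])
    cluster_ids = _partition_clusters(config, rng)
    markers = _draw_markers(config, rng, n)
    # long axis in-plane; rotation columns = (long, short, z) axes
    rotations = []
    for p in psi:
        e_long = np.array([0.0, math.sin(p), math.cos(p)])
        e_short = np.array([0.0, math.cos(p), -math.sin(p)])
        e_z = np.array([1.0, 0.0, 0.0])
        rotations.append(np.column_stack([e_long, e_short, e_z]))
    # in-plane placement uses the in-plane footprint as the bounding radius
    semi_for_placement = np.column_stack([a, b, np.minimum(b, half_z)])
    centers = _place_cells(config, rng, semi_for_placement, cluster_ids,
                           planar=True)

    cells = [
        CellRecord(
            cell_id=i,
            centroid=centers[i],
            semi_axes=semi[i],
            orientation=rotations[i][:, 0].copy(),
            markers=markers[i],
            cluster_id=cluster_ids[i],
        )
        for i in range(n)
    ]
    scene = GroundTruthScene(cells=cells, gradient_axis=g)
    stack = _render(config, rng, scene, rotations)
    return stack, scene
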