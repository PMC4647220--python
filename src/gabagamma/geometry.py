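"""Synthetic acquisition geometries shared by the MEG and PET simulators.

One geometry is shared by all subjects of a cohort (a single template grid;
per-subject anatomical warping is outside the scope of this package).  The
head frame has the sphere centre at the origin, +z up, -y posterior; V1 is a
small contiguous patch of source-grid points in the posterior lobe, paired
with a block of PET voxels and a finer block of "MR" voxels used for the
MR-voxel -> PET-voxel mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import GeometryError, HeadModel, PETGeometry, SourceGrid


def fibonacci_helmet(n_sensors: int, radius: float = 0.10,
                     min_z_frac: float = -0.35) -> np.ndarray:
    """Quasi-uniform sensor positions on a helmet-like spherical cap."""
    n_total = n_sensors
    while True:
        i = np.arange(n_total) + 0.5
        z = 1.0 - 2.0 * i / n_total
        keep = z > min_z_frac
        if keep.sum() >= n_sensors:
            break
        n_total = int(n_total * 1.3) + 1
    phi = np.pi * (1.0 + 5**0.5) * i[keep][:n_sensors]
    z = z[keep][:n_sensors]
    rho = np.sqrt(1.0 - z**2)
    pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    return radius * pts


def make_head_model(n_sensors: int = 102, radius: float = 0.10) -> HeadModel:
    """Radial point magnetometers on a helmet cap around the origin sphere."""
    pos = fibonacci_helmet(n_sensors, radius)
    ori = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    return HeadModel(np.zeros(3), pos, ori)


# V1 patch location in the head frame (posterior, slightly above centre), m.
_V1_CENTER = np.array([0.0, -0.054, 0.024])


def v1_patch_points(spacing: float = 0.006) -> np.ndarray:
    """A fixed contiguous 2 x 2 x 2 patch of source points representing V1."""
    offs = np.array([-0.5, 0.5]) * spacing
    g = np.stack(np.meshgrid(offs, offs, offs, indexing="ij"), -1).reshape(-1, 3)
    return _V1_CENTER + g


def posterior_box_grid(spacing: float = 0.006) -> SourceGrid:
    """Posterior volumetric grid (6 mm default) containing the V1 patch."""
    xs = np.arange(-0.021, 0.0211, spacing)
    ys = np.arange(-0.069, -0.0389, spacing)
    zs = np.arange(0.0, 0.0301, spacing)
    pts = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), -1).reshape(-1, 3)
    v1 = v1_patch_points(spacing)
    # mark the grid points nearest to the V1 patch as the V1 index set
    d = np.linalg.norm(pts[:, None, :] - v1[None, :, :], axis=2)
    v1_idx = np.unique(np.argmin(d, axis=0))
    return SourceGrid(pts, v1_idx, spacing * 1e3)


def v1_only_grid(spacing: float = 0.006) -> SourceGrid:
    """Source grid restricted to the V1 patch (V1-aggregated analyses only)."""
    pts = v1_patch_points(spacing)
    return SourceGrid(pts, np.arange(len(pts)), spacing * 1e3)


def _box_indices(geom: PETGeometry, center_frac, half_mm) -> np.ndarray:
    """Flat voxel indices of an axis-aligned box given fractional centre."""
    center_mm = np.asarray(center_frac) * np.asarray(geom.shape) * geom.voxel_size
    lo = geom.world_to_voxel(center_mm - half_mm)[0]
    hi = geom.world_to_voxel(center_mm + half_mm)[0]
    ii, jj, kk = [np.arange(l, h + 1) for l, h in zip(lo, hi)]
    grid = np.stack(np.meshgrid(ii, jj, kk, indexing="ij"), -1).reshape(-1, 3)
    return np.ravel_multi_index(grid.T, geom.shape)


@dataclass
class CohortGeometry:
    """Bundle of MEG and PET geometry shared across a synthetic cohort."""

    head: HeadModel
    grid: SourceGrid
    pet: PETGeometry
    roi_pons: np.ndarray
    roi_occipital: np.ndarray
    v1_pet: np.ndarray
    v1_mr_coords: np.ndarray  # (n, 3) world mm, finer than PET voxels

    @property
    def n_v1_pet(self) -> int:
        return len(self.v1_pet)

    @classmethod
    def _build(cls, n_sensors, grid, pet_shape, pet_voxel) -> "CohortGeometry":
        pet = PETGeometry(pet_shape, pet_voxel)
        v1 = _box_indices(pet, (0.50, 0.14, 0.52), np.array([8.0, 8.0, 7.0]))
        occ = _box_indices(pet, (0.50, 0.34, 0.52), np.array([9.0, 9.0, 7.0]))
        pons = _box_indices(pet, (0.50, 0.70, 0.22), np.array([9.0, 9.0, 9.0]))
        if set(v1) & set(occ) or set(v1) & set(pons) or set(occ) & set(pons):
            raise GeometryError("ROI boxes overlap; adjust geometry")
        # MR voxels: 2 mm lattice covering the V1 PET block
        centers = pet.voxel_centers(v1)
        lo, hi = centers.min(axis=0) - 2.0, centers.max(axis=0) + 2.0
        axes = [np.arange(l, h + 1e-9, 2.0) for l, h in zip(lo, hi)]
        mr = np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, 3)
        return cls(make_head_model(n_sensors), grid, pet, pons, occ, v1, mr)

    @classmethod
    def reduced(cls) -> "CohortGeometry":
        """Small configuration for simulation studies: 24 sensors, V1-only
        source grid, 6 mm PET voxels."""
        return cls._build(24, v1_only_grid(), (22, 22, 16), (6.0, 6.0, 6.5))

    @classmethod
    def demo(cls) -> "CohortGeometry":
        """Medium configuration for the analysis scripts: 48 sensors and a
        posterior volumetric source grid."""
        return cls._build(48, posterior_box_grid(), (32, 32, 24), (4.0, 4.0, 4.5))
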