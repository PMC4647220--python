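"""Dynamic flumazenil PET -> B'max parametric images (partial saturation).

The partial-saturation protocol delivers a single injection whose free
ligand concentration decays over the scan.  The pons — essentially devoid of
specific benzodiazepine binding — tracks the free (plus non-specific)
concentration ``F_t``; the occipital cortex, the densest receptor region,
provides a wide range of bound concentrations ``B_t = C_t - F_t`` as the
system moves along the saturation curve.  On the Scatchard plane the frame
trajectory ``(B_t, B_t / F_t)`` falls on a straight line with slope
``-1 / Kd_app``; the fitted apparent dissociation constant then converts the
late-frame bound map into ``B'max(v) = (C(v) - F) * (1 + Kd_app / F)``.

Frame labels follow the 1-based convention of acquisition protocols (the
static image sums frames 8-12); internal array indices are 0-based.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage, stats

from .containers import (BmaxMap, GeometryError, PETDynamic, PETGeometry,
                         ScatchardFit, StaticImage)

logger = logging.getLogger(__name__)

#: 1-based inclusive frame range summed into the static image (20-55 min)
STATIC_FRAMES = (8, 12)


class ScatchardError(RuntimeError):
    pass


def static_image(dyn: PETDynamic, frames: tuple = STATIC_FRAMES) -> StaticImage:
    """Voxelwise sum of the late frames (1-based labels, inclusive)."""
    lo, hi = frames
    if not (1 <= lo <= hi <= dyn.n_frames):
        raise ValueError(f"frame range {frames} outside 1..{dyn.n_frames}")
    values = dyn.frames[lo - 1:hi].sum(axis=0)
    return StaticImage(values, dyn.geometry, (lo, hi))


def estimate_free_ligand(img: StaticImage, pons_roi: np.ndarray) -> float:
    """Free (+ non-specific) concentration: mean static intensity in the pons.

    Returned on the static (summed) scale; divide by ``img.n_frames_summed``
    for the per-frame concentration.
    """
    pons_roi = np.asarray(pons_roi, int)
    if pons_roi.size == 0:
        raise GeometryError("empty pons ROI")
    return float(img.values.ravel()[pons_roi].mean())


def fit_scatchard(dyn: PETDynamic, occ_roi: np.ndarray = None,
                  pons_roi: np.ndarray = None) -> ScatchardFit:
    """Apparent Kd from the frame-wise occipital Scatchard line.

    Per frame, ``F_t`` is the mean pons intensity and ``B_t`` the mean
    occipital intensity minus ``F_t``; OLS of ``B_t / F_t`` on ``B_t`` has
    slope ``-1 / Kd_app``.  Returns per-frame-scale ``free_conc`` (the mean
    ``F_t`` over the late static frames), ``kd_app`` and the fit R^2.

    Raises :class:`ScatchardError` when the bound concentration does not
    vary across frames or the slope is non-negative (no saturation signal).
    """
    occ = np.asarray(occ_roi if occ_roi is not None else dyn.roi_occipital, int)
    pons = np.asarray(pons_roi if pons_roi is not None else dyn.roi_pons, int)
    if occ.size == 0 or pons.size == 0:
        raise GeometryError("empty occipital or pons ROI")
    flat = dyn.frames.reshape(dyn.n_frames, -1)
    F_t = flat[:, pons].mean(axis=1)
    B_t = flat[:, occ].mean(axis=1) - F_t
    if np.any(F_t <= 0):
        raise ScatchardError("non-positive free-ligand estimate")
    y = B_t / F_t
    if np.ptp(B_t) == 0:
        raise ScatchardError("Scatchard fit degenerate: bound concentration "
                             "does not vary across frames")
    fit = stats.linregress(B_t, y)
    if fit.slope >= 0:
        raise ScatchardError("Scatchard fit degenerate: non-negative slope "
                             "(no saturation signal)")
    kd = -1.0 / fit.slope
    lo, hi = STATIC_FRAMES
    free = float(F_t[lo - 1:hi].mean())
    return ScatchardFit(free, float(kd), float(fit.rvalue**2))


def bmax_map(img: StaticImage, fit: ScatchardFit) -> BmaxMap:
    """Voxelwise receptor density ``B'max = (C - F) (1 + Kd / F)``.

    ``C`` is the static image converted to the per-frame concentration scale;
    negative bound values (noise pushing a voxel below the free level) are
    clipped to zero and counted.
    """
    C = img.values / img.n_frames_summed
    bound = C - fit.free_conc
    n_clipped = int((bound < 0).sum())
    if n_clipped:
        logger.info("clipped %d voxels with negative bound concentration", n_clipped)
    bound = np.clip(bound, 0.0, None)
    values = bound * (1.0 + fit.kd_app / fit.free_conc)
    return BmaxMap(values, img.geometry, smoothed=False, n_clipped=n_clipped)


def smooth_map(bmap: BmaxMap, fwhm_mm: tuple = (15.0, 15.0, 21.0)) -> BmaxMap:
    """Gaussian smoothing with the given FWHM (mm), reflective boundaries."""
    fwhm = np.asarray(fwhm_mm, float)
    sigma_vox = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / bmap.geometry.voxel_size
    sm = ndimage.gaussian_filter(bmap.values, sigma_vox, mode="reflect")
    return BmaxMap(sm, bmap.geometry, smoothed=True, fwhm_mm=tuple(fwhm),
                   n_clipped=bmap.n_clipped)


def map_mr_to_pet(v1_mr_coords_mm: np.ndarray, geometry: PETGeometry) -> np.ndarray:
    """Unique PET voxel indices nearest to each V1 MR voxel centre."""
    ijk = geometry.world_to_voxel(np.atleast_2d(v1_mr_coords_mm))
    flat = np.ravel_multi_index(ijk.T, geometry.shape)
    return np.unique(flat)


def total_density(bmap: BmaxMap, voxel_indices: np.ndarray) -> float:
    """Sum of B'max over a flat voxel-index set."""
    voxel_indices = np.asarray(voxel_indices, int)
    if voxel_indices.size == 0:
        raise GeometryError("empty voxel set")
    return float(bmap.values.ravel()[voxel_indices].sum())


def v1_total_density(bmap: BmaxMap, v1_mr_coords_mm: np.ndarray,
                     geometry: PETGeometry = None) -> float:
    """Total receptor density over the unique V1-PET voxel set.

    Each V1 MR voxel is mapped to its nearest PET voxel; duplicates are
    removed before summation (the unique-set convention).
    """
    geometry = geometry or bmap.geometry
    unique = map_mr_to_pet(v1_mr_coords_mm, geometry)
    if unique.size == 0:
        raise GeometryError("V1 MR voxels map to no PET voxel")
    return total_density(bmap, unique)
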