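"""SUV-based and intensity-distribution metrics on the measurement lesion.

SUVpeak is the maximum, over lesion voxels, of the SUV field smoothed with a
3x3x3 uniform kernel (every voxel averaged with its 26 neighbors, weights
1/27). The whole grid is filtered — neighbors outside the segmentation but
inside the image contribute — and only the arg-max search is restricted to
the lesion; image borders are zero-padded. The coefficient of variation
COV = sigma_SUV / SUVmean (population SD over the active voxels) classifies
uptake heterogeneity at the 0.30 cut: COV >= 0.30 is heterogeneous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import VoxelGrid
from .segment import Lesion, LesionSet

COV_HETEROGENEITY_CUT = 0.30
MM3_PER_ML = 1000.0


@dataclass
class PetFeatures:
    suv_max: float
    suv_mean: float
    suv_sd: float
    suv_peak: float
    suv_max_location: tuple[float, float, float]   # world mm
    suv_peak_location: tuple[float, float, float]  # world mm
    mtv_ml: float
    tla: float            # SUV * mL
    cov: float
    heterogeneity: str    # homogeneous | heterogeneous


def _argmax_location(field: np.ndarray, mask: np.ndarray, grid: VoxelGrid):
    """Value and world coordinate of the mask-restricted arg-max.

    Ties break by lexicographic (C-order) voxel index, the first maximum
    encountered in a flat scan.
    """
    masked = np.where(mask, field, -np.inf)
    flat = int(np.argmax(masked))
    idx = np.unravel_index(flat, field.shape)
    value = float(field[idx])
    world = tuple(grid.world_coords(np.asarray(idx))[0])
    return value, world


def suv_statistics(grid: VoxelGrid, active_mask: np.ndarray):
    """(suv_max, suv_mean, sd, suv_max_location) over the active voxels.

    SD is the population convention (divide by N): COV describes the voxel
    set itself, not a sample estimate.
    """
    if not active_mask.any():
        raise ValueError("empty active mask")
    vox = grid.values[active_mask]
    suv_max, loc = _argmax_location(grid.values, active_mask, grid)
    return suv_max, float(vox.mean()), float(vox.std()), loc


def cov(sd: float, suv_mean: float) -> tuple[float, str]:
    """Coefficient of variation and its heterogeneity class."""
    if suv_mean <= 0:
        raise ValueError(f"suv_mean must be positive, got {suv_mean}")
    c = sd / suv_mean
    return c, "heterogeneous" if c >= COV_HETEROGENEITY_CUT else "homogeneous"


def suv_peak(grid: VoxelGrid, active_mask: np.ndarray):
    """SUVpeak and the cube-center location used for it.

    The kernel is defined on voxel indices (27 voxels), not physical mm, so
    anisotropic voxels still average exactly 27 neighbors.
    """
    if not active_mask.any():
        raise ValueError("empty active mask")
    filtered = ndimage.uniform_filter(grid.values, size=3, mode="constant", cval=0.0)
    return _argmax_location(filtered, active_mask, grid)


def mtv_tla(ls: LesionSet, lesion_id: int, suv_mean: float) -> tuple[float, float]:
    """Metabolic tumor volume (mL) and total lesion activity (SUV * mL)."""
    mtv = ls.lesions[lesion_id].n_active * ls.voxel_volume / MM3_PER_ML
    return mtv, suv_mean * mtv


def pet_features(grid: VoxelGrid, ls: LesionSet, lesion_id: int) -> PetFeatures:
    """All SUV-based metrics for one lesion."""
    lesion: Lesion = ls.lesions[lesion_id]
    suv_max, suv_mean, sd, max_loc = suv_statistics(grid, lesion.active_mask)
    peak, peak_loc = suv_peak(grid, lesion.active_mask)
    mtv, tla = mtv_tla(ls, lesion_id, suv_mean)
    c, het = cov(sd, suv_mean)
    return PetFeatures(suv_max=suv_max, suv_mean=suv_mean, suv_sd=sd,
                       suv_peak=peak, suv_max_location=max_loc,
                       suv_peak_location=peak_loc, mtv_ml=mtv, tla=tla,
                       cov=c, heterogeneity=het)
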