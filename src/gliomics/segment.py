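"""Threshold-based semiautomatic lesion segmentation.

Voxels at or above a threshold (absolute intensity, or a fraction of the
volume maximum) form the foreground; 26-connected components are the lesions.
Each lesion is partitioned into an *active* shell (above-threshold voxels)
and an *inner* region (enclosed holes — necrotic/non-enhancing tissue),
obtained by 6-connected hole filling. Multilesionality follows the
two-threshold rule: separate hypermetabolic foci that merge at a faint
background-level threshold are *multifocal*; foci that stay separate are
*multicentric*; both count as *multilesional*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage

from .io import Modality, VoxelGrid

log = logging.getLogger("gliomics")

DEFAULT_MIN_VOXELS = 10
DEFAULT_PET_FRACTION_OF_MAX = 0.40

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class Multilesionality(str, Enum):
    UNIFOCAL = "unifocal"
    MULTIFOCAL = "multifocal"
    MULTICENTRIC = "multicentric"

    @property
    def multilesional(self) -> bool:
        """Multifocal and multicentric jointly map to 'multilesional'."""
        return self is not Multilesionality.UNIFOCAL


@dataclass
class ThresholdRule:
    """Segmentation threshold: either an absolute intensity or a fraction of
    the volume maximum (exactly one must be set)."""

    absolute: float | None = None
    fraction_of_max: float | None = None

    def __post_init__(self) -> None:
        if (self.absolute is None) == (self.fraction_of_max is None):
            raise ValueError("specify exactly one of absolute / fraction_of_max")
        if self.fraction_of_max is not None and not (0 < self.fraction_of_max <= 1):
            raise ValueError("fraction_of_max must lie in (0, 1]")

    def resolve(self, grid: VoxelGrid) -> float:
        if self.absolute is not None:
            return float(self.absolute)
        return float(self.fraction_of_max * grid.values.max())


@dataclass
class Lesion:
    label: int
    active_mask: np.ndarray      # above-threshold voxels
    inner_mask: np.ndarray       # enclosed holes (necrotic / non-enhancing)

    @property
    def n_active(self) -> int:
        return int(self.active_mask.sum())

    @property
    def n_inner(self) -> int:
        return int(self.inner_mask.sum())

    @property
    def filled_mask(self) -> np.ndarray:
        return self.active_mask | self.inner_mask


@dataclass
class LesionSet:
    """Labeled segmentation of one volume."""

    label_map: np.ndarray        # 0 background, k = lesion k (active voxels)
    lesions: dict[int, Lesion]
    threshold: float
    modality: Modality
    voxel_volume: float          # mm^3
    classification: Multilesionality | None = None
    extras: dict = field(default_factory=dict)

    @property
    def labels(self) -> list[int]:
        return sorted(self.lesions)

    def lesion(self, label: int) -> Lesion:
        return self.lesions[label]

    @property
    def largest_lesion_id(self) -> int:
        return select_measurement_lesion(self)


def segment_threshold(grid: VoxelGrid, rule: ThresholdRule,
                      min_voxels: int = DEFAULT_MIN_VOXELS) -> LesionSet:
    """Segment a volume into lesions at a single threshold.

    Components (26-connectivity) with fewer than ``min_voxels`` active voxels
    are discarded. Labels are assigned by decreasing active size, label 1
    being the largest. Raises ``ValueError`` when no voxel reaches the
    threshold or no component survives the size filter.
    """
    threshold = rule.resolve(grid)
    fg = grid.values >= threshold
    if not fg.any():
        raise ValueError(f"no lesion above threshold {threshold:g}")
    labeled, n = ndimage.label(fg, structure=_STRUCT_26)
    sizes = ndimage.sum_labels(fg, labeled, index=np.arange(1, n + 1))
    keep = [(int(sz), old) for old, sz in zip(range(1, n + 1), sizes) if sz >= min_voxels]
    if not keep:
        raise ValueError(
            f"no component with >= {min_voxels} voxels above threshold {threshold:g}")
    # largest first; stable tie-break on original label order
    keep.sort(key=lambda t: (-t[0], t[1]))

    label_map = np.zeros(grid.values.shape, dtype=np.int32)
    lesions: dict[int, Lesion] = {}
    for new_label, (sz, old) in enumerate(keep, start=1):
        active = labeled == old
        filled = ndimage.binary_fill_holes(active)  # 6-connected background
        lesions[new_label] = Lesion(label=new_label, active_mask=active,
                                    inner_mask=filled & ~active)
        label_map[active] = new_label
        log.debug("lesion %d: N=%d, N_inner=%d", new_label, sz, lesions[new_label].n_inner)
    n_discarded = n - len(keep)
    if n_discarded:
        log.info("discarded %d component(s) below %d voxels", n_discarded, min_voxels)
    ls = LesionSet(label_map=label_map, lesions=lesions, threshold=threshold,
                   modality=grid.modality, voxel_volume=grid.voxel_volume)
    if len(lesions) == 1:
        ls.classification = Multilesionality.UNIFOCAL
    return ls


def estimate_background(grid: VoxelGrid, shell_voxels: int = 2) -> tuple[float, float]:
    """Mean and SD of intensity in a border shell of the volume.

    The faint-uptake threshold for the multifocal bridge test defaults to
    ``mean + 2*SD`` of this shell.
    """
    interior = np.zeros(grid.values.shape, dtype=bool)
    s = shell_voxels
    interior[s:-s, s:-s, s:-s] = True
    border = grid.values[~interior]
    return float(border.mean()), float(border.std())


def default_low_rule(grid: VoxelGrid, shell_voxels: int = 2) -> ThresholdRule:
    mean, sd = estimate_background(grid, shell_voxels)
    return ThresholdRule(absolute=mean + 2.0 * sd)


def classify_multilesionality(grid: VoxelGrid, high_rule: ThresholdRule,
                              low_rule: ThresholdRule | None = None,
                              min_voxels: int = DEFAULT_MIN_VOXELS) -> Multilesionality:
    """Classify a volume as unifocal / multifocal / multicentric.

    Foci are the components at the high (lesion-defining) threshold. With two
    or more foci, any pair sharing a component at the low (faint background
    uptake) threshold makes the tumor multifocal; otherwise multicentric.
    """
    if low_rule is None:
        low_rule = default_low_rule(grid)
    high = high_rule.resolve(grid)
    low = low_rule.resolve(grid)
    if not low < high:
        raise ValueError(f"low threshold {low:g} must be below high threshold {high:g}")
    foci = segment_threshold(grid, ThresholdRule(absolute=high), min_voxels)
    if len(foci.lesions) == 1:
        return Multilesionality.UNIFOCAL
    low_labeled, _ = ndimage.label(grid.values >= low, structure=_STRUCT_26)
    # low-threshold component hosting each focus (a focus sits inside exactly one)
    hosts = set()
    for lesion in foci.lesions.values():
        host_labels = np.unique(low_labeled[lesion.active_mask])
        hosts.add(int(host_labels.max()))
    if len(hosts) < len(foci.lesions):
        return Multilesionality.MULTIFOCAL
    return Multilesionality.MULTICENTRIC


def auto_mri_threshold(grid: VoxelGrid, n_candidates: int = 64,
                       min_voxels: int = DEFAULT_MIN_VOXELS) -> ThresholdRule:
    """Per-volume gray-level threshold maximizing the largest CE component.

    Deterministic stand-in for interactive contrast-enhancement delineation:
    candidate thresholds are scanned between the estimated background floor
    (border-shell mean + 2 SD) and the volume maximum, keeping the lowest
    threshold whose largest 26-connected component is maximal.
    """
    mean, sd = estimate_background(grid)
    floor = mean + 2.0 * sd
    top = float(grid.values.max())
    if floor >= top:
        raise ValueError("background floor reaches the volume maximum; no CE region")
    candidates = np.linspace(floor, top, n_candidates, endpoint=False)
    best_thr, best_size = None, -1
    for thr in candidates:
        fg = grid.values >= thr
        if not fg.any():
            break
        labeled, n = ndimage.label(fg, structure=_STRUCT_26)
        if n == 0:
            break
        largest = int(ndimage.sum_labels(fg, labeled, np.arange(1, n + 1)).max())
        if largest < min_voxels:
            continue
        if largest > best_size:
            best_size, best_thr = largest, float(thr)
    if best_thr is None:
        raise ValueError("no candidate threshold yields a component above min_voxels")
    return ThresholdRule(absolute=best_thr)


def select_measurement_lesion(ls: LesionSet) -> int:
    """Label of the largest lesion by filled volume ``(N + N') * Vv``.

    With multiple lesions, all per-lesion measures are computed on this one.
    Exact volume ties break to the lowest label.
    """
    if not ls.lesions:
        raise ValueError("empty LesionSet")
    return min(ls.labels, key=lambda k: (-(ls.lesions[k].n_active + ls.lesions[k].n_inner), k))
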