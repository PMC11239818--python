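"""Semi-automatic VOI refinement by histogram thresholding.

A reader first draws a rough envelope around the tumor across slices; the
analysis VOI is then the set of envelope voxels at or above a histogram
threshold computed from the envelope intensities (Otsu's criterion by
default, or a fixed quantile), with small speckle components removed.
Necrotic regions and clip artifacts are excluded afterwards, and when several
lesions are present the largest on DCE is taken as the index carcinoma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from deltarad.datatypes import VOIMask


@dataclass
class RoughContour:
    """Hand-drawn (or simulated) envelope containing the tumor voxels."""

    patient_id: str
    timepoint: str
    mask: np.ndarray
    reader_id: str = "truth"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("rough contour is empty")


@dataclass(frozen=True)
class SegmentationParams:
    """Threshold rule and speckle suppression for VOI refinement.

    ``min_component_voxels`` removes connected components (6-connectivity)
    smaller than the given size; default 5 suppresses isolated noise voxels.
    """

    threshold_method: str = "otsu"
    quantile: float = 0.5
    min_component_voxels: int = 5

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed_quantile"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed_quantile'")
        if not 0.0 < self.quantile < 1.0:
            raise ValueError("quantile must lie in (0, 1)")


def threshold_segment(
    volume: np.ndarray,
    rough: RoughContour,
    params: SegmentationParams = SegmentationParams(),
    threshold: float | None = None,
) -> VOIMask:
    """Refine a rough contour into the analysis VOI by histogram thresholding.

    The threshold is computed over the intensity histogram inside the rough
    contour (or passed explicitly via ``threshold``, which makes the
    operation idempotent on its own output). Voxels at or above the threshold
    are kept; components smaller than ``min_component_voxels`` are dropped. A
    constant-intensity envelope is degenerate and returned whole. If nothing
    survives, an empty VOI flagged for tumor-bed handling is returned.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.shape != rough.mask.shape:
        raise ValueError("volume and rough contour disagree in shape")
    inside = volume[rough.mask]
    if threshold is None:
        if np.ptp(inside) == 0:
            return VOIMask(rough.patient_id, rough.timepoint, rough.mask.copy(),
                           reader_id=rough.reader_id)
        if params.threshold_method == "otsu":
            threshold = float(threshold_otsu(inside))
        else:
            threshold = float(np.quantile(inside, params.quantile))
    refined = rough.mask & (volume >= threshold)
    refined = _drop_small_components(refined, params.min_component_voxels)
    return VOIMask(
        rough.patient_id,
        rough.timepoint,
        refined,
        reader_id=rough.reader_id,
        tumor_bed=not refined.any(),
    )


def _drop_small_components(mask: np.ndarray, min_voxels: int) -> np.ndarray:
    if min_voxels <= 1 or not mask.any():
        return mask
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_voxels
    keep[0] = False
    return keep[labels]


def exclude_regions(voi: VOIMask, exclusion: np.ndarray) -> VOIMask:
    """Remove necrotic regions / clip artifacts: voi AND NOT exclusion."""
    exclusion = np.asarray(exclusion, dtype=bool)
    if exclusion.shape != voi.mask.shape:
        raise ValueError("exclusion mask shape does not match VOI")
    remaining = voi.mask & ~exclusion
    return VOIMask(
        voi.patient_id,
        voi.timepoint,
        remaining,
        reader_id=voi.reader_id,
        repeat_index=voi.repeat_index,
        tumor_bed=voi.tumor_bed or not remaining.any(),
    )


def select_index_lesion(
    masks: list[VOIMask],
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> VOIMask:
    """Pick the index carcinoma: the largest candidate lesion on DCE.

    Volume is voxel count times voxel volume; ties are broken by the
    lexicographically smallest centroid so selection is deterministic.
    """
    if not masks:
        raise ValueError("no candidate lesions")
    voxvol = float(np.prod(voxel_spacing))

    def sort_key(m: VOIMask):
        if m.n_voxels == 0:
            centroid = (np.inf, np.inf, np.inf)
        else:
            centroid = tuple(np.mean(np.nonzero(m.mask), axis=1))
        return (-m.n_voxels * voxvol, centroid)

    return min(masks, key=sort_key)
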