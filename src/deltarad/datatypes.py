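"""Shared image-domain containers.

Array axis convention throughout the package: axes (i, j, k) where (i, j) are
in-plane (axial) and k indexes slices. ``voxel_spacing`` is the physical size
(mm) per axis in the same order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

TIMEPOINTS = ("BL", "C2", "C4")

SEQUENCES = ("DCE", "DWI")


@dataclass
class MRIStudy:
    """One patient-timepoint's aligned volumes.

    ``dce_subtraction`` is the 2.5-min post-contrast early-subtraction volume
    (arbitrary signal units); ``dwi_b100``/``dwi_b800`` are diffusion-weighted
    volumes at b = 100 and 800 s/mm2; ``adc`` is the apparent diffusion
    coefficient in mm2/s (NaN where undefined). ``dwi_b100`` and ``adc`` may be
    absent (``None``) when only the b = 800 volume was stored.
    """

    patient_id: str
    timepoint: str
    dce_subtraction: np.ndarray
    dwi_b800: np.ndarray
    voxel_spacing: tuple[float, float, float]
    dwi_b100: np.ndarray | None = None
    adc: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        shapes = {v.shape for v in self.volumes().values()}
        if len(shapes) != 1:
            raise ValueError(f"volumes of {self.patient_id}/{self.timepoint} disagree in shape: {shapes}")

    def volumes(self) -> dict[str, np.ndarray]:
        out = {"dce_subtraction": self.dce_subtraction, "dwi_b800": self.dwi_b800}
        if self.dwi_b100 is not None:
            out["dwi_b100"] = self.dwi_b100
        if self.adc is not None:
            out["adc"] = self.adc
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.dce_subtraction.shape

    def sequence_volume(self, sequence: str) -> np.ndarray:
        """Volume used for feature extraction: DCE -> early subtraction, DWI -> b800."""
        if sequence == "DCE":
            return self.dce_subtraction
        if sequence == "DWI":
            return self.dwi_b800
        raise ValueError(f"unknown sequence {sequence!r}; expected one of {SEQUENCES}")


@dataclass
class VOIMask:
    """Binary 3D tumor volume of interest tied to a study, reader and repeat.

    ``tumor_bed`` marks a mask contoured over the prior tumor bed after
    complete imaging response (the mask may then carry no visible tumor).
    """

    patient_id: str
    timepoint: str
    mask: np.ndarray
    reader_id: str = "truth"
    repeat_index: int = 0
    tumor_bed: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be a 3D volume")
        if self.n_voxels == 0 and not self.tumor_bed:
            raise ValueError(
                f"empty VOI for {self.patient_id}/{self.timepoint} without tumor_bed flag"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def volume_mm3(self, voxel_spacing: tuple[float, float, float]) -> float:
        return self.n_voxels * float(np.prod(voxel_spacing))


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary masks; 1.0 when both are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
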