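"""NIfTI-1 persistence of studies and masks.

Directory layout per cohort::

    cohort/<patient_id>/<timepoint>/dce_sub.nii.gz
                                    dwi_b100.nii.gz
                                    dwi_b800.nii.gz
                                    adc.nii.gz
                                    mask_r<reader>_k<repeat>.nii.gz

The affine is diagonal in the voxel spacing; volumes of one study must agree
in shape and affine, and a mismatch raises an error naming the offending
file. A study with no b=100 volume loads with ``dwi_b100`` and ``adc``
absent.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from deltarad.datatypes import MRIStudy, VOIMask

_VOLUME_FILES = {
    "dce_subtraction": "dce_sub.nii.gz",
    "dwi_b100": "dwi_b100.nii.gz",
    "dwi_b800": "dwi_b800.nii.gz",
    "adc": "adc.nii.gz",
}


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def study_dir(root: Path | str, patient_id: str, timepoint: str) -> Path:
    return Path(root) / patient_id / timepoint


def write_study(study: MRIStudy, root: Path | str) -> Path:
    """Write all present volumes of a study; returns the study directory."""
    out = study_dir(root, study.patient_id, study.timepoint)
    out.mkdir(parents=True, exist_ok=True)
    affine = _affine(study.voxel_spacing)
    for attr, fname in _VOLUME_FILES.items():
        volume = getattr(study, attr)
        if volume is None:
            continue
        nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine), out / fname)
    return out


def read_study(root: Path | str, patient_id: str, timepoint: str) -> MRIStudy:
    """Load a study, validating shape/affine consistency across volumes."""
    folder = study_dir(root, patient_id, timepoint)
    loaded: dict[str, np.ndarray] = {}
    shape = None
    affine = None
    ref_file = None
    for attr, fname in _VOLUME_FILES.items():
        path = folder / fname
        if not path.exists():
            continue
        img = nib.load(path)
        data = np.asarray(img.get_fdata())
        if shape is None:
            shape, affine, ref_file = data.shape, img.affine, path
        else:
            if data.shape != shape:
                raise ValueError(f"{path} shape {data.shape} mismatches {ref_file} shape {shape}")
            if not np.allclose(img.affine, affine):
                raise ValueError(f"{path} affine mismatches {ref_file}")
        loaded[attr] = data
    if "dce_subtraction" not in loaded or "dwi_b800" not in loaded:
        raise FileNotFoundError(f"study {patient_id}/{timepoint} lacks required volumes in {folder}")
    spacing = tuple(float(s) for s in np.abs(np.diag(affine)[:3]))
    return MRIStudy(
        patient_id=patient_id,
        timepoint=timepoint,
        dce_subtraction=loaded["dce_subtraction"],
        dwi_b800=loaded["dwi_b800"],
        dwi_b100=loaded.get("dwi_b100"),
        adc=loaded.get("adc"),
        voxel_spacing=spacing,
    )


def mask_filename(reader_id: str, repeat_index: int) -> str:
    return f"mask_r{reader_id}_k{repeat_index}.nii.gz"


def write_mask(mask: VOIMask, root: Path | str,
               voxel_spacing: tuple[float, float, float]) -> Path:
    out = study_dir(root, mask.patient_id, mask.timepoint)
    out.mkdir(parents=True, exist_ok=True)
    path = out / mask_filename(mask.reader_id, mask.repeat_index)
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), _affine(voxel_spacing))
    img.header["descrip"] = b"tumor_bed" if mask.tumor_bed else b""
    nib.save(img, path)
    return path


def read_mask(root: Path | str, patient_id: str, timepoint: str,
              reader_id: str = "truth", repeat_index: int = 0,
              expected_shape: tuple[int, ...] | None = None) -> VOIMask:
    path = study_dir(root, patient_id, timepoint) / mask_filename(reader_id, repeat_index)
    img = nib.load(path)
    data = np.asarray(img.get_fdata()) > 0.5
    if expected_shape is not None and data.shape != expected_shape:
        raise ValueError(f"{path} shape {data.shape} mismatches study shape {expected_shape}")
    tumor_bed = img.header["descrip"].tobytes().startswith(b"tumor_bed")
    return VOIMask(patient_id, timepoint, data, reader_id=reader_id,
                   repeat_index=repeat_index, tumor_bed=tumor_bed or not data.any())
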