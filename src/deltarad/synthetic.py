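"""Synthetic longitudinal breast-MRI cohort generator.

The generator emulates the statistical structure the downstream analysis
assumes, for a cohort of patients imaged at baseline (BL) and after 2 (C2)
and 4 (C4) cycles of neoadjuvant systemic therapy:

* a binary pathologic-complete-response (pCR) label at a configurable
  prevalence (default 78/163, i.e. ~48%);
* ellipsoidal tumors whose volume and interior texture heterogeneity decrease
  across BL -> C2 -> C4, with larger per-cycle-pair decreases for pCR
  patients (responders shrink and homogenize more);
* DCE early-subtraction and DWI b=100/b=800 volumes with spatially correlated
  interior texture (Gaussian-smoothed white noise) plus additive acquisition
  noise, and an ADC map derived from the DWI pair through the
  mono-exponential model;
* two-or-more simulated readers producing perturbed contours with repeat
  contours per reader, for inter-/intrareader agreement analysis;
* clinical covariates drawn from realistic category frequencies for
  stage I-III triple-negative breast cancer, independent of the label.

Determinism: every random draw is keyed by (seed, stream, patient index
[, timepoint index]) through ``numpy.random.SeedSequence``, so the same
config and seed reproduce the cohort bitwise and adding patients does not
reshuffle existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from deltarad.datatypes import TIMEPOINTS, MRIStudy, VOIMask

# Clinical covariate categories with cohort frequencies (counts out of 163)
# typical of a stage I-III TNBC neoadjuvant-therapy population.
CLINICAL_CATEGORIES: dict[str, dict[str, int]] = {
    "histology": {
        "Invasive ductal carcinoma": 146,
        "Metaplastic": 11,
        "Invasive mammary carcinoma": 3,
        "Poorly differentiated carcinoma": 2,
        "Apocrine": 1,
    },
    "clinical_stage": {"I": 22, "II": 114, "III": 27},
    "t_category": {"T1": 31, "T2": 112, "T3": 18, "T4": 2},
    "n_category": {"N0": 108, "N1": 36, "N2": 7, "N3": 12},
    "surgery": {"Breast-conserving surgery": 96, "Total mastectomy": 67},
}

# Stream ids for SeedSequence keying.
_STREAM_COHORT = 0
_STREAM_PATIENT = 1
_STREAM_STUDY = 2
_STREAM_READER = 3


@dataclass(frozen=True)
class ResponseEffect:
    """Effect sizes separating pCR from non-pCR tumor trajectories.

    ``volume_shrink_*`` multiply tumor volume per cycle pair (BL->C2, C2->C4);
    ``texture_homogenize_*`` multiply the interior texture standard deviation
    per cycle pair. Factors lie in (0, 1]; pCR factors must not exceed the
    non-pCR ones (responders shrink/homogenize at least as much).
    ``noise_sd`` is the additive acquisition-noise scale (signal units) and
    ``necrosis_prob`` the fraction of tumors given a low-signal necrotic core.
    """

    volume_shrink_pcr: float = 0.45
    volume_shrink_nonpcr: float = 0.80
    texture_homogenize_pcr: float = 0.60
    texture_homogenize_nonpcr: float = 0.90
    noise_sd: float = 8.0
    necrosis_prob: float = 0.10

    def __post_init__(self) -> None:
        for name in ("volume_shrink_pcr", "volume_shrink_nonpcr",
                     "texture_homogenize_pcr", "texture_homogenize_nonpcr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.volume_shrink_pcr > self.volume_shrink_nonpcr:
            raise ValueError("pCR volume-shrink factor must be <= non-pCR factor")
        if self.texture_homogenize_pcr > self.texture_homogenize_nonpcr:
            raise ValueError("pCR texture-homogenize factor must be <= non-pCR factor")
        if not 0.0 <= self.necrosis_prob <= 1.0:
            raise ValueError("necrosis_prob must lie in [0, 1]")

    def shrink(self, pcr: bool) -> float:
        return self.volume_shrink_pcr if pcr else self.volume_shrink_nonpcr

    def homogenize(self, pcr: bool) -> float:
        return self.texture_homogenize_pcr if pcr else self.texture_homogenize_nonpcr


def null_effect(effect: ResponseEffect | None = None) -> ResponseEffect:
    """Signal-removed variant: both groups get the non-pCR trajectory."""
    effect = effect or ResponseEffect()
    return replace(
        effect,
        volume_shrink_pcr=effect.volume_shrink_nonpcr,
        texture_homogenize_pcr=effect.texture_homogenize_nonpcr,
    )


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of the simulated cohort.

    Geometry defaults mirror a clinical axial breast protocol: ~1.06 mm
    in-plane spacing with 3 mm slices. ``base_radius_mm`` is the median BL
    in-plane tumor semi-axis; per-patient log-normal jitter terms
    (``radius_jitter``, ``texture_jitter``, ``factor_jitter``) spread tumor
    size, heterogeneity and response factors across patients so group overlap
    is realistic rather than deterministic.
    """

    n_patients: int = 163
    pcr_fraction: float = 78 / 163
    timepoints: tuple[str, ...] = TIMEPOINTS
    grid_shape: tuple[int, int, int] = (44, 44, 20)
    voxel_spacing: tuple[float, float, float] = (1.0625, 1.0625, 3.0)
    effect: ResponseEffect = field(default_factory=ResponseEffect)
    seed: int = 0
    base_radius_mm: float = 10.0
    radius_jitter: float = 0.25
    base_texture_sd: float = 40.0
    texture_jitter: float = 0.25
    factor_jitter: float = 0.30
    correlation_length_mm: float = 2.5
    base_intensity: float = 200.0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0.0 < self.pcr_fraction < 1.0:
            raise ValueError("pcr_fraction must lie strictly in (0, 1)")
        if any(s < 16 for s in self.grid_shape):
            raise ValueError("grid_shape must be >= 16 voxels per axis")
        unknown = set(self.timepoints) - set(TIMEPOINTS)
        if unknown:
            raise ValueError(f"unknown timepoints {sorted(unknown)}")


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    index: int
    pcr_label: int
    age: int
    clinical_stage: str
    t_category: str
    n_category: str
    histology: str
    surgery: str


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(k) for k in key]))


def generate_cohort(config: CohortConfig) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Draw patient records and the clinical table.

    Exactly ``round(n_patients * pcr_fraction)`` patients receive the pCR
    label, assigned by a seeded permutation. Clinical covariates are sampled
    from the category frequencies independent of the label.
    """
    n = config.n_patients
    n_pcr = int(np.floor(n * config.pcr_fraction + 0.5))
    if n_pcr == 0 or n_pcr == n:
        raise ValueError("pcr_fraction leaves one class empty at this cohort size")
    rng = _rng(config.seed, _STREAM_COHORT)
    labels = np.zeros(n, dtype=int)
    labels[rng.permutation(n)[:n_pcr]] = 1

    records = []
    for idx in range(n):
        prng = _rng(config.seed, _STREAM_PATIENT, idx)
        covariates = {}
        for var, table in CLINICAL_CATEGORIES.items():
            cats = list(table)
            probs = np.array(list(table.values()), dtype=float)
            covariates[var] = cats[prng.choice(len(cats), p=probs / probs.sum())]
        age = int(np.clip(np.round(prng.normal(49, 11)), 23, 78))
        records.append(
            PatientRecord(
                patient_id=f"P{idx:03d}",
                index=idx,
                pcr_label=int(labels[idx]),
                age=age,
                **covariates,
            )
        )
    clinical = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "pcr": [r.pcr_label for r in records],
            "age": [r.age for r in records],
            "clinical_stage": [r.clinical_stage for r in records],
            "t_category": [r.t_category for r in records],
            "n_category": [r.n_category for r in records],
            "histology": [r.histology for r in records],
            "surgery": [r.surgery for r in records],
        }
    )
    return records, clinical


@dataclass
class StudyTruth:
    """Ground-truth companions of one simulated study."""

    mask: np.ndarray
    necrosis: np.ndarray | None
    tumor_bed: bool
    radius_mm: tuple[float, float, float]
    texture_sd: float
    center_mm: tuple[float, float, float]


def _patient_params(patient: PatientRecord, config: CohortConfig) -> dict:
    rng = _rng(config.seed, _STREAM_PATIENT, patient.index, 1)
    eff = config.effect
    pcr = bool(patient.pcr_label)
    r0 = config.base_radius_mm * rng.lognormal(0.0, config.radius_jitter)
    sd0 = config.base_texture_sd * rng.lognormal(0.0, config.texture_jitter)
    shrink = float(np.clip(eff.shrink(pcr) * rng.lognormal(0.0, config.factor_jitter), 0.02, 1.0))
    homog = float(np.clip(eff.homogenize(pcr) * rng.lognormal(0.0, config.factor_jitter), 0.05, 1.0))
    center = np.array(config.grid_shape, dtype=float) / 2.0
    center += rng.uniform(-1.5, 1.5, size=3)
    center_mm = center * np.asarray(config.voxel_spacing)
    necrotic = bool(rng.uniform() < eff.necrosis_prob)
    adc0 = rng.normal(0.95e-3, 0.08e-3)
    return {
        "r0": r0, "sd0": sd0, "shrink": shrink, "homog": homog,
        "center_mm": center_mm, "necrotic": necrotic, "adc0": abs(adc0),
    }


def _ellipsoid_mask(config: CohortConfig, center_mm: np.ndarray,
                    radii_mm: np.ndarray) -> np.ndarray:
    spacing = np.asarray(config.voxel_spacing)
    coords = [np.arange(s) * sp for s, sp in zip(config.grid_shape, spacing)]
    di = (coords[0] - center_mm[0]) / radii_mm[0]
    dj = (coords[1] - center_mm[1]) / radii_mm[1]
    dk = (coords[2] - center_mm[2]) / radii_mm[2]
    return (
        di[:, None, None] ** 2 + dj[None, :, None] ** 2 + dk[None, None, :] ** 2
    ) <= 1.0


def _correlated_field(rng: np.random.Generator, shape: tuple[int, ...],
                      spacing: np.ndarray, length_mm: float) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation length."""
    sigma_vox = np.maximum(length_mm / spacing, 1e-6)
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)
    sd = field.std()
    return field / sd if sd > 0 else field


def compute_adc(
    s_low: np.ndarray,
    s_high: np.ndarray,
    b_low: float,
    b_high: float,
) -> np.ndarray:
    """ADC map from two diffusion-weighted volumes via the mono-exponential model.

    ADC = ln(S_low / S_high) / (b_high - b_low), in mm2/s when b-values are in
    s/mm2. Voxels where either signal is non-positive are returned as NaN
    (flagged) rather than raising.
    """
    if b_high <= b_low or b_low < 0:
        raise ValueError("require b_high > b_low >= 0")
    s_low = np.asarray(s_low, dtype=float)
    s_high = np.asarray(s_high, dtype=float)
    if s_low.shape != s_high.shape:
        raise ValueError("DWI volumes disagree in shape")
    valid = (s_low > 0) & (s_high > 0)
    adc = np.full(s_low.shape, np.nan)
    adc[valid] = np.log(s_low[valid] / s_high[valid]) / (b_high - b_low)
    return adc


def simulate_study(
    patient: PatientRecord,
    timepoint: str,
    config: CohortConfig,
    with_truth: bool = False,
) -> MRIStudy | tuple[MRIStudy, StudyTruth]:
    """Simulate one patient-timepoint's aligned DCE/DWI/ADC volumes.

    The tumor is an ellipsoid whose volume is scaled by the cumulative
    per-cycle-pair shrink factor and whose interior texture standard
    deviation is scaled by the cumulative homogenize factor. The ADC volume
    is computed from the generated b=100/b=800 pair with
    :func:`compute_adc`. When the tumor shrinks below the voxel scale the
    study is flagged for tumor-bed contouring and a small fixed-radius bed
    mask at the prior tumor centroid is returned as truth.
    """
    if timepoint not in config.timepoints:
        raise ValueError(f"timepoint {timepoint!r} not in config.timepoints")
    t_index = TIMEPOINTS.index(timepoint)
    params = _patient_params(patient, config)
    spacing = np.asarray(config.voxel_spacing)
    rng = _rng(config.seed, _STREAM_STUDY, patient.index, t_index)

    radius_factor = params["shrink"] ** (t_index / 3.0)  # volume factor^(1/3) per pair
    r_inplane = params["r0"] * radius_factor
    radii = np.array([r_inplane, r_inplane, 0.65 * r_inplane])
    texture_sd = params["sd0"] * params["homog"] ** t_index

    tumor_bed = bool(r_inplane < max(config.voxel_spacing[0], 1.0))
    if tumor_bed:
        # vanished tumor: contour a 4 mm bed at the prior centroid
        mask = _ellipsoid_mask(config, params["center_mm"], np.array([4.0, 4.0, 4.0]))
    else:
        mask = _ellipsoid_mask(config, params["center_mm"], radii)
    if not mask.any():
        mask = _ellipsoid_mask(config, params["center_mm"], np.maximum(radii, spacing))
        tumor_bed = True

    noise_sd = config.effect.noise_sd
    shape = config.grid_shape

    def _standardized_in_mask(field: np.ndarray) -> np.ndarray:
        # a correlated field's sample s.d. inside a small mask strays far
        # from its global scale; standardize within the mask so the
        # constructed interior texture s.d. is exact
        g = field[mask]
        sd = g.std()
        return (g - g.mean()) / sd if sd > 0 else g - g.mean()

    texture = _correlated_field(rng, shape, spacing, config.correlation_length_mm)
    dce = rng.normal(10.0, noise_sd * 0.5, size=shape)
    if not tumor_bed:
        dce[mask] = (
            config.base_intensity * radius_factor**0.5
            + texture_sd * _standardized_in_mask(texture)
            + rng.normal(0.0, noise_sd, size=int(mask.sum()))
        )

    necrosis = None
    if params["necrotic"] and not tumor_bed:
        necrosis = _ellipsoid_mask(config, params["center_mm"], np.maximum(radii * 0.3, 0.5))
        dce[necrosis] = rng.normal(15.0, noise_sd * 0.5, size=int(necrosis.sum()))

    # DWI: tumor restricts diffusion (high b800 signal); texture shares the
    # patient's homogenization trajectory through its own correlated field.
    dwi_texture = _correlated_field(rng, shape, spacing, config.correlation_length_mm)
    s100 = rng.normal(60.0, noise_sd * 0.5, size=shape)
    adc_true = np.full(shape, 1.9e-3) + 1e-4 * _correlated_field(
        rng, shape, spacing, config.correlation_length_mm
    )
    if not tumor_bed:
        dwi_g = _standardized_in_mask(dwi_texture)
        s100[mask] = (
            420.0 * radius_factor**0.5
            + 2.0 * texture_sd * dwi_g
            + rng.normal(0.0, noise_sd, size=int(mask.sum()))
        )
        adc_true[mask] = params["adc0"] + 1e-4 * dwi_g
    if necrosis is not None:
        s100[necrosis] = rng.normal(80.0, noise_sd * 0.5, size=int(necrosis.sum()))
        adc_true[necrosis] = 2.2e-3
    np.clip(s100, 1.0, None, out=s100)
    np.clip(adc_true, 1e-4, None, out=adc_true)
    s800 = s100 * np.exp(-adc_true * 700.0)

    study = MRIStudy(
        patient_id=patient.patient_id,
        timepoint=timepoint,
        dce_subtraction=dce,
        dwi_b100=s100,
        dwi_b800=s800,
        adc=compute_adc(s100, s800, 100.0, 800.0),
        voxel_spacing=tuple(config.voxel_spacing),
    )
    if not with_truth:
        return study
    truth = StudyTruth(
        mask=mask,
        necrosis=necrosis,
        tumor_bed=tumor_bed,
        radius_mm=tuple(np.array([4.0, 4.0, 4.0]) if tumor_bed else radii),
        texture_sd=float(texture_sd),
        center_mm=tuple(params["center_mm"]),
    )
    return study, truth


def _signed_distance_mm(mask: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """Positive inside the mask, negative outside, in millimetres."""
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return inside - outside


def simulate_reader_masks(
    true_mask: VOIMask,
    jitter: float,
    n_readers: int = 2,
    n_repeats: int = 2,
    seed: int = 0,
    jitter_intra: float | None = None,
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    boundary_length_mm: float = 4.0,
) -> list[VOIMask]:
    """Simulate readers re-contouring a tumor with boundary perturbations.

    Each reader carries a smooth per-reader bias field scaled by ``jitter``
    (mm of boundary displacement, the inter-reader scale); each repeat adds an
    independent smooth field scaled by ``jitter_intra`` (default: equal to
    ``jitter``). The inter-reader scale must be at least the intra-reader
    scale. A mask voxel is kept where signed distance plus perturbation stays
    positive, so ``jitter = jitter_intra = 0`` reproduces the truth exactly and
    Dice overlap with the truth decreases as jitter grows.
    """
    if jitter_intra is None:
        jitter_intra = jitter
    if jitter < 0 or jitter_intra < 0:
        raise ValueError("jitter scales must be non-negative")
    if jitter < jitter_intra:
        raise ValueError("inter-reader jitter must be >= intra-reader jitter")
    if true_mask.n_voxels == 0 and not true_mask.tumor_bed:
        raise ValueError("cannot perturb an empty truth mask")
    spacing = np.asarray(voxel_spacing, dtype=float)
    sdist = _signed_distance_mm(true_mask.mask, spacing)
    out = []
    for r in range(n_readers):
        reader_rng = _rng(seed, _STREAM_READER, r)
        bias = jitter * _correlated_field(reader_rng, true_mask.mask.shape, spacing,
                                          boundary_length_mm)
        for k in range(n_repeats):
            repeat_rng = _rng(seed, _STREAM_READER, r, k + 1)
            wobble = jitter_intra * _correlated_field(
                repeat_rng, true_mask.mask.shape, spacing, boundary_length_mm
            )
            mask = (sdist + bias + wobble) > 0
            out.append(
                VOIMask(
                    patient_id=true_mask.patient_id,
                    timepoint=true_mask.timepoint,
                    mask=mask,
                    reader_id=f"R{r + 1}",
                    repeat_index=k,
                    tumor_bed=true_mask.tumor_bed or not mask.any(),
                )
            )
    return out
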