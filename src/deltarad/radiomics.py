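"""First-order and gray-level co-occurrence matrix (GLCM) feature extraction.

Each volume of interest yields 310 features per MRI sequence: 10 first-order
statistics of the raw VOI intensities (minimum, maximum, mean, standard
deviation, skewness, excess kurtosis, and the 1st/5th/95th/99th percentiles)
plus 25 Haralick-style GLCM statistics at each of 12 co-occurrence offsets
(distances 1-3 voxels along the four in-plane directions), i.e. 300 texture
features. Co-occurrence is accumulated per axial slice because clinical breast
protocols have slice thickness several times the in-plane spacing; a 13
direction 3D mode is available through :class:`GLCMConfig`.

Gray levels are quantized to a fixed bin count over the VOI min-max range
before co-occurrence counting, so GLCM features are invariant to affine
intensity rescaling of the volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from deltarad.datatypes import MRIStudy, VOIMask

FIRST_ORDER_NAMES = (
    "firstorder_minimum",
    "firstorder_maximum",
    "firstorder_mean",
    "firstorder_stddev",
    "firstorder_kurtosis",
    "firstorder_skewness",
    "firstorder_p1",
    "firstorder_p5",
    "firstorder_p95",
    "firstorder_p99",
)

#: The 25 GLCM statistics computed per offset (textbook formulas; see
#: :func:`glcm_statistics`).
GLCM_STATISTIC_NAMES = (
    "autocorrelation",
    "joint_average",
    "cluster_prominence",
    "cluster_shade",
    "cluster_tendency",
    "contrast",
    "correlation",
    "difference_average",
    "difference_entropy",
    "difference_variance",
    "joint_energy",
    "joint_entropy",
    "imc1",
    "imc2",
    "idm",
    "idmn",
    "id",
    "idn",
    "inverse_variance",
    "maximum_probability",
    "sum_average",
    "sum_entropy",
    "sum_squares",
    "dissimilarity",
    "homogeneity",
)

#: In-plane offsets (di, dj) applied per axial slice; conventional 0/45/90/135
#: degree set. Direction index a0..a3 follows this order.
DIRECTIONS_2D = ((1, 0), (0, 1), (1, 1), (1, -1))

#: The 13 unique 3D directions (half of the 26-neighborhood).
DIRECTIONS_3D = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)


@dataclass(frozen=True)
class QuantizationParams:
    """Fixed-bin-count gray-level quantization over the VOI min-max range."""

    n_levels: int = 32

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")


@dataclass(frozen=True)
class GLCMConfig:
    """Offsets and statistics for co-occurrence texture features.

    Defaults produce 25 statistics x 3 distances x 4 in-plane directions = 300
    features, each offset reported separately.
    """

    distances: tuple[int, ...] = (1, 2, 3)
    directions: tuple[tuple[int, ...], ...] = DIRECTIONS_2D
    symmetric: bool = True
    statistics: tuple[str, ...] = GLCM_STATISTIC_NAMES

    def __post_init__(self) -> None:
        unknown = set(self.statistics) - set(GLCM_STATISTIC_NAMES)
        if unknown:
            raise ValueError(f"unknown GLCM statistics: {sorted(unknown)}")

    @property
    def n_features(self) -> int:
        return len(self.distances) * len(self.directions) * len(self.statistics)

    def feature_names(self) -> list[str]:
        return [
            f"glcm_{stat}_d{d}_a{a}"
            for d in self.distances
            for a in range(len(self.directions))
            for stat in self.statistics
        ]


@dataclass
class FeatureVector:
    """Named feature values for one (patient, block label, sequence).

    ``label`` is a raw timepoint (``BL``/``C2``/``C4``) or a delta label such
    as ``RD_C2-BL``. Missing features are NaN.
    """

    patient_id: str
    label: str
    sequence: str
    values: dict[str, float]

    def __len__(self) -> int:
        return len(self.values)

    def same_schema(self, other: "FeatureVector") -> bool:
        return list(self.values) == list(other.values)


def first_order_features(intensities: np.ndarray) -> dict[str, float]:
    """The 10 first-order statistics of the VOI intensity multiset.

    Standard deviation uses the n-1 denominator; skewness is the standardized
    third moment and kurtosis is Fisher excess (normal -> 0); both are set to
    0.0 by convention for constant input where they are undefined. Percentiles
    interpolate linearly between order statistics. Empty input yields NaNs.
    """
    v = np.asarray(intensities, dtype=float).ravel()
    if v.size == 0:
        return {name: float("nan") for name in FIRST_ORDER_NAMES}
    p1, p5, p95, p99 = np.percentile(v, [1, 5, 95, 99])
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    if sd > 0:
        skew = float(sps.skew(v, bias=True))
        kurt = float(sps.kurtosis(v, fisher=True, bias=True))
    else:
        skew = 0.0
        kurt = 0.0
    return {
        "firstorder_minimum": float(v.min()),
        "firstorder_maximum": float(v.max()),
        "firstorder_mean": float(v.mean()),
        "firstorder_stddev": sd,
        "firstorder_kurtosis": kurt,
        "firstorder_skewness": skew,
        "firstorder_p1": float(p1),
        "firstorder_p5": float(p5),
        "firstorder_p95": float(p95),
        "firstorder_p99": float(p99),
    }


def quantize(
    volume: np.ndarray,
    voi: VOIMask | np.ndarray,
    params: QuantizationParams = QuantizationParams(),
) -> np.ndarray:
    """Quantize VOI voxels to integer gray levels 1..n_levels (0 outside).

    Equal-width bins span [VOI min, VOI max]; the maximum maps to level
    ``n_levels``. A constant VOI collapses to a single level (level 1).
    """
    mask = voi.mask if isinstance(voi, VOIMask) else np.asarray(voi, dtype=bool)
    if not mask.any():
        raise ValueError("cannot quantize an empty VOI")
    volume = np.asarray(volume, dtype=float)
    vals = volume[mask]
    lo, hi = float(vals.min()), float(vals.max())
    out = np.zeros(volume.shape, dtype=np.int64)
    if hi <= lo:
        out[mask] = 1
        return out
    levels = np.floor((vals - lo) / (hi - lo) * params.n_levels).astype(np.int64) + 1
    np.clip(levels, 1, params.n_levels, out=levels)
    out[mask] = levels
    return out


def glcm_matrix(
    quantized: np.ndarray,
    offset: tuple[int, ...],
    n_levels: int,
    symmetric: bool = True,
) -> np.ndarray | None:
    """Normalized co-occurrence matrix of a quantized VOI at one voxel offset.

    ``quantized`` holds levels 1..n_levels inside the VOI and 0 outside; a
    pair is counted only when both voxels lie inside. A 2-component offset
    (di, dj) pairs voxels within each axial slice; a 3-component offset adds a
    slice step. Returns None when the offset yields no valid pair.
    """
    if len(offset) == 2:
        offset = (offset[0], offset[1], 0)
    oi, oj, ok = offset
    shape = quantized.shape
    src = tuple(slice(max(0, -o), s - max(0, o)) for o, s in zip((oi, oj, ok), shape))
    dst = tuple(slice(max(0, o), s - max(0, -o)) for o, s in zip((oi, oj, ok), shape))
    a = quantized[src]
    b = quantized[dst]
    valid = (a > 0) & (b > 0)
    if not valid.any():
        return None
    x = a[valid] - 1
    y = b[valid] - 1
    counts = np.bincount(x * n_levels + y, minlength=n_levels * n_levels).astype(float)
    counts = counts.reshape(n_levels, n_levels)
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


def glcm_statistics(matrix: np.ndarray | None) -> dict[str, float]:
    """The 25 GLCM statistics of a normalized co-occurrence matrix.

    Levels are indexed 1..L. Entropies use log base 2. Degenerate cases take
    their analytic limits: correlation of a zero-variance matrix is 1,
    information measures of correlation default to 0 when marginal entropy
    vanishes. ``None`` (no valid pairs) yields all-NaN.
    """
    if matrix is None:
        return {name: float("nan") for name in GLCM_STATISTIC_NAMES}
    P = np.asarray(matrix, dtype=float)
    L = P.shape[0]
    i = np.arange(1, L + 1, dtype=float)
    I = i[:, None]
    J = i[None, :]
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mux = float(np.dot(i, px))
    muy = float(np.dot(i, py))
    varx = float(np.dot((i - mux) ** 2, px))
    vary = float(np.dot((i - muy) ** 2, py))
    diff = np.abs(I - J)
    ssum = I + J

    # p_{x+y}(k), k = 2..2L and p_{x-y}(k), k = 0..L-1
    p_sum = np.bincount(ssum.astype(int).ravel(), weights=P.ravel(), minlength=2 * L + 1)[2:]
    p_diff = np.bincount(diff.astype(int).ravel(), weights=P.ravel(), minlength=L)[:L]
    k_sum = np.arange(2, 2 * L + 1, dtype=float)
    k_diff = np.arange(L, dtype=float)

    def entropy(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    pos = P > 0
    hxy = entropy(P.ravel())
    hx = entropy(px)
    hy = entropy(py)
    pxy = px[:, None] * py[None, :]
    with np.errstate(divide="ignore"):
        log_pxy = np.where(pxy > 0, np.log2(np.where(pxy > 0, pxy, 1.0)), 0.0)
    hxy1 = float(-(P[pos] * log_pxy[pos]).sum())
    hxy2 = entropy(pxy.ravel())

    if max(hx, hy) > 0:
        imc1 = (hxy - hxy1) / max(hx, hy)
    else:
        imc1 = 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    sig = np.sqrt(varx * vary)
    if sig > 0:
        correlation = (float((I * J * P).sum()) - mux * muy) / sig
    else:
        correlation = 1.0

    diff_avg = float(np.dot(k_diff, p_diff))
    off_diag = diff > 0
    inv_var = float((P[off_diag] / (I - J)[off_diag] ** 2).sum())

    return {
        "autocorrelation": float((I * J * P).sum()),
        "joint_average": mux,
        "cluster_prominence": float(((ssum - mux - muy) ** 4 * P).sum()),
        "cluster_shade": float(((ssum - mux - muy) ** 3 * P).sum()),
        "cluster_tendency": float(((ssum - mux - muy) ** 2 * P).sum()),
        "contrast": float(((I - J) ** 2 * P).sum()),
        "correlation": correlation,
        "difference_average": diff_avg,
        "difference_entropy": entropy(p_diff),
        "difference_variance": float(np.dot((k_diff - diff_avg) ** 2, p_diff)),
        "joint_energy": float((P**2).sum()),
        "joint_entropy": hxy,
        "imc1": float(imc1),
        "imc2": imc2,
        "idm": float((P / (1.0 + (I - J) ** 2)).sum()),
        "idmn": float((P / (1.0 + ((I - J) / L) ** 2)).sum()),
        "id": float((P / (1.0 + diff)).sum()),
        "idn": float((P / (1.0 + diff / L)).sum()),
        "inverse_variance": inv_var,
        "maximum_probability": float(P.max()),
        "sum_average": float(np.dot(k_sum, p_sum)),
        "sum_entropy": entropy(p_sum),
        "sum_squares": float(((I - mux) ** 2 * P).sum()),
        "dissimilarity": float((diff * P).sum()),
        "homogeneity": float((P / (1.0 + (I - J) ** 2)).sum()),
    }


def glcm_features(
    volume: np.ndarray,
    voi: VOIMask | np.ndarray,
    quant: QuantizationParams = QuantizationParams(),
    config: GLCMConfig = GLCMConfig(),
) -> dict[str, float]:
    """All GLCM features of one VOI on one volume (300 under defaults)."""
    quantized = quantize(volume, voi, quant)
    out: dict[str, float] = {}
    for d in config.distances:
        for a, direction in enumerate(config.directions):
            offset = tuple(int(c) * d for c in direction)
            mat = glcm_matrix(quantized, offset, quant.n_levels, config.symmetric)
            stats = glcm_statistics(mat)
            for stat in config.statistics:
                out[f"glcm_{stat}_d{d}_a{a}"] = stats[stat]
    return out


def extract_feature_vector(
    study: MRIStudy,
    voi: VOIMask,
    sequence: str,
    quant: QuantizationParams = QuantizationParams(),
    config: GLCMConfig = GLCMConfig(),
) -> FeatureVector:
    """Extract the full 310-feature vector for one sequence of one study.

    DCE features come from the early-subtraction volume and DWI features from
    the b = 800 volume. An empty VOI yields an all-NaN vector rather than an
    error so that vanished tumors propagate as missing values.
    """
    volume = study.sequence_volume(sequence)
    if voi.mask.shape != volume.shape:
        raise ValueError("VOI shape does not match study volumes")
    if voi.n_voxels == 0:
        names = list(FIRST_ORDER_NAMES) + config.feature_names()
        return FeatureVector(study.patient_id, study.timepoint, sequence,
                             {n: float("nan") for n in names})
    values = first_order_features(volume[voi.mask])
    values.update(glcm_features(volume, voi, quant, config))
    return FeatureVector(study.patient_id, study.timepoint, sequence, values)
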