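"""Delta radiomics: between-timepoint feature differences.

For an ordered timepoint pair (early, late) each feature yields an absolute
difference AD = late - early and a relative difference
RD = (late - early) / |early|, the standard sign-preserving delta-radiomics
definitions. Missing values propagate feature-wise: a feature missing at
either timepoint (or an early value at zero, for RD) is missing in the delta,
while the patient's other features are unaffected.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from deltarad.radiomics import FeatureVector

#: Ordered timepoint pairs (late, early) for which deltas are formed.
DELTA_PAIRS = (("C2", "BL"), ("C4", "BL"), ("C4", "C2"))

DELTA_MODES = ("AD", "RD")


def delta_label(mode: str, late: str, early: str) -> str:
    """Block label for a delta, e.g. ``RD_C2-BL``."""
    if mode not in DELTA_MODES:
        raise ValueError(f"mode must be one of {DELTA_MODES}")
    return f"{mode}_{late}-{early}"


def _check_pair(fv_late: FeatureVector, fv_early: FeatureVector) -> None:
    if fv_late.patient_id != fv_early.patient_id:
        raise ValueError("delta requires feature vectors of the same patient")
    if fv_late.sequence != fv_early.sequence:
        raise ValueError("delta requires feature vectors of the same sequence")
    if not fv_late.same_schema(fv_early):
        raise ValueError("feature schemas differ between timepoints")


def absolute_difference(fv_late: FeatureVector, fv_early: FeatureVector) -> FeatureVector:
    """AD = late - early per feature; missing in either propagates."""
    _check_pair(fv_late, fv_early)
    values = {
        name: fv_late.values[name] - fv_early.values[name]
        for name in fv_late.values
    }
    return FeatureVector(
        fv_late.patient_id,
        delta_label("AD", fv_late.label, fv_early.label),
        fv_late.sequence,
        values,
    )


def relative_difference(
    fv_late: FeatureVector,
    fv_early: FeatureVector,
    epsilon: float = 1e-12,
) -> FeatureVector:
    """RD = (late - early) / |early| per feature.

    Early values within ``epsilon`` of zero yield a missing delta (NaN)
    rather than an infinity.
    """
    _check_pair(fv_late, fv_early)
    values = {}
    for name in fv_late.values:
        early = fv_early.values[name]
        late = fv_late.values[name]
        if math.isnan(early) or math.isnan(late) or abs(early) <= epsilon:
            values[name] = float("nan")
        else:
            values[name] = (late - early) / abs(early)
    return FeatureVector(
        fv_late.patient_id,
        delta_label("RD", fv_late.label, fv_early.label),
        fv_late.sequence,
        values,
    )


def deltas_from_wide(
    table: pd.DataFrame,
    sequences: tuple[str, ...] = ("DCE", "DWI"),
    epsilon: float = 1e-12,
) -> pd.DataFrame:
    """Delta columns from a wide per-timepoint feature table.

    Input columns follow ``<sequence>_<timepoint>_<feature>``; output columns
    follow ``<sequence>_<mode>_<late>-<early>_<feature>`` for every ordered
    pair whose two timepoints are present.
    """
    out = {}
    for seq in sequences:
        for late, early in DELTA_PAIRS:
            late_cols = [c for c in table.columns if c.startswith(f"{seq}_{late}_")]
            for lc in late_cols:
                feat = lc[len(f"{seq}_{late}_"):]
                ec = f"{seq}_{early}_{feat}"
                if ec not in table.columns:
                    continue
                lv = table[lc].to_numpy(dtype=float)
                ev = table[ec].to_numpy(dtype=float)
                out[f"{seq}_{delta_label('AD', late, early)}_{feat}"] = lv - ev
                with np.errstate(divide="ignore", invalid="ignore"):
                    rd = np.where(np.abs(ev) > epsilon, (lv - ev) / np.abs(ev), np.nan)
                out[f"{seq}_{delta_label('RD', late, early)}_{feat}"] = rd
    return pd.DataFrame(out, index=table.index)
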