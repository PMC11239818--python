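"""Inter-reader and intrareader reproducibility of radiomic features.

Two (or more) readers contour every tumor, each several times; features are
extracted per contour. Per feature the module reports

* the Pearson correlation of the two readers' (repeat-averaged) values
  across patients,
* a two-sided Wilcoxon signed-rank test of the paired reader difference
  (zero differences dropped, the Wilcoxon convention), and
* the ratio of inter-reader to intrareader variance from a per-patient
  one-way random-effects method-of-moments decomposition: the intrareader
  variance is the mean within-reader repeat variance, the inter-reader
  variance is the variance of reader means in excess of the repeat noise
  (floored at zero), and the ratio is the cross-patient mean of the former
  over the latter.

Ratios are reported rounded to 4 decimals; summaries are the mean, median,
range and standard deviation over features, with counts of features whose
correlation exceeds a threshold broken down by feature class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

KEY_COLUMNS = ("patient_id", "reader_id", "repeat_index")


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in KEY_COLUMNS]


def pearson_per_feature(table_reader1: pd.DataFrame, table_reader2: pd.DataFrame) -> pd.Series:
    """Pairwise-complete Pearson r per feature between two readers.

    Tables are aligned on ``patient_id`` (one row per patient; average
    repeats first if needed). Features with zero variance in either reader
    are undefined (NaN).
    """
    t1 = table_reader1.set_index("patient_id") if "patient_id" in table_reader1 else table_reader1
    t2 = table_reader2.set_index("patient_id") if "patient_id" in table_reader2 else table_reader2
    t1 = t1.drop(columns=[c for c in KEY_COLUMNS if c in t1.columns])
    t2 = t2.drop(columns=[c for c in KEY_COLUMNS if c in t2.columns])
    if list(t1.columns) != list(t2.columns):
        raise ValueError("reader tables disagree in feature schema")
    t2 = t2.reindex(t1.index)
    out = {}
    for col in t1.columns:
        x = t1[col].to_numpy(dtype=float)
        y = t2[col].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
            out[col] = np.nan
        else:
            out[col] = float(np.corrcoef(x[ok], y[ok])[0, 1])
    return pd.Series(out, name="pearson_r")


def wilcoxon_signed_rank_per_feature(
    table_reader1: pd.DataFrame, table_reader2: pd.DataFrame
) -> pd.Series:
    """Two-sided Wilcoxon signed-rank p per feature for the reader difference.

    Zero differences are dropped (Wilcoxon convention); if all differences
    are zero the feature is in perfect agreement and p = 1 by convention.
    Features with fewer than 5 informative pairs are NaN.
    """
    t1 = table_reader1.set_index("patient_id") if "patient_id" in table_reader1 else table_reader1
    t2 = table_reader2.set_index("patient_id") if "patient_id" in table_reader2 else table_reader2
    t1 = t1.drop(columns=[c for c in KEY_COLUMNS if c in t1.columns])
    t2 = t2.drop(columns=[c for c in KEY_COLUMNS if c in t2.columns])
    if list(t1.columns) != list(t2.columns):
        raise ValueError("reader tables disagree in feature schema")
    t2 = t2.reindex(t1.index)
    out = {}
    for col in t1.columns:
        d = t1[col].to_numpy(dtype=float) - t2[col].to_numpy(dtype=float)
        d = d[~np.isnan(d)]
        informative = d[d != 0]
        if informative.size == 0:
            out[col] = 1.0
        elif informative.size < 5:
            out[col] = np.nan
        else:
            out[col] = float(sps.wilcoxon(informative, alternative="two-sided").pvalue)
    return pd.Series(out, name="wilcoxon_p")


def variance_ratio(table: pd.DataFrame) -> tuple[pd.Series, dict]:
    """Inter/intra variance ratio per feature plus the feature-level summary.

    ``table`` holds one row per (patient, reader, repeat) with the key
    columns of :data:`KEY_COLUMNS` plus feature columns; every reader needs
    at least 2 repeats per patient. Ratios are rounded to 4 decimals. A
    feature whose intrareader variance vanishes while readers still differ
    has an infinite ratio; such features are excluded from the summaries.
    """
    missing = [k for k in KEY_COLUMNS if k not in table.columns]
    if missing:
        raise ValueError(f"table lacks key columns {missing}")
    features = _feature_columns(table)
    counts = table.groupby(["patient_id", "reader_id"]).size()
    if (counts < 2).any():
        raise ValueError("every reader needs >= 2 repeats per patient")

    grouped = table.groupby(["patient_id", "reader_id"])[features]
    repeat_var = grouped.var(ddof=1)   # within-reader repeat variance
    reader_mean = grouped.mean()
    n_rep = counts.groupby(level="patient_id").mean()

    intra_p = repeat_var.groupby(level="patient_id").mean()
    between_p = reader_mean.groupby(level="patient_id").var(ddof=1)
    inter_p = (between_p - intra_p.div(n_rep, axis=0)).clip(lower=0.0)

    # patients with an undefined component (all-missing features) drop out
    # of both averages feature-wise
    valid = ~(intra_p.isna() | inter_p.isna())
    mean_intra = intra_p.where(valid).mean(axis=0)
    mean_inter = inter_p.where(valid).mean(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (mean_inter / mean_intra).round(4)
    ratio = ratio.where(mean_intra > 0,
                        np.where(mean_inter > 0, np.inf, 0.0))
    ratio[valid.sum(axis=0) == 0] = np.nan
    series = pd.Series(ratio, name="variance_ratio")
    series.index = pd.Index(features)
    finite = series[np.isfinite(series)]
    summary = {
        "mean": float(finite.mean()) if len(finite) else np.nan,
        "median": float(finite.median()) if len(finite) else np.nan,
        "min": float(finite.min()) if len(finite) else np.nan,
        "max": float(finite.max()) if len(finite) else np.nan,
        "sd": float(finite.std(ddof=1)) if len(finite) > 1 else np.nan,
        "n_features": int(len(series)),
        "n_excluded_infinite": int(np.isinf(series).sum()),
    }
    return series, summary


def _feature_class(name: str) -> str:
    base = name.split("_", 2)
    # columns may be '<seq>_<block>_<family>_...' or bare '<family>_...'
    for token in name.split("_"):
        if token in ("firstorder", "glcm"):
            return token
    return "other"


@dataclass
class AgreementReport:
    """Per-feature agreement metrics with feature-class summaries."""

    per_feature: pd.DataFrame
    variance_summary: dict
    r_threshold: float = 0.8

    def high_correlation_counts(self) -> pd.DataFrame:
        """Features with r > threshold, counted per feature class."""
        df = self.per_feature.copy()
        df["feature_class"] = [_feature_class(n) for n in df.index]
        rows = []
        for cls, g in df.groupby("feature_class"):
            rows.append(
                {
                    "feature_class": cls,
                    "n_features": len(g),
                    "n_high_r": int((g["pearson_r"] > self.r_threshold).sum()),
                }
            )
        return pd.DataFrame(rows)

    def summary_json(self) -> dict:
        counts = self.high_correlation_counts()
        return {
            "variance_ratio": self.variance_summary,
            "pearson_r_threshold": self.r_threshold,
            "high_correlation_counts": counts.to_dict(orient="records"),
        }


def agreement_report(
    repeat_table: pd.DataFrame,
    r_threshold: float = 0.8,
) -> AgreementReport:
    """Full agreement analysis from a (patient, reader, repeat) feature table.

    Pearson and Wilcoxon compare the first two readers' repeat-averaged
    values; the variance ratio uses all repeats of all readers.
    """
    readers = sorted(repeat_table["reader_id"].unique())
    if len(readers) < 2:
        raise ValueError("agreement needs at least 2 readers")
    features = _feature_columns(repeat_table)
    means = (
        repeat_table.groupby(["reader_id", "patient_id"], sort=True)[features]
        .mean()
        .reset_index()
    )
    t1 = means[means["reader_id"] == readers[0]].drop(columns="reader_id")
    t2 = means[means["reader_id"] == readers[1]].drop(columns="reader_id")
    r = pearson_per_feature(t1, t2)
    p = wilcoxon_signed_rank_per_feature(t1, t2)
    ratio, summary = variance_ratio(repeat_table)
    per_feature = pd.concat([r, p, ratio], axis=1)
    return AgreementReport(per_feature=per_feature, variance_summary=summary,
                           r_threshold=r_threshold)
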