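"""Simulation experiments exercising the pipeline under known conditions.

These routines generate full synthetic cohorts with planted (or removed)
response effects, run segmentation, feature extraction, delta computation,
screening and modeling end to end, and return the resulting performance
numbers. They back both the validation test suite and the reproduction
script.

Problem sizes mirror the clinical study design (163 patients, ~48% pCR,
2:1 stratified split); to keep a single planted-effect run in the tens of
seconds the planted and null experiments simulate only the BL and C2
timepoints, which are the ones the early-change (RD C2/BL) model needs.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from deltarad.modeling import (
    ModelSpec,
    SplitSpec,
    cross_validate,
    evaluate_holdout,
    fit_elastic_net,
    stratified_split,
)
from deltarad.pipeline import (
    ModelingParams,
    _model_feature_columns,
    build_feature_table,
    build_reader_repeat_table,
)
from deltarad.screening import screen_features
from deltarad.synthetic import CohortConfig, generate_cohort, null_effect


def _two_timepoint_config(seed: int, n_patients: int = 163,
                          null: bool = False) -> CohortConfig:
    config = CohortConfig(n_patients=n_patients, timepoints=("BL", "C2"), seed=seed)
    if null:
        config = dataclasses.replace(config, effect=null_effect(config.effect))
    return config


def _family_model(features, labels, family_blocks, seed, modeling: ModelingParams,
                  train_idx, test_idx, screening_df):
    spec = ModelSpec(blocks=tuple(family_blocks))
    cols = _model_feature_columns(spec, screening_df, modeling)
    train, test = features.iloc[train_idx], features.iloc[test_idx]
    model = fit_elastic_net(train[cols], labels[train_idx], seed=seed,
                            n_cs=modeling.n_cs)
    result = evaluate_holdout(model, spec, train[cols], labels[train_idx],
                              test[cols], labels[test_idx])
    return result, cols


def planted_effect_run(seed: int, n_patients: int = 163,
                       with_cv3: bool = True) -> dict[str, float]:
    """Early-change vs baseline model comparison on one planted-effect cohort.

    Returns train/test AUCs of the relative-difference C2/BL model and of the
    baseline-only model, plus (optionally) the 3-fold pooled CV AUC of the
    early-change model on the whole cohort.
    """
    config = _two_timepoint_config(seed, n_patients)
    records, clinical = generate_cohort(config)
    labels = clinical["pcr"].to_numpy()
    features = build_feature_table(records, config)
    modeling = ModelingParams()

    train_idx, test_idx = stratified_split(labels, SplitSpec(seed=seed))
    screening_df = screen_features(
        features.iloc[train_idx], labels[train_idx],
        features.iloc[test_idx], labels[test_idx],
    )
    rd_blocks = [("RD_C2-BL", "DCE"), ("RD_C2-BL", "DWI")]
    bl_blocks = [("BL", "DCE"), ("BL", "DWI")]
    rd_result, rd_cols = _family_model(features, labels, rd_blocks, seed, modeling,
                                       train_idx, test_idx, screening_df)
    bl_result, _ = _family_model(features, labels, bl_blocks, seed, modeling,
                                 train_idx, test_idx, screening_df)
    out = {
        "rd_train_auc": rd_result.auc_train,
        "rd_test_auc": rd_result.auc_test,
        "bl_train_auc": bl_result.auc_train,
        "bl_test_auc": bl_result.auc_test,
        "n_screen_passed": int(screening_df["passes"].sum()),
    }
    if with_cv3:
        out["rd_cv3_auc"] = cross_validate(
            features[rd_cols], labels, folds=3, seed=seed,
            fit_kwargs={"n_cs": modeling.n_cs},
        )
    return out


def null_control_run(seed: int, n_patients: int = 163) -> dict[str, float]:
    """Early-change model on a signal-removed cohort (label-independent
    trajectories); test AUC should hover around chance."""
    config = _two_timepoint_config(seed, n_patients, null=True)
    records, clinical = generate_cohort(config)
    labels = clinical["pcr"].to_numpy()
    features = build_feature_table(records, config)
    modeling = ModelingParams()
    train_idx, test_idx = stratified_split(labels, SplitSpec(seed=seed))
    screening_df = screen_features(
        features.iloc[train_idx], labels[train_idx],
        features.iloc[test_idx], labels[test_idx],
    )
    rd_blocks = [("RD_C2-BL", "DCE"), ("RD_C2-BL", "DWI")]
    result, _ = _family_model(features, labels, rd_blocks, seed, modeling,
                              train_idx, test_idx, screening_df)
    return {
        "rd_test_auc": result.auc_test,
        "n_screen_passed": int(screening_df["passes"].sum()),
    }


def agreement_jitter_run(seed: int, jitter_inter: float = 1.0,
                         jitter_intra: float = 1.0,
                         n_patients: int = 50) -> dict[str, float]:
    """Median inter/intra variance ratio of GLCM features at given jitters."""
    from deltarad.agreement import variance_ratio

    config = CohortConfig(n_patients=max(n_patients, 2), timepoints=("BL",), seed=seed)
    records, _ = generate_cohort(config)
    table = build_reader_repeat_table(
        records[:n_patients], config, jitter=jitter_inter,
        jitter_intra=jitter_intra, seed=seed,
    )
    ratios, summary = variance_ratio(table)
    glcm_ratios = ratios[[n.startswith("glcm_") for n in ratios.index]]
    finite = glcm_ratios[np.isfinite(glcm_ratios)]
    return {
        "median_glcm_variance_ratio": float(finite.median()),
        "mean_variance_ratio": summary["mean"],
    }
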