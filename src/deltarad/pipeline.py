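"""End-to-end orchestration: simulate -> segment -> extract -> delta ->
screen -> model -> agreement, with cohort summary statistics and a run
manifest.

All stage outputs are plain tables (CSV) and JSON; every source of
randomness derives from the single pipeline seed, so re-running a config
reproduces all numeric outputs bitwise.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

from deltarad import __version__
from deltarad.agreement import AgreementReport, agreement_report
from deltarad.datatypes import SEQUENCES, VOIMask
from deltarad.delta import DELTA_PAIRS, absolute_difference, relative_difference
from deltarad.modeling import (
    ModelResult,
    ModelSpec,
    SplitSpec,
    cross_validate,
    enumerate_model_grid,
    evaluate_holdout,
    fit_elastic_net,
    fit_svm,
    stratified_split,
)
from deltarad.radiomics import GLCMConfig, QuantizationParams, extract_feature_vector
from deltarad.screening import screen_features
from deltarad.segmentation import (
    RoughContour,
    SegmentationParams,
    exclude_regions,
    threshold_segment,
)
from deltarad.synthetic import (
    CohortConfig,
    PatientRecord,
    ResponseEffect,
    generate_cohort,
    simulate_reader_masks,
    simulate_study,
)


# ---------------------------------------------------------------------------
# cohort summary statistics (Table-1 style)

def _fisher_rx2_montecarlo(table: np.ndarray, rng: np.random.Generator,
                           n_mc: int = 20000) -> float:
    """Monte-Carlo Fisher exact p for an r x 2 contingency table.

    Samples tables from the conditional null by permuting group labels
    (margins fixed) and compares the conditional probability of each sampled
    table with that of the observed one.
    """
    from scipy.special import gammaln

    def log_prob(t: np.ndarray) -> float:
        # product-hypergeometric probability given fixed margins
        rows = t.sum(axis=1)
        cols = t.sum(axis=0)
        n = t.sum()
        logC = (
            gammaln(rows + 1).sum()
            + gammaln(cols + 1).sum()
            - gammaln(n + 1)
            - gammaln(t + 1).sum()
        )
        return float(logC)

    levels = np.repeat(np.arange(table.shape[0]), table.sum(axis=1))
    n_group1 = int(table[:, 1].sum())
    obs = log_prob(table)
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(levels)
        g1 = perm[:n_group1]
        t = np.zeros_like(table)
        counts = np.bincount(g1, minlength=table.shape[0])
        t[:, 1] = counts
        t[:, 0] = table.sum(axis=1) - counts
        if log_prob(t) <= obs + 1e-9:
            hits += 1
    return (hits + 1) / (n_mc + 1)


def cohort_stats(
    clinical: pd.DataFrame,
    label_col: str = "pcr",
    continuous: tuple[str, ...] = ("age",),
    seed: int = 0,
    n_mc: int = 20000,
) -> pd.DataFrame:
    """Compare clinical characteristics between pCR and non-pCR groups.

    Continuous variables use the two-sided Wilcoxon rank-sum test;
    categorical variables use Fisher's exact test (Monte-Carlo, seeded, for
    tables larger than 2 x 2). Returns one row per variable level with
    counts, percentages per group, and the variable-level p-value; empty
    category levels are dropped.
    """
    labels = clinical[label_col].to_numpy(dtype=int)
    if min(np.bincount(labels, minlength=2)) < 2:
        raise ValueError("need >= 2 patients per group")
    rng = np.random.default_rng(seed)
    g1 = clinical[labels == 1]
    g0 = clinical[labels == 0]
    rows = []
    variables = [c for c in clinical.columns if c not in ("patient_id", label_col)]
    for var in variables:
        if var in continuous:
            x1 = g1[var].to_numpy(dtype=float)
            x0 = g0[var].to_numpy(dtype=float)
            p = float(sps.mannwhitneyu(x1, x0, alternative="two-sided").pvalue)
            rows.append(
                {
                    "variable": var, "level": "median (range)",
                    "total": f"{clinical[var].median():g} ({clinical[var].min():g}-{clinical[var].max():g})",
                    "pcr": f"{np.median(x1):g} ({x1.min():g}-{x1.max():g})",
                    "non_pcr": f"{np.median(x0):g} ({x0.min():g}-{x0.max():g})",
                    "p_value": p,
                }
            )
            continue
        levels = [lv for lv in clinical[var].unique() if (clinical[var] == lv).any()]
        table = np.array(
            [[(g0[var] == lv).sum(), (g1[var] == lv).sum()] for lv in levels], dtype=int
        )
        keep = table.sum(axis=1) > 0
        table, levels = table[keep], [lv for lv, k in zip(levels, keep) if k]
        if table.shape[0] == 2:
            p = float(sps.fisher_exact(table)[1])
        else:
            p = _fisher_rx2_montecarlo(table, rng, n_mc=n_mc)
        n = len(clinical)
        for lv, (c0, c1) in zip(levels, table):
            tot = c0 + c1
            rows.append(
                {
                    "variable": var, "level": str(lv),
                    "total": f"{tot} ({100 * tot / n:.0f}%)",
                    "pcr": f"{c1} ({100 * c1 / max(len(g1), 1):.0f}%)",
                    "non_pcr": f"{c0} ({100 * c0 / max(len(g0), 1):.0f}%)",
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# feature-table assembly

def segment_study(study, truth, seg_params: SegmentationParams,
                  dilate_voxels: int = 2) -> dict[str, VOIMask]:
    """Refine the (simulated) rough contours of one study per sequence.

    The rough contour is the truth mask dilated by ``dilate_voxels`` —
    emulating a generous hand-drawn envelope — thresholded on the sequence's
    own volume, with the necrotic core excluded.
    """
    rough_mask = ndimage.binary_dilation(truth.mask, iterations=dilate_voxels)
    vois = {}
    for seq in SEQUENCES:
        rough = RoughContour(study.patient_id, study.timepoint, rough_mask)
        if truth.tumor_bed:
            # vanished tumor: keep the contoured bed as drawn
            voi = VOIMask(study.patient_id, study.timepoint, truth.mask.copy(),
                          tumor_bed=True)
        else:
            voi = threshold_segment(study.sequence_volume(seq), rough, seg_params)
            if truth.necrosis is not None:
                voi = exclude_regions(voi, truth.necrosis)
        vois[seq] = voi
    return vois


def patient_feature_row(
    patient: PatientRecord,
    config: CohortConfig,
    seg_params: SegmentationParams,
    quant: QuantizationParams,
    glcm: GLCMConfig,
) -> dict[str, float]:
    """All 310 x (timepoints + deltas) x sequences features of one patient."""
    per_seq: dict[str, dict[str, object]] = {seq: {} for seq in SEQUENCES}
    for tp in config.timepoints:
        study, truth = simulate_study(patient, tp, config, with_truth=True)
        vois = segment_study(study, truth, seg_params)
        for seq in SEQUENCES:
            per_seq[seq][tp] = extract_feature_vector(study, vois[seq], seq, quant, glcm)
    row: dict[str, float] = {}
    for seq in SEQUENCES:
        blocks = dict(per_seq[seq])
        for late, early in DELTA_PAIRS:
            if late in blocks and early in blocks:
                ad = absolute_difference(blocks[late], blocks[early])
                rd = relative_difference(blocks[late], blocks[early])
                blocks[ad.label] = ad
                blocks[rd.label] = rd
        for label, fv in blocks.items():
            for name, value in fv.values.items():
                row[f"{seq}_{label}_{name}"] = value
    return row


def build_feature_table(
    records: list[PatientRecord],
    config: CohortConfig,
    seg_params: SegmentationParams = SegmentationParams(),
    quant: QuantizationParams = QuantizationParams(),
    glcm: GLCMConfig = GLCMConfig(),
) -> pd.DataFrame:
    """Assemble the patients x features table (310 x 18 columns by default)."""
    rows = [
        patient_feature_row(p, config, seg_params, quant, glcm) for p in records
    ]
    return pd.DataFrame(rows, index=[p.patient_id for p in records])


def build_reader_repeat_table(
    records: list[PatientRecord],
    config: CohortConfig,
    timepoint: str = "BL",
    jitter: float = 1.0,
    jitter_intra: float = 1.0,
    n_readers: int = 2,
    n_repeats: int = 2,
    sequence: str = "DCE",
    quant: QuantizationParams = QuantizationParams(),
    glcm: GLCMConfig = GLCMConfig(),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulated multi-reader repeat-contour feature table for agreement."""
    rows = []
    for patient in records:
        study, truth = simulate_study(patient, timepoint, config, with_truth=True)
        true_voi = VOIMask(patient.patient_id, timepoint, truth.mask,
                           tumor_bed=truth.tumor_bed)
        masks = simulate_reader_masks(
            true_voi, jitter, n_readers=n_readers, n_repeats=n_repeats,
            seed=seed + patient.index, jitter_intra=jitter_intra,
            voxel_spacing=config.voxel_spacing,
        )
        for m in masks:
            fv = extract_feature_vector(study, m, sequence, quant, glcm)
            rows.append(
                {"patient_id": patient.patient_id, "reader_id": m.reader_id,
                 "repeat_index": m.repeat_index, **fv.values}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# configuration

def _strict_kwargs(d: dict, cls, what: str) -> dict:
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {what} config: {sorted(unknown)}")
    return d


@dataclass(frozen=True)
class ModelingParams:
    split_ratio: tuple[int, int] = (2, 1)
    cv_folds_hyper: int = 5  # must not exceed the smaller training class
    n_cs: int = 25
    max_model_features: int = 40
    fallback_top_k: int = 30
    combinations: tuple[tuple[str, ...], ...] = (("C4", "AD_C4-BL"),)
    run_cv3: bool = True
    run_svm: bool = False


@dataclass(frozen=True)
class ScreeningParams:
    auc_floor: float = 0.7
    p_ceiling: float = 0.001


@dataclass(frozen=True)
class AgreementParams:
    enabled: bool = True
    n_patients: int = 30
    timepoint: str = "BL"
    jitter: float = 1.0
    jitter_intra: float = 1.0
    n_readers: int = 2
    n_repeats: int = 2


@dataclass(frozen=True)
class PipelineConfig:
    """Schema-validated configuration of a full pipeline run."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    quantization: QuantizationParams = field(default_factory=QuantizationParams)
    glcm: GLCMConfig = field(default_factory=GLCMConfig)
    screening: ScreeningParams = field(default_factory=ScreeningParams)
    modeling: ModelingParams = field(default_factory=ModelingParams)
    agreement: AgreementParams = field(default_factory=AgreementParams)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(_strict_kwargs(d, cls, "pipeline"))
        seed = int(d.pop("seed", 0))
        kwargs: dict = {"seed": seed}
        nested = {
            "cohort": CohortConfig,
            "segmentation": SegmentationParams,
            "quantization": QuantizationParams,
            "glcm": GLCMConfig,
            "screening": ScreeningParams,
            "modeling": ModelingParams,
            "agreement": AgreementParams,
        }
        for key, sub_cls in nested.items():
            if key not in d:
                continue
            sub = dict(_strict_kwargs(d.pop(key), sub_cls, key))
            if key == "cohort":
                if "effect" in sub:
                    sub["effect"] = ResponseEffect(
                        **_strict_kwargs(sub["effect"], ResponseEffect, "effect"))
                sub.setdefault("seed", seed)
                for tup in ("timepoints", "grid_shape", "voxel_spacing"):
                    if tup in sub:
                        sub[tup] = tuple(sub[tup])
            if key == "glcm":
                for tup in ("distances", "statistics"):
                    if tup in sub:
                        sub[tup] = tuple(sub[tup])
                if "directions" in sub:
                    sub["directions"] = tuple(tuple(x) for x in sub["directions"])
            if key == "modeling":
                if "split_ratio" in sub:
                    sub["split_ratio"] = tuple(sub["split_ratio"])
                if "combinations" in sub:
                    sub["combinations"] = tuple(tuple(c) for c in sub["combinations"])
            kwargs[key] = sub_cls(**sub)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return json.loads(json.dumps(dataclasses.asdict(self)))


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class PipelineResult:
    config: PipelineConfig
    clinical: pd.DataFrame
    cohort_table: pd.DataFrame
    features: pd.DataFrame
    train_ids: np.ndarray
    test_ids: np.ndarray
    screening: pd.DataFrame
    models: list[ModelResult]
    cv3_aucs: dict[str, float]
    agreement: AgreementReport | None
    manifest: dict


def _model_feature_columns(
    spec: ModelSpec,
    screening_df: pd.DataFrame,
    params: ModelingParams,
) -> list[str]:
    """Screened features within the spec's blocks, capped; fall back to the
    top-k by training AUC when nothing passes the screen."""
    in_blocks = screening_df[screening_df["feature"].str.startswith(tuple(spec.column_prefixes()))]
    passed = in_blocks[in_blocks["passes"]]
    if len(passed) >= 2:
        return list(passed["feature"].head(params.max_model_features))
    ranked = in_blocks.sort_values("auc_train", ascending=False, kind="stable")
    return list(ranked["feature"].head(params.fallback_top_k))


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run every stage on a synthetic cohort and (optionally) persist outputs."""
    t0 = time.time()
    cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
    records, clinical = generate_cohort(cohort_cfg)
    table1 = cohort_stats(clinical, seed=config.seed)

    features = build_feature_table(
        records, cohort_cfg, config.segmentation, config.quantization, config.glcm
    )
    labels = clinical["pcr"].to_numpy()

    split = SplitSpec(ratio=config.modeling.split_ratio, seed=config.seed)
    train_idx, test_idx = stratified_split(labels, split)
    train, test = features.iloc[train_idx], features.iloc[test_idx]
    y_train, y_test = labels[train_idx], labels[test_idx]

    screening_df = screen_features(
        train, y_train, test, y_test,
        auc_floor=config.screening.auc_floor, p_ceiling=config.screening.p_ceiling,
    )

    grid = enumerate_model_grid(
        timepoints=cohort_cfg.timepoints,
        combinations=config.modeling.combinations,
    )
    if config.modeling.run_svm:
        grid = grid + [
            dataclasses.replace(spec, learner=learner)
            for spec in grid if spec.learner == "elastic_net_logistic"
            for learner in ("svm_linear", "svm_rbf")
        ]
    models: list[ModelResult] = []
    cv3_aucs: dict[str, float] = {}
    for spec in grid:
        cols = _model_feature_columns(spec, screening_df, config.modeling)
        if len(cols) < 2:
            continue
        folds = config.modeling.cv_folds_hyper
        if spec.learner == "elastic_net_logistic":
            model = fit_elastic_net(
                train[cols], y_train, cv_folds=folds,
                seed=config.seed, n_cs=config.modeling.n_cs,
            )
        else:
            model = fit_svm(train[cols], y_train, kernel=spec.learner.split("_")[1],
                            cv_folds=folds, seed=config.seed)
        models.append(evaluate_holdout(model, spec, train[cols], y_train,
                                       test[cols], y_test))
        if config.modeling.run_cv3 and spec.learner == "elastic_net_logistic":
            cv3_aucs[spec.name] = cross_validate(
                features[cols], labels, folds=3, seed=config.seed,
                fit_kwargs={"n_cs": config.modeling.n_cs, "cv_folds": folds},
            )

    agreement = None
    if config.agreement.enabled:
        a = config.agreement
        subset = records[: a.n_patients]
        repeat_table = build_reader_repeat_table(
            subset, cohort_cfg, timepoint=a.timepoint, jitter=a.jitter,
            jitter_intra=a.jitter_intra, n_readers=a.n_readers,
            n_repeats=a.n_repeats, quant=config.quantization, glcm=config.glcm,
            seed=config.seed,
        )
        agreement = agreement_report(repeat_table)

    manifest = {
        "software_version": __version__,
        "config_hash": config_hash(config),
        "seed": config.seed,
        "n_patients": cohort_cfg.n_patients,
        "n_feature_columns": int(features.shape[1]),
        "n_models": len(models),
        "started_unix": t0,
        "elapsed_s": time.time() - t0,
        "stage_checksums": {},
    }

    result = PipelineResult(
        config=config, clinical=clinical, cohort_table=table1, features=features,
        train_ids=train_idx, test_ids=test_idx, screening=screening_df,
        models=models, cv3_aucs=cv3_aucs, agreement=agreement, manifest=manifest,
    )
    if outdir is not None:
        write_outputs(result, Path(outdir))
    return result


def _checksum(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = {
        "clinical.csv": result.clinical.to_csv(index=False),
        "cohort_table.csv": result.cohort_table.to_csv(index=False),
        "features.csv": result.features.to_csv(index_label="patient_id"),
        "screening.csv": result.screening.to_csv(index=False),
        "split.json": json.dumps(
            {"train": result.train_ids.tolist(), "test": result.test_ids.tolist()}
        ),
        "models.json": json.dumps(
            {
                "models": [m.to_dict() for m in result.models],
                "cv3_auc": result.cv3_aucs,
            },
            indent=2,
        ),
        "config.json": json.dumps(result.config.to_dict(), indent=2),
    }
    if result.agreement is not None:
        outputs["agreement.csv"] = result.agreement.per_feature.to_csv(index_label="feature")
        outputs["agreement_summary.json"] = json.dumps(result.agreement.summary_json(), indent=2)
    for fname, text in outputs.items():
        (outdir / fname).write_text(text)
        result.manifest["stage_checksums"][fname] = _checksum(text)
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
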