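"""End-to-end orchestration: extract -> split -> train -> calibrate -> evaluate.

The independent-test half is never visible to training or calibration; the
pipeline enforces this with explicit residue-key bookkeeping and fails hard
on any overlap. Every stage logs one structured line with its input/output
row counts so the residue bookkeeping (e.g. 534 -> 312/111/111) is auditable,
and a JSON manifest records seeds, sizes and the property-table checksum.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from hotseq.calibration import CalibrationTable, apply_correction, fit_correction
from hotseq.fasta_io import ProteinChain, read_fasta, write_residue_table
from hotseq.features import FeatureConfig, extract_features_many
from hotseq.metrics import metrics_report, per_amino_acid_report
from hotseq.model import (
    ModelParams,
    TrainedModel,
    predict_hs_probability,
    property_table_checksum,
    save_model,
    train,
)
from hotseq.properties import PropertyTable, load_default_properties, load_properties_csv
from hotseq.splitting import (
    DatasetSplit,
    residues_from_frame,
    residues_to_frame,
    split_report,
    stratified_split,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Paths and parameters for one pipeline run."""

    fasta_path: Path
    labels_path: Path
    out_dir: Path
    seed: int = 0
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    model_params: ModelParams | None = None
    property_table_path: Path | None = None
    verbosity: int = logging.INFO


@dataclass
class PipelineResult:
    """Everything a run computes, before any of it is written to disk."""

    split: DatasetSplit
    model: TrainedModel
    calibration: CalibrationTable
    independent_predictions: pd.DataFrame
    independent_metrics: dict[str, float]
    tuning_predictions: pd.DataFrame
    tuning_metrics: dict[str, float]
    per_amino_acid: pd.DataFrame
    manifest: dict


def _keys(frame: pd.DataFrame) -> set[tuple[str, int]]:
    return set(zip(frame["chain_id"].astype(str), frame["position"].astype(int)))


def _select(features: pd.DataFrame, residues) -> tuple[pd.DataFrame, list[str]]:
    """Feature rows and labels for a residue partition, leakage-checked upstream."""
    wanted = {(r.chain_id, r.position): r.label for r in residues}
    mask = [
        (cid, pos) in wanted
        for cid, pos in zip(features["chain_id"].astype(str), features["position"].astype(int))
    ]
    subset = features.loc[mask].reset_index(drop=True)
    if len(subset) != len(wanted):
        raise PipelineError(
            f"labels refer to {len(wanted)} residues but only {len(subset)} have features"
        )
    labels = [
        wanted[(cid, pos)]
        for cid, pos in zip(subset["chain_id"].astype(str), subset["position"].astype(int))
    ]
    return subset, labels


def run_from_data(
    chains: list[ProteinChain],
    labels: pd.DataFrame,
    *,
    seed: int = 0,
    feature_config: FeatureConfig | None = None,
    model_params: ModelParams | None = None,
    table: PropertyTable | None = None,
) -> PipelineResult:
    """Run the full pipeline in memory and return every computed object."""
    table = table or load_default_properties()
    feature_config = feature_config or FeatureConfig()
    model_params = model_params or ModelParams(random_seed=seed)

    features = extract_features_many(chains, table, feature_config)
    logger.info("stage=extract chains=%d residues=%d features=%d",
                len(chains), len(features), features.shape[1] - 3)

    residues = residues_from_frame(labels)
    split = stratified_split(residues, seed=seed)
    logger.info("stage=split total=%d train=%d tuning=%d independent=%d",
                len(residues), len(split.train), len(split.tuning_test), len(split.independent_test))

    train_features, train_labels = _select(features, split.train)
    tuning_features, tuning_labels = _select(features, split.tuning_test)
    indep_features, indep_labels = _select(features, split.independent_test)

    train_keys, tuning_keys, indep_keys = map(_keys, (train_features, tuning_features, indep_features))
    if (train_keys & indep_keys) or (tuning_keys & indep_keys) or (train_keys & tuning_keys):
        raise PipelineError("leakage: train/tuning/independent partitions overlap")

    checksum = property_table_checksum(table)
    model = train(
        train_features,
        train_labels,
        model_params,
        amino_acids=list(train_features["amino_acid"]),
        property_checksum=checksum,
    )
    logger.info("stage=train rows=%d trees=%d", len(train_features), model_params.n_trees)

    calibration = fit_correction(model, tuning_features, tuning_labels, fitted_on=f"tuning-seed-{seed}")
    logger.info("stage=calibrate rows=%d corrected_aa=%d",
                len(tuning_features), sum(1 for v in calibration.correction.values() if v > 0))

    def _predict(feats: pd.DataFrame) -> pd.DataFrame:
        out = feats[["chain_id", "position", "amino_acid"]].copy()
        out["raw_hs_probability"] = predict_hs_probability(model, feats)
        return apply_correction(out, calibration)

    tuning_pred = _predict(tuning_features)
    indep_pred = _predict(indep_features)

    tuning_metrics = metrics_report(
        tuning_pred["predicted_class"], tuning_labels, tuning_pred["corrected_hs_probability"]
    )
    indep_metrics = metrics_report(
        indep_pred["predicted_class"], indep_labels, indep_pred["corrected_hs_probability"]
    )
    per_aa = per_amino_acid_report(indep_pred, indep_labels)
    logger.info("stage=evaluate independent_accuracy=%.3f", indep_metrics["accuracy"])

    from hotseq import __version__

    manifest = {
        "version": __version__,
        "seed": seed,
        "n_chains": len(chains),
        "n_residues_labeled": len(residues),
        "partition_sizes": {
            "train": len(split.train),
            "tuning_test": len(split.tuning_test),
            "independent_test": len(split.independent_test),
        },
        "n_features": features.shape[1] - 3,
        "property_table_checksum": checksum,
        "model_params": {
            "n_trees": model_params.n_trees,
            "bootstrap_replicas": model_params.bootstrap_replicas,
            "class_weighting": model_params.class_weighting,
            "random_seed": model_params.random_seed,
        },
    }
    return PipelineResult(
        split=split,
        model=model,
        calibration=calibration,
        independent_predictions=indep_pred,
        independent_metrics=indep_metrics,
        tuning_predictions=tuning_pred,
        tuning_metrics=tuning_metrics,
        per_amino_acid=per_aa,
        manifest=manifest,
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the pipeline from files and write all artifacts plus a manifest.

    Artifacts: features.csv, split CSVs and split_report.csv, model.joblib,
    calibration.json, predictions CSVs, metrics.json, manifest.json.
    """
    logging.basicConfig(level=config.verbosity)
    for path in (config.fasta_path, config.labels_path):
        if not Path(path).exists():
            raise PipelineError(f"input path does not exist: {path}")

    chains = read_fasta(config.fasta_path)
    labels = pd.read_csv(config.labels_path)
    table = (
        load_properties_csv(config.property_table_path)
        if config.property_table_path
        else load_default_properties()
    )
    result = run_from_data(
        chains,
        labels,
        seed=config.seed,
        feature_config=config.feature_config,
        model_params=config.model_params,
        table=table,
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    features = extract_features_many(chains, table, config.feature_config)
    write_residue_table(features, out / "features.csv")
    for name, part in (
        ("train", result.split.train),
        ("tuning_test", result.split.tuning_test),
        ("independent_test", result.split.independent_test),
    ):
        residues_to_frame(list(part)).to_csv(out / f"split_{name}.csv", index=False)
    split_report(result.split).to_csv(out / "split_report.csv")
    save_model(result.model, out / "model.joblib")
    result.calibration.to_json(out / "calibration.json")
    write_residue_table(result.tuning_predictions, out / "predictions_tuning.csv")
    write_residue_table(result.independent_predictions, out / "predictions_independent.csv")
    result.per_amino_acid.to_csv(out / "per_amino_acid_report.csv", index=False)
    (out / "metrics.json").write_text(json.dumps(
        {"tuning": result.tuning_metrics, "independent": result.independent_metrics}, indent=2))
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    return result
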