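"""End-to-end orchestration: simulate/load -> QC -> model -> call -> validate.

A run is fully described by a :class:`RunConfig` (serializable to YAML);
all randomness flows from its single seed through named substreams, and
the resolved config is written back next to the outputs so any run can
be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calls, model, qc, qpcr, simulate
from .errors import ConfigurationError, DataError
from .gpr import ArrayScan, read_annotation, read_gpr, read_sample_metadata

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed for one reproducible pipeline run."""

    output_dir: str = "lpsmono_run"
    # synthetic run (default) or load from files:
    simulation: simulate.SimulationConfig | None = field(
        default_factory=simulate.SimulationConfig)
    gpr_dir: str | None = None
    metadata_path: str | None = None
    annotation_path: str | None = None
    qc_thresholds: qc.QCThresholds = field(default_factory=qc.QCThresholds)
    call_thresholds: calls.CallThresholds = field(default_factory=calls.CallThresholds)
    normalization: str = "median"
    prior_df: float = 4.0
    pi0_de: float = 0.01
    n_qpcr_subjects: int = 6
    qpcr_ct_noise_sd: float = 0.2
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        try:
            if data.get("simulation") is not None:
                sim = dict(data["simulation"])
                for key in ("fc_range", "a_range", "purity_range"):
                    if key in sim and sim[key] is not None:
                        sim[key] = tuple(sim[key])
                data["simulation"] = simulate.SimulationConfig(**sim)
            if "qc_thresholds" in data:
                data["qc_thresholds"] = qc.QCThresholds(**data["qc_thresholds"])
            if "call_thresholds" in data:
                data["call_thresholds"] = calls.CallThresholds(**data["call_thresholds"])
            return cls(**data)
        except TypeError as exc:
            raise ConfigurationError("run_config", str(exc)) from exc


def _analyze_arm(arrays: list[ArrayScan], qc_tables, annotation,
                 config: RunConfig) -> dict:
    matrix = model.build_ratio_matrix(arrays, qc_tables, annotation)
    matrix = model.normalize(matrix, method=config.normalization)
    mask, audit = qc.feature_inclusion(matrix, config.qc_thresholds)
    included = matrix.subset_genes(mask)
    results = model.analyze(
        included, prior_df=config.prior_df, pi0_de=config.pi0_de,
        consistency_fold=config.call_thresholds.min_fold)
    de = calls.call_de(results, config.call_thresholds,
                       contrast=arrays[0].contrast)
    return {"matrix": matrix, "inclusion_audit": audit, "results": results,
            "de_list": de}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and write outputs under ``output_dir``.

    Returns the run report (also written as ``report.json``): sample
    gate, per-array QC pass fractions, DE counts by direction per arm,
    qPCR concordance, and — for synthetic runs — sensitivity and
    observed FDR against the truth table.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_resolved.yaml")
    report: dict = {"stages": []}
    try:
        # ---- stage: inputs -------------------------------------------------
        truth = None
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            arrays, metadata, truth = simulate.generate_experiment(sim)
            annotation = simulate.make_annotation(sim)
        else:
            if not (config.gpr_dir and config.metadata_path and config.annotation_path):
                raise ConfigurationError(
                    "gpr_dir", "file inputs required when simulation is disabled")
            arrays = [read_gpr(p) for p in sorted(Path(config.gpr_dir).glob("*.gpr"))]
            metadata = read_sample_metadata(config.metadata_path)
            annotation = read_annotation(config.annotation_path)
        if not arrays:
            raise DataError("no arrays to analyse")
        report["stages"].append("inputs")

        # ---- stage: sample gate -------------------------------------------
        gated = qc.gate_samples(metadata, config.qc_thresholds)
        gated_subjects = {s for s, _ in gated}
        kept_arrays = [a for a in arrays if a.subject_id in gated_subjects]
        report["sample_gate"] = {
            "n_samples": len(metadata), "n_gated": len(gated),
            "subjects_excluded": sorted({a.subject_id for a in arrays}
                                        - gated_subjects)}
        if not kept_arrays:
            raise DataError("sample gate excluded every array")
        report["stages"].append("sample_gate")

        # ---- stage: spot QC ------------------------------------------------
        qc_tables = qc.run_spot_qc(kept_arrays, config.qc_thresholds)
        summary = qc.qc_summary(qc_tables)
        summary.to_csv(out / "qc_summary.tsv", sep="\t", index=False)
        report["qc"] = {
            "mean_pass_fraction": float(
                summary.loc[summary["array_id"] == "MEAN", "pass_fraction"].iloc[0])}
        report["stages"].append("spot_qc")

        # ---- stage: model + calls per arm ---------------------------------
        arm_out = {}
        for arm in ("LPS", "saline"):
            arm_arrays = [a for a in kept_arrays if a.arm == arm]
            if len(arm_arrays) < 3:
                log.info("arm %s: %d arrays, skipped", arm, len(arm_arrays))
                continue
            arm_out[arm] = _analyze_arm(arm_arrays, qc_tables, annotation, config)
            res = arm_out[arm]["results"]
            res.to_csv(out / f"gene_results_{arm}.tsv", sep="\t", index=False)
            de = arm_out[arm]["de_list"]
            de.records.to_csv(out / f"de_list_{arm}.tsv", sep="\t", index=False)
            n_up, n_down = calls.classify_directions(de)
            report[f"de_{arm}"] = {"n_called": len(de), "n_up": n_up,
                                   "n_down": n_down}
        report["stages"].append("model_and_calls")

        # ---- stage: truth comparison (synthetic runs) ----------------------
        if truth is not None and "LPS" in arm_out:
            de_genes = arm_out["LPS"]["de_list"].gene_ids
            true_de = set(truth.loc[truth["is_de"], "gene_id"])
            tp = len(de_genes & true_de)
            report["recovery"] = {
                "n_true_de": len(true_de), "n_called": len(de_genes),
                "sensitivity": tp / len(true_de) if true_de else float("nan"),
                "observed_fdr": (len(de_genes) - tp) / len(de_genes)
                if de_genes else 0.0,
            }
            report["stages"].append("truth_comparison")

        # ---- stage: qPCR validation ---------------------------------------
        if truth is not None and "LPS" in arm_out and len(arm_out["LPS"]["de_list"]):
            de = arm_out["LPS"]["de_list"]
            picked = list(de.records["gene_id"].head(8))
            table = simulate.generate_qpcr(
                truth, n_subjects=config.n_qpcr_subjects,
                ct_noise_sd=config.qpcr_ct_noise_sd,
                seed=config.seed, gene_ids=picked)
            folds = qpcr.all_fold_changes(table)
            conc, summary_text = qpcr.concordance(de, folds)
            conc.to_csv(out / "qpcr_concordance.tsv", sep="\t", index=False)
            report["qpcr_concordance"] = summary_text
            report["stages"].append("qpcr_validation")

        report["status"] = "OK"
    except Exception as exc:
        stage = report["stages"][-1] if report["stages"] else "startup"
        report["status"] = "FAILED"
        report["error"] = f"after stage '{stage}': {exc}"
        (out / "FAILED").write_text(report["error"] + "\n")
        _write_report(report, out)
        raise
    _write_report(report, out)
    return report


def synthetic_replicate(sim_config: simulate.SimulationConfig,
                        qc_thresholds: qc.QCThresholds | None = None,
                        call_thresholds: calls.CallThresholds | None = None,
                        normalization: str = "median",
                        prior_df: float = 4.0, pi0_de: float = 0.01) -> dict:
    """One in-memory simulate -> QC -> model -> call pass on the LPS arm.

    Returns called/true gene-ID sets, sensitivity and observed FDR —
    the unit of the null-control and spike-recovery experiments.
    """
    qc_thresholds = qc_thresholds or qc.QCThresholds()
    call_thresholds = call_thresholds or calls.CallThresholds()
    arrays, _, truth = simulate.generate_experiment(sim_config)
    annotation = simulate.make_annotation(sim_config)
    lps = [a for a in arrays if a.arm == "LPS"]
    qc_tables = qc.run_spot_qc(lps, qc_thresholds)
    matrix = model.build_ratio_matrix(lps, qc_tables, annotation)
    matrix = model.normalize(matrix, method=normalization)
    mask, _ = qc.feature_inclusion(matrix, qc_thresholds)
    results = model.analyze(matrix.subset_genes(mask), prior_df=prior_df,
                            pi0_de=pi0_de,
                            consistency_fold=call_thresholds.min_fold)
    de = calls.call_de(results, call_thresholds, contrast=sim_config.contrast)
    called = de.gene_ids
    true_de = set(truth.loc[truth["is_de"], "gene_id"])
    tp = len(called & true_de)
    return {
        "called": called, "true_de": true_de,
        "n_called": len(called),
        "sensitivity": tp / len(true_de) if true_de else float("nan"),
        "false_positives": len(called) - tp,
        "observed_fdr": (len(called) - tp) / len(called) if called else 0.0,
        "results": results,
    }


def _write_report(report: dict, out: Path) -> None:
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str) + "\n")
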