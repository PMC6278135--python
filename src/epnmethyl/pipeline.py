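"""End-to-end orchestration: simulate -> select probes -> cluster -> copy
number -> gene-panel classifier -> IHC, with a single JSON-serializable run
report that echoes the full effective configuration."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import classifier, clustering, copynumber, ihc, probes
from .cohort import CohortConfig, SyntheticCohort, config_to_dict, generate_cohort, read_cohort, write_cohort
from .errors import PipelineError

logger = logging.getLogger(__name__)

STAGES = ("simulate", "select_probes", "cluster", "cnv", "classifier", "ihc")


@dataclass(frozen=True)
class RunConfig:
    """Every tunable of the pipeline, with the published defaults where the
    study states one (SD 0.25; marker means 0.5/0.2; QC quantiles
    0.05/0.95/0.8; 1:2 split; 80% IHC cutoff) and documented pipeline
    decisions otherwise."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    stages: tuple[str, ...] = STAGES
    sd_threshold: float = 0.25
    hyper_mean_min: float = 0.5
    hypo_mean_max: float = 0.2
    qc_lower_q: float = 0.05
    qc_upper_q: float = 0.95
    qc_mad_q: float = 0.8
    cnv_offset: float = 1.0
    gain_threshold: float = 0.15
    loss_threshold: float = -0.15
    min_arm_probes: int = 20
    amp_threshold: float = 0.3
    min_transitions: int = 10
    train_fraction: float = 1.0 / 3.0
    clip_eps: float = 1e-3
    ihc_cutoff: float = 80.0
    seed: int = 0
    input_dir: str | None = None
    output_dir: str | None = None


def _config_echo(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["cohort"] = config_to_dict(config.cohort)
    d["stages"] = list(config.stages)
    return d


def _confusion_dict(cm: classifier.ConfusionMatrix) -> dict:
    return {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn,
            "sensitivity": cm.sensitivity, "specificity": cm.specificity}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the run report.

    A stage failure raises :class:`PipelineError` naming the stage; if an
    output directory is set, the partial report accumulated so far is
    persisted before the error propagates.
    """
    report: dict = {"config": _config_echo(config), "seed": config.seed, "stages": {}}
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    cohort: SyntheticCohort | None = None
    try:
        cohort = _stage_inputs(config, report, out_dir)
        if "select_probes" in config.stages:
            marker_set = _stage_select_probes(config, cohort, report)
        else:
            marker_set = None
        if "cluster" in config.stages:
            _stage_cluster(config, cohort, marker_set, report, out_dir)
        if "cnv" in config.stages:
            _stage_cnv(config, cohort, report, out_dir)
        if "classifier" in config.stages:
            _stage_classifier(config, cohort, report, out_dir)
        if "ihc" in config.stages:
            _stage_ihc(config, cohort, report)
    except PipelineError:
        raise
    except Exception as exc:  # halt with the stage name, persist partial report
        stage = report.get("_current_stage", "inputs")
        if out_dir:
            (out_dir / "report.json").write_text(json.dumps(report, indent=2))
        raise PipelineError(stage, str(exc)) from exc
    finally:
        report.pop("_current_stage", None)

    if out_dir:
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report


def _stage_inputs(config: RunConfig, report: dict, out_dir) -> SyntheticCohort | None:
    if "simulate" in config.stages:
        report["_current_stage"] = "simulate"
        cohort_config = dataclasses.replace(config.cohort, seed=config.seed)
        cohort = generate_cohort(cohort_config)
        report["stages"]["simulate"] = {
            "n_samples": int(len(cohort.sample_sheet)),
            "n_probes": int(len(cohort.annotation)),
        }
        if out_dir:
            write_cohort(cohort, out_dir / "cohort")
        return cohort
    if config.input_dir is None:
        if set(config.stages) - {"simulate"}:
            raise PipelineError("inputs", "no input_dir and simulate stage disabled")
        return None
    return read_cohort(config.input_dir)


def _tumor_labels(cohort: SyntheticCohort) -> dict[str, str]:
    sheet = cohort.sample_sheet
    return dict(zip(sheet["sample_id"], sheet["subgroup"]))


def _stage_select_probes(config: RunConfig, cohort, report: dict) -> probes.MarkerSet:
    report["_current_stage"] = "select_probes"
    autosomal = probes.filter_autosomal(cohort.annotation)
    labels = _tumor_labels(cohort)
    tumors = [s for s in cohort.beta.columns if labels.get(s) in ("PFA", "PFB")]
    tumor_beta = cohort.beta.loc[list(autosomal), tumors]
    high_sd = probes.select_high_sd_island_probes(
        tumor_beta, cohort.annotation, sd_threshold=config.sd_threshold)
    markers = probes.select_subgroup_markers(
        tumor_beta, labels, hyper_mean_min=config.hyper_mean_min,
        hypo_mean_max=config.hypo_mean_max)
    report["stages"]["select_probes"] = {
        "n_total": int(len(cohort.annotation)),
        "n_autosomal": len(autosomal),
        "n_high_sd_island": len(high_sd),
        "n_subgroup_markers": len(markers),
    }
    return high_sd


def _stage_cluster(config: RunConfig, cohort, marker_set, report: dict, out_dir) -> None:
    report["_current_stage"] = "cluster"
    labels = _tumor_labels(cohort)
    tumors = [s for s in cohort.beta.columns if labels.get(s) in ("PFA", "PFB")]
    assignment = clustering.hierarchical_cluster(cohort.beta[tumors], marker_set, k=2)
    assignment = clustering.assign_subgroup_labels(assignment, cohort.beta[tumors], marker_set)
    predicted = {s: assignment.subgroup_of(s) for s in tumors}
    agreement = sum(predicted[s] == labels[s] for s in tumors) / len(tumors)
    report["stages"]["cluster"] = {
        "linkage": assignment.linkage_method,
        "metric": assignment.distance_metric,
        "cluster_marker_mean": {str(k): v for k, v in assignment.cluster_marker_mean.items()},
        "agreement_with_truth": agreement,
    }
    if out_dir:
        pd.DataFrame({
            "sample_id": tumors,
            "cluster": [assignment.cluster_of[s] for s in tumors],
            "subgroup": [predicted[s] for s in tumors],
        }).to_csv(out_dir / "assignments.csv", index=False)


def _stage_cnv(config: RunConfig, cohort, report: dict, out_dir) -> None:
    report["_current_stage"] = "cnv"
    sheet = cohort.sample_sheet
    controls = list(sheet.loc[sheet["subgroup"] == "CONTROL", "sample_id"])
    if len(controls) < 2:
        raise PipelineError("cnv", "need >= 2 control samples")
    tumors = list(sheet.loc[sheet["subgroup"] != "CONTROL", "sample_id"])
    ctrl = copynumber.IntensityMatrix(cohort.meth[controls], cohort.unmeth[controls])
    tum = copynumber.IntensityMatrix(cohort.meth[tumors], cohort.unmeth[tumors])
    qc = copynumber.probe_qc(ctrl, lower_q=config.qc_lower_q,
                             upper_q=config.qc_upper_q, mad_q=config.qc_mad_q)
    truth = dict(zip(sheet["sample_id"], sheet["has_1q_gain"]))
    calls_1q, arm_rows, unstable = {}, [], {}
    for sid in tumors:
        profile = copynumber.log2_profile(sid, tum, ctrl, qc, cohort.annotation,
                                          offset=config.cnv_offset)
        for call in copynumber.call_all_arms(
                profile, gain_threshold=config.gain_threshold,
                loss_threshold=config.loss_threshold, min_probes=config.min_arm_probes):
            arm_rows.append({"sample_id": sid, "arm": call.arm,
                             "median_log2": call.median_log2,
                             "n_probes": call.n_probes, "call": call.call})
            if call.arm == "1q":
                calls_1q[sid] = call.call
        flag, transitions = copynumber.instability_flag(
            profile, "chr11", amp_threshold=config.amp_threshold,
            min_transitions=config.min_transitions)
        unstable[sid] = {"flag": bool(flag), "transitions": transitions}
    correct = sum((calls_1q.get(s) == "gain") == bool(truth[s]) for s in tumors)
    report["stages"]["cnv"] = {
        "n_qc_probes": len(qc),
        "calls_1q": calls_1q,
        "gain_call_accuracy_vs_truth": correct / len(tumors),
        "chr11_instability": unstable,
    }
    if out_dir:
        pd.DataFrame(arm_rows).to_csv(out_dir / "arm_calls.csv", index=False)


def _stage_classifier(config: RunConfig, cohort, report: dict, out_dir) -> None:
    report["_current_stage"] = "classifier"
    panel = cohort.gene_panel
    train, validation = classifier.stratified_split(
        panel, train_fraction=config.train_fraction, seed=config.seed)
    result = classifier.train_classifier(train, validation, clip_eps=config.clip_eps)
    report["stages"]["classifier"] = {
        "n_train": int(len(train)),
        "n_validation": int(len(validation)),
        "fits": {
            gene: {cls: {"alpha": f.alpha, "beta": f.beta, "n": f.n_observations}
                   for cls, f in by_class.items()}
            for gene, by_class in result["fits"].items()
        },
        "thresholds_percent": result["thresholds"],
        "selected_mode": result["rule"].mode,
        "confusion": {name: _confusion_dict(cm)
                      for name, cm in result["confusion"].items()},
    }
    if out_dir:
        (out_dir / "rule.json").write_text(json.dumps(
            {"thresholds": result["thresholds"], "mode": result["rule"].mode}, indent=2))


def _stage_ihc(config: RunConfig, cohort, report: dict) -> None:
    report["_current_stage"] = "ihc"
    frame = ihc.categorize_frame(cohort.ihc, cutoff=config.ihc_cutoff)
    predictions = ihc.ihc_predict_subgroup(frame["category"])
    labels = _tumor_labels(cohort)
    truths = [labels[s] for s in frame["sample_id"]]
    evaluable = [i for i, p in enumerate(predictions) if p != ihc.NOT_EVALUABLE]
    cm = classifier.evaluate([predictions.iloc[i] for i in evaluable],
                             [truths[i] for i in evaluable])
    report["stages"]["ihc"] = {
        "cutoff": config.ihc_cutoff,
        "n_evaluable": len(evaluable),
        "confusion": _confusion_dict(cm),
    }
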