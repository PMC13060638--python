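"""End-to-end orchestration: simulate/ingest → quantify → QC → calibrate →
classify → respond → survival, with a machine-readable run manifest.

The pipeline is deterministic for a fixed configuration and seed; the
manifest records the configuration echo, SHA-256 hashes of any file inputs,
and per-stage record counts, so a run can be audited and reproduced.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import calling, qc, response, simulate, survival
from .ddpcr import SampleMeasurement, ValidationError, VolumeConfig, quantify_table
from .io import read_droplet_table, read_sample_sheet, write_table

__all__ = ["RunConfig", "run_pipeline", "serial_pairs_from_measurements"]


@dataclass
class RunConfig:
    outdir: str = "ctmeth-run"
    seed: int = 0
    simulate: bool = True
    droplet_table: str | None = None      # required when simulate is False
    sample_sheet: str | None = None
    qc_table: str | None = None
    panel_file: str | None = None         # skip calibration, use fixed panel
    min_specificity: float = 95.0
    decrease_threshold: float = 75.0
    aggregation: str = "sum"
    lob_mode: str = "youden"              # youden | fixed
    droplet_volume_nl: float = 0.85
    plasma_volume_ml: float = 4.0
    ci_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def volumes(self) -> VolumeConfig:
        return VolumeConfig(droplet_volume_nl=self.droplet_volume_nl,
                            plasma_volume_ml=self.plasma_volume_ml,
                            ci_alpha=self.ci_alpha)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def serial_pairs_from_measurements(
    measurements: Mapping[str, SampleMeasurement],
    sample_sheet: pd.DataFrame,
    panel: calling.MarkerPanel,
    aggregation: str = "sum",
) -> list[response.SerialPair]:
    """Join baseline/post samples by patient and aggregate each timepoint."""
    serial = sample_sheet[sample_sheet.timepoint.isin(["baseline", "post"])]
    pairs = []
    for pid, grp in serial.groupby("patient_id", sort=True):
        tp = dict(zip(grp.timepoint, grp.sample_id))
        if "baseline" not in tp or "post" not in tp:
            continue
        states = {}
        for name in ("baseline", "post"):
            sid = tp[name]
            if sid not in measurements:
                raise ValidationError(f"patient {pid}: sample {sid} was not quantified")
            states[name] = response.aggregate_fraction(
                measurements[sid], panel, mode=aggregation)
        pairs.append(response.SerialPair(
            patient_id=str(pid), baseline=states["baseline"], post=states["post"]))
    return pairs


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run manifest (also written
    to ``<outdir>/manifest.json``)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "inputs": {}, "stages": {}}

    # ---- inputs -----------------------------------------------------------
    if config.simulate:
        cohort = simulate.simulate_cohorts(simulate.CohortSpec(seed=config.seed))
        droplets, sheet = cohort.droplets, cohort.samples
        truth = cohort.truth
        write_table(droplets, outdir / "droplets.tsv")
        write_table(sheet, outdir / "samples.tsv")
        write_table(truth, outdir / "truth.tsv")
        qc_droplets = simulate.simulate_qc_table(
            sorted(sheet.sample_id), seed=config.seed + 1)
        write_table(qc_droplets, outdir / "qc_droplets.tsv")
    else:
        if not config.droplet_table or not config.sample_sheet:
            raise ValidationError("droplet_table and sample_sheet are required "
                                  "when simulate is false")
        droplets = read_droplet_table(config.droplet_table)
        sheet = read_sample_sheet(config.sample_sheet)
        truth = None
        manifest["inputs"]["droplet_table"] = _sha256(config.droplet_table)
        manifest["inputs"]["sample_sheet"] = _sha256(config.sample_sheet)
        qc_droplets = (read_droplet_table(config.qc_table)
                       if config.qc_table else None)

    markers = list(calling.DEFAULT_MARKERS)
    reference = "ALB"
    missing_alb = set(droplets.sample_id) - set(
        droplets[droplets.target == reference].sample_id)
    if missing_alb:
        raise ValidationError(
            f"samples lack {reference} wells: {sorted(missing_alb)[:5]}")

    # ---- quantify ---------------------------------------------------------
    measurements, quant_table = quantify_table(
        droplets, reference=reference, volumes=config.volumes())
    write_table(quant_table, outdir / "quantification.tsv")
    manifest["stages"]["quantify"] = {"n_samples": len(measurements)}

    # ---- QC ---------------------------------------------------------------
    if qc_droplets is not None:
        qc_df = qc.qc_table(qc_droplets)
        write_table(qc_df, outdir / "qc_report.tsv")
        manifest["stages"]["qc"] = {
            "n_samples": len(qc_df),
            "n_flagged": int((qc_df["flags"] != "").sum()),
        }

    # ---- calibrate / panel ------------------------------------------------
    profiles = calling.profiles_from_table(droplets, markers)
    if config.panel_file:
        panel = calling.MarkerPanel.from_json(config.panel_file)
        manifest["inputs"]["panel_file"] = _sha256(config.panel_file)
        manifest["stages"]["calibrate"] = {"mode": "fixed-panel"}
    else:
        baseline = sheet[sheet.timepoint == "baseline"]
        ctrl_ids = baseline.loc[baseline.group == "control", "sample_id"]
        case_ids = baseline.loc[(baseline.group == "case")
                                & (baseline.cohort == "localized"), "sample_id"] \
            if "cohort" in baseline.columns else \
            baseline.loc[baseline.group == "case", "sample_id"]
        if ctrl_ids.empty or case_ids.empty:
            raise ValidationError("calibration needs control and case baseline samples")
        if config.lob_mode == "fixed":
            search = calling.combined_rule_search(
                {s: profiles[s] for s in ctrl_ids},
                {s: profiles[s] for s in case_ids},
                calling.DEFAULT_LOB, min_specificity=config.min_specificity)
            panel = search.panel
        else:
            cal = calling.calibrate_panel(
                {s: profiles[s] for s in ctrl_ids},
                {s: profiles[s] for s in case_ids},
                min_specificity=config.min_specificity, markers=markers)
            cal.to_json(outdir / "calibration.json")
            panel = cal.panel
        manifest["stages"]["calibrate"] = {
            "lob": dict(panel.lob),
            "min_positive_markers": panel.min_positive_markers,
            "exception_sets": [sorted(s) for s in panel.exception_sets],
        }
    panel.to_json(outdir / "panel.json")

    # ---- classify ---------------------------------------------------------
    calls_df = calling.classify_profiles(profiles, panel)
    calls_df = calls_df.merge(sheet[["sample_id", "patient_id", "cohort", "timepoint"]],
                              on="sample_id", how="left")
    write_table(calls_df, outdir / "calls.tsv")
    base_calls = calls_df[calls_df.timepoint == "baseline"]
    manifest["stages"]["classify"] = {
        "n_samples": len(calls_df),
        "baseline_positive_by_cohort": {
            str(c): int((g.ctdna_status == "positive").sum())
            for c, g in base_calls.groupby("cohort")},
        "baseline_n_by_cohort": {
            str(c): int(len(g)) for c, g in base_calls.groupby("cohort")},
    }

    # ---- respond ----------------------------------------------------------
    pairs = serial_pairs_from_measurements(measurements, sheet, panel,
                                           aggregation=config.aggregation)
    resp_calls = response.classify_pairs(pairs, config.decrease_threshold)
    if resp_calls:
        write_table(response.calls_table(resp_calls), outdir / "response.tsv")
        summary = response.summarize_calls(resp_calls)
        (outdir / "response_summary.json").write_text(json.dumps(summary, indent=2))
        manifest["stages"]["respond"] = {"n_patients": len(resp_calls), **summary}

    # ---- survival ---------------------------------------------------------
    if resp_calls:
        groups_by_pid = {c.patient_id: c.group for c in resp_calls}
        records = simulate.simulate_survival(groups_by_pid, seed=config.seed + 2) \
            if config.simulate else None
        if records is not None:
            by_group: dict[str, list] = {}
            for r in records:
                by_group.setdefault(r.stratum, []).append(r)
            if len(by_group) >= 2 and "good" in by_group:
                table = survival.median_table(by_group, reference="good")
                write_table(table, outdir / "survival.tsv")
                chi2, p = survival.logrank_test(by_group)
                manifest["stages"]["survival"] = {
                    "logrank_chi2": chi2, "logrank_p": p,
                    "n_per_group": {g: len(v) for g, v in by_group.items()},
                }

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
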