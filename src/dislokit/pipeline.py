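"""End-to-end orchestration: simulate → build cohort → classify → evaluate.

The patient-level pipeline answers "which patients had at least one
dislocation" (risk of dislocation); the event-level pipeline answers "which
dislocation episodes are captured" (relevant when every episode matters,
e.g. smaller clinical studies).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd

from . import io as dio
from .classifier import (
    ALL_STEPS,
    STEPS,
    classify_events,
    classify_patients,
    match_contacts_to_events,
    review_adjust,
)
from .cohort import Cohort, build_cohort, window_contacts
from .metrics import (
    Incidence,
    accuracy,
    confusion,
    incidence,
    review_burden,
    round_half_up,
)
from .model import CodeSet, DislokitError
from .simulate import CalibrationProfile, default_profile, event_profile, generate

#: Human-readable description of the codes each step adds (flow summary).
STEP_CODES_ADDED = {
    1: "DT840(A) + KNFH20, laterality known",
    2: "KNFH20 alone (any diagnosis), laterality known",
    3: "DS730 / KNFH00, KNFH02, KNFH21, KNFH22, laterality known",
    4: "step 1-3 codes with unknown laterality",
    "4A": "step 4 after chart review of group-4 contacts",
    5: "DT840(A) alone, acute or ER contact, laterality known",
    "5A": "step 5 after chart review of group-4/5 contacts",
}

METRIC_ROW_ORDER = (1, 2, 3, 4, "4A", 5, "5A")


def metrics_table(classifications, truth) -> pd.DataFrame:
    """Accuracy per step against the gold standard, one row per step.

    Rows are ordered 1, 2, 3, 4, 4A, 5, 5A; review steps assume
    :func:`review_adjust` has been applied.
    """
    rows = []
    for step in METRIC_ROW_ORDER:
        ct = confusion(classifications, truth, step)
        acc = accuracy(ct)
        burden = review_burden(classifications, step) if step in ("4A", "5A") else None
        row = {
            "step": str(step),
            "codes_added": STEP_CODES_ADDED[step],
            "tp": ct.tp, "fp": ct.fp, "tn": ct.tn, "fn": ct.fn,
            "flagged": ct.tp + ct.fp,
        }
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            m = getattr(acc, name)
            row[name] = m.value if m else None
            row[f"{name}_low"] = m.ci_low if m else None
            row[f"{name}_high"] = m.ci_high if m else None
        row["review_patients"] = burden.patients if burden else 0
        row["review_contacts"] = burden.contacts if burden else 0
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PatientPipelineResult:
    cohort: Cohort
    windowed: Dict
    classifications: List
    truth: List
    metrics: pd.DataFrame
    incidence: Incidence

    def metric(self, step, name: str) -> float:
        row = self.metrics.loc[self.metrics["step"] == str(step)]
        return float(row.iloc[0][name])


def evaluate_registry(
    cohort_records, contacts, truth, codes: Optional[CodeSet] = None
) -> PatientPipelineResult:
    """Run cohort building, classification, review and evaluation on loaded
    registry objects."""
    codes = codes or CodeSet()
    cohort = build_cohort(cohort_records)
    windowed = window_contacts(cohort, contacts)
    classifications = classify_patients(cohort, windowed, codes)
    review_adjust(classifications, truth, "4A")
    review_adjust(classifications, truth, "5A")
    return PatientPipelineResult(
        cohort=cohort,
        windowed=windowed,
        classifications=classifications,
        truth=list(truth),
        metrics=metrics_table(classifications, truth),
        incidence=incidence(cohort, truth),
    )


def run_patient_pipeline(
    profile: Optional[CalibrationProfile] = None,
    seed: int = 42,
    mode: str = "quota",
    codes: Optional[CodeSet] = None,
) -> PatientPipelineResult:
    """Simulate a registry and evaluate the algorithm at patient level."""
    profile = profile or default_profile()
    cohort_df, contacts_df, truth_df = generate(profile, seed=seed, mode=mode, codes=codes)
    return evaluate_registry(
        dio.cohort_from_df(cohort_df),
        dio.contacts_from_df(contacts_df),
        dio.truth_from_df(truth_df),
        codes=codes,
    )


@dataclass
class EventPipelineResult:
    total_events: int
    metrics: pd.DataFrame  # per step: detected, sensitivity, flagged, ppv

    def metric(self, step, name: str) -> float:
        row = self.metrics.loc[self.metrics["step"] == str(step)]
        return float(row.iloc[0][name])


def event_metrics_table(event_detections, classifications, matching) -> pd.DataFrame:
    """Event-level sensitivity and PPV per step (steps 1-5).

    Sensitivity: detected episodes / all verified episodes. PPV: qualifying
    contacts matched to a verified episode / all qualifying contacts, at
    group <= step.
    """
    groups = {}
    for c in classifications:
        groups.update(c.contact_groups)
    n_events = len(event_detections)
    rows = []
    for k in STEPS:
        detected = sum(e.detected_at_step[k] for e in event_detections)
        flagged = [cid for cid, g in groups.items() if g <= k]
        matched = sum(1 for cid in flagged if matching.get(cid) is not None)
        rows.append(
            {
                "step": str(k),
                "events_detected": detected,
                "events_total": n_events,
                "sensitivity": round_half_up(100.0 * detected / n_events),
                "sensitivity_whole": round_half_up(100.0 * detected / n_events, 0),
                "contacts_flagged": len(flagged),
                "ppv": round_half_up(100.0 * matched / len(flagged)) if flagged else None,
            }
        )
    return pd.DataFrame(rows)


def run_event_pipeline(
    profile: Optional[CalibrationProfile] = None,
    seed: int = 42,
    mode: str = "quota",
    codes: Optional[CodeSet] = None,
) -> EventPipelineResult:
    """Simulate an event-calibrated registry and evaluate per episode."""
    profile = profile or event_profile()
    codes = codes or CodeSet()
    cohort_df, contacts_df, truth_df = generate(profile, seed=seed, mode=mode, codes=codes)
    cohort = build_cohort(dio.cohort_from_df(cohort_df))
    contacts = dio.contacts_from_df(contacts_df)
    truth = dio.truth_from_df(truth_df)
    windowed = window_contacts(cohort, contacts)
    classifications = classify_patients(cohort, windowed, codes)
    detections = classify_events(truth, classifications, windowed)
    matching = match_contacts_to_events(truth, classifications, windowed)
    return EventPipelineResult(
        total_events=len(truth),
        metrics=event_metrics_table(detections, classifications, matching),
    )


# ---------------------------------------------------------------------------
# configured end-to-end run (CLI `run` subcommand)
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration for an end-to-end run.

    Either ``profile`` (a calibration profile to simulate from; "default"
    and "event" name the built-ins) or explicit registry paths
    (cohort/contacts/truth) must be given.
    """

    out_dir: str = "runs/latest"
    seed: int = 42
    mode: str = "quota"
    level: str = "patient"
    profile: Optional[str] = "default"
    cohort_path: Optional[str] = None
    contacts_path: Optional[str] = None
    truth_path: Optional[str] = None
    codes_path: Optional[str] = None

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls(**data)

    def validate(self) -> None:
        if self.level not in ("patient", "event"):
            raise DislokitError(f"level must be patient or event: {self.level!r}")
        simulated = self.profile is not None
        if not simulated:
            for name in ("cohort_path", "contacts_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise DislokitError(f"input path missing: {name}={p}")
            if self.truth_path is None:
                raise DislokitError(
                    "review_adjust (steps 4A/5A) and evaluation require a truth "
                    "table; supply truth_path or simulate"
                )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write a machine-readable report.

    Writes ``metrics.csv`` (7 step rows at patient level), a flow summary
    mirroring the published flowchart, and ``run_report.json`` with seeds
    and versions. Returns the report dict.
    """
    from . import __version__

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    codes = CodeSet.from_file(config.codes_path) if config.codes_path else CodeSet()
    stages = []

    def stage(name):
        stages.append(name)

    try:
        if config.profile is not None:
            stage("simulate")
            profile = {
                "default": default_profile,
                "event": event_profile,
            }.get(config.profile)
            profile = profile() if profile else CalibrationProfile.from_yaml(config.profile)
            cohort_df, contacts_df, truth_df = generate(
                profile, seed=config.seed, mode=config.mode, codes=codes, out_dir=out / "registry"
            )
            records = dio.cohort_from_df(cohort_df)
            contacts = dio.contacts_from_df(contacts_df)
            truth = dio.truth_from_df(truth_df)
        else:
            stage("load")
            records = dio.read_cohort(config.cohort_path)
            contacts = dio.read_contacts(config.contacts_path)
            truth = dio.read_truth(config.truth_path)

        if config.level == "patient":
            stage("build-cohort")
            stage("classify")
            stage("evaluate")
            result = evaluate_registry(records, contacts, truth, codes=codes)
            dio.write_csv(result.metrics, out / "metrics.csv")
            flow = result.metrics[
                ["step", "codes_added", "flagged", "tp", "fp",
                 "sensitivity", "specificity", "ppv", "npv",
                 "review_patients", "review_contacts"]
            ]
            dio.write_csv(flow, out / "flow_summary.csv")
            summary = {
                "incidence_pct": result.incidence.percent,
                "positives": result.incidence.numerator,
                "cohort_size": result.incidence.denominator,
            }
        else:
            stage("build-cohort")
            stage("classify-events")
            stage("evaluate")
            cohort = build_cohort(records)
            windowed = window_contacts(cohort, contacts)
            classifications = classify_patients(cohort, windowed, codes)
            detections = classify_events(truth, classifications, windowed)
            matching = match_contacts_to_events(truth, classifications, windowed)
            table = event_metrics_table(detections, classifications, matching)
            dio.write_csv(table, out / "metrics.csv")
            summary = {"total_events": len(truth)}
    except Exception as exc:
        raise DislokitError(f"stage {stages[-1] if stages else 'setup'} failed: {exc}") from exc

    report = {
        "version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "level": config.level,
        "stages": stages,
        **summary,
    }
    (out / "run_report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
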