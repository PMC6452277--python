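"""End-to-end pipeline orchestration, summary tables, and run manifests.

The stages run in processing order — consolidate ADT encounters, restrict
and dedupe charges, classify and clean audit events, link events to
admissions, attach charges, sessionize, stamp provision days, apply
cohort filters, compute metrics at the three levels — with every stage's
drop/merge/dedup counts collected into a manifest that reconciles the
event ledger end to end:

    input events = linked + near-dropped + far-dropped
                   + removed + collapsed + deduped

Summaries mirror the two standard reporting tables: per-function
frequency (median, IQR, min, max per level) and the distribution of
distinct-function counts 0–9.  Quantiles use linear interpolation
(named in the manifest).  All thresholds live in one config block so a
sensitivity re-run is a single flag away.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import io as ipio
from .charges import dedupe_hospital_accounts, filter_inpatient
from .encounters import DEFAULT_MERGE_GAP_HOURS, consolidate
from .linkage import (
    DEFAULT_NEAR_WINDOW_HOURS,
    attach_charges,
    link_events,
)
from .metrics import (
    DEFAULT_LOS_HARD_CAP,
    DEFAULT_MAX_PROVISION_DAY,
    DEFAULT_MIN_GROUP_SIZE,
    assign_provision_days,
    compute_metrics,
    filter_admissions_by_los,
    provisioning_heatmap,
)
from .models import (
    Admission,
    AuditEvent,
    ChargeRecord,
    CORE_FUNCTIONS,
    ClassifiedEvent,
    Level,
    ProvisionContext,
    RawEncounter,
    Session,
    UsageMetrics,
)
from .sessions import (
    DEFAULT_SESSION_GAP_MINUTES,
    build_sessions,
    session_diagnostics,
)
from .taxonomy import (
    ExternalAction,
    Taxonomy,
    clean_events,
    load_external_map,
    load_taxonomy,
)

QUANTILE_RULE = "linear interpolation"


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline in one place."""

    merge_gap_hours: float = DEFAULT_MERGE_GAP_HOURS
    session_gap_minutes: float = DEFAULT_SESSION_GAP_MINUTES
    near_window_hours: float = DEFAULT_NEAR_WINDOW_HOURS
    los_hard_cap: int = DEFAULT_LOS_HARD_CAP
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE
    max_provision_day: int = DEFAULT_MAX_PROVISION_DAY
    strict_class: bool = False
    strict_actions: bool = False
    apply_los_filter: bool = True
    taxonomy_path: Optional[str] = None
    external_map_path: Optional[str] = None

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    admissions: list[Admission]
    admissions_in_cohort: list[Admission]
    events: list[ClassifiedEvent]
    sessions: list[Session]
    contexts: list[ProvisionContext]
    metrics: dict[Level, list[UsageMetrics]]
    reports: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


class StageError(RuntimeError):
    """A stage failed; carries the stage name and reports collected so
    far."""

    def __init__(self, stage: str, reports: dict, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.reports = reports


def run_pipeline(
    events: Sequence[AuditEvent],
    encounters: Sequence[RawEncounter],
    charges: Optional[Sequence[ChargeRecord]] = None,
    config: Optional[PipelineConfig] = None,
    taxonomy: Optional[Taxonomy] = None,
    external_map: Optional[dict[str, ExternalAction]] = None,
) -> PipelineResult:
    """Run all stages on in-memory records; see the module docstring.

    ``charges=None`` skips charge restriction and attachment (the
    no-charges mode); everything else is unchanged.
    """
    cfg = config or PipelineConfig()
    if taxonomy is None:
        taxonomy = load_taxonomy(cfg.taxonomy_path)
    if external_map is None and cfg.external_map_path:
        external_map = load_external_map(cfg.external_map_path)
    reports: dict = {}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, reports, exc) from exc
        return deco

    @stage("consolidate_encounters")
    def admissions():
        adms = consolidate(encounters, cfg.merge_gap_hours)
        reports["consolidation"] = {
            "n_encounters": len(encounters),
            "n_admissions": len(adms),
            "n_merged": len(encounters) - len(adms),
        }
        return adms

    deduped_charges: Optional[list[ChargeRecord]] = None
    if charges is not None:
        @stage("process_charges")
        def deduped_charges():
            inpatient, frep = filter_inpatient(charges, cfg.strict_class)
            deduped, drep = dedupe_hospital_accounts(inpatient)
            reports["charge_filter"] = dataclasses.asdict(frep)
            reports["charge_dedup"] = dataclasses.asdict(drep)
            return deduped

    @stage("clean_events")
    def cleaned():
        cleaned, crep = clean_events(
            events, taxonomy, external_map, strict=cfg.strict_actions,
            login_run_max_gap_minutes=cfg.session_gap_minutes)
        reports["cleaning"] = dataclasses.asdict(crep)
        return cleaned

    @stage("link_events")
    def linked():
        linked, lrep = link_events(cleaned, admissions,
                                   cfg.near_window_hours)
        reports["linkage"] = dataclasses.asdict(lrep)
        return linked

    if deduped_charges is not None:
        @stage("attach_charges")
        def admissions_with_dx():
            out, arep = attach_charges(admissions, deduped_charges)
            reports["charge_attach"] = dataclasses.asdict(arep)
            return out
    else:
        admissions_with_dx = admissions

    @stage("sessionize")
    def sessions():
        return build_sessions(linked, cfg.session_gap_minutes)

    @stage("provision_days")
    def stamped():
        evs, contexts, flagged = assign_provision_days(
            linked, admissions_with_dx)
        reports["provisioning"] = {
            "n_contexts": len(contexts),
            "admissions_without_events": flagged,
        }
        return evs, contexts

    linked_stamped, contexts = stamped

    @stage("cohort_filter")
    def cohort():
        if not cfg.apply_los_filter or not admissions_with_dx:
            reports["los_filter"] = {"applied": False}
            return list(admissions_with_dx)
        kept, cap = filter_admissions_by_los(
            admissions_with_dx, cfg.los_hard_cap, cfg.min_group_size)
        reports["los_filter"] = {
            "applied": True, "effective_cap": cap,
            "n_admissions_in": len(admissions_with_dx),
            "n_admissions_kept": len(kept),
        }
        return kept

    cohort_ids = {a.admission_id for a in cohort}
    sess_cohort = [s for s in sessions if s.admission_id in cohort_ids]
    ev_cohort = [e for e in linked_stamped
                 if e.admission_id in cohort_ids]

    @stage("metrics")
    def metric_tables():
        return {
            lvl: compute_metrics(sess_cohort, ev_cohort, lvl,
                                 cfg.max_provision_day)
            for lvl in Level
        }

    n_clean_in = reports["cleaning"]["n_input"]
    lr, cr = reports["linkage"], reports["cleaning"]
    reconciled = (lr["n_linked"] + lr["n_dropped_near"]
                  + lr["n_dropped_far"] + cr["n_removed"]
                  + cr["n_login_collapsed"] + cr["n_deduped"])
    manifest = {
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.content_hash(),
        "quantile_rule": QUANTILE_RULE,
        "n_input_events": n_clean_in,
        "event_ledger_reconciled": reconciled == n_clean_in,
        "counts": {
            "linked": lr["n_linked"],
            "dropped_near": lr["n_dropped_near"],
            "dropped_far": lr["n_dropped_far"],
            "removed": cr["n_removed"],
            "login_collapsed": cr["n_login_collapsed"],
            "deduped": cr["n_deduped"],
        },
        "n_sessions": len(sessions),
        "n_admissions": len(admissions),
    }
    if not manifest["event_ledger_reconciled"]:
        raise StageError("reconciliation", reports,
                         AssertionError("event ledger does not reconcile"))

    return PipelineResult(
        admissions=admissions_with_dx,
        admissions_in_cohort=cohort,
        events=linked_stamped,
        sessions=sessions,
        contexts=contexts,
        metrics=metric_tables,
        reports=reports,
        manifest=manifest,
    )


# --------------------------------------------------------------------------
# Summary tables
# --------------------------------------------------------------------------

def summarize_frequency(
    metrics: Sequence[UsageMetrics], level: Union[Level, str],
) -> pd.DataFrame:
    """Median / IQR / min / max of per-function frequency at one level.

    One row per core function.  IQR is Q3 − Q1 with linear-interpolation
    quantiles.
    """
    level = Level(level)
    rows = [m for m in metrics if m.level is level]
    if not rows:
        raise ValueError(f"no metrics at level {level.value!r}")
    out = []
    for func in CORE_FUNCTIONS:
        vals = np.array([m.frequency.get(func, 0) for m in rows])
        q1, med, q3 = np.percentile(vals, [25, 50, 75],
                                    method="linear")
        out.append({
            "function": func.value,
            "median": med,
            "q1": q1,
            "q3": q3,
            "iqr": q3 - q1,
            "min": int(vals.min()),
            "max": int(vals.max()),
            "n_units": len(vals),
        })
    return pd.DataFrame(out)


def summarize_comprehensiveness(
    metrics: Sequence[UsageMetrics], level: Union[Level, str],
) -> pd.DataFrame:
    """Counts and percentages of units by distinct-function count 0-9."""
    level = Level(level)
    rows = [m for m in metrics if m.level is level]
    n = len(rows)
    counts = np.bincount([m.comprehensiveness for m in rows],
                         minlength=10)[:10]
    return pd.DataFrame({
        "n_functions": np.arange(10),
        "count": counts,
        "percent": np.round(100.0 * counts / n, 2) if n else counts * 0.0,
    })


# --------------------------------------------------------------------------
# File-level entry point
# --------------------------------------------------------------------------

def run_pipeline_files(
    audit_path,
    adt_path,
    out_dir,
    charges_path=None,
    config: Optional[PipelineConfig] = None,
    schema: Optional[ipio.SchemaConfig] = None,
) -> PipelineResult:
    """Read the three CSVs, run the pipeline, write every output table.

    Outputs under ``out_dir``: ``admissions.csv``, ``sessions.csv``,
    ``metrics_{session,admission,patient}.csv``, frequency and
    comprehensiveness summary tables per level, the provisioning heatmap
    matrices, session-length diagnostics, per-stage reports and the run
    manifest (JSON).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config or PipelineConfig()

    events, ev_rep = ipio.read_audit_log(audit_path, schema)
    encounters, adt_rep = ipio.read_encounters(adt_path, schema)
    charges = None
    if charges_path is not None:
        charges, ch_rep = ipio.read_charges(charges_path, schema)
        ch_rep.to_json(out / "load_report_charges.json")
    ev_rep.to_json(out / "load_report_audit.json")
    adt_rep.to_json(out / "load_report_adt.json")

    result = run_pipeline(events, encounters, charges, cfg)

    ipio.write_table(result.admissions, out / "admissions.csv",
                     kind="admissions")
    ipio.write_table(result.sessions, out / "sessions.csv",
                     kind="sessions")
    ipio.write_table(result.contexts, out / "provision_contexts.csv",
                     kind="provision")
    for lvl, ms in result.metrics.items():
        ipio.write_table(ms, out / f"metrics_{lvl.value}.csv",
                         kind="metrics")
        if ms:
            summarize_frequency(ms, lvl).to_csv(
                out / f"summary_frequency_{lvl.value}.csv", index=False)
        summarize_comprehensiveness(ms, lvl).to_csv(
            out / f"summary_comprehensiveness_{lvl.value}.csv",
            index=False)

    heat = provisioning_heatmap(result.contexts)
    heat["counts"].to_csv(out / "heatmap_counts.csv")
    heat["percent"].to_csv(out / "heatmap_percent.csv")

    diag = session_diagnostics(result.sessions)
    diag["duration"].to_csv(out / "session_duration_hist.csv",
                            index=False)
    diag["events_per_session"].to_csv(
        out / "session_event_count_hist.csv", index=False)

    with open(out / "stage_reports.json", "w", encoding="utf-8") as fh:
        json.dump(result.reports, fh, indent=2, default=str)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
    return result
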