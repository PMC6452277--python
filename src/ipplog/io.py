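"""CSV input/output with schema mapping and load reporting.

Epic extract headers vary by site, so column names are mapped through a
:class:`SchemaConfig` (optionally loaded from YAML) rather than hard-coded.
Readers return record lists plus a :class:`LoadReport` that conserves
counts (accepted + rejected = input rows); writers emit a deterministic
column order with ISO-8601 timestamps so round trips are exact to the
second.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from .models import (
    Admission,
    AuditEvent,
    ChargeRecord,
    ClassifiedEvent,
    EncounterClass,
    Function,
    Level,
    ProvisionContext,
    RawEncounter,
    Session,
    UsageMetrics,
)

PathLike = Union[str, Path]

#: Timestamp formats tried in order when none is configured: ISO-8601 first,
#: then the US-style month/day/year clock stamp audit extracts commonly use.
DEFAULT_TS_FORMATS = ("ISO8601", "%m/%d/%Y %H:%M:%S")

_LIST_SEP = ";"  # separator for list-valued cells (diagnosis codes, ids)


@dataclass
class SchemaConfig:
    """Column-name mapping for the three input tables.

    Values are ``{logical_name: actual_header}``; unspecified tables use
    the logical names directly.  ``timestamp_format`` may be ``"ISO8601"``
    or a ``strptime`` pattern; ``None`` tries :data:`DEFAULT_TS_FORMATS`.
    """

    audit: dict[str, str] = field(default_factory=dict)
    adt: dict[str, str] = field(default_factory=dict)
    charges: dict[str, str] = field(default_factory=dict)
    timestamp_format: Optional[str] = None
    max_reject_fraction: float = 0.05

    @classmethod
    def from_yaml(cls, path: PathLike) -> "SchemaConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            audit=raw.get("audit", {}) or {},
            adt=raw.get("adt", {}) or {},
            charges=raw.get("charges", {}) or {},
            timestamp_format=raw.get("timestamp_format"),
            max_reject_fraction=raw.get("max_reject_fraction", 0.05),
        )

    def column(self, table: str, logical: str) -> str:
        return getattr(self, table).get(logical, logical)


@dataclass
class LoadReport:
    """Per-file load accounting: accepted + rejected = input rows."""

    path: str
    n_rows: int = 0
    n_accepted: int = 0
    n_rejected: int = 0
    reject_examples: list[str] = field(default_factory=list)

    def check_conservation(self) -> None:
        assert self.n_accepted + self.n_rejected == self.n_rows

    def to_json(self, path: PathLike) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


class LoadError(RuntimeError):
    """Raised on missing files/columns or an excessive reject fraction."""


def _parse_timestamps(raw: pd.Series, fmt: Optional[str]) -> pd.Series:
    formats = (fmt,) if fmt else DEFAULT_TS_FORMATS
    parsed = pd.Series(pd.NaT, index=raw.index)
    remaining = raw.astype("string")
    for f in formats:
        mask = parsed.isna()
        if not mask.any():
            break
        parsed.loc[mask] = pd.to_datetime(
            remaining[mask], format=f, errors="coerce"
        )
    return parsed


def _require_columns(df: pd.DataFrame, cols: Sequence[str],
                     path: PathLike) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing mandatory column(s) {missing}")


def _read_csv(path: PathLike) -> pd.DataFrame:
    p = Path(path)
    if not p.exists():
        raise LoadError(f"input file not found: {p}")
    return pd.read_csv(p, dtype="string", keep_default_na=False,
                       na_values=[""])


# --------------------------------------------------------------------------
# Readers
# --------------------------------------------------------------------------

def read_audit_log(
    path: PathLike, schema: Optional[SchemaConfig] = None
) -> tuple[list[AuditEvent], LoadReport]:
    """Read raw audit-log events; reject rows with unparseable timestamps.

    Aborts with :class:`LoadError` when the reject fraction exceeds the
    configured ceiling (default 5%), since that signals a format mismatch
    rather than scattered bad rows.
    """
    schema = schema or SchemaConfig()
    df = _read_csv(path)
    cols = {k: schema.column("audit", k)
            for k in ("patient_id", "action", "timestamp")}
    _require_columns(df, list(cols.values()), path)
    ext_col = schema.column("audit", "extended_info")

    report = LoadReport(path=str(path), n_rows=len(df))
    ts = _parse_timestamps(df[cols["timestamp"]], schema.timestamp_format)
    bad = ts.isna() | df[cols["patient_id"]].isna()
    report.n_rejected = int(bad.sum())
    report.n_accepted = len(df) - report.n_rejected
    report.reject_examples = df.loc[bad, cols["timestamp"]].head(5).tolist()
    if len(df) and report.n_rejected / len(df) > schema.max_reject_fraction:
        raise LoadError(
            f"{path}: {report.n_rejected}/{len(df)} rows unparseable "
            f"(limit {schema.max_reject_fraction:.0%})"
        )

    good = df.loc[~bad]
    ext = (good[ext_col] if ext_col in good.columns
           else pd.Series(pd.NA, index=good.index))
    events = [
        AuditEvent(
            patient_id=str(pid),
            action=str(act),
            timestamp=t.to_pydatetime(),
            extended_info=None if pd.isna(x) else str(x),
        )
        for pid, act, t, x in zip(
            good[cols["patient_id"]], good[cols["action"]], ts[~bad], ext
        )
    ]
    report.check_conservation()
    return events, report


def read_encounters(
    path: PathLike, schema: Optional[SchemaConfig] = None
) -> tuple[list[RawEncounter], LoadReport]:
    """Read raw ADT encounter records."""
    schema = schema or SchemaConfig()
    df = _read_csv(path)
    cols = {k: schema.column("adt", k)
            for k in ("patient_id", "encounter_id", "admit", "discharge",
                      "encounter_class")}
    _require_columns(df, list(cols.values()), path)
    acct_col = schema.column("adt", "hospital_account_id")

    admit = _parse_timestamps(df[cols["admit"]], schema.timestamp_format)
    disch = _parse_timestamps(df[cols["discharge"]], schema.timestamp_format)
    bad = admit.isna() | disch.isna() | df[cols["patient_id"]].isna()
    report = LoadReport(path=str(path), n_rows=len(df),
                        n_rejected=int(bad.sum()))
    report.n_accepted = len(df) - report.n_rejected

    good = df.loc[~bad]
    acct = (good[acct_col] if acct_col in good.columns
            else pd.Series(pd.NA, index=good.index))
    encounters = [
        RawEncounter(
            patient_id=str(pid),
            encounter_id=str(eid),
            admit=a.to_pydatetime(),
            discharge=d.to_pydatetime(),
            encounter_class=EncounterClass(str(cls)),
            hospital_account_id=None if pd.isna(h) else str(h),
        )
        for pid, eid, a, d, cls, h in zip(
            good[cols["patient_id"]], good[cols["encounter_id"]],
            admit[~bad], disch[~bad], good[cols["encounter_class"]], acct,
        )
    ]
    report.check_conservation()
    return encounters, report


def read_charges(
    path: PathLike, schema: Optional[SchemaConfig] = None
) -> tuple[list[ChargeRecord], LoadReport]:
    """Read hospital-charges records; diagnosis codes are ';'-separated."""
    schema = schema or SchemaConfig()
    df = _read_csv(path)
    cols = {k: schema.column("charges", k)
            for k in ("hospital_account_id", "patient_id", "admit",
                      "discharge", "diagnosis_codes", "encounter_class")}
    _require_columns(
        df, [cols["hospital_account_id"], cols["patient_id"],
             cols["admit"], cols["discharge"], cols["encounter_class"]],
        path,
    )
    admit = _parse_timestamps(df[cols["admit"]], schema.timestamp_format)
    disch = _parse_timestamps(df[cols["discharge"]], schema.timestamp_format)
    bad = (admit.isna() | disch.isna()
           | df[cols["hospital_account_id"]].isna())
    report = LoadReport(path=str(path), n_rows=len(df),
                        n_rejected=int(bad.sum()))
    report.n_accepted = len(df) - report.n_rejected

    good = df.loc[~bad]
    dx = (good[cols["diagnosis_codes"]]
          if cols["diagnosis_codes"] in good.columns
          else pd.Series(pd.NA, index=good.index))
    charges = [
        ChargeRecord(
            hospital_account_id=str(h),
            patient_id=str(pid),
            admit=a.to_pydatetime(),
            discharge=d.to_pydatetime(),
            diagnosis_codes=(
                () if pd.isna(codes)
                else tuple(c for c in str(codes).split(_LIST_SEP) if c)
            ),
            encounter_class=EncounterClass(str(cls)),
        )
        for h, pid, a, d, codes, cls in zip(
            good[cols["hospital_account_id"]], good[cols["patient_id"]],
            admit[~bad], disch[~bad], dx, good[cols["encounter_class"]],
        )
    ]
    report.check_conservation()
    return charges, report


# --------------------------------------------------------------------------
# Writers: record lists -> CSV with deterministic column order
# --------------------------------------------------------------------------

def _iso(ts: datetime) -> str:
    return ts.isoformat(sep=" ", timespec="seconds")


_COLUMNS: dict[str, list[str]] = {
    "audit": ["patient_id", "action", "extended_info", "timestamp"],
    "adt": ["patient_id", "encounter_id", "hospital_account_id", "admit",
            "discharge", "encounter_class"],
    "charges": ["hospital_account_id", "patient_id", "admit", "discharge",
                "diagnosis_codes", "encounter_class"],
    "admissions": ["patient_id", "admission_id", "start", "end",
                   "source_encounter_ids", "hospital_account_ids",
                   "diagnosis_codes", "charge_matched"],
    "classified": ["patient_id", "action", "extended_info", "timestamp",
                   "function", "active", "admission_id", "provision_day"],
    "sessions": ["session_id", "patient_id", "admission_id", "start", "end",
                 "event_count", "active_task_counts", "zero_time"],
    "metrics": ["level", "unit_id", "frequency", "comprehensiveness",
                "comprehensiveness_pct", "n_sessions", "admin_active_count"],
    "provision": ["admission_id", "patient_id", "provision_date",
                  "los_days", "provisioning_day"],
}


def _row(rec) -> dict:  # noqa: C901 - simple per-type dispatch
    if isinstance(rec, AuditEvent):
        return {"patient_id": rec.patient_id, "action": rec.action,
                "extended_info": rec.extended_info or "",
                "timestamp": _iso(rec.timestamp)}
    if isinstance(rec, RawEncounter):
        return {"patient_id": rec.patient_id,
                "encounter_id": rec.encounter_id,
                "hospital_account_id": rec.hospital_account_id or "",
                "admit": _iso(rec.admit), "discharge": _iso(rec.discharge),
                "encounter_class": rec.encounter_class.value}
    if isinstance(rec, ChargeRecord):
        return {"hospital_account_id": rec.hospital_account_id,
                "patient_id": rec.patient_id, "admit": _iso(rec.admit),
                "discharge": _iso(rec.discharge),
                "diagnosis_codes": _LIST_SEP.join(rec.diagnosis_codes),
                "encounter_class": rec.encounter_class.value}
    if isinstance(rec, Admission):
        return {"patient_id": rec.patient_id,
                "admission_id": rec.admission_id,
                "start": _iso(rec.start), "end": _iso(rec.end),
                "source_encounter_ids":
                    _LIST_SEP.join(rec.source_encounter_ids),
                "hospital_account_ids":
                    _LIST_SEP.join(sorted(rec.hospital_account_ids)),
                "diagnosis_codes": _LIST_SEP.join(rec.diagnosis_codes),
                "charge_matched": rec.charge_matched}
    if isinstance(rec, ClassifiedEvent):
        return {"patient_id": rec.patient_id, "action": rec.action,
                "extended_info": rec.extended_info or "",
                "timestamp": _iso(rec.timestamp),
                "function": rec.function.value, "active": rec.active,
                "admission_id": rec.admission_id or "",
                "provision_day": ("" if rec.provision_day is None
                                  else rec.provision_day)}
    if isinstance(rec, Session):
        return {"session_id": rec.session_id, "patient_id": rec.patient_id,
                "admission_id": rec.admission_id, "start": _iso(rec.start),
                "end": _iso(rec.end), "event_count": rec.event_count,
                "active_task_counts": json.dumps(
                    {f.value: n for f, n
                     in sorted(rec.active_task_counts.items())}),
                "zero_time": rec.zero_time}
    if isinstance(rec, UsageMetrics):
        return {"level": rec.level.value, "unit_id": rec.unit_id,
                "frequency": json.dumps(
                    {f.value: n for f, n in sorted(rec.frequency.items())}),
                "comprehensiveness": rec.comprehensiveness,
                "comprehensiveness_pct":
                    round(rec.comprehensiveness_pct, 2),
                "n_sessions": rec.n_sessions,
                "admin_active_count": rec.admin_active_count}
    if isinstance(rec, ProvisionContext):
        return {"admission_id": rec.admission_id,
                "patient_id": rec.patient_id,
                "provision_date": rec.provision_date.isoformat(),
                "los_days": rec.los_days,
                "provisioning_day": rec.provisioning_day}
    raise TypeError(f"unsupported record type: {type(rec).__name__}")


_KIND_OF_TYPE = {
    AuditEvent: "audit", RawEncounter: "adt", ChargeRecord: "charges",
    Admission: "admissions", ClassifiedEvent: "classified",
    Session: "sessions", UsageMetrics: "metrics",
    ProvisionContext: "provision",
}


def write_table(records: Sequence, path: PathLike,
                kind: Optional[str] = None) -> int:
    """Write a homogeneous record list to CSV; return the data-row count.

    ``kind`` (one of ``audit/adt/charges/admissions/classified/sessions/
    metrics/provision``) is required for an empty list, where the header
    cannot be inferred from the records.
    """
    if records:
        inferred = _KIND_OF_TYPE.get(type(records[0]))
        if inferred is None:
            raise TypeError(
                f"unsupported record type: {type(records[0]).__name__}")
        if kind is not None and kind != inferred:
            raise ValueError(f"kind={kind!r} but records are {inferred!r}")
        kind = inferred
        if any(type(r) is not type(records[0]) for r in records):
            raise TypeError("records must be homogeneous")
    elif kind is None:
        raise ValueError("kind is required when writing an empty list")
    if kind not in _COLUMNS:
        raise ValueError(f"unknown table kind {kind!r}")

    df = pd.DataFrame([_row(r) for r in records], columns=_COLUMNS[kind])
    df.to_csv(path, index=False)
    return len(df)


# --------------------------------------------------------------------------
# Round-trip readers for processed tables (sessions, metrics)
# --------------------------------------------------------------------------

def read_sessions(path: PathLike) -> list[Session]:
    df = pd.read_csv(path, dtype={"session_id": str, "patient_id": str,
                                  "admission_id": str})
    out = []
    for r in df.itertuples(index=False):
        counts = {Function(k): v
                  for k, v in json.loads(r.active_task_counts).items()}
        out.append(Session(
            session_id=r.session_id, patient_id=r.patient_id,
            admission_id=r.admission_id,
            start=datetime.fromisoformat(r.start),
            end=datetime.fromisoformat(r.end),
            event_count=int(r.event_count),
            active_task_counts=counts,
        ))
    return out


def read_metrics(path: PathLike) -> list[UsageMetrics]:
    df = pd.read_csv(path, dtype={"unit_id": str})
    return [
        UsageMetrics(
            level=Level(r.level), unit_id=r.unit_id,
            frequency={Function(k): v
                       for k, v in json.loads(r.frequency).items()},
            comprehensiveness=int(r.comprehensiveness),
            n_sessions=int(r.n_sessions),
            admin_active_count=int(r.admin_active_count),
        )
        for r in df.itertuples(index=False)
    ]
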