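"""Shared record types for the inpatient-portal log pipeline.

The pipeline turns three raw tables — audit-log events, ADT (admission/
discharge/transfer) encounters, and hospital charges — into sessionized
engagement metrics.  Every stage exchanges the plain record types defined
here; pandas DataFrames are used internally for aggregation but the module
boundaries speak in these types.

All timestamps are naive local datetimes at second resolution: a
single-institution extract has one clock, so no timezone arithmetic is
performed anywhere in the package.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from datetime import date, datetime
from enum import Enum
from typing import Optional


# --------------------------------------------------------------------------
# Portal function vocabulary
# --------------------------------------------------------------------------

class Function(str, Enum):
    """The nine patient-facing portal functions plus Administrative.

    A *function* is a group of raw audit-log actions.  Administrative
    collects navigation, login bookkeeping and other plumbing; it is never
    counted in frequency or comprehensiveness.
    """

    EDUCATION = "Access educational materials"
    NOTES = "Access personal notes"
    ADMINISTRATIVE = "Administrative"
    CHECK_MESSAGES = "Check secure messages"
    HAPPENING_SOON = "Happening soon"
    I_WOULD_LIKE = "I would like"
    MYCHART = "MyChart Ambulatory"
    CARE_TEAM = "Review current care team"
    VITALS_LABS = "Review vitals and lab results"
    SEND_MESSAGE = "Send a secure message"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The nine functions that enter frequency and comprehensiveness, in a fixed
#: reporting order.  Administrative is deliberately absent.
CORE_FUNCTIONS: tuple[Function, ...] = tuple(
    f for f in Function if f is not Function.ADMINISTRATIVE
)


class EncounterClass(str, Enum):
    INPATIENT = "inpatient"
    OUTPATIENT = "outpatient"
    EMERGENCY = "emergency"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# --------------------------------------------------------------------------
# Raw inputs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AuditEvent:
    """One raw audit-log record: (patient, action code, extended info, time).

    ``patient_id`` is the de-identified study identifier that replaces the
    MRN; ``action`` is the raw activity code (e.g. ``"Get Care Team"``);
    ``extended_info`` disambiguates external Media/Web content calls.
    """

    patient_id: str
    action: str
    timestamp: datetime
    extended_info: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if not isinstance(self.timestamp, datetime):
            raise TypeError("timestamp must be a datetime")


@dataclass(frozen=True)
class RawEncounter:
    """One raw ADT record (one contact serial number)."""

    patient_id: str
    encounter_id: str
    admit: datetime
    discharge: datetime
    encounter_class: EncounterClass = EncounterClass.INPATIENT
    hospital_account_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.admit > self.discharge:
            raise ValueError(
                f"encounter {self.encounter_id}: admit after discharge"
            )


@dataclass
class Admission:
    """A consolidated continuous-care interval.

    Built from one or more raw encounters after overlap and adjacency
    merging; within one patient, admission intervals are pairwise disjoint
    with gaps strictly greater than the merge threshold.
    """

    patient_id: str
    admission_id: str
    start: datetime
    end: datetime
    source_encounter_ids: tuple[str, ...]
    hospital_account_ids: frozenset[str] = frozenset()
    diagnosis_codes: tuple[str, ...] = ()
    charge_matched: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("admission start after end")
        if not self.source_encounter_ids:
            raise ValueError("admission needs at least one source encounter")


@dataclass(frozen=True)
class ChargeRecord:
    """One hospital-charges row, linking diagnoses to an admission period."""

    hospital_account_id: str
    patient_id: str
    admit: datetime
    discharge: datetime
    diagnosis_codes: tuple[str, ...] = ()
    encounter_class: EncounterClass = EncounterClass.INPATIENT

    def __post_init__(self) -> None:
        if not self.hospital_account_id:
            raise ValueError("hospital_account_id must be non-empty")


# --------------------------------------------------------------------------
# Processed records
# --------------------------------------------------------------------------

@dataclass
class ClassifiedEvent:
    """An audit event after taxonomy mapping and (optionally) linkage.

    ``active`` distinguishes actions the patient intentionally initiated
    from background portal traffic; only active, non-Administrative events
    count toward engagement metrics.  ``provision_day`` is the 0-based
    calendar-day offset from the admission's tablet-provision date.
    """

    patient_id: str
    action: str
    timestamp: datetime
    function: Function
    active: bool
    extended_info: Optional[str] = None
    admission_id: Optional[str] = None
    provision_day: Optional[int] = None


@dataclass
class Session:
    """A maximal run of one patient's events with no over-threshold gap.

    ``zero_time`` is True iff the session activated no function beyond
    Administrative — the landing-screen-only visits that make duration an
    unusable engagement measure.
    """

    session_id: str
    patient_id: str
    admission_id: str
    start: datetime
    end: datetime
    event_count: int
    active_task_counts: dict[Function, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("session start after end")
        if self.event_count < 1:
            raise ValueError("session must contain at least one event")

    @property
    def zero_time(self) -> bool:
        return not any(
            n > 0
            for f, n in self.active_task_counts.items()
            if f is not Function.ADMINISTRATIVE
        )

    @property
    def duration_seconds(self) -> float:
        return (self.end - self.start).total_seconds()


class Level(str, Enum):
    SESSION = "session"
    ADMISSION = "admission"
    PATIENT = "patient"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class UsageMetrics:
    """Per-unit engagement measures at one level of analysis.

    ``frequency`` counts active tasks per core function (Administrative
    excluded); ``comprehensiveness`` is the number of the nine functions
    with nonzero frequency; ``admin_active_count`` tallies active
    Administrative tasks separately so they are visible without polluting
    the nine-function measures.
    """

    level: Level
    unit_id: str
    frequency: dict[Function, int]
    comprehensiveness: int
    n_sessions: int
    admin_active_count: int = 0

    def __post_init__(self) -> None:
        expected = sum(
            1 for f in CORE_FUNCTIONS if self.frequency.get(f, 0) > 0
        )
        if self.comprehensiveness != expected:
            raise ValueError(
                "comprehensiveness inconsistent with frequency map"
            )
        if not 0 <= self.comprehensiveness <= 9:
            raise ValueError("comprehensiveness out of [0, 9]")

    @property
    def comprehensiveness_pct(self) -> float:
        """Auxiliary percentage-of-functions view (c / 9 * 100)."""
        return 100.0 * self.comprehensiveness / 9.0


@dataclass(frozen=True)
class ProvisionContext:
    """Tablet-provisioning timing for one admission.

    ``provision_date`` is the calendar date of the admission's first audit
    event (the extract has no explicit provisioning table, so first use
    stands in for hand-off).  ``provisioning_day`` is days from admission
    to provisioning; ``los_days`` is the calendar-day length of stay.
    """

    admission_id: str
    patient_id: str
    provision_date: date
    los_days: int
    provisioning_day: int

    def __post_init__(self) -> None:
        if self.provisioning_day > self.los_days:
            raise ValueError("provisioning_day exceeds los_days")
        if self.provisioning_day < 0 or self.los_days < 0:
            raise ValueError("negative provisioning_day or los_days")


# --------------------------------------------------------------------------
# Deterministic identifiers
# --------------------------------------------------------------------------

def _digest(*parts: str) -> str:
    return hashlib.sha1("|".join(parts).encode("utf-8")).hexdigest()[:12]


def make_admission_id(patient_id: str, start: datetime) -> str:
    """Deterministic admission id from patient and interval start."""
    return "A-" + _digest(patient_id, start.isoformat())


def make_session_id(patient_id: str, admission_id: str,
                    start: datetime) -> str:
    """Deterministic session id from patient, admission and first event."""
    return "S-" + _digest(patient_id, admission_id, start.isoformat())
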