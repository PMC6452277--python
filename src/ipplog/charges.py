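"""Hospital-charges processing: inpatient restriction and account dedup.

Charges carry the diagnoses attached to an admission period via the
hospital account id.  Because the portal is inpatient-only, outpatient and
emergency charge rows are dropped first; because a single charge may cover
multiple encounters, the extract contains duplicate hospital account ids
(with differing admit/discharge stamps) that must collapse to one row per
account.  Duplicates whose diagnosis payloads disagree are never hidden:
they are resolved deterministically (earliest admit wins) and flagged in
the consistency report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .models import ChargeRecord, EncounterClass


class UnknownEncounterClassError(ValueError):
    pass


@dataclass
class ChargeFilterReport:
    n_input: int = 0
    n_retained: int = 0
    dropped_by_class: dict[str, int] = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped_by_class.values())


@dataclass
class DedupReport:
    n_input: int = 0
    n_retained: int = 0
    n_collapsed: int = 0
    conflicting_account_ids: list[str] = field(default_factory=list)


def filter_inpatient(
    charges: Sequence[ChargeRecord], strict: bool = False
) -> tuple[list[ChargeRecord], ChargeFilterReport]:
    """Keep inpatient charges only; count drops per encounter class.

    With ``strict`` a record whose class is not a known
    :class:`EncounterClass` raises; otherwise it is dropped and counted
    under its raw label.
    """
    report = ChargeFilterReport(n_input=len(charges))
    kept: list[ChargeRecord] = []
    for c in charges:
        cls = c.encounter_class
        if not isinstance(cls, EncounterClass):
            if strict:
                raise UnknownEncounterClassError(str(cls))
            key = str(cls)
            report.dropped_by_class[key] = (
                report.dropped_by_class.get(key, 0) + 1)
            continue
        if cls is EncounterClass.INPATIENT:
            kept.append(c)
        else:
            report.dropped_by_class[cls.value] = (
                report.dropped_by_class.get(cls.value, 0) + 1)
    report.n_retained = len(kept)
    return kept, report


def dedupe_hospital_accounts(
    charges: Sequence[ChargeRecord],
) -> tuple[list[ChargeRecord], DedupReport]:
    """Collapse duplicate hospital account ids to one record each.

    Duplicates with identical diagnosis codes collapse silently; duplicates
    with conflicting codes are flagged in the report and resolved by
    keeping the record with the earliest admit timestamp (ties broken by
    discharge then payload, so the outcome is input-order independent).
    """
    report = DedupReport(n_input=len(charges))
    by_account: dict[str, list[ChargeRecord]] = {}
    for c in charges:
        by_account.setdefault(c.hospital_account_id, []).append(c)

    kept: list[ChargeRecord] = []
    for acct in sorted(by_account):
        group = sorted(by_account[acct],
                       key=lambda c: (c.admit, c.discharge,
                                      c.diagnosis_codes))
        kept.append(group[0])
        report.n_collapsed += len(group) - 1
        payloads = {tuple(sorted(c.diagnosis_codes)) for c in group}
        if len(payloads) > 1:
            report.conflicting_account_ids.append(acct)
    report.n_retained = len(kept)
    return kept, report
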