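"""Temporal linkage of events to admissions, and charge attachment.

The audit log and ADT share no encounter key, so the study identifier plus
time containment is the only join: an event belongs to the admission whose
[start, end] interval (closed on both ends) contains its timestamp.
Events outside every admission are dropped, classified *near* (within a
configurable window of an admission boundary — likely boundary noise) or
*far* (portal use recorded long after any encounter).  Charges attach to
admissions through the hospital account ids collected during encounter
consolidation.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from datetime import timedelta
from typing import Sequence

from .models import Admission, ChargeRecord, ClassifiedEvent

DEFAULT_NEAR_WINDOW_HOURS = 24.0


@dataclass
class LinkReport:
    """Partition accounting: linked + near + far = input events."""

    n_input: int = 0
    n_linked: int = 0
    n_dropped_near: int = 0
    n_dropped_far: int = 0

    def check_conservation(self) -> None:
        assert (self.n_linked + self.n_dropped_near
                + self.n_dropped_far) == self.n_input, "link count leak"


@dataclass
class ChargeAttachReport:
    n_admissions: int = 0
    n_matched: int = 0
    n_unmatched_admissions: int = 0
    n_orphan_charges: int = 0
    orphan_account_ids: list[str] = field(default_factory=list)


def link_events(
    events: Sequence[ClassifiedEvent],
    admissions: Sequence[Admission],
    near_window_hours: float = DEFAULT_NEAR_WINDOW_HOURS,
) -> tuple[list[ClassifiedEvent], LinkReport]:
    """Attach each event to the admission containing its timestamp.

    Requires consolidated (per-patient disjoint) admissions, which make
    containment unambiguous.  Returns the linked events (admission_id set)
    and the drop report; out-of-admission events are classified *near*
    when within ``near_window_hours`` of any admission boundary of that
    patient, else *far*.
    """
    by_patient: dict[str, list[Admission]] = {}
    for adm in admissions:
        by_patient.setdefault(adm.patient_id, []).append(adm)
    starts: dict[str, list] = {}
    for pid, adms in by_patient.items():
        adms.sort(key=lambda a: a.start)
        for prev, nxt in zip(adms, adms[1:]):
            if nxt.start <= prev.end:
                raise ValueError(
                    f"admissions overlap for patient {pid}; consolidate "
                    "before linking")
        starts[pid] = [a.start for a in adms]

    window = timedelta(hours=near_window_hours)
    report = LinkReport(n_input=len(events))
    linked: list[ClassifiedEvent] = []
    for ev in events:
        adms = by_patient.get(ev.patient_id)
        if adms:
            i = bisect.bisect_right(starts[ev.patient_id], ev.timestamp)
            cand = adms[i - 1] if i else None
            if cand is not None and cand.start <= ev.timestamp <= cand.end:
                linked.append(replace(ev, admission_id=cand.admission_id))
                report.n_linked += 1
                continue
            near = any(
                abs(ev.timestamp - a.start) <= window
                or abs(ev.timestamp - a.end) <= window
                for a in adms
            )
        else:
            near = False
        if near:
            report.n_dropped_near += 1
        else:
            report.n_dropped_far += 1
    report.check_conservation()
    return linked, report


def attach_charges(
    admissions: Sequence[Admission],
    charges: Sequence[ChargeRecord],
) -> tuple[list[Admission], ChargeAttachReport]:
    """Attach diagnosis codes to admissions via hospital account ids.

    An admission built from encounters spanning several account ids gets
    the union of the matching charges' diagnoses.  Admissions without a
    matching charge are flagged (``charge_matched=False``), never dropped;
    charges matching no admission are counted as orphans.
    """
    by_account = {c.hospital_account_id: c for c in charges}
    if len(by_account) != len(charges):
        raise ValueError("charges must be deduped before attachment")

    report = ChargeAttachReport(n_admissions=len(admissions))
    used: set[str] = set()
    out: list[Admission] = []
    for adm in admissions:
        matched = [by_account[a] for a in sorted(adm.hospital_account_ids)
                   if a in by_account]
        used.update(c.hospital_account_id for c in matched)
        codes = sorted({d for c in matched for d in c.diagnosis_codes})
        if matched:
            report.n_matched += 1
        else:
            report.n_unmatched_admissions += 1
        out.append(replace(adm, diagnosis_codes=tuple(codes),
                           charge_matched=bool(matched)))
    orphans = sorted(set(by_account) - used)
    report.n_orphan_charges = len(orphans)
    report.orphan_account_ids = orphans[:20]
    return out, report
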