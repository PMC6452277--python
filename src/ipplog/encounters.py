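"""Consolidation of raw ADT encounters into admissions.

A hospital stay often appears in the ADT extract as several raw encounters:
a transfer between facilities produces a new contact serial number, a
procedure at a sister hospital produces an overlapping record ("multiple
admissions but a single discharge"), and so on.  Two transformations turn
these into continuous-care admissions:

1. **Overlap merge** — encounters whose intervals intersect (closed
   intervals; touching counts) are unioned.
2. **Adjacency merge** — consecutive intervals separated by a
   discharge-to-admission gap of at most ``gap_hours`` (default 4, the
   window that covers the bulk of between-facility transfers) are unioned,
   applied transitively to a fixed point.

A gap of exactly ``gap_hours`` merges: "within 4 hours" is read
inclusively.  Admission ids are deterministic hashes of (patient, start),
so re-runs reproduce identical ids.
"""

from __future__ import annotations

from datetime import timedelta
from itertools import groupby
from typing import Sequence

from .models import Admission, RawEncounter, make_admission_id

DEFAULT_MERGE_GAP_HOURS = 4.0


def _single_patient(encounters: Sequence[RawEncounter]) -> str:
    pids = {e.patient_id for e in encounters}
    if len(pids) != 1:
        raise ValueError(
            f"expected encounters for one patient, got {sorted(pids)}")
    return pids.pop()


def merge_overlapping(
    encounters: Sequence[RawEncounter],
) -> list[Admission]:
    """Union overlapping encounters of one patient into admissions.

    Output intervals are the connected components of the interval-overlap
    graph; each admission spans component-min(admit) to component-max(
    discharge) and carries every source encounter id exactly once.
    """
    if not encounters:
        return []
    pid = _single_patient(encounters)
    ordered = sorted(encounters, key=lambda e: (e.admit, e.discharge,
                                                e.encounter_id))
    groups: list[list[RawEncounter]] = [[ordered[0]]]
    reach = ordered[0].discharge
    for enc in ordered[1:]:
        if enc.admit <= reach:  # closed-interval overlap (touching merges)
            groups[-1].append(enc)
            reach = max(reach, enc.discharge)
        else:
            groups.append([enc])
            reach = enc.discharge
    return [_component_to_admission(pid, grp) for grp in groups]


def _component_to_admission(pid: str,
                            group: Sequence[RawEncounter]) -> Admission:
    start = min(e.admit for e in group)
    end = max(e.discharge for e in group)
    return Admission(
        patient_id=pid,
        admission_id=make_admission_id(pid, start),
        start=start,
        end=end,
        source_encounter_ids=tuple(
            sorted(e.encounter_id for e in group)),
        hospital_account_ids=frozenset(
            e.hospital_account_id for e in group
            if e.hospital_account_id),
    )


def merge_adjacent(
    admissions: Sequence[Admission],
    gap_hours: float = DEFAULT_MERGE_GAP_HOURS,
) -> list[Admission]:
    """Merge consecutive admissions separated by at most ``gap_hours``.

    Applied transitively: a chain of sub-threshold gaps collapses into one
    admission.  Inputs must be one patient's pairwise non-overlapping
    admissions.
    """
    if gap_hours < 0:
        raise ValueError("gap_hours must be non-negative")
    if not admissions:
        return []
    pid = _single_patient(admissions)
    gap = timedelta(hours=gap_hours)
    ordered = sorted(admissions, key=lambda a: a.start)
    merged: list[Admission] = [ordered[0]]
    for adm in ordered[1:]:
        prev = merged[-1]
        if adm.start - prev.end <= gap:
            merged[-1] = Admission(
                patient_id=pid,
                admission_id=make_admission_id(pid, prev.start),
                start=prev.start,
                end=max(prev.end, adm.end),
                source_encounter_ids=tuple(sorted(
                    prev.source_encounter_ids + adm.source_encounter_ids)),
                hospital_account_ids=(prev.hospital_account_ids
                                      | adm.hospital_account_ids),
            )
        else:
            merged.append(adm)
    return merged


def consolidate(
    encounters: Sequence[RawEncounter],
    gap_hours: float = DEFAULT_MERGE_GAP_HOURS,
) -> list[Admission]:
    """Full consolidation for any mix of patients.

    Per patient: overlap merge, then adjacency merge re-applied to a fixed
    point (one pass over sorted disjoint intervals already is one, but the
    fixed point is asserted so merge order can never matter).  Idempotent;
    preserves the multiset of encounter ids.
    """
    out: list[Admission] = []
    keyed = sorted(encounters, key=lambda e: (e.patient_id, e.admit,
                                              e.encounter_id))
    for _, grp in groupby(keyed, key=lambda e: e.patient_id):
        admissions = merge_overlapping(list(grp))
        while True:
            merged = merge_adjacent(admissions, gap_hours)
            if len(merged) == len(admissions):
                break
            admissions = merged
        out.extend(merged)
    out.sort(key=lambda a: (a.patient_id, a.start))
    return out
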