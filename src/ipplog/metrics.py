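"""Engagement metrics: LOS conventions, provision days, frequency and
comprehensiveness.

Conventions, all calendar-day based (never hour counts):

* **LOS** = discharge date − admit date in days; a same-day stay has
  LOS 0.
* **Provision date** = the calendar date of the admission's first audit
  event.  The extract has no explicit provisioning table, so first
  portal use stands in for tablet hand-off.
* **Provision day** of an event = its date − provision date (0-based);
  **provisioning day** of an admission = provision date − admit date.
* The **LOS cap** combines an a-priori hard cap (default 30 days) with a
  data-driven cap: the largest observed LOS such that every observed LOS
  value up to it still has at least ``min_group_size`` admissions.  The
  stricter of the two wins, so summary statistics never rest on sparse
  long-stay tails.

Frequency counts active, non-Administrative tasks per core function;
comprehensiveness counts the core functions touched (0–9).  Both default
to the first 10 provision days of each admission.  Active Administrative
tasks are tallied separately and never enter either measure.
"""

from __future__ import annotations

import bisect
from collections import Counter
from dataclasses import replace
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from .models import (
    Admission,
    ClassifiedEvent,
    CORE_FUNCTIONS,
    Function,
    Level,
    ProvisionContext,
    Session,
    UsageMetrics,
)

DEFAULT_MAX_PROVISION_DAY = 9   # "first 10 provision days", 0-based
DEFAULT_LOS_HARD_CAP = 30
DEFAULT_MIN_GROUP_SIZE = 30


# --------------------------------------------------------------------------
# Length of stay
# --------------------------------------------------------------------------

def compute_los(admission: Admission) -> int:
    """Calendar-day length of stay; same-day admit/discharge gives 0."""
    return (admission.end.date() - admission.start.date()).days


def compute_los_cap(
    admissions: Union[Sequence[Admission], Mapping[int, int]],
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
) -> int:
    """Largest LOS whose patient group still meets the a-priori size.

    Long-stay tails are too thin for robust summary statistics, so the
    cohort is cut at the largest observed LOS that still has at least
    ``min_group_size`` admissions; every longer stay is excluded by the
    filter.  Returns -1 when no LOS group reaches the size (the filter
    then excludes everything).  Accepts either admissions or a
    ``{los: count}`` table.
    """
    if min_group_size < 1:
        raise ValueError("min_group_size must be >= 1")
    if isinstance(admissions, Mapping):
        counts = dict(admissions)
    else:
        counts = Counter(compute_los(a) for a in admissions)
    if not counts:
        raise ValueError("no admissions to compute a LOS cap from")
    qualifying = [los for los, n in counts.items()
                  if n >= min_group_size]
    return max(qualifying, default=-1)


def filter_admissions_by_los(
    admissions: Sequence[Admission],
    hard_cap: int = DEFAULT_LOS_HARD_CAP,
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
) -> tuple[list[Admission], int]:
    """Drop admissions longer than min(data-driven cap, hard cap).

    Returns the retained admissions and the effective cap applied.
    """
    if not admissions:
        return [], hard_cap
    cap = min(compute_los_cap(admissions, min_group_size), hard_cap)
    return [a for a in admissions if compute_los(a) <= cap], cap


# --------------------------------------------------------------------------
# Provision days
# --------------------------------------------------------------------------

def assign_provision_days(
    events: Sequence[ClassifiedEvent],
    admissions: Sequence[Admission],
) -> tuple[list[ClassifiedEvent], list[ProvisionContext], list[str]]:
    """Stamp each linked event with its 0-based provision day.

    Returns the stamped events, one :class:`ProvisionContext` per
    admission that has events, and the ids of admissions with no events
    (flagged, no context).
    """
    by_admission: dict[str, Admission] = {a.admission_id: a
                                          for a in admissions}
    first_date: dict[str, object] = {}
    for ev in events:
        if ev.admission_id is None:
            raise ValueError("events must be linked before provision-day "
                             "assignment")
        d = ev.timestamp.date()
        cur = first_date.get(ev.admission_id)
        if cur is None or d < cur:
            first_date[ev.admission_id] = d

    stamped = [
        replace(ev, provision_day=(ev.timestamp.date()
                                   - first_date[ev.admission_id]).days)
        for ev in events
    ]
    contexts = []
    for aid in sorted(first_date):
        adm = by_admission[aid]
        contexts.append(ProvisionContext(
            admission_id=aid,
            patient_id=adm.patient_id,
            provision_date=first_date[aid],
            los_days=compute_los(adm),
            provisioning_day=(first_date[aid] - adm.start.date()).days,
        ))
    flagged = sorted(set(by_admission) - set(first_date))
    return stamped, contexts, flagged


# --------------------------------------------------------------------------
# Frequency and comprehensiveness
# --------------------------------------------------------------------------

def _unit_metrics(level: Level, unit_id: str,
                  events: Iterable[ClassifiedEvent],
                  n_sessions: int, max_day: int) -> UsageMetrics:
    freq: dict[Function, int] = {f: 0 for f in CORE_FUNCTIONS}
    admin = 0
    for ev in events:
        if not ev.active or ev.provision_day is None \
                or ev.provision_day > max_day:
            continue
        if ev.function is Function.ADMINISTRATIVE:
            admin += 1
        else:
            freq[ev.function] += 1
    return UsageMetrics(
        level=level, unit_id=unit_id, frequency=freq,
        comprehensiveness=sum(1 for f in CORE_FUNCTIONS if freq[f] > 0),
        n_sessions=n_sessions, admin_active_count=admin,
    )


def _events_by_session(
    sessions: Sequence[Session], events: Sequence[ClassifiedEvent]
) -> dict[str, list[ClassifiedEvent]]:
    by_adm: dict[str, list[Session]] = {}
    for s in sessions:
        by_adm.setdefault(s.admission_id, []).append(s)
    starts: dict[str, list] = {}
    for aid, ss in by_adm.items():
        ss.sort(key=lambda s: s.start)
        starts[aid] = [s.start for s in ss]

    assigned: dict[str, list[ClassifiedEvent]] = {s.session_id: []
                                                  for s in sessions}
    for ev in events:
        ss = by_adm.get(ev.admission_id or "")
        if not ss:
            raise ValueError(
                f"event at {ev.timestamp} has no session (admission "
                f"{ev.admission_id})")
        i = bisect.bisect_right(starts[ev.admission_id], ev.timestamp)
        if i == 0:
            raise ValueError("event precedes every session of its "
                             "admission")
        sess = ss[i - 1]
        if not sess.start <= ev.timestamp <= sess.end:
            raise ValueError("event falls between sessions; rebuild "
                             "sessions from the same event set")
        assigned[sess.session_id].append(ev)
    return assigned


def compute_metrics(
    sessions: Sequence[Session],
    events: Sequence[ClassifiedEvent],
    level: Union[Level, str],
    max_provision_day: int = DEFAULT_MAX_PROVISION_DAY,
) -> list[UsageMetrics]:
    """Per-unit frequency and comprehensiveness at one level of analysis.

    ``events`` must be the linked, provision-day-stamped events the
    sessions were built from.  A session's provision day is that of its
    first event; sessions starting after ``max_provision_day`` are not
    units at the session level and do not count toward ``n_sessions``
    elsewhere.  The patient level aggregates all of a patient's
    admissions (the provision-day filter applies within each admission).
    """
    level = Level(level)
    assigned = _events_by_session(sessions, events)

    def session_day(s: Session) -> int:
        evs = assigned[s.session_id]
        return min(e.provision_day for e in evs) if evs else 0

    in_window = [s for s in sessions
                 if session_day(s) <= max_provision_day]

    if level is Level.SESSION:
        return [
            _unit_metrics(level, s.session_id, assigned[s.session_id],
                          n_sessions=1, max_day=max_provision_day)
            for s in sorted(in_window,
                            key=lambda s: (s.patient_id, s.start))
        ]

    if level is Level.ADMISSION:
        key = lambda s: s.admission_id  # noqa: E731
    else:
        key = lambda s: s.patient_id  # noqa: E731

    groups: dict[str, list[Session]] = {}
    for s in sessions:
        groups.setdefault(key(s), []).append(s)
    out = []
    for unit_id in sorted(groups):
        ss = groups[unit_id]
        evs = [e for s in ss for e in assigned[s.session_id]]
        n_sessions = sum(1 for s in ss
                         if session_day(s) <= max_provision_day)
        out.append(_unit_metrics(level, unit_id, evs, n_sessions,
                                 max_provision_day))
    return out


# --------------------------------------------------------------------------
# Provisioning heatmap (day of provisioning x LOS)
# --------------------------------------------------------------------------

def provisioning_heatmap(
    contexts: Sequence[ProvisionContext],
    max_los: int = 10,
) -> dict[str, pd.DataFrame]:
    """Counts and LOS-normalized percentages of provisioning timing.

    Rows are the day of provisioning (0 = provisioned on admission day),
    columns the calendar-day LOS, both 0..``max_los``; stays longer than
    ``max_los`` are excluded.  ``percent`` normalizes each LOS column to
    100, so each column shows when patients with that LOS typically
    received their tablet.
    """
    idx = range(max_los + 1)
    counts = pd.DataFrame(0, index=idx, columns=idx)
    counts.index.name = "provisioning_day"
    counts.columns.name = "los_days"
    for c in contexts:
        if c.los_days <= max_los:
            counts.loc[c.provisioning_day, c.los_days] += 1
    col_sums = counts.sum(axis=0)
    percent = counts.div(col_sums.where(col_sums > 0, other=1),
                         axis=1) * 100.0
    return {"counts": counts, "percent": percent}
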