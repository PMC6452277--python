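"""Sessionization: inactivity-gap partitioning of linked events.

A *session* is a maximal run of one patient's events, within one
admission, with no inactivity gap exceeding the threshold (default
15 minutes).  Login/logout stamps are deliberately not trusted as session
delimiters — the portal's idle auto-logout fires unreliably — so the gap
rule is the sole boundary criterion.  A gap of exactly the threshold
stays in-session ("without 15 min of inactivity", read inclusively);
strictly greater splits.

Sessions are built after cleaning and linkage, so removed system actions
(notably the 5-minute wallpaper refresh) can no longer bridge genuine
gaps; :func:`session_diagnostics` exists precisely to show that contrast
on demand.
"""

from __future__ import annotations

from collections import Counter
from datetime import timedelta
from itertools import groupby
from typing import Sequence

import numpy as np
import pandas as pd

from .models import ClassifiedEvent, Function, Session, make_session_id

DEFAULT_SESSION_GAP_MINUTES = 15.0


def build_sessions(
    events: Sequence[ClassifiedEvent],
    gap_minutes: float = DEFAULT_SESSION_GAP_MINUTES,
) -> list[Session]:
    """Partition linked events into sessions per (patient, admission).

    Every event lands in exactly one session; session start/end are the
    first/last event timestamps; ``active_task_counts`` tallies active
    events by function (Administrative included, reported separately
    downstream).
    """
    if gap_minutes < 0:
        raise ValueError("gap_minutes must be non-negative")
    gap = timedelta(minutes=gap_minutes)

    linked = [e for e in events if e.admission_id is not None]
    if len(linked) != len(events):
        raise ValueError("all events must be linked to an admission")
    ordered = sorted(
        linked, key=lambda e: (e.patient_id, e.admission_id, e.timestamp,
                               e.action))

    sessions: list[Session] = []
    for (pid, adm), grp in groupby(
            ordered, key=lambda e: (e.patient_id, e.admission_id)):
        run: list[ClassifiedEvent] = []
        for ev in grp:
            if run and ev.timestamp - run[-1].timestamp > gap:
                sessions.append(_finish(pid, adm, run))
                run = []
            run.append(ev)
        if run:
            sessions.append(_finish(pid, adm, run))
    return sessions


def _finish(pid: str, admission_id: str,
            run: list[ClassifiedEvent]) -> Session:
    counts: Counter[Function] = Counter(
        e.function for e in run if e.active)
    start = run[0].timestamp
    return Session(
        session_id=make_session_id(pid, admission_id, start),
        patient_id=pid,
        admission_id=admission_id,
        start=start,
        end=run[-1].timestamp,
        event_count=len(run),
        active_task_counts=dict(counts),
    )


def session_diagnostics(
    sessions: Sequence[Session],
    duration_bin_minutes: float = 5.0,
    max_events_bin: int = 50,
) -> dict[str, pd.DataFrame]:
    """Histogram tables of session duration and per-session event counts.

    Returns ``{"duration": df, "events_per_session": df}``; duration is
    binned in ``duration_bin_minutes`` steps with the left edge labelled
    (a single-event session lands in the 0 bin).  Run this on sessions
    built with and without artifact cleaning to visualise how retained
    wallpaper refreshes chain sessions into implausibly long ones.
    """
    if not sessions:
        empty = pd.DataFrame({"bin": [], "count": []})
        return {"duration": empty, "events_per_session": empty.copy()}

    minutes = np.array([s.duration_seconds / 60.0 for s in sessions])
    dur_bins = np.floor(minutes / duration_bin_minutes).astype(int)
    dur = (pd.Series(dur_bins * duration_bin_minutes)
           .value_counts().sort_index())
    dur_df = pd.DataFrame({"bin": dur.index.to_numpy(dtype=float),
                           "count": dur.to_numpy()})

    nev = pd.Series([min(s.event_count, max_events_bin) for s in sessions])
    ev = nev.value_counts().sort_index()
    ev_df = pd.DataFrame({"bin": ev.index.to_numpy(dtype=float),
                          "count": ev.to_numpy()})
    return {"duration": dur_df, "events_per_session": ev_df}
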