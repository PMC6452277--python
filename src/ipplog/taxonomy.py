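"""Action taxonomy and audit-log cleaning.

The raw activity codes group into nine patient-facing portal functions
plus an Administrative bucket, each action flagged Active (intentionally
initiated by the patient) or Not active (background portal traffic).
Three system-generated codes are removed outright:

* ``Get Menu Items`` — pure navigation;
* ``Get Provider`` — replicated once per care-team member every time
  ``Get Care Team`` runs, so it would multiply-count a single action;
* ``Get Wallpaper Data`` — a page refresh fired every 5 minutes that,
  left in place, chains genuinely separate sessions together.

``Media/Web content`` rows are remote-internet calls whose extended-info
code identifies an external action (dining orders, welcome video,
tutorials …); these are remapped to concrete active tasks.  Cleaning also
collapses runs of sequential logins to the earliest one and drops exact
(patient, action, timestamp) duplicates, reporting every count so that
survivors + removed + collapsed + deduped = input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import timedelta
from enum import Enum
from typing import Iterable, Optional, Sequence

import yaml

from .models import AuditEvent, ClassifiedEvent, Function


class Disposition(str, Enum):
    KEEP = "keep"
    REMOVE = "remove"
    REMAP = "remap"


@dataclass(frozen=True)
class TaxonomyEntry:
    raw_action: str
    function: Function
    active: bool
    disposition: Disposition = Disposition.KEEP


@dataclass(frozen=True)
class ExternalAction:
    """One Media/Web-content external action and its remap target."""

    extended_info_code: str
    label: str
    mapped_action: str
    mapped_function: Function
    active: bool = True


#: Raw action whose extended info selects an external action.
MEDIA_WEB_ACTION = "Media/Web content"

#: Actions treated as portal logins for sequential-run collapsing.
LOGIN_ACTIONS = frozenset({"Login", "Logout", "Login/logout"})

_A, _N = True, False
_DEFAULT_ROWS: tuple[tuple[str, Function, bool, Disposition], ...] = (
    # Access educational materials
    ("Get 1 patient-prescribed education title",
     Function.EDUCATION, _A, Disposition.KEEP),
    ("Update education status", Function.EDUCATION, _A, Disposition.KEEP),
    ("Get patient-prescribed education titles",
     Function.EDUCATION, _N, Disposition.KEEP),
    # Access personal notes
    ("Create patient note", Function.NOTES, _A, Disposition.KEEP),
    ("Delete patient media", Function.NOTES, _A, Disposition.KEEP),
    ("Delete patient note", Function.NOTES, _A, Disposition.KEEP),
    ("Update patient note", Function.NOTES, _A, Disposition.KEEP),
    ("Get patient notes", Function.NOTES, _N, Disposition.KEEP),
    # Administrative
    ("Identify user with lock", Function.ADMINISTRATIVE, _A,
     Disposition.KEEP),
    ("Make Bedside link", Function.ADMINISTRATIVE, _A, Disposition.KEEP),
    ("Send MyChart email", Function.ADMINISTRATIVE, _A, Disposition.KEEP),
    ("Accept terms and conditions", Function.ADMINISTRATIVE, _N,
     Disposition.KEEP),
    ("Handshake", Function.ADMINISTRATIVE, _N, Disposition.KEEP),
    ("Load terms and conditions", Function.ADMINISTRATIVE, _N,
     Disposition.KEEP),
    ("Set lock for user", Function.ADMINISTRATIVE, _N, Disposition.KEEP),
    ("Update photo for user", Function.ADMINISTRATIVE, _N,
     Disposition.KEEP),
    ("Login/logout", Function.ADMINISTRATIVE, _N, Disposition.KEEP),
    # Raw extracts log the two halves separately; same classification.
    ("Login", Function.ADMINISTRATIVE, _N, Disposition.KEEP),
    ("Logout", Function.ADMINISTRATIVE, _N, Disposition.KEEP),
    # Check secure messages
    ("Get messages", Function.CHECK_MESSAGES, _A, Disposition.KEEP),
    # Happening soon
    ("Create user-created event", Function.HAPPENING_SOON, _A,
     Disposition.KEEP),
    ("Delete user-created event", Function.HAPPENING_SOON, _A,
     Disposition.KEEP),
    ("Get appointment event detail", Function.HAPPENING_SOON, _A,
     Disposition.KEEP),
    ("Get medication administration details", Function.HAPPENING_SOON, _A,
     Disposition.KEEP),
    ("Get surgery event detail", Function.HAPPENING_SOON, _A,
     Disposition.KEEP),
    ("Load schedule", Function.HAPPENING_SOON, _A, Disposition.KEEP),
    # I would like
    ("Delete patient request", Function.I_WOULD_LIKE, _A, Disposition.KEEP),
    ("Save patient request", Function.I_WOULD_LIKE, _A, Disposition.KEEP),
    ("Get patient requests", Function.I_WOULD_LIKE, _N, Disposition.KEEP),
    # MyChart Ambulatory
    ("Create MyChart account", Function.MYCHART, _A, Disposition.KEEP),
    ("Load MyChart info", Function.MYCHART, _A, Disposition.KEEP),
    ("Validate MyChart login", Function.MYCHART, _N, Disposition.KEEP),
    ("Validate MyChart password", Function.MYCHART, _N, Disposition.KEEP),
    # Review current care team
    ("Get Care Team", Function.CARE_TEAM, _A, Disposition.KEEP),
    # Review vitals and lab results
    ("Get lab result comments", Function.VITALS_LABS, _A, Disposition.KEEP),
    ("Get health metrics", Function.VITALS_LABS, _N, Disposition.KEEP),
    ("Switch bedside admission", Function.VITALS_LABS, _N,
     Disposition.KEEP),
    # Send a secure message
    ("Save message", Function.SEND_MESSAGE, _A, Disposition.KEEP),
    # System-generated noise, removed from analysis
    ("Get Menu Items", Function.ADMINISTRATIVE, _N, Disposition.REMOVE),
    ("Get Provider", Function.ADMINISTRATIVE, _N, Disposition.REMOVE),
    ("Get Wallpaper Data", Function.ADMINISTRATIVE, _N,
     Disposition.REMOVE),
    # Remote-internet calls, remapped via extended info
    (MEDIA_WEB_ACTION, Function.ADMINISTRATIVE, _N, Disposition.REMAP),
)

#: Default external-action map.  The extract identifies these only through
#: site-specific extended-info codes; the defaults key on the label string
#: itself and are meant to be overridden with real codes per site.
DEFAULT_EXTERNAL_ACTIONS: tuple[ExternalAction, ...] = (
    ExternalAction("Dining on demand", "Dining on demand",
                   "Dining on demand", Function.ADMINISTRATIVE, True),
    ExternalAction("Welcome video", "Welcome video",
                   "Welcome video", Function.EDUCATION, True),
    ExternalAction("Getting started", "Getting started",
                   "Getting started", Function.EDUCATION, True),
    ExternalAction("MCB patients' rights and responsibilities",
                   "MCB patients' rights and responsibilities",
                   "MCB patients' rights and responsibilities",
                   Function.EDUCATION, True),
    ExternalAction("MCB patients' tutorial", "MCB patients' tutorial",
                   "MCB patients' tutorial", Function.EDUCATION, True),
)


class Taxonomy:
    """Lookup table from raw action code to (function, active, disposition)."""

    def __init__(self, entries: Iterable[TaxonomyEntry]):
        self._by_action: dict[str, TaxonomyEntry] = {}
        for e in entries:
            if e.raw_action in self._by_action:
                raise ValueError(f"duplicate raw action {e.raw_action!r}")
            self._by_action[e.raw_action] = e

    def lookup(self, raw_action: str) -> Optional[TaxonomyEntry]:
        return self._by_action.get(raw_action)

    def __len__(self) -> int:
        return len(self._by_action)

    def entries(self) -> list[TaxonomyEntry]:
        return list(self._by_action.values())

    @property
    def functions(self) -> set[Function]:
        return {e.function for e in self._by_action.values()
                if e.disposition is Disposition.KEEP}


def default_taxonomy() -> Taxonomy:
    return Taxonomy(TaxonomyEntry(*row) for row in _DEFAULT_ROWS)


def default_external_map() -> dict[str, ExternalAction]:
    return {e.extended_info_code: e for e in DEFAULT_EXTERNAL_ACTIONS}


def load_taxonomy(path: Optional[str] = None) -> Taxonomy:
    """Load a taxonomy from YAML, or the built-in default when ``path`` is
    None.

    YAML layout: a list of mappings with keys ``action``, ``function``,
    ``active`` and optional ``disposition``.
    """
    if path is None:
        return default_taxonomy()
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValueError("taxonomy config must be a list of entries")
    entries = []
    for item in raw:
        try:
            entries.append(TaxonomyEntry(
                raw_action=item["action"],
                function=Function(item["function"]),
                active=bool(item["active"]),
                disposition=Disposition(item.get("disposition", "keep")),
            ))
        except (KeyError, ValueError) as exc:
            raise ValueError(f"malformed taxonomy entry {item!r}") from exc
    return Taxonomy(entries)


def load_external_map(path: Optional[str] = None) -> dict[str, ExternalAction]:
    if path is None:
        return default_external_map()
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    out: dict[str, ExternalAction] = {}
    for item in raw:
        code = item["extended_info_code"]
        if code in out:
            raise ValueError(f"duplicate extended-info code {code!r}")
        out[code] = ExternalAction(
            extended_info_code=code,
            label=item.get("label", code),
            mapped_action=item["mapped_action"],
            mapped_function=Function(item["mapped_function"]),
            active=bool(item.get("active", True)),
        )
    return out


# --------------------------------------------------------------------------
# Cleaning
# --------------------------------------------------------------------------

@dataclass
class CleaningReport:
    """Count conservation: survivors + removed + collapsed + deduped = input."""

    n_input: int = 0
    n_survivors: int = 0
    n_removed: int = 0          # remove-disposition actions dropped
    n_login_collapsed: int = 0  # extra logins in sequential runs
    n_deduped: int = 0          # exact (patient, action, time) duplicates
    n_remapped: int = 0         # Media/Web content re-labelled (survive)
    n_unmapped: int = 0         # unknown actions routed to Administrative
    removed_by_action: dict[str, int] = field(default_factory=dict)

    def check_conservation(self) -> None:
        assert (self.n_survivors + self.n_removed + self.n_login_collapsed
                + self.n_deduped) == self.n_input, "cleaning count leak"


class UnmappedActionError(KeyError):
    pass


def _canonical_sort(events: Sequence[AuditEvent]) -> list[AuditEvent]:
    # Output must not depend on input row order.
    return sorted(events, key=lambda e: (e.patient_id, e.timestamp,
                                         e.action, e.extended_info or ""))


def clean_events(
    events: Sequence[AuditEvent],
    taxonomy: Optional[Taxonomy] = None,
    external_map: Optional[dict[str, ExternalAction]] = None,
    *,
    strict: bool = False,
    keep_system_actions: bool = False,
    login_run_max_gap_minutes: float = 15.0,
) -> tuple[list[ClassifiedEvent], CleaningReport]:
    """Classify raw events and strip the documented logging artifacts.

    Steps, in order: canonical sort; drop remove-disposition actions;
    remap Media/Web content via extended info; collapse sequential login
    runs to the earliest login; drop exact duplicates; label every
    survivor with function + active flag.

    A login run is *sequential* only while consecutive logins are within
    ``login_run_max_gap_minutes`` of each other (default: the session
    inactivity threshold).  Logins separated by a longer silence open
    distinct use periods and are never artifacts of one another, so they
    are kept.

    ``strict`` raises on an unmapped action instead of routing it to
    Administrative/inactive.  ``keep_system_actions`` retains the
    remove-disposition rows (classified Administrative/inactive) — used
    only for before/after cleaning diagnostics, never in the metric path.
    """
    taxonomy = taxonomy or default_taxonomy()
    external_map = external_map if external_map is not None \
        else default_external_map()
    report = CleaningReport(n_input=len(events))

    ordered = _canonical_sort(events)

    # classification + removal + remap in one pass
    staged: list[ClassifiedEvent] = []
    for ev in ordered:
        entry = taxonomy.lookup(ev.action)
        if entry is None:
            if strict:
                raise UnmappedActionError(ev.action)
            report.n_unmapped += 1
            staged.append(ClassifiedEvent(
                patient_id=ev.patient_id, action=ev.action,
                timestamp=ev.timestamp, extended_info=ev.extended_info,
                function=Function.ADMINISTRATIVE, active=False))
            continue
        if entry.disposition is Disposition.REMOVE:
            if keep_system_actions:
                staged.append(ClassifiedEvent(
                    patient_id=ev.patient_id, action=ev.action,
                    timestamp=ev.timestamp, extended_info=ev.extended_info,
                    function=Function.ADMINISTRATIVE, active=False))
            else:
                report.n_removed += 1
                report.removed_by_action[ev.action] = (
                    report.removed_by_action.get(ev.action, 0) + 1)
            continue
        if entry.disposition is Disposition.REMAP:
            ext = external_map.get(ev.extended_info or "")
            if ext is None:
                if strict:
                    raise UnmappedActionError(
                        f"{ev.action} / {ev.extended_info!r}")
                report.n_unmapped += 1
                staged.append(ClassifiedEvent(
                    patient_id=ev.patient_id, action=ev.action,
                    timestamp=ev.timestamp, extended_info=ev.extended_info,
                    function=Function.ADMINISTRATIVE, active=False))
            else:
                report.n_remapped += 1
                staged.append(ClassifiedEvent(
                    patient_id=ev.patient_id, action=ext.mapped_action,
                    timestamp=ev.timestamp, extended_info=ev.extended_info,
                    function=ext.mapped_function, active=ext.active))
            continue
        staged.append(ClassifiedEvent(
            patient_id=ev.patient_id, action=ev.action,
            timestamp=ev.timestamp, extended_info=ev.extended_info,
            function=entry.function, active=entry.active))

    # collapse sequential login runs (same login action back to back within
    # a patient, no intervening action) keeping the earliest
    run_gap = timedelta(minutes=login_run_max_gap_minutes)
    collapsed: list[ClassifiedEvent] = []
    for ev in staged:
        prev = collapsed[-1] if collapsed else None
        if (prev is not None
                and ev.patient_id == prev.patient_id
                and ev.action in LOGIN_ACTIONS
                and ev.action == prev.action
                and ev.timestamp - prev.timestamp <= run_gap):
            report.n_login_collapsed += 1
            continue
        collapsed.append(ev)

    # exact-duplicate removal: keep first after canonical sort
    survivors: list[ClassifiedEvent] = []
    seen: set[tuple[str, str, object]] = set()
    for ev in collapsed:
        key = (ev.patient_id, ev.action, ev.timestamp)
        if key in seen:
            report.n_deduped += 1
            continue
        seen.add(key)
        survivors.append(ev)

    report.n_survivors = len(survivors)
    if not keep_system_actions:
        report.check_conservation()
    return survivors, report
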