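"""Seeded synthetic ADT / charges / audit-log generator with ground truth.

No public inpatient-portal audit-log dataset exists, so the pipeline is
exercised on simulated cohorts that reproduce the documented statistical
structure (log-normal length of stay, delayed tablet provisioning,
bursty within-day sessions) and — via :func:`corrupt` — every logging
artifact the cleaning stages exist to remove:

* wallpaper page refreshes at an exact 5-minute cadence,
* runs of sequential logins,
* exact duplicate (patient, action, timestamp) rows,
* out-of-encounter stray events (near and far),
* admissions split across several raw ADT encounters by transfers,
* duplicate hospital-account charge rows.

Generation and corruption are separated so each artifact can be injected
alone and its cleaning-report count checked against the injection ledger.
All randomness flows from the single config seed; re-runs are
byte-identical.

By construction the clean cohort keeps intra-session gaps under 10
minutes and inter-session gaps over 30 minutes, so the 15-minute session
boundary is unambiguous; boundary behaviour is tested with dedicated
fixtures at exactly 15 min ± 1 s, not with this generator.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Optional, Sequence

import numpy as np

from .models import (
    AuditEvent,
    ChargeRecord,
    EncounterClass,
    Function,
    RawEncounter,
    make_admission_id,
    make_session_id,
)
from .taxonomy import Disposition, default_taxonomy

ARTIFACT_TYPES = ("wallpaper", "sequential_login", "dup_timestamp",
                  "stray_event", "transfer_split", "dup_account")

#: Active / inactive raw actions per function, read off the default
#: taxonomy so the generator can never drift from the classifier.
_TAX = default_taxonomy()
_ACTIVE_ACTIONS: dict[Function, list[str]] = {}
_INACTIVE_ACTIONS: dict[Function, list[str]] = {}
for _e in _TAX.entries():
    if _e.disposition is not Disposition.KEEP:
        continue
    if _e.raw_action in ("Login", "Logout", "Login/logout"):
        continue
    (_ACTIVE_ACTIONS if _e.active else _INACTIVE_ACTIONS).setdefault(
        _e.function, []).append(_e.raw_action)


def _default_function_probs() -> dict[Function, float]:
    # Qualitative usage profile: care team and schedule most used,
    # secure-message sending rarest; a sliver of active Administrative
    # tasks exercises their separate tally.
    return {
        Function.CARE_TEAM: 0.28,
        Function.HAPPENING_SOON: 0.25,
        Function.VITALS_LABS: 0.14,
        Function.CHECK_MESSAGES: 0.10,
        Function.EDUCATION: 0.08,
        Function.MYCHART: 0.04,
        Function.NOTES: 0.04,
        Function.I_WOULD_LIKE: 0.02,
        Function.ADMINISTRATIVE: 0.04,
        Function.SEND_MESSAGE: 0.01,
    }


def _default_artifact_rates() -> dict[str, float]:
    return {t: 0.0 for t in ARTIFACT_TYPES}


@dataclass
class SimulationConfig:
    """Cohort and artifact parameters for :func:`simulate`.

    ``los_lognormal`` are the (mu, sigma) of the underlying log-normal
    whose rounded draw is the calendar-day LOS (median ≈ 3 days);
    ``provisioning_delay_probs`` is a categorical over whole days from
    admission to tablet hand-off; ``sessions_per_day_nb`` are the
    (n, p) of a negative binomial for per-provision-day session counts
    (mean 2); ``artifact_rates`` are per-opportunity injection
    probabilities, all zero for a clean cohort.
    """

    n_patients: int = 100
    seed: int = 0
    los_lognormal: tuple[float, float] = (1.1, 0.8)
    los_max_days: int = 45
    provisioning_delay_probs: dict[int, float] = field(
        default_factory=lambda: {0: 0.50, 1: 0.25, 2: 0.15, 3: 0.07,
                                 4: 0.03})
    sessions_per_day_nb: tuple[float, float] = (2.0, 0.5)
    actions_per_session_mean: float = 3.0
    inactive_action_prob: float = 0.2
    multi_admission_prob: float = 0.15
    outpatient_charge_prob: float = 0.15
    function_use_probs: dict[Function, float] = field(
        default_factory=_default_function_probs)
    artifact_rates: dict[str, float] = field(
        default_factory=_default_artifact_rates)
    study_start: datetime = datetime(2014, 1, 15, 0, 0, 0)

    def __post_init__(self) -> None:
        # YAML configs carry string keys; coerce to the enum
        self.function_use_probs = {
            Function(k): float(v)
            for k, v in self.function_use_probs.items()}
        self.provisioning_delay_probs = {
            int(k): float(v)
            for k, v in self.provisioning_delay_probs.items()}
        if isinstance(self.study_start, str):
            self.study_start = datetime.fromisoformat(self.study_start)

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        probs = list(self.function_use_probs.values())
        if any(not 0 <= p <= 1 for p in probs) or not probs:
            raise ValueError("function_use_probs must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("function_use_probs must sum to 1")
        if any(not 0 <= p for p in self.provisioning_delay_probs.values()):
            raise ValueError("provisioning delay probs must be >= 0")
        for k, v in self.artifact_rates.items():
            if k not in ARTIFACT_TYPES:
                raise ValueError(f"unknown artifact type {k!r}")
            if not 0 <= v <= 1:
                raise ValueError(f"artifact rate {k} out of [0, 1]")
        n, p = self.sessions_per_day_nb
        if n <= 0 or not 0 < p <= 1:
            raise ValueError("invalid negative-binomial parameters")


# --------------------------------------------------------------------------
# Ground truth
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrueSession:
    session_id: str
    patient_id: str
    admission_id: str
    start: datetime
    end: datetime
    n_events: int
    active_counts: dict  # Function -> int, active events only


@dataclass(frozen=True)
class TrueAdmission:
    patient_id: str
    admission_id: str
    start: datetime
    end: datetime
    encounter_ids: tuple[str, ...]
    los_raw: float  # continuous log-normal draw behind the integer LOS


@dataclass
class GroundTruth:
    """Generator-side bookkeeping of what the pipeline should recover."""

    admissions: list[TrueAdmission] = field(default_factory=list)
    sessions: list[TrueSession] = field(default_factory=list)

    def sessions_of(self, admission_id: str) -> list[TrueSession]:
        return sorted((s for s in self.sessions
                       if s.admission_id == admission_id),
                      key=lambda s: s.start)

    def _provision_dates(self) -> dict[str, date]:
        out: dict[str, date] = {}
        for s in self.sessions:
            d = s.start.date()
            cur = out.get(s.admission_id)
            if cur is None or d < cur:
                out[s.admission_id] = d
        return out

    def session_provision_day(self, s: TrueSession) -> int:
        return (s.start.date() - self._provision_dates()[s.admission_id]).days

    def expected_metrics(
        self, level: str, max_provision_day: int = 9,
        admission_ids: Optional[set[str]] = None,
    ) -> dict[str, dict]:
        """Expected per-unit metrics: {unit_id: {"frequency": {...},
        "comprehensiveness": int, "n_sessions": int}}.

        ``admission_ids`` optionally restricts to a cohort subset (e.g.
        after a LOS cap); patients with no surviving admission disappear.
        """
        sessions = [s for s in self.sessions
                    if admission_ids is None
                    or s.admission_id in admission_ids]
        prov = self._provision_dates()
        per_session = [
            (s, (s.start.date() - prov[s.admission_id]).days)
            for s in sessions
        ]

        def freq_of(counts: dict) -> dict:
            return {f: n for f, n in counts.items()
                    if f is not Function.ADMINISTRATIVE and n > 0}

        if level == "session":
            out = {}
            for s, pd_ in per_session:
                if pd_ > max_provision_day:
                    continue
                freq = freq_of(s.active_counts)
                out[s.session_id] = {
                    "frequency": freq,
                    "comprehensiveness": len(freq),
                    "n_sessions": 1,
                }
            return out

        key = ((lambda s: s.admission_id) if level == "admission"
               else (lambda s: s.patient_id))
        grouped: dict[str, list] = {}
        for s, pd_ in per_session:
            grouped.setdefault(key(s), []).append((s, pd_))
        out = {}
        for unit_id, items in grouped.items():
            total: dict[Function, int] = {}
            n_in = 0
            for s, pd_ in items:
                if pd_ > max_provision_day:
                    continue
                n_in += 1
                for f, n in s.active_counts.items():
                    total[f] = total.get(f, 0) + n
            freq = freq_of(total)
            out[unit_id] = {
                "frequency": freq,
                "comprehensiveness": len(freq),
                "n_sessions": n_in,
            }
        return out

    def to_json(self, path) -> None:
        payload = {
            "admissions": [
                {**dataclasses.asdict(a),
                 "start": a.start.isoformat(), "end": a.end.isoformat()}
                for a in self.admissions
            ],
            "sessions": [
                {**dataclasses.asdict(s),
                 "start": s.start.isoformat(), "end": s.end.isoformat(),
                 "active_counts": {f.value: n for f, n
                                   in s.active_counts.items()}}
                for s in self.sessions
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class SimulatedData:
    """The three raw tables plus the generator's ground truth."""

    events: list[AuditEvent]
    encounters: list[RawEncounter]
    charges: list[ChargeRecord]
    truth: GroundTruth
    config: SimulationConfig


# --------------------------------------------------------------------------
# Simulation
# --------------------------------------------------------------------------

def _draw_categorical(rng: np.random.Generator,
                      probs: dict[int, float]) -> int:
    keys = sorted(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    return int(rng.choice(keys, p=p / p.sum()))


def _session_events(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    pid: str,
    start: datetime,
    window_end: datetime,
) -> tuple[list[AuditEvent], dict[Function, int]]:
    """One session: a login followed by drawn actions, gaps 45–300 s."""
    funcs = sorted(cfg.function_use_probs, key=lambda f: f.value)
    fprobs = np.array([cfg.function_use_probs[f] for f in funcs])
    n_actions = int(rng.poisson(cfg.actions_per_session_mean))

    events = [AuditEvent(pid, "Login", start)]
    counts: dict[Function, int] = {}
    t = start
    for _ in range(n_actions):
        t = t + timedelta(seconds=int(rng.integers(45, 301)))
        if t > window_end:
            break
        fi = int(rng.choice(len(funcs), p=fprobs))
        func = funcs[fi]
        inactive_pool = _INACTIVE_ACTIONS.get(func, [])
        if inactive_pool and rng.random() < cfg.inactive_action_prob:
            action = inactive_pool[int(rng.integers(len(inactive_pool)))]
            events.append(AuditEvent(pid, action, t))
        else:
            pool = _ACTIVE_ACTIONS[func]
            action = pool[int(rng.integers(len(pool)))]
            events.append(AuditEvent(pid, action, t))
            counts[func] = counts.get(func, 0) + 1
    return events, counts


def simulate(config: SimulationConfig) -> SimulatedData:
    """Generate a seeded cohort; see the module docstring for structure.

    With all artifact rates zero the emitted tables are exactly
    recoverable: consolidation returns the true admissions, cleaning is
    the identity, and sessionization reproduces the true sessions.
    Nonzero rates delegate to :func:`corrupt` on the clean output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()
    events: list[AuditEvent] = []
    encounters: list[RawEncounter] = []
    charges: list[ChargeRecord] = []
    counter = 0

    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        n_adm = 1 + int(rng.random() < config.multi_admission_prob)
        prev_discharge: Optional[datetime] = None
        for _ in range(n_adm):
            counter += 1
            if prev_discharge is None:
                day0 = config.study_start + timedelta(
                    days=int(rng.integers(0, 600)))
            else:
                day0 = prev_discharge + timedelta(
                    days=int(rng.integers(60, 120)))
            day0 = datetime.combine(day0.date(), time(0, 0))

            los_raw = float(rng.lognormal(*config.los_lognormal))
            los = min(int(round(los_raw)), config.los_max_days)
            admit = day0 + timedelta(
                hours=int(rng.integers(6, 12)),
                minutes=int(rng.integers(0, 60)))
            if los == 0:
                discharge = day0 + timedelta(
                    hours=int(rng.integers(16, 20)),
                    minutes=int(rng.integers(0, 60)))
            else:
                discharge = day0 + timedelta(
                    days=los, hours=int(rng.integers(14, 20)),
                    minutes=int(rng.integers(0, 60)))
            prev_discharge = discharge

            eid, acct = f"E{counter:06d}", f"H{counter:06d}"
            adm_id = make_admission_id(pid, admit)
            truth.admissions.append(TrueAdmission(
                patient_id=pid, admission_id=adm_id, start=admit,
                end=discharge, encounter_ids=(eid,), los_raw=los_raw))
            encounters.append(RawEncounter(
                patient_id=pid, encounter_id=eid, admit=admit,
                discharge=discharge,
                encounter_class=EncounterClass.INPATIENT,
                hospital_account_id=acct))
            n_dx = int(rng.integers(1, 5))
            charges.append(ChargeRecord(
                hospital_account_id=acct, patient_id=pid, admit=admit,
                discharge=discharge,
                diagnosis_codes=tuple(
                    f"D{int(rng.integers(10, 99))}.{int(rng.integers(0, 9))}"
                    for _ in range(n_dx)),
                encounter_class=EncounterClass.INPATIENT))

            delay = min(
                _draw_categorical(rng, config.provisioning_delay_probs),
                los)
            n_nb, p_nb = config.sessions_per_day_nb
            first_session_done = False
            for k in range(delay, los + 1):
                day = (admit + timedelta(days=k)).date()
                win_start = max(admit + timedelta(minutes=5),
                                datetime.combine(day, time(8, 0)))
                win_end = min(discharge - timedelta(minutes=5),
                              datetime.combine(day, time(22, 0)))
                if win_end - win_start < timedelta(minutes=40):
                    continue
                n_sess = int(rng.negative_binomial(n_nb, p_nb))
                if not first_session_done:
                    n_sess = max(1, n_sess)
                t = win_start + timedelta(
                    minutes=int(rng.integers(0, 45)))
                for _ in range(n_sess):
                    if t > win_end - timedelta(minutes=5):
                        break
                    sess_events, counts = _session_events(
                        rng, config, pid, t, win_end)
                    events.extend(sess_events)
                    truth.sessions.append(TrueSession(
                        session_id=make_session_id(pid, adm_id, t),
                        patient_id=pid, admission_id=adm_id, start=t,
                        end=sess_events[-1].timestamp,
                        n_events=len(sess_events),
                        active_counts=counts))
                    first_session_done = True
                    # inter-session gap strictly > 30 min
                    t = sess_events[-1].timestamp + timedelta(
                        minutes=31 + int(rng.integers(0, 60)))

        if rng.random() < config.outpatient_charge_prob:
            counter += 1
            ts = config.study_start + timedelta(
                days=int(rng.integers(0, 700)), hours=10)
            cls = (EncounterClass.OUTPATIENT if rng.random() < 0.5
                   else EncounterClass.EMERGENCY)
            charges.append(ChargeRecord(
                hospital_account_id=f"HX{counter:06d}", patient_id=pid,
                admit=ts, discharge=ts + timedelta(hours=2),
                diagnosis_codes=("D00.0",), encounter_class=cls))

    # emit the audit log in scrambled order: the pipeline must not depend
    # on row order
    order = rng.permutation(len(events))
    events = [events[j] for j in order]

    data = SimulatedData(events=events, encounters=encounters,
                         charges=charges, truth=truth, config=config)
    if any(v > 0 for v in config.artifact_rates.values()):
        data, _ = corrupt(data, config.artifact_rates,
                          seed=config.seed + 1)
    return data


# --------------------------------------------------------------------------
# Corruption
# --------------------------------------------------------------------------

@dataclass
class InjectionLedger:
    """Exactly what :func:`corrupt` injected, for report reconciliation."""

    n_wallpaper: int = 0
    n_sequential_login: int = 0
    n_dup_timestamp: int = 0
    n_stray_near: int = 0
    n_stray_far: int = 0
    n_transfer_split: int = 0   # extra encounter rows created
    n_dup_account: int = 0

    @property
    def n_stray(self) -> int:
        return self.n_stray_near + self.n_stray_far


def corrupt(
    data: SimulatedData,
    artifact_rates: dict[str, float],
    seed: int,
) -> tuple[SimulatedData, InjectionLedger]:
    """Inject logging artifacts into a clean cohort.

    Each artifact type is injected independently at its per-opportunity
    rate; the returned ledger counts every injected row so tests can
    reconcile it against cleaning/drop reports.  Rates of zero are the
    identity.
    """
    for k in artifact_rates:
        if k not in ARTIFACT_TYPES:
            raise ValueError(f"unknown artifact type {k!r}")
    rng = np.random.default_rng(seed)
    ledger = InjectionLedger()
    rate = {t: artifact_rates.get(t, 0.0) for t in ARTIFACT_TYPES}
    truth = data.truth

    events = list(data.events)
    encounters = list(data.encounters)
    charges = list(data.charges)

    # -- wallpaper: 5-minute refresh cadence spanning each provision day's
    # sessions, so real inter-session gaps get bridged until cleaning
    if rate["wallpaper"] > 0:
        for adm in truth.admissions:
            if rng.random() >= rate["wallpaper"]:
                continue
            by_day: dict[date, list[TrueSession]] = {}
            for s in truth.sessions_of(adm.admission_id):
                by_day.setdefault(s.start.date(), []).append(s)
            for day_sessions in by_day.values():
                t = day_sessions[0].start + timedelta(seconds=300)
                end = day_sessions[-1].end
                while t <= end:
                    events.append(AuditEvent(
                        adm.patient_id, "Get Wallpaper Data", t))
                    ledger.n_wallpaper += 1
                    t += timedelta(seconds=300)

    # -- sequential logins: tack 1-3 extra logins right after a session's
    # real login (well before its first action at >= 45 s)
    if rate["sequential_login"] > 0:
        for s in truth.sessions:
            if rng.random() >= rate["sequential_login"]:
                continue
            n_extra = int(rng.integers(1, 4))
            for j in range(1, n_extra + 1):
                events.append(AuditEvent(
                    s.patient_id, "Login",
                    s.start + timedelta(seconds=j)))
            ledger.n_sequential_login += n_extra

    # -- duplicate timestamps: exact copies of non-login rows
    if rate["dup_timestamp"] > 0:
        for ev in list(events):
            if ev.action in ("Login", "Logout", "Get Wallpaper Data"):
                continue
            if rng.random() < rate["dup_timestamp"]:
                events.append(AuditEvent(ev.patient_id, ev.action,
                                         ev.timestamp, ev.extended_info))
                ledger.n_dup_timestamp += 1

    # -- stray events outside every admission
    if rate["stray_event"] > 0:
        last_discharge: dict[str, datetime] = {}
        for adm in truth.admissions:
            last_discharge[adm.patient_id] = max(
                last_discharge.get(adm.patient_id, adm.end), adm.end)
        for adm in truth.admissions:
            if rng.random() < rate["stray_event"]:
                events.append(AuditEvent(
                    adm.patient_id, "Get Care Team",
                    adm.end + timedelta(
                        hours=int(rng.integers(1, 21)),
                        seconds=int(rng.integers(0, 3600)))))
                ledger.n_stray_near += 1
        for pid, last in sorted(last_discharge.items()):
            if rng.random() < rate["stray_event"]:
                events.append(AuditEvent(
                    pid, "Get Care Team",
                    last + timedelta(days=int(rng.integers(40, 400)),
                                     hours=12)))
                ledger.n_stray_far += 1

    # -- transfer splits: one raw encounter becomes two pieces separated
    # by a sub-4-hour gap (or overlapping), same hospital account
    if rate["transfer_split"] > 0:
        by_eid = {e.encounter_id: e for e in encounters}
        new_encounters: list[RawEncounter] = []
        for enc in encounters:
            span = enc.discharge - enc.admit
            if (span > timedelta(hours=16)
                    and rng.random() < rate["transfer_split"]):
                frac = 0.3 + 0.4 * rng.random()
                mid = enc.admit + span * frac
                mid = mid.replace(microsecond=0)
                if rng.random() < 0.5:
                    gap = timedelta(minutes=int(rng.integers(15, 235)))
                    second_start = mid + gap
                else:  # overlapping pieces
                    second_start = mid - timedelta(
                        minutes=int(rng.integers(30, 120)))
                new_encounters.append(RawEncounter(
                    patient_id=enc.patient_id,
                    encounter_id=enc.encounter_id + ".1",
                    admit=enc.admit, discharge=mid,
                    encounter_class=enc.encounter_class,
                    hospital_account_id=enc.hospital_account_id))
                new_encounters.append(RawEncounter(
                    patient_id=enc.patient_id,
                    encounter_id=enc.encounter_id + ".2",
                    admit=second_start, discharge=enc.discharge,
                    encounter_class=enc.encounter_class,
                    hospital_account_id=enc.hospital_account_id))
                ledger.n_transfer_split += 1
            else:
                new_encounters.append(enc)
        del by_eid
        encounters = new_encounters

    # -- duplicate hospital accounts: same account id and diagnoses,
    # different admit/discharge stamps (the later copy loses the dedup)
    if rate["dup_account"] > 0:
        for c in list(charges):
            if c.encounter_class is not EncounterClass.INPATIENT:
                continue
            if rng.random() < rate["dup_account"]:
                charges.append(ChargeRecord(
                    hospital_account_id=c.hospital_account_id,
                    patient_id=c.patient_id,
                    admit=c.admit + timedelta(hours=2),
                    discharge=c.discharge + timedelta(hours=1),
                    diagnosis_codes=c.diagnosis_codes,
                    encounter_class=c.encounter_class))
                ledger.n_dup_account += 1

    order = rng.permutation(len(events))
    events = [events[j] for j in order]
    return (SimulatedData(events=events, encounters=encounters,
                          charges=charges, truth=truth,
                          config=data.config),
            ledger)
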