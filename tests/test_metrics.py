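"""LOS conventions, provision days, frequency/comprehensiveness, heatmap."""

from __future__ import annotations

import random
from datetime import datetime

import pytest

from ipplog import (
    Admission,
    ClassifiedEvent,
    Function,
    Level,
    assign_provision_days,
    build_sessions,
    compute_los,
    compute_los_cap,
    compute_metrics,
    filter_admissions_by_los,
    make_admission_id,
    provisioning_heatmap,
)
from ipplog.models import ProvisionContext


def admission(start, end, pid="P1"):
    return Admission(
        patient_id=pid, admission_id=make_admission_id(pid, start),
        start=start, end=end, source_encounter_ids=("E1",))


def event(ts, pid="P1", adm=None, action="Get Care Team",
          function=Function.CARE_TEAM, active=True):
    return ClassifiedEvent(patient_id=pid, action=action, timestamp=ts,
                           function=function, active=active,
                           admission_id=adm)


class TestComputeLos:
    def test_overnight_stay_is_one_day(self):
        a = admission(datetime(2015, 1, 1, 23, 0),
                      datetime(2015, 1, 2, 1, 0))
        assert compute_los(a) == 1

    def test_same_calendar_day_is_zero(self):
        a = admission(datetime(2015, 1, 1, 8, 0),
                      datetime(2015, 1, 1, 19, 0))
        assert compute_los(a) == 0

    def test_jan_first_to_fourth_is_three(self):
        a = admission(datetime(2015, 1, 1, 10, 0),
                      datetime(2015, 1, 4, 9, 0))
        assert compute_los(a) == 3


class TestLosCap:
    @staticmethod
    def brute_force_cap(counts, min_group_size):
        # largest LOS whose group meets the a-priori size
        best = -1
        for cand in sorted(counts):
            if counts[cand] >= min_group_size:
                best = max(best, cand)
        return best

    def test_reference_count_table(self):
        counts = {0: 100, 1: 80, 2: 40, 3: 10}
        assert compute_los_cap(counts, min_group_size=30) == 2
        assert self.brute_force_cap(counts, 30) == 2

    def test_all_groups_large_cap_is_max_observed(self):
        counts = {0: 50, 1: 45, 3: 31}
        assert compute_los_cap(counts, min_group_size=30) == 3
        assert compute_los_cap(counts, min_group_size=1) == 3

    def test_matches_bruteforce_on_random_tables(self):
        rnd = random.Random(55)
        for _ in range(200):
            counts = {l: rnd.randrange(1, 120)
                      for l in rnd.sample(range(0, 40),
                                          rnd.randrange(1, 15))}
            size = rnd.randrange(1, 100)
            assert compute_los_cap(counts, size) \
                == self.brute_force_cap(counts, size)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_los_cap({0: 10}, min_group_size=0)
        with pytest.raises(ValueError):
            compute_los_cap({}, min_group_size=5)

    def test_filter_applies_stricter_of_data_and_hard_cap(self):
        adms = []
        for day in range(6):
            for i in range(40 if day < 4 else 5):
                adms.append(admission(
                    datetime(2015, 1, 1, 8), datetime(2015, 1, 1 + day, 9),
                    pid=f"P{day}_{i}"))
        kept, cap = filter_admissions_by_los(adms, hard_cap=30,
                                             min_group_size=30)
        assert cap == 3
        assert all(compute_los(a) <= 3 for a in kept)
        kept2, cap2 = filter_admissions_by_los(adms, hard_cap=2,
                                               min_group_size=30)
        assert cap2 == 2


class TestProvisionDays:
    def test_first_event_on_admit_date_day_zero(self):
        adm = admission(datetime(2015, 1, 1, 8), datetime(2015, 1, 5, 9))
        evs = [event(datetime(2015, 1, 1, 14), adm=adm.admission_id)]
        stamped, contexts, flagged = assign_provision_days(evs, [adm])
        assert stamped[0].provision_day == 0
        assert contexts[0].provisioning_day == 0
        assert flagged == []

    def test_delayed_provisioning_offsets(self):
        adm = admission(datetime(2015, 1, 1, 8), datetime(2015, 1, 8, 9))
        evs = [event(datetime(2015, 1, 3, 10), adm=adm.admission_id),
               event(datetime(2015, 1, 5, 10), adm=adm.admission_id)]
        stamped, contexts, _ = assign_provision_days(evs, [adm])
        assert contexts[0].provisioning_day == 2
        assert [e.provision_day for e in stamped] == [0, 2]

    def test_provisioned_second_day_of_three_day_stay(self):
        adm = admission(datetime(2015, 1, 1, 8), datetime(2015, 1, 4, 9))
        evs = [event(datetime(2015, 1, 2, 10), adm=adm.admission_id)]
        _, contexts, _ = assign_provision_days(evs, [adm])
        assert contexts[0].los_days == 3
        assert contexts[0].provisioning_day == 1

    def test_admission_without_events_flagged(self):
        adm = admission(datetime(2015, 1, 1, 8), datetime(2015, 1, 2, 9))
        _, contexts, flagged = assign_provision_days([], [adm])
        assert contexts == []
        assert flagged == [adm.admission_id]


def _build(pid_events):
    """Link, stamp and sessionize a dict {pid: [(ts, function, active)]}
    on one 20-day admission per patient; returns (sessions, events)."""
    sessions, events = [], []
    adms = []
    for pid, evs in pid_events.items():
        start = datetime(2015, 2, 1, 6)
        adm = admission(start, datetime(2015, 2, 21, 10), pid=pid)
        adms.append(adm)
        events += [
            event(ts, pid=pid, adm=adm.admission_id, function=f,
                  active=a,
                  action="Send MyChart email"
                  if f is Function.ADMINISTRATIVE else f.value)
            for ts, f, a in evs
        ]
    events, contexts, _ = assign_provision_days(events, adms)
    sessions = build_sessions(events)
    return sessions, events


class TestComputeMetrics:
    def test_session_frequency_and_comprehensiveness(self):
        t0 = datetime(2015, 2, 2, 9)
        sessions, events = _build({"P1": [
            (t0, Function.CARE_TEAM, True),
            (t0.replace(minute=2), Function.CARE_TEAM, True),
            (t0.replace(minute=4), Function.CARE_TEAM, True),
            (t0.replace(minute=6), Function.NOTES, False),
        ]})
        (m,) = compute_metrics(sessions, events, "session")
        assert m.frequency[Function.CARE_TEAM] == 3
        assert m.frequency[Function.NOTES] == 0
        assert m.comprehensiveness == 1
        assert m.n_sessions == 1

    def test_admin_only_session_scores_zero(self):
        t0 = datetime(2015, 2, 2, 9)
        sessions, events = _build({"P1": [
            (t0, Function.ADMINISTRATIVE, False),
            (t0.replace(minute=1), Function.ADMINISTRATIVE, True),
        ]})
        (m,) = compute_metrics(sessions, events, "session")
        assert all(v == 0 for v in m.frequency.values())
        assert m.comprehensiveness == 0
        assert m.admin_active_count == 1

    def test_patient_comprehensiveness_unions_admissions(self):
        pid = "P1"
        a1 = admission(datetime(2015, 1, 1, 6), datetime(2015, 1, 4, 10),
                       pid=pid)
        a2 = admission(datetime(2015, 5, 1, 6), datetime(2015, 5, 4, 10),
                       pid=pid)
        evs = [
            event(datetime(2015, 1, 2, 9), pid=pid, adm=a1.admission_id,
                  function=Function.CARE_TEAM),
            event(datetime(2015, 1, 2, 9, 5), pid=pid,
                  adm=a1.admission_id, function=Function.HAPPENING_SOON),
            event(datetime(2015, 5, 2, 9), pid=pid, adm=a2.admission_id,
                  function=Function.VITALS_LABS),
            event(datetime(2015, 5, 2, 9, 5), pid=pid,
                  adm=a2.admission_id, function=Function.CHECK_MESSAGES),
            event(datetime(2015, 5, 2, 9, 10), pid=pid,
                  adm=a2.admission_id, function=Function.EDUCATION),
        ]
        evs, _, _ = assign_provision_days(evs, [a1, a2])
        sessions = build_sessions(evs)
        by_level = {
            lvl: compute_metrics(sessions, evs, lvl)
            for lvl in ("admission", "patient")
        }
        adm_c = sorted(m.comprehensiveness
                       for m in by_level["admission"])
        assert adm_c == [2, 3]
        (pm,) = by_level["patient"]
        assert pm.comprehensiveness == 5
        assert pm.comprehensiveness >= max(adm_c)

    def test_provision_day_filter_and_monotonicity(self):
        pid = "P1"
        adm = admission(datetime(2015, 2, 1, 6),
                        datetime(2015, 2, 25, 10), pid=pid)
        evs = [event(datetime(2015, 2, 1 + d, 9), pid=pid,
                     adm=adm.admission_id) for d in range(0, 15)]
        evs, _, _ = assign_provision_days(evs, [adm])
        sessions = build_sessions(evs)
        freq = {}
        for max_day in (4, 9, 30):
            (m,) = compute_metrics(sessions, evs, Level.ADMISSION,
                                   max_provision_day=max_day)
            freq[max_day] = (m.frequency[Function.CARE_TEAM], m.n_sessions)
        assert freq[4] == (5, 5)
        assert freq[9] == (10, 10)
        assert freq[30] == (15, 15)

    def test_admission_frequency_sums_sessions(self, clean_cohort,
                                               clean_result):
        res = clean_result
        sess_by_adm = {}
        session_of = {s.session_id: s for s in res.sessions}
        for m in res.metrics[Level.SESSION]:
            adm = session_of[m.unit_id].admission_id
            agg = sess_by_adm.setdefault(adm, {})
            for f, n in m.frequency.items():
                agg[f] = agg.get(f, 0) + n
        for m in res.metrics[Level.ADMISSION]:
            expected = sess_by_adm.get(m.unit_id, {})
            got = {f: n for f, n in m.frequency.items() if n > 0}
            assert got == {f: n for f, n in expected.items() if n > 0}

    def test_comprehensiveness_bounds_all_levels(self, clean_result):
        for lvl in Level:
            for m in clean_result.metrics[lvl]:
                assert 0 <= m.comprehensiveness <= 9


class TestProvisioningHeatmap:
    def ctx(self, pday, los, i):
        return ProvisionContext(
            admission_id=f"A{i}", patient_id=f"P{i}",
            provision_date=datetime(2015, 1, 1 + pday).date(),
            los_days=los, provisioning_day=pday)

    def test_all_provisioned_on_admission_day_single_row(self):
        contexts = [self.ctx(0, los, i)
                    for i, los in enumerate([0, 1, 2, 3, 3])]
        heat = provisioning_heatmap(contexts)
        assert heat["counts"].loc[0].sum() == 5
        assert heat["counts"].drop(index=0).to_numpy().sum() == 0
        assert heat["percent"].loc[0, 3] == 100.0

    def test_single_patient_single_cell(self):
        heat = provisioning_heatmap([self.ctx(1, 4, 0)])
        assert heat["counts"].loc[1, 4] == 1
        assert heat["percent"].loc[1, 4] == 100.0

    def test_column_sums_match_per_los_counts(self):
        rnd = random.Random(9)
        contexts = []
        for i in range(200):
            los = rnd.randrange(0, 12)
            contexts.append(self.ctx(rnd.randrange(0, los + 1), los, i))
        heat = provisioning_heatmap(contexts, max_los=10)
        import collections
        per_los = collections.Counter(c.los_days for c in contexts
                                      if c.los_days <= 10)
        for los in range(11):
            assert heat["counts"][los].sum() == per_los.get(los, 0)
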