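"""Synthetic-data generator: determinism, artifacts, distributions."""

from __future__ import annotations

from collections import Counter
from datetime import timedelta

import numpy as np
import pytest
from scipy import stats

from ipplog import SimulationConfig, corrupt, simulate
from ipplog.models import Function
from ipplog.simulate import ARTIFACT_TYPES

from conftest import metric_mismatches, run_uncapped


class TestDeterminism:
    def test_identical_seed_reproduces_byte_identical_tables(self, tmp_path):
        from ipplog.io import write_table
        paths = []
        for run in range(2):
            d = simulate(SimulationConfig(n_patients=15, seed=8))
            p = tmp_path / f"run{run}"
            p.mkdir()
            write_table(d.events, p / "audit.csv")
            write_table(d.encounters, p / "adt.csv")
            write_table(d.charges, p / "charges.csv")
            paths.append(p)
        for name in ("audit.csv", "adt.csv", "charges.csv"):
            assert (paths[0] / name).read_bytes() \
                == (paths[1] / name).read_bytes()

    def test_different_seeds_differ(self):
        a = simulate(SimulationConfig(n_patients=10, seed=1))
        b = simulate(SimulationConfig(n_patients=10, seed=2))
        assert a.events != b.events


class TestStructure:
    def test_sessions_respect_gap_margins(self, clean_cohort):
        """Intra-session gaps < 10 min, inter-session gaps > 30 min, so
        the 15-minute threshold is unambiguous by construction."""
        truth = clean_cohort.truth
        by_adm = {}
        for s in truth.sessions:
            by_adm.setdefault(s.admission_id, []).append(s)
        events_by_pid = {}
        for e in clean_cohort.events:
            events_by_pid.setdefault(e.patient_id, []).append(e)
        for ss in by_adm.values():
            ss.sort(key=lambda s: s.start)
            for prev, nxt in zip(ss, ss[1:]):
                assert nxt.start - prev.end > timedelta(minutes=30)
        for s in truth.sessions:
            evs = sorted(
                (e for e in events_by_pid[s.patient_id]
                 if s.start <= e.timestamp <= s.end),
                key=lambda e: e.timestamp)
            assert len(evs) == s.n_events
            for a, b in zip(evs, evs[1:]):
                assert b.timestamp - a.timestamp < timedelta(minutes=10)

    def test_events_fall_inside_their_admissions(self, clean_cohort):
        spans = {}
        for a in clean_cohort.truth.admissions:
            spans.setdefault(a.patient_id, []).append((a.start, a.end))
        for e in clean_cohort.events:
            assert any(s <= e.timestamp <= t
                       for s, t in spans[e.patient_id])

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            simulate(SimulationConfig(n_patients=0))
        with pytest.raises(ValueError):
            SimulationConfig(
                artifact_rates={"wallpaper": 1.5}).validate()
        with pytest.raises(ValueError):
            SimulationConfig(artifact_rates={"bogus": 0.1}).validate()
        bad_probs = {f: 0.5 for f in (Function.CARE_TEAM,
                                      Function.NOTES,
                                      Function.EDUCATION)}
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(function_use_probs=bad_probs).validate()

    def test_los_approximates_lognormal(self):
        """Chi-square goodness of fit of integer LOS against the rounded
        log-normal, alpha=0.01, across seeded replicates (>=90% pass)."""
        mu, sigma = 1.1, 0.8
        passes = 0
        n_rep = 10
        for seed in range(n_rep):
            d = simulate(SimulationConfig(n_patients=400, seed=seed))
            los = np.array([
                (a.end.date() - a.start.date()).days
                for a in d.truth.admissions
            ])
            edges = np.arange(0, 13)
            counts = np.array(
                [(los == k).sum() for k in edges[:-1]]
                + [(los >= edges[-1]).sum()])
            cdf = stats.lognorm(s=sigma, scale=np.exp(mu)).cdf
            probs = np.array(
                [cdf(k + 0.5) - (cdf(k - 0.5) if k else 0.0)
                 for k in edges[:-1]]
                + [1.0 - cdf(edges[-1] - 0.5)])
            keep = probs * len(los) >= 5
            chi = stats.chisquare(counts[keep],
                                  probs[keep] / probs[keep].sum()
                                  * counts[keep].sum())
            if chi.pvalue > 0.01:
                passes += 1
        assert passes >= 0.9 * n_rep


class TestCorrupt:
    def test_zero_rates_identity(self, clean_cohort):
        d, ledger = corrupt(clean_cohort, {t: 0.0 for t in ARTIFACT_TYPES},
                            seed=3)
        assert sorted(d.events, key=lambda e: (e.patient_id, e.timestamp,
                                               e.action)) \
            == sorted(clean_cohort.events,
                      key=lambda e: (e.patient_id, e.timestamp, e.action))
        assert d.encounters == clean_cohort.encounters
        assert d.charges == clean_cohort.charges
        assert ledger.n_wallpaper == ledger.n_dup_timestamp == 0

    def test_wallpaper_cadence_is_exactly_300s(self, clean_cohort):
        d, ledger = corrupt(clean_cohort, {"wallpaper": 1.0}, seed=4)
        assert ledger.n_wallpaper > 0
        wp = sorted(
            (e for e in d.events if e.action == "Get Wallpaper Data"),
            key=lambda e: (e.patient_id, e.timestamp))
        assert len(wp) == ledger.n_wallpaper
        # consecutive refreshes within one patient-day run 300 s apart
        n_pairs = 0
        for a, b in zip(wp, wp[1:]):
            if (a.patient_id == b.patient_id
                    and a.timestamp.date() == b.timestamp.date()):
                assert (b.timestamp - a.timestamp).total_seconds() == 300
                n_pairs += 1
        assert n_pairs > 0

    def test_sequential_login_cleanup_restores_clean_stream(self,
                                                            clean_cohort):
        from ipplog.taxonomy import clean_events
        d, ledger = corrupt(clean_cohort, {"sequential_login": 0.3},
                            seed=5)
        assert ledger.n_sequential_login > 0
        cleaned_dirty, rep = clean_events(d.events)
        cleaned_clean, _ = clean_events(clean_cohort.events)
        assert rep.n_login_collapsed == ledger.n_sequential_login
        assert cleaned_dirty == cleaned_clean

    def test_dup_timestamp_dedup_count_matches_ledger(self, clean_cohort):
        from ipplog.taxonomy import clean_events
        d, ledger = corrupt(clean_cohort, {"dup_timestamp": 0.2}, seed=6)
        assert ledger.n_dup_timestamp > 0
        _, rep = clean_events(d.events)
        assert rep.n_deduped == ledger.n_dup_timestamp


class TestRecovery:
    def test_clean_path_recovers_truth_exactly(self, clean_cohort,
                                               clean_result):
        assert metric_mismatches(clean_cohort.truth, clean_result) == []
        got = {(s.session_id, s.start, s.end, s.event_count)
               for s in clean_result.sessions}
        want = {(s.session_id, s.start, s.end, s.n_events)
                for s in clean_cohort.truth.sessions}
        assert got == want

    @pytest.mark.parametrize("artifact", ARTIFACT_TYPES)
    def test_single_artifact_robustness(self, clean_cohort, artifact):
        d, ledger = corrupt(clean_cohort, {artifact: 0.2}, seed=10)
        result = run_uncapped(d)
        assert metric_mismatches(clean_cohort.truth, result) == []
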