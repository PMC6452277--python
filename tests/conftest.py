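"""Shared fixtures and helpers for the ipplog test suite."""

from __future__ import annotations

from datetime import datetime, timedelta

import pytest

from ipplog import Level
from ipplog.pipeline import PipelineConfig, run_pipeline
from ipplog.simulate import SimulationConfig, simulate

BASE = datetime(2015, 3, 10, 8, 0, 0)


def dt(**kwargs) -> datetime:
    """Offset from the suite's base timestamp, e.g. dt(hours=2, minutes=5)."""
    return BASE + timedelta(**kwargs)


#: Pipeline config for ground-truth comparisons: no LOS-based cohort
#: exclusion, so every simulated unit is compared (the cap logic has its
#: own tests).
UNCAPPED = PipelineConfig(los_hard_cap=10**6, min_group_size=1)


def metric_mismatches(truth, result, max_provision_day=9):
    """Count units whose pipeline metrics differ from ground truth.

    Compares unit-id sets and, per unit, the nonzero frequency map,
    comprehensiveness, and n_sessions at all three levels.  Returns a
    list of human-readable mismatch descriptions (empty = exact match).
    """
    problems = []
    for lvl in Level:
        exp = truth.expected_metrics(lvl.value, max_provision_day)
        got = {m.unit_id: m for m in result.metrics[lvl]}
        if set(exp) != set(got):
            problems.append(
                f"{lvl.value}: unit sets differ "
                f"({len(exp)} expected vs {len(got)} observed)")
            continue
        for uid, e in exp.items():
            m = got[uid]
            freq = {f: n for f, n in m.frequency.items() if n > 0}
            if (freq != e["frequency"]
                    or m.comprehensiveness != e["comprehensiveness"]
                    or m.n_sessions != e["n_sessions"]):
                problems.append(f"{lvl.value}/{uid}: metrics differ")
    return problems


def run_uncapped(data):
    return run_pipeline(data.events, data.encounters, data.charges,
                        UNCAPPED)


@pytest.fixture(scope="session")
def clean_cohort():
    """A mid-sized clean cohort shared by read-only tests."""
    return simulate(SimulationConfig(n_patients=60, seed=42))


@pytest.fixture(scope="session")
def clean_result(clean_cohort):
    return run_uncapped(clean_cohort)
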