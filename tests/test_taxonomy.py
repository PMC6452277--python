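"""Action taxonomy and audit-log cleaning."""

from __future__ import annotations

import random

import pytest
import yaml

from ipplog import AuditEvent, Function, clean_events, default_taxonomy, load_taxonomy
from ipplog.taxonomy import (
    Disposition,
    UnmappedActionError,
    default_external_map,
)

from conftest import dt


class TestDefaultTaxonomy:
    @pytest.mark.parametrize("action, function, active", [
        ("Save message", Function.SEND_MESSAGE, True),
        ("Get patient notes", Function.NOTES, False),
        ("Get Care Team", Function.CARE_TEAM, True),
        ("Get messages", Function.CHECK_MESSAGES, True),
        ("Load schedule", Function.HAPPENING_SOON, True),
        ("Get lab result comments", Function.VITALS_LABS, True),
        ("Get health metrics", Function.VITALS_LABS, False),
        ("Save patient request", Function.I_WOULD_LIKE, True),
        ("Create MyChart account", Function.MYCHART, True),
        ("Update education status", Function.EDUCATION, True),
        ("Send MyChart email", Function.ADMINISTRATIVE, True),
        ("Login/logout", Function.ADMINISTRATIVE, False),
    ])
    def test_classification(self, action, function, active):
        entry = default_taxonomy().lookup(action)
        assert entry is not None
        assert entry.function is function
        assert entry.active is active
        assert entry.disposition is Disposition.KEEP

    @pytest.mark.parametrize("action", [
        "Get Menu Items", "Get Provider", "Get Wallpaper Data"])
    def test_system_noise_marked_for_removal(self, action):
        assert default_taxonomy().lookup(action).disposition \
            is Disposition.REMOVE

    def test_nine_core_functions_plus_administrative(self):
        funcs = default_taxonomy().functions
        assert len(funcs) == 10
        assert Function.ADMINISTRATIVE in funcs

    def test_yaml_round_trip(self, tmp_path):
        entries = [
            {"action": e.raw_action, "function": e.function.value,
             "active": e.active, "disposition": e.disposition.value}
            for e in default_taxonomy().entries()
        ]
        p = tmp_path / "taxonomy.yaml"
        p.write_text(yaml.safe_dump(entries))
        loaded = load_taxonomy(str(p))
        assert {(e.raw_action, e.function, e.active, e.disposition)
                for e in loaded.entries()} \
            == {(e.raw_action, e.function, e.active, e.disposition)
                for e in default_taxonomy().entries()}

    def test_duplicate_action_rejected(self, tmp_path):
        p = tmp_path / "taxonomy.yaml"
        p.write_text(yaml.safe_dump([
            {"action": "X", "function": "Administrative", "active": True},
            {"action": "X", "function": "Administrative", "active": False},
        ]))
        with pytest.raises(ValueError, match="duplicate"):
            load_taxonomy(str(p))


class TestCleanEvents:
    def test_sequential_logins_collapse_to_earliest(self):
        events = [
            AuditEvent("P1", "Login", dt(minutes=0)),
            AuditEvent("P1", "Login", dt(minutes=0, seconds=30)),
            AuditEvent("P1", "Login", dt(minutes=1)),
            AuditEvent("P1", "Get Care Team", dt(minutes=2)),
        ]
        out, report = clean_events(events)
        assert [(e.action, e.timestamp) for e in out] == [
            ("Login", dt(minutes=0)),
            ("Get Care Team", dt(minutes=2)),
        ]
        assert report.n_login_collapsed == 2

    def test_logins_in_separate_use_periods_not_collapsed(self):
        events = [
            AuditEvent("P1", "Login", dt(minutes=0)),
            AuditEvent("P1", "Login", dt(minutes=40)),
        ]
        out, report = clean_events(events)
        assert len(out) == 2
        assert report.n_login_collapsed == 0

    def test_same_timestamp_duplicates_reduced_to_one(self):
        events = [
            AuditEvent("P1", "Get messages", dt(minutes=5)),
            AuditEvent("P1", "Get messages", dt(minutes=5)),
        ]
        out, report = clean_events(events)
        assert len(out) == 1
        assert report.n_deduped == 1

    def test_wallpaper_stream_stripped_to_real_actions(self):
        # refresh every 5 min for an hour, three real actions interleaved
        events = [AuditEvent("P1", "Get Wallpaper Data", dt(minutes=5 * i))
                  for i in range(12)]
        events += [
            AuditEvent("P1", "Login", dt(minutes=1)),
            AuditEvent("P1", "Get Care Team", dt(minutes=12)),
            AuditEvent("P1", "Load schedule", dt(minutes=33)),
        ]
        out, report = clean_events(events)
        assert len(out) == 3
        assert report.n_removed == 12
        assert report.removed_by_action == {"Get Wallpaper Data": 12}

    def test_no_removed_actions_survive(self):
        events = [AuditEvent("P1", a, dt(minutes=i)) for i, a in enumerate(
            ["Get Menu Items", "Get Provider", "Get Wallpaper Data",
             "Get Care Team"])]
        out, _ = clean_events(events)
        assert {e.action for e in out} == {"Get Care Team"}

    def test_media_web_content_remapped_via_extended_info(self):
        events = [AuditEvent("P1", "Media/Web content", dt(minutes=1),
                             extended_info="Welcome video")]
        out, report = clean_events(events)
        assert report.n_remapped == 1
        assert out[0].function is Function.EDUCATION
        assert out[0].active is True
        assert out[0].action == "Welcome video"

    def test_dining_on_demand_maps_to_active_administrative(self):
        events = [AuditEvent("P1", "Media/Web content", dt(minutes=1),
                             extended_info="Dining on demand")]
        out, _ = clean_events(events)
        assert out[0].function is Function.ADMINISTRATIVE
        assert out[0].active is True

    def test_unmapped_action_routed_or_strict(self):
        events = [AuditEvent("P1", "Mystery Action", dt())]
        out, report = clean_events(events)
        assert out[0].function is Function.ADMINISTRATIVE
        assert not out[0].active
        assert report.n_unmapped == 1
        with pytest.raises(UnmappedActionError):
            clean_events(events, strict=True)

    def test_conservation_and_order_independence(self):
        rnd = random.Random(31)
        actions = ["Login", "Get Care Team", "Get Wallpaper Data",
                   "Get messages", "Get Menu Items", "Load schedule"]
        events = [
            AuditEvent(f"P{rnd.randrange(4)}", rnd.choice(actions),
                       dt(seconds=rnd.randrange(7200)))
            for _ in range(400)
        ]
        out, report = clean_events(events)
        assert (report.n_survivors + report.n_removed
                + report.n_login_collapsed + report.n_deduped) \
            == report.n_input
        shuffled = events[:]
        rnd.shuffle(shuffled)
        out2, report2 = clean_events(shuffled)
        assert out == out2
        assert report == report2

    def test_no_surviving_duplicate_keys(self):
        rnd = random.Random(13)
        events = [
            AuditEvent("P1", rnd.choice(["Get messages", "Login"]),
                       dt(seconds=rnd.randrange(100)))
            for _ in range(200)
        ]
        out, _ = clean_events(events)
        keys = [(e.patient_id, e.action, e.timestamp) for e in out]
        assert len(keys) == len(set(keys))

    def test_external_map_defaults_cover_all_five_labels(self):
        labels = {e.label for e in default_external_map().values()}
        assert labels == {
            "Dining on demand", "Welcome video", "Getting started",
            "MCB patients' rights and responsibilities",
            "MCB patients' tutorial"}
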