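# ipplog

Engagement metrics for **inpatient portals** (IPPs) from raw EHR audit
logs.

Hospitals that hand tablets to admitted patients (e.g. Epic's MyChart
Bedside) accumulate server-side audit logs of every tap — alongside
ADT (admission/discharge/transfer) records and hospital-charge files.
None of these were designed for research: encounters split across
transfers, page refreshes fire every five minutes, logins stutter in
bursts, and events appear outside any admission. `ipplog` is for
clinical-informatics researchers who need to turn that raw material
into defensible engagement measures.

## What it computes

The pipeline reconstructs three nested units of analysis and scores
each with two measures over the nine patient-facing portal functions
(care team, schedule, vitals/labs, secure messaging in/out, requests,
notes, education, ambulatory-portal access):

* **Admission** — raw ADT encounters are consolidated: overlapping
  intervals are unioned, and consecutive encounters with a
  discharge-to-admission gap ≤ 4 h (transfers) are merged transitively.
* **Session** — after artifact cleaning, a session is a maximal run of
  one patient's events with no inactivity gap exceeding 15 min:
  events *t*₁ ≤ … ≤ *t*ₙ share a session iff every consecutive gap
  *t*ᵢ₊₁ − *t*ᵢ ≤ 15 min. Login/logout stamps are not trusted as
  delimiters (idle auto-logout is unreliable).
* **Patient** — all of a patient's admissions combined.

For a unit *u* and function *f*:

* **frequency** *F*ᵤ(*f*) = number of *active* (patient-initiated)
  tasks of function *f* within *u*, restricted to the first 10 tablet
  provision days of each admission;
* **comprehensiveness** *C*ᵤ = |{*f* : *F*ᵤ(*f*) > 0}| ∈ [0, 9].

Administrative actions (navigation, login bookkeeping) never count in
either measure; session *duration* is computed only as a diagnostic,
because "zero-time" sessions (landing screen only) bias it beyond
repair. Admissions in the long-stay tail are excluded where the LOS
group falls under an a-priori size of 30.

Cleaning removes the documented logging artifacts before
sessionization: `Get Menu Items` (navigation), `Get Provider`
(replicated once per care-team member), `Get Wallpaper Data` (5-minute
refresh that chains genuine sessions together), sequential-login
bursts, exact duplicate rows, and out-of-encounter events; external
`Media/Web content` calls are remapped to concrete active tasks via
their extended-info codes. Every stage reports counts that reconcile
exactly: `input = linked + dropped(near/far) + removed + collapsed +
deduped`.

Because no public audit-log dataset exists, the package ships a seeded
synthetic generator (`ipplog.simulate`) that emits the three raw
tables with known ground truth and can inject each artifact at a
controlled rate — the basis of the test suite's exact-recovery checks.

## Worked example

```python
from ipplog import (SimulationConfig, simulate, run_pipeline, Level,
                    summarize_frequency, summarize_comprehensiveness)

data = simulate(SimulationConfig(n_patients=200, seed=7))
result = run_pipeline(data.events, data.encounters, data.charges)
print(result.manifest["counts"])
print(result.reports["los_filter"])
pm = result.metrics[Level.PATIENT]
print(summarize_frequency(pm, "patient").to_string(index=False))
```

prints

```
{'linked': 7768, 'dropped_near': 0, 'dropped_far': 0, 'removed': 0,
 'login_collapsed': 0, 'deduped': 0}
{'applied': True, 'effective_cap': 3, 'n_admissions_in': 229,
 'n_admissions_kept': 131}
                     function  median  q1  q3  iqr  min  max  n_units
 Access educational materials     0.5 0.0 1.0  1.0    0    8      122
        Access personal notes     0.0 0.0 1.0  1.0    0    3      122
        Check secure messages     1.0 0.0 2.0  2.0    0   12      122
               Happening soon     2.0 1.0 6.0  5.0    0   16      122
                 I would like     0.0 0.0 0.0  0.0    0    2      122
           MyChart Ambulatory     0.0 0.0 1.0  1.0    0    4      122
     Review current care team     3.0 1.0 6.0  5.0    0   24      122
Review vitals and lab results     1.0 0.0 2.0  2.0    0   15      122
        Send a secure message     0.0 0.0 0.0  0.0    0    2      122
```

All 7,768 simulated events linked (this cohort is artifact-free, so
nothing was removed); the data-driven LOS cap landed at 3 days for
this small cohort, keeping 131 of 229 admissions; care team and
schedule ("Happening soon") dominate, secure-message sending is
rarest — the qualitative profile the generator encodes. Of the 1,948
sessions, 124 are zero-time (no function beyond Administrative).

The same run from a shell:

```bash
ipplog simulate --seed 7 --n-patients 200 --out sim/
ipplog run --audit sim/audit_log.csv --adt sim/adt.csv \
           --charges sim/charges.csv --out out/
ipplog summarize --metrics out/metrics_patient.csv --level patient --out out/
ipplog heatmap --contexts out/provision_contexts.csv --out out/
```

`out/` then holds `sessions.csv`, `metrics_{session,admission,patient}.csv`,
frequency/comprehensiveness summary tables, the provisioning-day ×
LOS heatmap matrices, per-stage reports, and a `manifest.json` whose
config hash makes re-runs verifiably identical.

## Layout

| module | role |
|---|---|
| `ipplog.models` | record types, function vocabulary, deterministic ids |
| `ipplog.io` | schema-mapped CSV readers/writers, load reports |
| `ipplog.encounters` | overlap + 4-hour adjacency consolidation |
| `ipplog.charges` | inpatient restriction, hospital-account dedup |
| `ipplog.taxonomy` | action→function table, artifact cleaning |
| `ipplog.linkage` | event↔admission containment, charge attachment |
| `ipplog.sessions` | 15-minute-gap sessionization, diagnostics |
| `ipplog.metrics` | LOS/provision-day conventions, frequency & comprehensiveness |
| `ipplog.simulate` | seeded synthetic cohorts + artifact injection |
| `ipplog.pipeline` | orchestration, summaries, manifest |
| `ipplog.cli` | `ipplog simulate / run / summarize / heatmap` |

See `docs/methods.md` for the modelling assumptions and numerical
conventions.
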