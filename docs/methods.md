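# Methods

This note documents the conventions, assumptions and design choices
behind `ipplog`'s processing of inpatient-portal (IPP) audit logs, and
what the synthetic-data validation does and does not establish.

## Data model

Three raw tables enter the pipeline, joined only by the de-identified
study identifier (the audit log and ADT share no encounter key):

1. **Audit log** — one row per server-side action: patient id, activity
   code, optional extended-info code, timestamp. Timestamps are naive
   local datetimes at second resolution; a single-institution extract
   has one clock, so no timezone handling exists anywhere. Input
   formats (ISO-8601 or US `MM/DD/YYYY HH:MM:SS`) are configurable per
   site because extract headers and stamp styles vary; outputs are
   always ISO-8601.
2. **ADT** — one row per raw encounter (contact serial number) with
   admit/discharge times, encounter class and hospital account id.
3. **Charges** — one row per charge with hospital account id and
   diagnosis codes (carried as opaque strings; no ontology work).

## Admission consolidation

A continuous-care admission is the connected component of raw
encounters under two relations, applied per patient:

* **overlap** (closed intervals; touching counts), covering
  procedure-at-sister-hospital patterns that produce several admits but
  one discharge;
* **adjacency**: discharge-to-admission gap ≤ `merge_gap_hours`
  (default 4 h), covering between-facility transfers, applied
  transitively to a fixed point so merge order cannot matter.

A gap of *exactly* 4 h merges — "within" is read inclusively. The gap
is measured discharge-to-admission, the only defensible reading when
unit/facility codes that would distinguish true discharges from
transfers are absent. Admission ids are content hashes of
(patient, interval start), so re-runs are reproducible.

## Action taxonomy and cleaning

Every activity code maps to one of nine patient-facing functions or
Administrative, with an Active flag separating patient-initiated tasks
from background traffic. The bundled table covers the 30+ known codes;
site-specific tables can be supplied as YAML. Unmapped codes route to
Administrative/inactive with a warning (or raise, under `strict`).

Cleaning performs, in order, on a canonically sorted stream
(patient, time, action — output is independent of input row order):

1. **Removal** of system-generated codes: `Get Menu Items`
   (navigation), `Get Provider` (emitted once per care-team member per
   `Get Care Team`, so retaining it would multiply-count one action),
   and `Get Wallpaper Data` (page refresh every 5 min).
2. **Remapping** of `Media/Web content` rows to concrete active tasks
   via their extended-info code. The default map sends the four
   education-like external actions (welcome video, getting started,
   tutorial, rights & responsibilities) to *Access educational
   materials* and dining orders to an active Administrative task; real
   deployments should override the codes, which are site-specific.
3. **Sequential-login collapse** to the earliest login of a run. A run
   is bounded: consecutive identical logins more than
   `login_run_max_gap_minutes` apart (default: the session threshold,
   15 min) are *not* one run. An unbounded collapse would swallow the
   lone login of a genuine landing-screen visit into the next
   session's login and destroy that session's true start time; the
   bounded rule removes exactly the burst artifact.
4. **Exact-duplicate removal** of identical (patient, action,
   timestamp) rows, keeping the first after canonical sort. Such ties
   may be real or artifactual; since that cannot be decided from the
   log, the dropped count is always reported.

The cleaning report conserves counts exactly:
`survivors + removed + collapsed + deduped = input`.

## Linkage

An event belongs to the admission whose closed interval [start, end]
contains its timestamp (an event at the discharge second is
in-encounter); consolidated admissions are disjoint per patient, so
containment is unambiguous. Events outside every admission are
dropped, classified **near** when within `near_window_hours` (default
24 h — a diagnostic convention, not an empirical constant) of any
admission boundary, else **far**. No rescue rule exists for near
strays. Charges attach to admissions through the union of hospital
account ids collected during consolidation; admissions without a
matching charge are flagged, never dropped.

## Sessionization

Within one (patient, admission), a session breaks exactly where the
inter-event gap exceeds `session_gap_minutes` (default 15; exactly 15
stays in-session). The threshold is deliberately above the
institution-typical 10-minute idle logout, which fires unreliably and
is ignored as a signal. Sessions are built only *after* cleaning and
linkage, so removed refreshes can no longer bridge genuine gaps —
`session_diagnostics` exists to show the before/after contrast, and
retaining wallpaper events can only merge sessions (5 min < 15 min),
never split them.

A session is **zero-time** iff it activates no function outside
Administrative. (A zero-*duration* session can still activate a
function — two different actions in the same second — so duration is
not the criterion.) Duration is emitted only in diagnostics, never as
an engagement measure.

## Engagement measures and cohort rules

All day arithmetic is calendar-day based: LOS = discharge date − admit
date (same-day stay → 0). The provision date of an admission is the
date of its **first audit event** — the extract has no provisioning
table, so first use proxies tablet hand-off; an admission with no
events gets no provision context and is flagged. Provision day of an
event is its date minus the provision date (0-based).

Frequency counts active non-Administrative tasks per function with
provision day ≤ `max_provision_day` (default 9, i.e. the first 10
provision days; 29 gives the 30-day variant). Comprehensiveness is the
number of the nine functions with nonzero frequency. Active
Administrative tasks are tallied in a separate column and never enter
either measure. The provision-day filter applies within each
admission, also at the patient level. Two auxiliary views are emitted
(`comprehensiveness_pct` = C/9·100; per-unit session counts) since
some summaries express the measures that way; the task-count
definitions are primary.

Two cohort caps combine, the stricter winning: a hard LOS cap (default
30 days) and a data-driven cap — the largest observed LOS whose group
still has at least `min_group_size` (default 30) admissions. The
data-driven rule cuts the thin long-stay tail where summary statistics
would rest on a handful of patients; it intentionally does not require
*short* LOS groups to be large, because short stays can be legitimately
rare without invalidating the tail cut.

Quantile convention for summary tables: linear interpolation, recorded
in the run manifest.

## Synthetic cohorts

The generator draws, per patient: 1–2 admissions; LOS as a rounded
log-normal (μ=1.1, σ=0.8 → median ≈ 3 days, right-skewed like real
stays); a categorical provisioning delay (50% day 0, tailing to day
4); negative-binomial session counts per provision day (mean 2); and
per-session action counts (Poisson, mean 3) over a function-use
profile in which care team and schedule dominate and secure-message
sending is rarest — a qualitative echo of published usage patterns,
with no claim to institutional magnitudes. Sessions live in an
08:00–22:00 day window, so they never cross midnight; intra-session
gaps are 45–300 s and inter-session gaps > 31 min, leaving the
15-minute boundary unambiguous (boundary behaviour is tested with
dedicated ±1 s fixtures instead). All randomness flows from one seed;
re-runs are byte-identical.

`corrupt` injects, each at an independent per-opportunity rate, the
six documented artifacts: wallpaper refreshes at an exact 300 s cadence
spanning each day's sessions (so they bridge real gaps until cleaned);
1–3 extra logins right after a session's login; exact duplicate rows;
near (< 21 h post-discharge) and far (> 40 days) stray events;
admission splits into two sub-4-hour-gap or overlapping ADT pieces; and
duplicate hospital-account charge rows with shifted timestamps. An
injection ledger records every added row so tests reconcile cleaning
and drop reports against it exactly.

**What passing recovery tests shows — and does not.** Exact recovery on
these cohorts demonstrates that each cleaning stage removes precisely
its artifact and nothing else under unambiguous gap margins. Real logs
are messier: boundary-straddling gaps near 15 min, midnight-crossing
sessions, unknown activity codes, clock skew, and compound artifacts
are either exercised separately by unit fixtures or out of scope; on
real data the thresholds are judgement calls, and sensitivity re-runs
(all thresholds sit in one config block) are the appropriate check.

## Numerical and degenerate-input conventions

* Ties at identical timestamps sort by action label; dedup keeps the
  first record after canonical sort (deterministic, order-independent).
* Duplicate charge payload conflicts resolve to the earliest admit,
  and are always surfaced in the consistency report.
* Empty inputs: empty event lists produce empty session lists and
  empty histograms; a LOS cap cannot be computed from zero admissions
  (error); writing an empty table requires an explicit table kind.
* Problem sizes in the validation suite — 500 random fixtures per
  oracle, a 1,000-patient recovery cohort, 40-patient contrast
  cohorts — were chosen so the whole suite completes in seconds while
  leaving every check exact rather than statistical.

## Known limitations

* First portal use proxies provisioning; a patient who ignores the
  tablet for a day shifts their provision days accordingly.
* The hospital account id is required as an input column; how an
  institution constructs it when one charge covers several encounters
  is outside the package.
* Near-boundary stray events are dropped, not rescued; no device-level
  identity tracking; no clustering of users or actions.
* The generator does not model clinically realistic diagnosis codes,
  tablet hardware events, or multi-site clock skew.
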