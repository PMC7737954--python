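# Methods

## The problem

Door-to-door recruitment studies select geocoded residential structures,
visit each one up to a fixed number of times, and need to know — every
field day — which households to attempt next and how the campaign is
converging on its recruitment targets. `fieldtrack` implements the
computational core of such a workflow as a headless library: the
persistent data model is two flat CSV files (a preload of structures and a
visit log), and every behavioral rule is a pure function over them.

## Data model

A **Structure** is one geocoded residential unit: HHID (unique ID),
community code, WGS84 centroid (decimal degrees), and an area type
(`NEIGHBORHOOD` for door-to-door work, `APARTMENT` for centralized
recruitment in housing complexes). A **HouseholdLog** is the ordered list
of visit records for one HHID. Record 0 is the preload row itself —
immutable by construction, so the provenance of the selection can never be
edited away — and real visit attempts are numbered contiguously from 1.
Each visit carries a STATUS (did anyone answer, was it a home at all) and
a DETAILS value conditioned on that status (the terminal contact results
— recruited, refused, ineligible — live under `CONTACT_MADE`). Both
vocabularies are configuration, not code: `StudyConfig` serializes to
YAML and every validation goes through it.

Timestamps are ISO 8601 local time. The datum is WGS84; the tile module
assumes spherical Web-Mercator, the universal web-mapping convention.

## Visit protocol

A household closes when a visit carries a terminal status or detail
(recruited / refused / ineligible / not-a-home / vacant — the last two
terminal on first occurrence and pooled into one "not a home" reporting
column), or when `max_visits` attempts (default 3) are exhausted, in which
case the final outcome is `NO_CONTACT`. Setting a follow-up date is not a
visit and does not consume an attempt. All engine operations are pure
(log in, new log out), which makes the simulator, the tests and the CLI
share one code path.

Closure is monotone under appended visits. Edits are deliberately allowed
to re-open a household: a mis-keyed "recruited" must be correctable, and
the alternative (freezing closed logs entirely) would push corrections
outside the audited data path. The preload row is the only immutable
record.

## Marker states and the Saturday rule

The field-prioritization scheme is a total function
`derive_marker_state(log, today, config)` onto six base colors and three
outline modifiers. Precedence, highest first:

1. **GREEN** — closed; absorbing for all later dates; never outlined.
2. **PINK** — a pending follow-up date equal to today. An explicit
   resident appointment outranks every advisory, including the Saturday
   rule on a weekday.
3. **BLACK + advisory** — the Saturday rule: an open household with two
   or more no-answer attempts and no visit yet on a Saturday. Advisory
   only — recording a weekday visit remains legal; the simulator's field
   policy, however, waits for Saturday.
4. **BLACK / GREY** — a pending follow-up on a Saturday / on a weekday.
   Any pending follow-up date earlier than today adds a **RED outline**
   (overdue), on top of whichever base applies (also on a rule-3 BLACK).
5. **ORANGE** — visited but open with nothing scheduled; **black
   outline** when the latest visit is dated today.
6. **BLUE** — never visited.

A follow-up date is *pending* until a later visit occurs on or after it;
that visit consumes the appointment whether it was kept on the day or made
late. Saturday is ISO weekday 6. A future-Saturday appointment shows BLACK
even before any visit: pre-first-visit scheduling is rare but
representable, and hiding it would lose information.

`daily_worklist` orders open households PINK, then overdue (red outline),
then BLACK when today is Saturday (on weekdays BLACK sinks to the bottom —
those households should wait), then GREY, ORANGE, BLUE, ties on HHID.

The exhaustiveness test enumerates a factorial design over the features
the function reads — 0–3 visits, miss/contact pattern, Saturday visited or
not, follow-up date in {none, past, today, future weekday, future
Saturday}, visited today or not (~300 reachable logs) — and checks
totality, determinism and the outline constraints, with the documented
example cases frozen by hand.

## Sampling and merge

Selection is uniform without replacement: candidates not in the exclusion
set are sorted by HHID, shuffled with a PCG64 generator (NumPy's named,
versioned bit generator) and the first *n* taken. Sorting first makes the
draw independent of input order; PCG64 makes it reproducible across
platforms, which matters when the selection run on a laptop must match the
one archived with the protocol. Mid-campaign merges add visit-0-only logs
for new structures and refuse (with the colliding HHIDs listed) to touch
any household with a recorded visit; re-merging the same selection is a
no-op. Replenishment per community is `max(0, target − recruited)` — the
default target is 100 — and only once every current selection is closed;
while any household is open the campaign might still meet the target.
Apartment-complex convenience recruitment needs no selection algorithm:
an operator-supplied list is merged the same way.

## Offline tiles

`latlon_to_tile` is the standard slippy-map transform
(`x = ⌊(λ+180)/360·2^z⌋`, `y = ⌊(1 − asinh(tan φ)/π)/2·2^z⌋`),
latitudes clamped to ±85.0511°. `tiles_for_bbox` computes the tile ranges
per zoom directly from the corner fractions with a half-open convention: a
bbox edge exactly on a tile boundary does not pull in the neighbor, and a
degenerate point yields exactly one tile per zoom. Tile fractions within
1e-13 (relative) of an integer are snapped before flooring so that the
inverse transform's one-ulp roundoff cannot flip a tile index across a
boundary — without the snap, the north-west corner of a tile bbox can map
back to the row above. The manifest writer lays out the de-facto
`z/x/y.png` directory skeleton with empty placeholders and a CSV index;
imagery retrieval is out of scope. Storage estimates use a nominal
15 kB/tile, a typical size for pre-rendered 256×256 street tiles.

## Reporting

The outcome table counts households with ≥1 recorded visit; open
households are excluded unless requested, in which case they form a
PENDING column (either way, outcome counts sum to the visited denominator
row by row, and the TOTAL row is the element-wise sum of the groups).
Percentages are rounded half-up — to one decimal in outcome tables, to the
nearest integer for the scheduled/unscheduled split and the mean
recruited per community — matching how such tables are conventionally
printed; Python's built-in banker's rounding would disagree on exact
halves. A visit is *scheduled* iff an earlier record of the same household
set FU_DATE to that visit's date — detected from log structure, since the
schema carries no scheduled flag. Empty inputs report 0.0 percentages and
flag the affected rows rather than dividing by zero.

## Synthetic campaigns

The generator scatters structures uniformly in per-community bounding
boxes (default: 0.02°×0.02° boxes on a grid near 18°N, 66.7°W, the scale
of a peri-urban study area) and the simulator replays a campaign through
the public engine API only — every simulated log is produced by
`record_visit` under the real config, so the simulator doubles as an
integration harness. The calendar runs Monday–Saturday; Sundays are
skipped. Each day the worklist is walked in priority order; the policy
attempts PINK and overdue households, BLACK households on Saturdays only,
BLUE/ORANGE households always, and leaves GREY households for their
appointment day.

Per visit: a structure is non-residential with probability
`p_not_a_home` (drawn once per structure); otherwise someone answers with
probability `p_contact`; conditional on contact the result is recruited /
refused / ineligible with the spec probabilities and undecided with the
remainder; an undecided resident books a follow-up 1–7 days ahead (never
a Sunday) with probability `fu_request_prob` (default 0.25, a plausible
appointment uptake; no published value exists to calibrate it).

Defaults are calibrated to a published campaign's final-outcome mix
(9.7% recruited, 8.5% refused, 37.4% ineligible, 25.6% no contact,
18.8% not a home over 23,830 households in 38 communities):
`CampaignSpec.from_final_outcome_rates` inverts those shares exactly when
undecided contacts are absent — the non-home share maps directly, three
straight misses must equal the no-contact share
(`p_contact = 1 − (r_nc/(1−r_nah))^{1/3}` ≈ 0.319), and contacted
households split proportionally. Acceptance-scale runs use 5,000
households (10 communities × 500), large enough that every outcome share
sits within ~3 binomial σ (≈1.2 points at worst) of its target while a
full simulation completes in seconds.

What the simulator does **not** model: travel time and routing, staff
capacity limits, within-household participant counts, weather or seasonal
contact-rate variation, spatially correlated vacancy, and follow-ups
requested on no-answer visits. Consequently a passing recovery test shows
the protocol machinery and the estimators are consistent — not that real
campaigns behave like the generator.

One protocol guarantee is narrower than it may appear: "every NO_CONTACT
closure contains a Saturday visit" is enforced by the field policy only
along the pure no-answer track, because the Saturday advisory is defined
on no-answer counts. A household whose attempts include a
contacted-but-undecided visit can exhaust its cap on weekdays (e.g. via a
kept weekday appointment) without the advisory ever firing; its closure is
labelled NO_CONTACT by the outcome rule even though contact occurred. The
invariant test therefore conditions on all-miss histories.

## Numerical and formatting choices

- CSV: UTF-8, comma, header mandatory; coordinates serialized with
  shortest-repr so write→read round-trips are exact.
- Saves are atomic (temp file + rename); each save also writes a
  date-stamped archive snapshot, one per calendar date, later dates never
  touching earlier snapshots.
- The external questionnaire link key is the identity mapping on HHID —
  deterministic and collision-free because HHIDs are already unique.
- Seeds: every stochastic routine takes an explicit integer seed; there is
  no hidden global state.

## Known limitations

- The participants-per-household conversion (targets are phrased per
  participant, recruitment is per household) is not modelled; replenishment
  counts recruited households against the community target.
- Visit deletion is unsupported by design; corrections go through edits,
  keeping visit numbering stable.
- The log store is flat CSV; concurrent writers are out of scope (the
  intended deployment is one device per field team).
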