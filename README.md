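# fieldtrack

Offline household-visit tracking for field recruitment studies.

Community-based cohort studies recruit by knocking on doors: a random
sample of geocoded residential structures is selected per community, each
structure is visited up to three times on different days — with at least
one attempt on a Saturday when nobody has answered — and every attempt is
logged until the household reaches a final outcome (recruited, refused,
ineligible, not a home, or no contact). `fieldtrack` is the computational
core of that workflow as a headless Python library plus a thin CLI, for
study planners and field-data engineers who need the logic without a GUI:

- **Data model & I/O** — a preload CSV of structures
  (`HHID, CLUSTER, LAT, LONG`) and a visit-log CSV
  (`REF, HHID, CLUSTER, LONG, LAT, VISIT, STRUCTURE, STATUS, DETAILS,
  VISIT_DATETIME, FU_DATE, FU_NOTES, INITIALS`), fully validated, with
  atomic saves and date-stamped archive snapshots. Visit 0 is the
  immutable preload row.
- **Visit engine** — pure append/edit operations with auto visit
  numbering, status→details conditioned vocabularies (configurable per
  study), closure after a terminal visit or `max_visits` attempts, and
  final-outcome classification.
- **Marker states** — the field-prioritization color scheme as a total
  function: blue (needs initial visit), orange (unscheduled follow-up;
  black-outlined if already visited today), grey/black (follow-up
  scheduled on a weekday/Saturday), pink (scheduled today), green
  (closed), red outline (overdue), plus the Saturday-rule advisory after
  two no-answer attempts, and a prioritized daily worklist.
- **Sampling & merge** — seeded, platform-reproducible random selection
  (PCG64 over the HHID-sorted pool) and mid-campaign merges that provably
  never touch visited households; per-community replenishment planning
  against a recruitment target (default 100).
- **Offline tiles** — slippy-map x/y/z tile math
  (`x = ⌊(λ+180)/360·2^z⌋`, `y = ⌊(1 − asinh(tan φ)/π)/2·2^z⌋`) and
  `z/x/y.png` manifests for serving basemaps without connectivity.
- **Reporting** — final-outcome tables by area type or community (counts
  and half-up percentages with a TOTAL row) and visit-activity summaries
  (scheduled vs unscheduled attempts, mean recruited per community).
- **Synthetic campaigns** — a community generator and a campaign
  simulator that drives only the public engine API, with defaults
  calibrated to a published 23,830-household campaign's outcome mix.

## Worked example

```python
from datetime import date
import fieldtrack as ft

spec = ft.CampaignSpec(n_clusters=3, structures_per_cluster=200, seed=7)
structures = ft.generate_communities(spec)
logs = ft.simulate_campaign(structures, spec, start_date=date(2018, 4, 2))

summary = ft.summarize_outcomes(logs, "cluster")
print(summary.frame[["VISITED", "RECRUITED_N", "RECRUITED_PCT",
                     "NO_CONTACT_PCT", "NOT_A_HOME_PCT"]])

activity = ft.summarize_activity(logs)
print(f"\n{activity.total_visits} visits, "
      f"{activity.scheduled_pct}% scheduled, "
      f"mean {activity.mean_recruited_per_cluster} recruited/community")

needs = ft.needed_replenishment(ft.group_by_cluster(logs))
print("replenishment:", needs)
```

prints

```
         VISITED  RECRUITED_N  RECRUITED_PCT  NO_CONTACT_PCT  NOT_A_HOME_PCT
CLUSTER
C01          200           17            8.5            25.5            18.5
C02          200           17            8.5            24.5            21.5
C03          200           17            8.5            25.5            14.5
TOTAL        600           51            8.5            25.2            18.2

1136 visits, 0% scheduled, mean 17 recruited/community
replenishment: {'C01': 83, 'C02': 83, 'C03': 83}
```

Each community of 200 structures closed with about 8.5% of households
recruited and a quarter never contacted after three attempts (the default
probabilities are calibrated to a real campaign's totals; 0% scheduled
because the default mix has no undecided contacts, the only visits that
book appointments). Every cluster fell short of the 100-recruit target
and all selections are exhausted, so the planner is told to select 83
more structures per community — drawn with `random_select` excluding
visited HHIDs and folded in with `merge_new_selection`.

The same workflow is available from a shell:

```bash
fieldtrack simulate --clusters 3 --per-cluster 200 --seed 7 --out sim/
fieldtrack worklist sim/visits.csv --date 2018-04-07
fieldtrack report sim/visits.csv --by cluster --out report.csv
fieldtrack tiles --bbox 17.95 -66.80 18.01 -66.74 --zmin 12 --zmax 16 --out tiles/
```

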