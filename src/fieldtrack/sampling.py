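"""Seeded random selection of structures and mid-campaign merges.

Selection is a uniform sample without replacement drawn with a PCG64
generator via a Fisher-Yates shuffle of the HHID-sorted candidate list, so
the same seed reproduces the same selection on any platform and input
order is irrelevant. Merging folds a fresh selection into an in-progress
campaign without touching any household that already has recorded visits.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

from .config import DEFAULT_CONFIG, StudyConfig
from .errors import MergeConflictError, ValidationError
from .model import FinalOutcome, HouseholdLog, Structure
from .visit_engine import final_outcome, is_closed


def random_select(
    structures: Iterable[Structure],
    n: int,
    seed: int,
    exclude: frozenset[str] | set[str] = frozenset(),
) -> list[Structure]:
    """Uniform sample of ``min(n, eligible)`` structures without replacement.

    Candidates are the structures whose HHID is not in ``exclude``, sorted
    by HHID before shuffling so the draw depends only on (candidates, seed).
    """
    if n < 0:
        raise ValidationError(f"sample size must be >= 0, got {n}")
    eligible = sorted(
        (s for s in structures if s.hhid not in exclude),
        key=lambda s: s.hhid,
    )
    k = min(n, len(eligible))
    if k == 0:
        return []
    rng = np.random.Generator(np.random.PCG64(seed))
    order = rng.permutation(len(eligible))  # Fisher-Yates under the hood
    return [eligible[i] for i in order[:k]]


def visited_hhids(
    logs: Mapping[str, HouseholdLog] | Iterable[HouseholdLog],
) -> set[str]:
    """HHIDs with at least one recorded visit attempt, regardless of outcome."""
    if isinstance(logs, Mapping):
        logs = logs.values()
    return {log.hhid for log in logs if log.n_visits >= 1}


def merge_new_selection(
    current_logs: Mapping[str, HouseholdLog],
    new_selection: Iterable[Structure],
) -> dict[str, HouseholdLog]:
    """Add fresh (visit-0 only) logs for newly selected structures.

    Existing logs pass through unchanged. A new structure whose HHID already
    has recorded visits is a conflict; one that merely duplicates an
    unvisited preload row is a no-op, making the merge idempotent.
    """
    new_selection = list(new_selection)
    visited = visited_hhids(current_logs)
    collisions = [s.hhid for s in new_selection if s.hhid in visited]
    if collisions:
        raise MergeConflictError(collisions)

    next_ref = 1 + max(
        (log.records[0].ref for log in current_logs.values()), default=-1
    )
    merged = dict(current_logs)
    for structure in new_selection:
        if structure.hhid in merged:
            continue  # already preloaded, never visited: keep as-is
        merged[structure.hhid] = HouseholdLog.from_structure(
            structure, ref=next_ref
        )
        next_ref += 1
    return merged


def needed_replenishment(
    logs_by_cluster: Mapping[str, Mapping[str, HouseholdLog]],
    config: StudyConfig = DEFAULT_CONFIG,
) -> dict[str, int]:
    """Per-cluster shortfall once all current selections are exhausted.

    A cluster needs ``target - recruited`` additional structures only when
    every currently selected household is closed; while any remains open
    the answer is 0 (recruitment may still succeed there).
    """
    needs = {}
    for cluster, logs in logs_by_cluster.items():
        all_closed = all(is_closed(log, config) for log in logs.values())
        if not all_closed:
            needs[cluster] = 0
            continue
        recruited = sum(
            1 for log in logs.values()
            if final_outcome(log, config) is FinalOutcome.RECRUITED
        )
        needs[cluster] = max(0, config.target_per_community - recruited)
    return needs


def group_by_cluster(
    logs: Mapping[str, HouseholdLog],
) -> dict[str, dict[str, HouseholdLog]]:
    """Partition a log collection by community code."""
    grouped: dict[str, dict[str, HouseholdLog]] = {}
    for hhid, log in logs.items():
        grouped.setdefault(log.cluster, {})[hhid] = log
    return grouped
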