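"""0/1 knapsack selection of the coordinated functional components group.

Each functional-space component becomes an item whose weight is its count
of median-retained targets and whose value is the summed degree of those
targets in the PPI-converged network.  The capacity is a fixed fraction
(default 90%, rounded up) of the retained-target count.  The dynamic
program maximizes total value; among value-optimal solutions it prefers
the fewest items, then the lexicographically smallest id set, so the
selection is fully deterministic.

Weights are per-item target counts, so a target shared by two selected
components is counted twice against the capacity — exactly as the additive
recurrence defines it.  The distinct-target union of the selection is
reported alongside as a coverage diagnostic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

from .network import ConvergedNetwork

__all__ = [
    "KnapsackItem",
    "KnapsackSolution",
    "capacity_from_fraction",
    "build_items",
    "solve_knapsack",
    "brute_force_knapsack",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class KnapsackItem:
    component_id: str
    weight: int  # count of the component's retained targets
    value: float  # summed degree of those targets in the converged network

    def __post_init__(self) -> None:
        if self.weight < 0 or self.value < 0:
            raise ValueError(f"{self.component_id}: negative weight or value")
        if self.weight == 0 and self.value != 0:
            raise ValueError(f"{self.component_id}: zero-weight item must have zero value")


@dataclass
class KnapsackSolution:
    selected_ids: tuple[str, ...]  # sorted
    total_value: float
    total_weight: int
    capacity: int
    covered_targets: frozenset[str] = frozenset()

    @property
    def n_selected(self) -> int:
        return len(self.selected_ids)

    @property
    def n_covered(self) -> int:
        return len(self.covered_targets)


def capacity_from_fraction(n_retained: int, fraction: float = 0.90) -> int:
    """Smallest integer ≥ fraction × n_retained (e.g. 90% of 473 → 426)."""
    if n_retained < 1:
        raise ValueError("n_retained must be >= 1")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    # tiny slack guards against float noise pushing an exact product up a unit
    return math.ceil(fraction * n_retained - 1e-9)


def build_items(
    space_ids: list[str],
    retained: set[str],
    conv: ConvergedNetwork,
) -> list[KnapsackItem]:
    """One item per functional-space component over the retained targets.

    weight = number of the component's targets inside ``retained``;
    value = sum of those targets' degrees in the converged network.
    Components touching no retained target are excluded (logged).
    """
    unknown = sorted(t for t in retained if t not in conv.graph)
    if unknown:
        raise ValueError(f"retained target(s) not in network: {', '.join(unknown)}")
    items: list[KnapsackItem] = []
    for cid in space_ids:
        kept = [t for t in conv.targets_of(cid) if t in retained]
        if not kept:
            log.info("build_items: %s has no retained targets; excluded", cid)
            continue
        items.append(
            KnapsackItem(component_id=cid, weight=len(kept),
                         value=float(sum(conv.degree(t) for t in kept)))
        )
    return items


def _objective(value: float, ids: tuple[str, ...]) -> tuple:
    # maximize value, then fewest items, then lexicographically smallest set
    return (-value, len(ids), ids)


def solve_knapsack(items: list[KnapsackItem], capacity: int) -> KnapsackSolution:
    """Exact 0/1 knapsack with the deterministic lexicographic objective.

    Classic table over total weight 0..capacity; each cell keeps the best
    (value, −count, id set) reachable at exactly that budget or less.
    """
    if capacity < 0:
        raise ValueError("capacity must be >= 0")
    items = sorted(items, key=lambda it: it.component_id)
    # cell: (value, ids tuple sorted) — best solution with weight <= w
    best: list[tuple[float, tuple[str, ...]]] = [(0.0, ())] * (capacity + 1)
    for it in items:
        if it.weight > capacity:
            continue
        for w in range(capacity, it.weight - 1, -1):
            base_v, base_ids = best[w - it.weight]
            cand = (base_v + it.value, tuple(sorted(base_ids + (it.component_id,))))
            if _objective(*cand) < _objective(*best[w]):
                best[w] = cand
    value, ids = min(best, key=lambda cell: _objective(*cell))
    weight = _total_weight(items, ids)
    return KnapsackSolution(
        selected_ids=ids, total_value=value, total_weight=weight, capacity=capacity
    )


def brute_force_knapsack(items: list[KnapsackItem], capacity: int) -> KnapsackSolution:
    """Exhaustive-enumeration oracle with the same objective (≤ 20 items)."""
    if len(items) > 20:
        raise ValueError("brute force limited to 20 items")
    if capacity < 0:
        raise ValueError("capacity must be >= 0")
    best_ids: tuple[str, ...] = ()
    best_value = 0.0
    for k in range(len(items) + 1):
        for subset in combinations(sorted(items, key=lambda it: it.component_id), k):
            if sum(it.weight for it in subset) > capacity:
                continue
            ids = tuple(sorted(it.component_id for it in subset))
            value = sum(it.value for it in subset)
            if _objective(value, ids) < _objective(best_value, best_ids):
                best_ids, best_value = ids, value
    return KnapsackSolution(
        selected_ids=best_ids, total_value=best_value,
        total_weight=_total_weight(items, best_ids), capacity=capacity,
    )


def _total_weight(items: list[KnapsackItem], ids: tuple[str, ...]) -> int:
    by_id = {it.component_id: it for it in items}
    return sum(by_id[i].weight for i in ids)


def attach_coverage(
    solution: KnapsackSolution, conv: ConvergedNetwork, retained: set[str]
) -> KnapsackSolution:
    """Fill in the distinct retained targets covered by the selection."""
    covered: set[str] = set()
    for cid in solution.selected_ids:
        covered.update(t for t in conv.targets_of(cid) if t in retained)
    solution.covered_targets = frozenset(covered)
    return solution
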