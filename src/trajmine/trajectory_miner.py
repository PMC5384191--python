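"""Frequent-itemset trajectory mining over patient event sequences.

Concept sets that co-occur in many patients are found by Eclat-style
depth-first search over transaction-id sets (one transaction per patient:
the distinct concepts of their first-appearance sequence). Each frequent set
is then ordered by first appearance and counted hierarchically: the count at
prefix length k is the number of patients whose first-appearance order of
the itemset's concepts begins with that k-prefix, so patients realizing only
a prefix still contribute to it — this is what makes edge probabilities
below 1 possible. Orderings whose every node count clears the support
threshold are condensed into trajectories with per-edge progression
probabilities counts[i+1]/counts[i] and median transit times.

Branching trajectories are not normalized against one another: a patient can
follow several trajectories at once, so edge probabilities across siblings
deliberately do not sum to one.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .event_model import EventStream, FirstAppearanceSequence, all_first_appearances

__all__ = [
    "Trajectory",
    "mine_frequent_sets",
    "order_and_count",
    "condense",
    "median_transit_time",
    "mine_trajectories",
    "save_trajectories",
    "load_trajectories",
]


@dataclass
class Trajectory:
    """An ordered concept sequence with hierarchical patient counts.

    ``counts[i]`` patients realize the prefix ``nodes[:i+1]``; counts are
    non-increasing and ``probs[i] = counts[i+1] / counts[i]`` is the
    probability of progressing along edge i. ``median_days`` holds per-edge
    median elapsed days between first appearances (None where no patient
    realizes the longer prefix) and ``total_median_days`` the median
    first-to-last span among patients completing the full trajectory.
    """

    nodes: tuple[str, ...]
    counts: tuple[int, ...]
    probs: tuple[float, ...] = ()
    median_days: tuple[float | None, ...] = ()
    total_median_days: float | None = None
    n_patients_complete: int = 0

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.nodes):
            raise ValueError("one count per node required")
        if any(b > a for a, b in zip(self.counts, self.counts[1:])):
            raise ValueError("counts must be non-increasing")
        if not self.probs:
            self.probs = tuple(
                b / a for a, b in zip(self.counts, self.counts[1:])
            )
        if not self.n_patients_complete:
            self.n_patients_complete = self.counts[-1]

    def __len__(self) -> int:
        return len(self.nodes)


# ---------------------------------------------------------------------------
# Frequent itemset mining (Eclat)


def mine_frequent_sets(
    transactions: dict[str, frozenset[str]] | list[frozenset[str]],
    min_support: float = 0.05,
    min_size: int = 2,
) -> list[tuple[frozenset[str], int]]:
    """All itemsets of >= ``min_size`` items supported by >= ceil(min_support*N)
    transactions, via depth-first tidset intersection (Eclat).

    Returns (itemset, support count) pairs, deterministically ordered by
    (-support, sorted items).
    """
    if isinstance(transactions, dict):
        tx = [transactions[k] for k in sorted(transactions)]
    else:
        tx = list(transactions)
    if not tx:
        raise ValueError("no transactions")
    if not (0 < min_support <= 1):
        raise ValueError("min_support must be in (0, 1]")
    n = len(tx)
    min_count = max(1, int(np.ceil(min_support * n)))
    tidsets: dict[str, frozenset[int]] = {}
    for tid, items in enumerate(tx):
        for it in items:
            tidsets.setdefault(it, set()).add(tid)  # type: ignore[arg-type]
    items = sorted(it for it, tids in tidsets.items() if len(tids) >= min_count)
    out: list[tuple[frozenset[str], int]] = []

    def recurse(prefix: tuple[str, ...], tids, candidates: list[str]) -> None:
        for i, it in enumerate(candidates):
            new_tids = tids & tidsets[it] if tids is not None else tidsets[it]
            if len(new_tids) < min_count:
                continue
            new_prefix = prefix + (it,)
            if len(new_prefix) >= min_size:
                out.append((frozenset(new_prefix), len(new_tids)))
            recurse(new_prefix, new_tids, candidates[i + 1:])

    recurse((), None, items)
    out.sort(key=lambda t: (-t[1], sorted(t[0])))
    return out


def brute_force_frequent_sets(
    transactions: list[frozenset[str]], min_support: float, min_size: int = 2
) -> list[tuple[frozenset[str], int]]:
    """Exhaustive enumeration over the power set; oracle for small inputs."""
    n = len(transactions)
    min_count = max(1, int(np.ceil(min_support * n)))
    universe = sorted(set().union(*transactions)) if transactions else []
    out = []
    for k in range(min_size, len(universe) + 1):
        for combo in itertools.combinations(universe, k):
            s = frozenset(combo)
            supp = sum(1 for t in transactions if s <= t)
            if supp >= min_count:
                out.append((s, supp))
    out.sort(key=lambda t: (-t[1], sorted(t[0])))
    return out


# ---------------------------------------------------------------------------
# Ordering and hierarchical counting


def order_and_count(
    itemset: frozenset[str],
    sequences: dict[str, FirstAppearanceSequence],
) -> list[tuple[tuple[str, ...], list[int]]]:
    """Hierarchical patient counts along every realized ordering of an itemset.

    A patient's restriction is their first-appearance sequence filtered to
    the itemset's concepts. Every full ordering realized by at least one
    patient is a candidate; its count at prefix length k is the number of
    patients whose restriction begins with that k-prefix (patients holding
    only a subset of the items count toward the prefixes they realize).
    """
    if not itemset:
        raise ValueError("empty itemset")
    restrictions = []
    for seq in sequences.values():
        r = tuple(c for c in seq.sequence if c in itemset)
        if r:
            restrictions.append(r)
    full = sorted({r for r in restrictions if len(r) == len(itemset)})
    out = []
    for ordering in full:
        counts = []
        for k in range(1, len(ordering) + 1):
            prefix = ordering[:k]
            counts.append(sum(1 for r in restrictions if r[:k] == prefix))
        out.append((ordering, counts))
    return out


def condense(
    candidates: list[tuple[tuple[str, ...], list[int]]],
    min_patients: int = 20,
) -> list[Trajectory]:
    """Keep orderings whose every node count is strictly above ``min_patients``;
    merge orderings that are prefixes of retained longer ones."""
    kept = [
        (nodes, counts)
        for nodes, counts in candidates
        if all(c > min_patients for c in counts)
    ]
    # drop any ordering that is a strict prefix of another retained ordering
    retained = []
    for nodes, counts in kept:
        if any(
            len(other) > len(nodes) and other[: len(nodes)] == nodes
            for other, _ in kept
        ):
            continue
        retained.append(Trajectory(nodes=nodes, counts=tuple(counts)))
    retained.sort(key=lambda t: (-t.counts[0], t.nodes))
    return retained


def median_transit_time(
    trajectory: Trajectory,
    sequences: dict[str, FirstAppearanceSequence],
) -> Trajectory:
    """Attach per-edge and total median elapsed days to a trajectory.

    A patient traverses edge i if their restriction to the trajectory's
    nodes begins with the (i+2)-prefix; completing patients realize the full
    ordering. Even counts take the midpoint of the two central values.
    """
    nodes = trajectory.nodes
    node_set = set(nodes)
    per_edge: list[list[float]] = [[] for _ in range(len(nodes) - 1)]
    totals: list[float] = []
    for seq in sequences.values():
        r = [c for c in seq.sequence if c in node_set]
        k = 0
        while k < len(r) and k < len(nodes) and r[k] == nodes[k]:
            k += 1
        for i in range(min(k - 1, len(nodes) - 1)):
            d0, d1 = seq.date_of(nodes[i]), seq.date_of(nodes[i + 1])
            per_edge[i].append((d1 - d0).days)
        if k == len(nodes):
            totals.append((seq.date_of(nodes[-1]) - seq.date_of(nodes[0])).days)
    trajectory.median_days = tuple(
        float(np.median(v)) if v else None for v in per_edge
    )
    trajectory.total_median_days = float(np.median(totals)) if totals else None
    return trajectory


# ---------------------------------------------------------------------------
# End-to-end mining


def mine_trajectories(
    stream: EventStream,
    min_support: float = 0.05,
    min_size: int = 2,
    min_patients: int = 20,
    include_history: bool = False,
) -> list[Trajectory]:
    """Full pipeline: transactions -> frequent sets -> ordered counts ->
    condensed trajectories with transit times."""
    sequences = all_first_appearances(stream, include_history=include_history)
    transactions = {p: frozenset(s.sequence) for p, s in sequences.items()}
    frequent = mine_frequent_sets(transactions, min_support, min_size)
    candidates: list[tuple[tuple[str, ...], list[int]]] = []
    for itemset, _ in frequent:
        candidates.extend(order_and_count(itemset, sequences))
    trajectories = condense(candidates, min_patients)
    for t in trajectories:
        median_transit_time(t, sequences)
    return trajectories


def save_trajectories(trajectories: list[Trajectory], path) -> None:
    data = [
        {
            "nodes": list(t.nodes),
            "counts": list(t.counts),
            "probs": list(t.probs),
            "median_days": list(t.median_days),
            "total_median_days": t.total_median_days,
            "n_patients_complete": t.n_patients_complete,
        }
        for t in trajectories
    ]
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def load_trajectories(path) -> list[Trajectory]:
    with open(path) as fh:
        data = json.load(fh)
    return [
        Trajectory(
            nodes=tuple(d["nodes"]),
            counts=tuple(d["counts"]),
            probs=tuple(d["probs"]),
            median_days=tuple(d.get("median_days") or ()),
            total_median_days=d.get("total_median_days"),
            n_patients_complete=d.get("n_patients_complete", 0),
        )
        for d in data
    ]
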