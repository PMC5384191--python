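"""Back-door confounder adjustment of event-pair risks.

An observed risk P(y|x) — the fraction of patients with event x who later
experience y — can be inflated by confounders: events z associated with both
x and y. The mined trajectories themselves nominate the candidate
confounders: every retained trajectory that passes through x and then y
contributes the set of events strictly between them as one path, and the
union of those intermediate events forms the confounder pool Z for the pair.

The adjusted risk is the back-door (do-operator) estimate

    P(y | do(x)) = sum_z  P(y | x, stratum z) * P(stratum z)

where patients are partitioned into strata by the subset of Z they
experience, P(y|x, z) is estimated among x-patients of that stratum (y
counted only after x) and the stratum weight P(z) is its cohort-wide
prevalence. With a single stratum the sum collapses to the raw risk —
the pair is then unconfounded by construction — and for a pure confounder
(z causes both x and y, no direct effect) the adjusted risk returns to the
background rate of y. Strata with few x-patients are pooled into one
"rare" stratum to control variance.

``k`` reports the number of distinct non-empty intermediate-event paths
nominated by the trajectories for the pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .event_model import EventStream, all_first_appearances
from .trajectory_miner import Trajectory

__all__ = [
    "Stratum",
    "AdjustedRisk",
    "enumerate_paths",
    "adjusted_risk",
    "confounded_flag",
    "compare_trajectory_sets",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Stratum:
    z_set: frozenset[str]
    p_y_given_xz: float
    weight: float
    n_x_patients: int
    pooled: bool = False


@dataclass(frozen=True)
class AdjustedRisk:
    x: str
    y: str
    k: int
    raw: float
    adjusted: float
    strata: tuple[Stratum, ...]


def enumerate_paths(
    x: str, y: str, trajectories: list[Trajectory]
) -> list[tuple[frozenset[str], int]]:
    """Confounder-event sets on trajectories carrying a patient from x to y.

    Each trajectory containing x before y contributes the set of its other
    events preceding y — the trajectory events that can act as common causes
    of the pair, whether they appear before x or between x and y. Identical
    sets are merged (orderings collapse — confounding is about joint
    presence) with summed completing-patient counts. The empty set (a direct
    x -> y edge) is a valid path.
    """
    if x == y:
        raise ValueError("x and y must differ")
    paths: dict[frozenset[str], int] = {}
    for t in trajectories:
        if x not in t.nodes or y not in t.nodes:
            continue
        ix, iy = t.nodes.index(x), t.nodes.index(y)
        if ix >= iy:
            continue
        z = frozenset(t.nodes[:iy]) - {x}
        paths[z] = paths.get(z, 0) + t.n_patients_complete
    return sorted(paths.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))


def adjusted_risk(
    x: str,
    y: str,
    trajectories: list[Trajectory],
    stream: EventStream,
    min_stratum: int = 5,
) -> AdjustedRisk:
    """Raw P(y|x) and back-door-adjusted P(y|do(x)) for an event pair."""
    paths = enumerate_paths(x, y, trajectories)
    z_pool = sorted(set().union(*(z for z, _ in paths)) - {x, y}) if paths else []
    k = sum(1 for z, _ in paths if z)

    sequences = all_first_appearances(stream)
    x_pat: dict[str, tuple[frozenset[str], bool]] = {}
    strata_members: dict[frozenset[str], list[str]] = {}
    cohort_pattern: dict[str, frozenset[str]] = {}
    n_cohort = 0
    for pid, seq in sequences.items():
        n_cohort += 1
        concepts = set(seq.sequence)
        pattern = frozenset(c for c in z_pool if c in concepts)
        cohort_pattern[pid] = pattern
        if x in concepts:
            # y counts only when it first appears after x
            pos = {c: i for i, c in enumerate(seq.sequence)}
            success = y in concepts and pos[y] > pos[x]
            x_pat[pid] = (pattern, success)
            strata_members.setdefault(pattern, []).append(pid)
    if not x_pat:
        raise ValueError(f"no patient experiences {x!r}")
    raw = sum(1 for _, s in x_pat.values() if s) / len(x_pat)

    # pool x-sparse strata to control variance
    big = {p for p, mem in strata_members.items() if len(mem) >= min_stratum}
    pooled = [p for p in strata_members if p not in big]
    if pooled and len(strata_members) > 1:
        logger.debug("pooling %d sparse strata for pair (%s, %s)", len(pooled), x, y)

    prevalence: dict[frozenset[str], int] = {}
    for pat in cohort_pattern.values():
        prevalence[pat] = prevalence.get(pat, 0) + 1

    strata: list[Stratum] = []
    entries: list[tuple[frozenset[str], list[str], bool]] = [
        (p, strata_members[p], False) for p in sorted(big, key=lambda s: (len(s), sorted(s)))
    ]
    if pooled:
        members = [pid for p in pooled for pid in strata_members[p]]
        if not big:
            entries.append((frozenset().union(*pooled), members, False))
        else:
            entries.append((frozenset(), members, True))
            # cohort weight of the pooled stratum = summed pattern prevalence
    pooled_set = set(pooled)
    weights = []
    for pat, members, is_pooled in entries:
        succ = sum(1 for pid in members if x_pat[pid][1])
        p_y = succ / len(members)
        if is_pooled:
            w = sum(prevalence.get(p, 0) for p in pooled_set)
        elif not big:
            w = sum(prevalence.get(p, 0) for p in prevalence)  # single stratum
        else:
            w = prevalence.get(pat, 0)
        weights.append(w)
        strata.append(Stratum(pat, p_y, 0.0, len(members), is_pooled))
    total_w = sum(weights)
    if total_w == 0:
        # degenerate: weight strata by their x-patient counts instead
        weights = [s.n_x_patients for s in strata]
        total_w = sum(weights)
    strata = [
        Stratum(s.z_set, s.p_y_given_xz, w / total_w, s.n_x_patients, s.pooled)
        for s, w in zip(strata, weights)
    ]
    adjusted = sum(s.p_y_given_xz * s.weight for s in strata)
    return AdjustedRisk(x, y, k, raw, float(adjusted), tuple(strata))


def confounded_flag(risk: AdjustedRisk, tol: float = 0.01) -> bool:
    """True iff the adjusted risk departs from the raw risk by more than tol."""
    return abs(risk.adjusted - risk.raw) > tol


def compare_trajectory_sets(
    risks_a: list[AdjustedRisk], risks_b: list[AdjustedRisk]
) -> tuple[float, float]:
    """Agreement between two trajectory sets' adjusted risks.

    Returns (R^2 of adjusted risks over shared (x, y) pairs, R^2 of the risk
    change regressed on the change in stratum composition — number of
    nominated paths k). The first should be high and the second low when the
    two sets describe the same outcomes through different extraneous
    variables.
    """
    a = {(r.x, r.y): r for r in risks_a}
    b = {(r.x, r.y): r for r in risks_b}
    shared = sorted(set(a) & set(b))
    if len(shared) < 3:
        raise ValueError("need at least 3 shared (x, y) pairs")
    adj_a = np.array([a[p].adjusted for p in shared])
    adj_b = np.array([b[p].adjusted for p in shared])
    r2 = float(stats.linregress(adj_a, adj_b).rvalue ** 2)
    dk = np.array([a[p].k - b[p].k for p in shared], dtype=float)
    dr = adj_a - adj_b
    if np.ptp(dk) == 0 or np.ptp(dr) == 0:
        r2_delta = 0.0
    else:
        r2_delta = float(stats.linregress(dk, dr).rvalue ** 2)
    return r2, r2_delta
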