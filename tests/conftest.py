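"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from trajmine import (
    Vocabulary,
    VocabEntry,
    make_cohort,
    mine_trajectories,
    worked_example_cohort,
)
from trajmine.pipeline import default_cohort_spec

COHORT_SEED = 11


# ---------------------------------------------------------------------------
# Independent oracles


def sw_oracle(query: str, term: str, match: int = 2, mismatch: int = -1,
              gap: int = -1) -> tuple[int, int]:
    """Exhaustive-over-gap-counts local alignment oracle.

    For every cell keeps a map {n_gaps: best score of an alignment ending
    here with exactly n_gaps gaps}; returns (max score, min gaps among
    max-scoring alignments). Independent of the production DP, which tracks
    a single lexicographic optimum.
    """
    nq, nt = len(query), len(term)
    best_score, best_gaps = 0, 0
    prev = [{0: 0} for _ in range(nq + 1)]
    for j in range(1, nt + 1):
        cur = [{0: 0}]
        for i in range(1, nq + 1):
            cell: dict[int, int] = {0: 0}

            def add(g: int, s: int) -> None:
                if s >= 0 and s > cell.get(g, -1):
                    cell[g] = s

            sub = match if query[i - 1] == term[j - 1] else mismatch
            for g, s in prev[i - 1].items():
                add(g, s + sub)
            for g, s in prev[i].items():
                add(g + 1, s + gap)
            for g, s in cur[i - 1].items():
                add(g + 1, s + gap)
            cur.append(cell)
            for g, s in cell.items():
                if s > best_score or (s == best_score and g < best_gaps):
                    best_score, best_gaps = s, g
        prev = cur
    if best_score == 0:
        best_gaps = 0
    return best_score, best_gaps


def brute_force_itemsets(transactions: list[frozenset[str]], min_support: float,
                         min_size: int = 2) -> set[tuple[frozenset[str], int]]:
    """Power-set enumeration of frequent itemsets; oracle for tiny inputs."""
    n = len(transactions)
    min_count = max(1, int(np.ceil(min_support * n)))
    universe = sorted(set().union(*transactions)) if transactions else []
    out = set()
    for k in range(min_size, len(universe) + 1):
        for combo in itertools.combinations(universe, k):
            s = frozenset(combo)
            supp = sum(1 for t in transactions if s <= t)
            if supp >= min_count:
                out.add((s, supp))
    return out


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture()
def toy_vocab() -> Vocabulary:
    return Vocabulary([
        VocabEntry("C001", "disease", "cancer"),
        VocabEntry("C002", "disease", "gastritis"),
        VocabEntry("C003", "drug", "chemo"),
        VocabEntry("C004", "procedure", "therapy"),
        VocabEntry("C005", "disease", "nausea"),
    ])


@pytest.fixture()
def worked() -> EventStream:
    return worked_example_cohort()


@pytest.fixture(scope="session")
def planted_cohort():
    """The reference synthetic cohort (n = 2,000) plus its planted truth."""
    spec = default_cohort_spec(2000, COHORT_SEED)
    stream, truth = make_cohort(spec)
    return stream, truth


@pytest.fixture(scope="session")
def external_holdout():
    """An independent 1,000-patient cohort from the same planted process."""
    stream, _ = make_cohort(default_cohort_spec(1000, 7000 + COHORT_SEED))
    return stream


@pytest.fixture(scope="session")
def mined_trajectories(planted_cohort):
    """Trajectories mined from the reference cohort at default thresholds."""
    stream, _ = planted_cohort
    return mine_trajectories(stream, min_support=0.05, min_size=2,
                             min_patients=20)
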