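"""Dated patient event streams and first-appearance sequences.

The atom of every downstream statistic is a :class:`ClinicalEvent` — one
patient experienced one concept on one date. Context-classified mentions are
folded into an :class:`EventStream`: ``noise`` mentions are dropped,
``current`` mentions are dated at the note date, ``history`` mentions keep
the note date but carry a ``history`` flag (they describe the past at an
unknown date and are excluded from trajectory construction by default).
Duplicate (patient, date, concept) rows collapse to one event: time
resolution is the note date.

Also houses the age-dependence screen: a two-sample Kolmogorov-Smirnov test
per concept (carriers vs non-carriers) under Bonferroni correction, used to
rule age out as a confounder before mining trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .vocab_annotator import Mention

__all__ = [
    "EVENT_GROUPS",
    "ClinicalEvent",
    "EventStream",
    "FirstAppearanceSequence",
    "mentions_to_events",
    "first_appearance",
    "ks_age_dependence",
    "read_event_stream",
    "write_event_stream",
]

EVENT_GROUPS = ("disease", "drug", "procedure", "death", "admission")

_COLS = ["patient_id", "date", "concept_id", "group", "context"]


@dataclass(frozen=True)
class ClinicalEvent:
    patient_id: str
    date: pd.Timestamp
    concept_id: str
    group: str
    context: str = "current"


@dataclass
class EventStream:
    """Sorted, deduplicated cohort event table.

    ``df`` has columns patient_id, date, concept_id, group, context, sorted
    by (patient_id, date, concept_id) with no duplicate (patient, date,
    concept) row. ``ages`` optionally maps patient -> age in years at first
    event.
    """

    df: pd.DataFrame
    ages: dict[str, float] | None = None
    _sequences: dict = field(default_factory=dict, init=False, repr=False)

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in _COLS:
            if col not in df.columns:
                raise ValueError(f"event stream missing column {col!r}")
        df["date"] = pd.to_datetime(df["date"])
        df = (
            df[_COLS]
            .drop_duplicates(subset=["patient_id", "date", "concept_id"])
            .sort_values(["patient_id", "date", "concept_id"], kind="mergesort")
            .reset_index(drop=True)
        )
        self.df = df

    @property
    def patients(self) -> list[str]:
        return sorted(self.df["patient_id"].unique())

    @property
    def n_patients(self) -> int:
        return self.df["patient_id"].nunique()

    def concepts(self) -> list[str]:
        return sorted(self.df["concept_id"].unique())

    def patients_with(self, concept_id: str) -> set[str]:
        return set(self.df.loc[self.df["concept_id"] == concept_id, "patient_id"])


@dataclass(frozen=True)
class FirstAppearanceSequence:
    """A patient's distinct concepts ordered by earliest date.

    Same-date ties are broken by concept id so the sequence is deterministic
    at note-date resolution.
    """

    patient_id: str
    sequence: tuple[str, ...]
    first_dates: tuple[pd.Timestamp, ...]

    def __len__(self) -> int:
        return len(self.sequence)

    def date_of(self, concept_id: str) -> pd.Timestamp:
        return self.first_dates[self.sequence.index(concept_id)]


def mentions_to_events(
    labeled: list[tuple[Mention, str]],
    manifest: pd.DataFrame,
    group_of: dict[str, str] | None = None,
) -> EventStream:
    """Convert (mention, context-label) pairs into an event stream.

    ``manifest`` maps doc_id -> (patient_id, date). Noise mentions are
    dropped; current and history mentions are kept with their context flag.
    """
    man = manifest.set_index("doc_id")
    missing = sorted({m.doc_id for m, _ in labeled} - set(man.index))
    if missing:
        raise KeyError(f"doc ids absent from manifest: {missing}")
    rows = []
    for m, label in labeled:
        if label == "noise":
            continue
        rec = man.loc[m.doc_id]
        group = group_of.get(m.concept_id, m.group) if group_of else m.group
        rows.append((str(rec["patient_id"]), rec["date"], m.concept_id, group, label))
    return EventStream(pd.DataFrame(rows, columns=_COLS))


def first_appearance(
    stream: EventStream, patient_id: str, include_history: bool = False
) -> FirstAppearanceSequence:
    """Distinct concepts of one patient in order of earliest occurrence."""
    sub = stream.df[stream.df["patient_id"] == patient_id]
    if sub.empty:
        raise KeyError(f"unknown patient {patient_id!r}")
    if not include_history:
        sub = sub[sub["context"] != "history"]
    firsts = (
        sub.groupby("concept_id", sort=False)["date"].min().reset_index()
        .sort_values(["date", "concept_id"], kind="mergesort")
    )
    return FirstAppearanceSequence(
        patient_id,
        tuple(firsts["concept_id"]),
        tuple(firsts["date"]),
    )


def all_first_appearances(
    stream: EventStream, include_history: bool = False
) -> dict[str, FirstAppearanceSequence]:
    """First-appearance sequences for every patient (vectorized, cached)."""
    key = ("fa", include_history)
    if key in stream._sequences:
        return stream._sequences[key]
    df = stream.df
    if not include_history:
        df = df[df["context"] != "history"]
    firsts = (
        df.groupby(["patient_id", "concept_id"], sort=False)["date"].min()
        .reset_index()
        .sort_values(["patient_id", "date", "concept_id"], kind="mergesort")
    )
    out: dict[str, FirstAppearanceSequence] = {}
    for pid, grp in firsts.groupby("patient_id", sort=False):
        out[str(pid)] = FirstAppearanceSequence(
            str(pid), tuple(grp["concept_id"]), tuple(grp["date"])
        )
    stream._sequences[key] = out
    return out


def ks_age_dependence(
    stream: EventStream,
    ages: dict[str, float] | None = None,
    alpha: float = 0.25,
) -> pd.DataFrame:
    """Two-sample KS test of age for carriers vs non-carriers, per concept.

    The per-test threshold is Bonferroni-corrected: alpha / m with m the
    number of concepts tested. A generous family level (default 25%) makes
    the correction deliberately sensitive — even small age shifts would flag
    a concept, so concepts that survive can be treated as age-independent
    when trajectories are drawn.
    """
    ages = ages if ages is not None else stream.ages
    if not ages:
        raise ValueError("no ages available")
    age_s = pd.Series(ages, dtype=float)
    concepts = stream.concepts()
    rows = []
    for c in concepts:
        carriers = stream.patients_with(c) & set(age_s.index)
        rest = set(age_s.index) - carriers
        if len(carriers) < 2 or len(rest) < 2:
            continue  # too few carriers to compare; skipped
        d, p = ks_2samp(age_s[sorted(carriers)], age_s[sorted(rest)])
        rows.append((c, float(d), float(p)))
    m = len(rows)
    thresh = alpha / m if m else np.nan
    out = pd.DataFrame(rows, columns=["concept_id", "D", "p"])
    out["threshold"] = thresh
    out["significant"] = out["p"] < thresh
    return out


def write_event_stream(stream: EventStream, path) -> None:
    df = stream.df.copy()
    df["date"] = df["date"].dt.strftime("%Y-%m-%d")
    df.to_csv(path, sep="\t", index=False)


def read_event_stream(path, ages_path=None) -> EventStream:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "concept_id": str})
    ages = None
    if ages_path is not None:
        a = pd.read_csv(ages_path, sep="\t", dtype={"patient_id": str})
        ages = dict(zip(a["patient_id"], a["age_years"].astype(float)))
    return EventStream(df, ages=ages)
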