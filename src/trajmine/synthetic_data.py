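"""Synthetic vocabularies, note corpora and patient cohorts with known truth.

Every statistical claim the package makes is exercised against data whose
generating process is planted and returned alongside the data:

* cohorts whose event sequences follow a first-order Markov chain over
  concepts, with confounder triples (z causes both x and y, optional direct
  x -> y effect) overlaid ahead of the chain and an optional terminal death
  event;
* note corpora embedding vocabulary terms among screened distractor words,
  with configurable per-character typo and word-compounding rates and
  class-specific cue words realizing current/history/noise context labels;
* the two-patient worked-example cohort (p1: a,b,c,d; p2: a,b,d) whose
  trajectory arithmetic is known in closed form.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .context_classifier import CLASSES
from .event_model import EventStream
from .vocab_annotator import (
    CutoffParams,
    VocabEntry,
    Vocabulary,
    align_local,
    decompound,
    score_cutoff,
)

__all__ = [
    "ConfounderTriple",
    "CohortSpec",
    "CorpusSpec",
    "GoldMention",
    "make_vocabulary",
    "make_cohort",
    "make_note_corpus",
    "worked_example_cohort",
]

BASE_DATE = pd.Timestamp("2010-01-01")


class SpecValidationError(ValueError):
    """A generator spec field is out of range; the message names the field."""


def _check_prob(name: str, v: float) -> None:
    if not 0.0 <= v <= 1.0:
        raise SpecValidationError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class ConfounderTriple:
    """A planted common cause: z raises both x and y.

    ``p_z`` is z's prevalence; absent z, x and y occur at their baseline
    rates. ``p_direct`` is the direct x -> y effect (zero for a pure
    confounder). Inserted events respect first-appearance order z < x < y.
    """

    z: str
    x: str
    y: str
    p_x_given_z: float
    p_y_given_z: float
    p_direct: float = 0.0
    p_z: float = 0.5
    p_x_base: float = 0.05
    p_y_base: float = 0.05

    def __post_init__(self) -> None:
        for name in ("p_x_given_z", "p_y_given_z", "p_direct", "p_z",
                     "p_x_base", "p_y_base"):
            _check_prob(f"confounder_triples.{name}", getattr(self, name))


@dataclass
class CohortSpec:
    """Planted generative parameters for a synthetic cohort.

    The Markov chain starts from ``initial_distribution`` and follows
    ``transition_matrix`` rows (which may sum to < 1; the remainder is the
    stop probability). Inter-event gaps are geometric with success
    probability ``gap_p`` (mean gap 1/gap_p days).
    """

    n_patients: int
    concepts: dict[str, str]  # concept -> group
    initial_distribution: dict[str, float]
    transition_matrix: dict[str, dict[str, float]]
    confounder_triples: list[ConfounderTriple] = field(default_factory=list)
    death_concept: str | None = None
    p_death: float = 0.0
    mean_events_per_patient: float = 8.0
    gap_p: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise SpecValidationError("n_patients must be >= 1")
        for c, p in self.initial_distribution.items():
            if c not in self.concepts:
                raise SpecValidationError(
                    f"initial_distribution concept {c!r} not in concepts"
                )
            _check_prob(f"initial_distribution[{c!r}]", p)
        tot = sum(self.initial_distribution.values())
        if tot > 1 + 1e-9:
            raise SpecValidationError("initial_distribution sums above 1")
        for c, row in self.transition_matrix.items():
            if c not in self.concepts:
                raise SpecValidationError(
                    f"transition_matrix row concept {c!r} not in concepts"
                )
            s = 0.0
            for c2, p in row.items():
                if c2 not in self.concepts:
                    raise SpecValidationError(
                        f"transition_matrix[{c!r}] target {c2!r} not in concepts"
                    )
                _check_prob(f"transition_matrix[{c!r}][{c2!r}]", p)
                s += p
            if s > 1 + 1e-9:
                raise SpecValidationError(f"transition_matrix[{c!r}] row sums above 1")
        for t in self.confounder_triples:
            for c in (t.z, t.x, t.y):
                if c not in self.concepts:
                    raise SpecValidationError(
                        f"confounder_triples concept {c!r} not in concepts"
                    )
        if self.death_concept is not None and self.death_concept not in self.concepts:
            raise SpecValidationError("death_concept not in concepts")
        _check_prob("p_death", self.p_death)
        if not 0.0 < self.gap_p <= 1.0:
            raise SpecValidationError("gap_p must be in (0, 1]")


def make_cohort(spec: CohortSpec) -> tuple[EventStream, dict]:
    """Draw a cohort from the spec; return the stream and the planted truth."""
    rng = np.random.default_rng(spec.seed)
    init_concepts = sorted(spec.initial_distribution)
    init_p = np.array([spec.initial_distribution[c] for c in init_concepts])
    p_stop0 = 1.0 - init_p.sum()
    max_chain = max(1, int(np.ceil(3 * spec.mean_events_per_patient)))
    rows = []
    for i in range(spec.n_patients):
        pid = f"p{i:05d}"
        day = 0
        seq: list[str] = []
        for t in spec.confounder_triples:
            has_z = rng.random() < t.p_z
            has_x = rng.random() < (t.p_x_given_z if has_z else t.p_x_base)
            has_y = rng.random() < (t.p_y_given_z if has_z else t.p_y_base)
            if has_x and not has_y:
                has_y = rng.random() < t.p_direct
            for concept, present in ((t.z, has_z), (t.x, has_x), (t.y, has_y)):
                if present:
                    seq.append(concept)
        # Markov chain
        u = rng.random()
        state = None
        if u >= p_stop0:
            state = init_concepts[
                int(np.searchsorted(np.cumsum(init_p), u - p_stop0, side="right"))
            ]
        steps = 0
        while state is not None and steps < max_chain:
            seq.append(state)
            steps += 1
            row = spec.transition_matrix.get(state, {})
            targets = sorted(row)
            probs = np.array([row[c] for c in targets]) if targets else np.empty(0)
            u = rng.random()
            cum = np.cumsum(probs)
            nxt = int(np.searchsorted(cum, u, side="right"))
            state = targets[nxt] if nxt < len(targets) else None
        if spec.death_concept is not None and rng.random() < spec.p_death:
            seq.append(spec.death_concept)
        for concept in seq:
            rows.append(
                (pid, BASE_DATE + pd.Timedelta(days=day), concept,
                 spec.concepts[concept], "current")
            )
            day += int(rng.geometric(spec.gap_p))
    stream = EventStream(
        pd.DataFrame(rows, columns=["patient_id", "date", "concept_id",
                                    "group", "context"])
    )
    truth = {
        "initial_distribution": dict(spec.initial_distribution),
        "transition_matrix": {
            c: dict(row) for c, row in spec.transition_matrix.items()
        },
        "confounder_triples": list(spec.confounder_triples),
        "death_concept": spec.death_concept,
        "p_death": spec.p_death,
        "seed": spec.seed,
    }
    return stream, truth


def worked_example_cohort() -> EventStream:
    """The closed-form two-patient cohort: p1 gets a,b,c,d; p2 gets a,b,d.

    On this stream the ordering a -> b -> d has hierarchical counts
    [2, 2, 2] (edge probabilities 1), a -> b -> c has [2, 2, 1]
    (P(c | a,b) = 0.5), the background probability of c is 0.5 and of
    a, b, d is 1.
    """
    rows = []
    for pid, seq in (("p1", "abcd"), ("p2", "abd")):
        for day, concept in enumerate(seq):
            rows.append(
                (pid, BASE_DATE + pd.Timedelta(days=day), concept,
                 "disease", "current")
            )
    return EventStream(
        pd.DataFrame(rows, columns=["patient_id", "date", "concept_id",
                                    "group", "context"])
    )


# ---------------------------------------------------------------------------
# Vocabulary and note corpus generation

_SYLLABLES = [c + v for c in "bdfgklmnprstv" for v in "aeiou"]

# cue words realizing the three context classes in generated notes; two per
# class so selecting both makes every mention carry a selected cue
CUE_WORDS = {
    "current": ["today", "acute"],
    "history": ["previously", "formerly"],
    "noise": ["denies", "excluded"],
}

_DISTRACTOR_POOL = [
    "ward", "chart", "visit", "spoke", "family", "morning", "review",
    "stable", "plan", "clinic", "follow", "signed", "doctor", "nurse",
    "report", "weight", "normal", "slight", "general", "routine",
]

_N_DISTRACTORS = 80  # large pool keeps any one distractor's df (and tf-idf rank) low


def make_vocabulary(
    n_terms: int = 12, seed: int = 0, min_len: int = 5
) -> Vocabulary:
    """A pronounceable synthetic concept dictionary (terms >= ``min_len`` chars),
    groups cycling through disease/drug/procedure."""
    rng = np.random.default_rng(seed)
    groups = ("disease", "drug", "procedure")
    entries = []
    seen: set[str] = set()
    while len(entries) < n_terms:
        n_syl = int(rng.integers(3, 5))
        term = "".join(rng.choice(_SYLLABLES) for _ in range(n_syl))
        if len(term) < min_len or term in seen:
            continue
        seen.add(term)
        i = len(entries)
        entries.append(VocabEntry(f"C{i:03d}", groups[i % 3], term, (f"C{i:03d}",)))
    return Vocabulary(entries)


@dataclass(frozen=True)
class GoldMention:
    doc_id: str
    start: int
    end: int
    surface: str
    concept_id: str
    label: str
    compound: bool


@dataclass
class CorpusSpec:
    """Parameters of a synthetic annotated note corpus."""

    n_docs: int
    vocab: Vocabulary
    typo_rate: float = 0.0
    compound_rate: float = 0.0
    context_mix: tuple[float, float, float] = (1.0, 0.0, 0.0)
    mentions_per_doc: tuple[int, int] = (1, 3)
    params: CutoffParams = field(default_factory=CutoffParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_docs < 1:
            raise SpecValidationError("n_docs must be >= 1")
        if not self.vocab.entries:
            raise SpecValidationError("vocab must be non-empty")
        _check_prob("typo_rate", self.typo_rate)
        _check_prob("compound_rate", self.compound_rate)
        if abs(sum(self.context_mix) - 1.0) > 1e-9:
            raise SpecValidationError("context_mix must sum to 1")


def _screen_word(word: str, vocab: Vocabulary, params: CutoffParams) -> bool:
    """True if the word cannot be mistaken for vocabulary content."""
    if vocab.lookup(word) or decompound(word, vocab, params):
        return False
    for term in vocab.terms:
        if abs(len(term) - len(word)) > max(len(word), len(term)) // 2 + 2:
            continue
        aln = align_local(word, term)
        if (aln.n_gaps <= params.max_gaps
                and aln.score >= score_cutoff(len(word), len(term), params)):
            return False
    return True


def make_note_corpus(
    spec: CorpusSpec,
) -> tuple[dict[str, str], pd.DataFrame, list[GoldMention]]:
    """Generate documents, a (doc_id, patient_id, date) manifest and gold
    standoff mentions with context labels.

    Each mention is a vocabulary term surrounded by cue words of its context
    class and screened distractor words. With probability ``typo_rate`` per
    character the term suffers a substitution; with probability
    ``compound_rate`` it is fused with the following distractor into one
    compound token (gold span covers the term part only).
    """
    rng = np.random.default_rng(spec.seed)
    distractors = [
        w for w in _DISTRACTOR_POOL if _screen_word(w, spec.vocab, spec.params)
    ]
    pool_rng = np.random.default_rng(spec.seed + 1)
    while len(distractors) < _N_DISTRACTORS:
        w = "".join(pool_rng.choice(_SYLLABLES)
                    for _ in range(int(pool_rng.integers(2, 4))))
        if w not in distractors and _screen_word(w, spec.vocab, spec.params):
            distractors.append(w)
    cues = {
        lab: [w for w in ws if _screen_word(w, spec.vocab, spec.params)]
        for lab, ws in CUE_WORDS.items()
    }
    if not distractors or any(not v for v in cues.values()):
        raise SpecValidationError(
            "vocab collides with every distractor or cue word pool"
        )
    entries = spec.vocab.entries
    compoundable = [e for e in entries if len(e.term) >= spec.params.min_split]
    if spec.compound_rate > 0 and not compoundable:
        raise SpecValidationError(
            "compound_rate > 0 requires vocab terms of at least min_split chars"
        )
    letters = string.ascii_lowercase
    docs: dict[str, str] = {}
    gold: list[GoldMention] = []
    manifest_rows = []
    lo, hi = spec.mentions_per_doc
    for d in range(spec.n_docs):
        doc_id = f"d{d:05d}"
        pid = f"p{d % max(1, spec.n_docs // 3):05d}"
        date = BASE_DATE + pd.Timedelta(days=d)
        manifest_rows.append((doc_id, pid, date.strftime("%Y-%m-%d")))
        parts: list[str] = []
        pos = 0

        def emit(word: str) -> int:
            nonlocal pos
            if parts:
                parts.append(" ")
                pos += 1
            start = pos
            parts.append(word)
            pos += len(word)
            return start

        n_mentions = int(rng.integers(lo, hi + 1))
        for _ in range(n_mentions):
            for _ in range(int(rng.integers(1, 3))):
                emit(str(rng.choice(distractors)))
            label = CLASSES[
                int(rng.choice(len(CLASSES), p=np.asarray(spec.context_mix)))
            ]
            emit(str(rng.choice(cues[label])))
            compound = rng.random() < spec.compound_rate
            entry = (
                compoundable[int(rng.integers(len(compoundable)))]
                if compound
                else entries[int(rng.integers(len(entries)))]
            )
            surface = "".join(
                (rng.choice([c2 for c2 in letters if c2 != ch])
                 if rng.random() < spec.typo_rate else ch)
                for ch in entry.term
            )
            token = surface + str(rng.choice(distractors)) if compound else surface
            start = emit(token)
            gold.append(
                GoldMention(doc_id, start, start + len(surface), surface,
                            entry.concept_id, label, compound)
            )
            emit(str(rng.choice(cues[label])))
        emit(str(rng.choice(distractors)) + ".")
        docs[doc_id] = "".join(parts)
    manifest = pd.DataFrame(manifest_rows, columns=["doc_id", "patient_id", "date"])
    return docs, manifest, gold
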