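"""Dictionary-based concept annotation of free clinical text.

Maps vocabulary terms and synonyms onto note text. Clinical prose is full of
unstructured spelling variation and (in Scandinavian languages) agglutinated
compound words, so three matching routes are combined:

* exact lower-cased term lookup per token;
* gap-limited Smith-Waterman local alignment against candidate terms, accepted
  when the score clears a log-linear cutoff in the two string lengths;
* greedy longest-match decompounding of tokens into consecutive vocabulary
  terms, each split at least ``min_split`` characters long.

Character offsets are 0-based, half-open, into the original document text.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "VocabEntry",
    "Vocabulary",
    "AlignmentResult",
    "Mention",
    "CutoffParams",
    "VocabularyFormatError",
    "load_vocabulary",
    "decompound",
    "align_local",
    "score_cutoff",
    "annotate_text",
]

VALID_GROUPS = ("disease", "drug", "procedure")

_WORD_RE = re.compile(r"\w+", re.UNICODE)


class VocabularyFormatError(ValueError):
    """Raised when a vocabulary table violates the expected schema."""


@dataclass(frozen=True)
class VocabEntry:
    concept_id: str
    group: str
    term: str
    hierarchy_path: tuple[str, ...] = ()


@dataclass
class Vocabulary:
    """A concept dictionary: terms/synonyms with group and hierarchy.

    ``entries`` may map several terms to one concept (synonyms) and, in
    principle, one term to several concepts; lookups resolve ties by lowest
    concept id for determinism.
    """

    entries: list[VocabEntry]
    _by_term: dict[str, list[VocabEntry]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        dups = []
        for e in self.entries:
            if not e.term:
                raise VocabularyFormatError("empty term in vocabulary")
            if e.group not in VALID_GROUPS:
                raise VocabularyFormatError(
                    f"unknown group {e.group!r} for concept {e.concept_id!r}"
                )
            key = (e.concept_id, e.term)
            if key in seen:
                dups.append(key)
            seen.add(key)
        if dups:
            raise VocabularyFormatError(f"duplicate (concept_id, term) rows: {dups}")
        by_term: dict[str, list[VocabEntry]] = {}
        for e in self.entries:
            by_term.setdefault(e.term, []).append(e)
        for lst in by_term.values():
            lst.sort(key=lambda e: str(e.concept_id))
        object.__setattr__(self, "_by_term", by_term)

    @property
    def terms(self) -> list[str]:
        return sorted(self._by_term)

    def lookup(self, term: str) -> list[VocabEntry]:
        return self._by_term.get(term, [])


@dataclass(frozen=True)
class AlignmentResult:
    """Best local alignment between a corpus word and a vocabulary term.

    ``score == match * n_matches + mismatch_pen * n_mismatches + gap_pen *
    n_gaps`` with the default 2/-1/-1 weights. Spans are 0-based half-open
    character intervals into query and target.
    """

    score: int
    n_matches: int
    n_mismatches: int
    n_gaps: int
    query_span: tuple[int, int]
    target_span: tuple[int, int]


@dataclass(frozen=True)
class Mention:
    doc_id: str
    char_span: tuple[int, int]
    surface: str
    concept_id: str
    group: str
    alignment: AlignmentResult
    via_decompound: bool = False


@dataclass
class CutoffParams:
    """Acceptance threshold for fuzzy matches.

    The cutoff on the alignment score is ``a*log(query_len) + b*log(term_len)
    + c`` — a log-linear plane in the two lengths, so longer words need
    proportionally better alignments. The defaults let an exact match of a
    5-character term pass (score 10 vs threshold 4*ln 5 ~ 6.4) while rejecting
    heavily eroded long matches.
    """

    a: float = 2.0
    b: float = 2.0
    c: float = 0.0
    min_split: int = 5
    max_gaps: int = 2

    def __post_init__(self) -> None:
        if self.min_split < 1:
            raise ValueError("min_split must be >= 1")
        if self.max_gaps < 0:
            raise ValueError("max_gaps must be >= 0")


def load_vocabulary(path) -> Vocabulary:
    """Read a vocabulary TSV with columns concept_id, group, term, hierarchy_path.

    Terms are lower-cased and whitespace-normalized. ``hierarchy_path`` is a
    ``/``-joined id path and may be empty.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["concept_id", "group", "term"]
    for col in required:
        if col not in df.columns:
            raise VocabularyFormatError(f"missing column {col!r} in {path}")
    entries = []
    for i, row in enumerate(df.itertuples(index=False)):
        group = row.group.strip()
        if group not in VALID_GROUPS:
            raise VocabularyFormatError(
                f"row {i}: unknown group {group!r} (expected one of {VALID_GROUPS})"
            )
        term = " ".join(row.term.split()).lower()
        path_str = getattr(row, "hierarchy_path", "") or ""
        hpath = tuple(p for p in path_str.split("/") if p)
        entries.append(VocabEntry(row.concept_id.strip(), group, term, hpath))
    return Vocabulary(entries)


# ---------------------------------------------------------------------------
# Local alignment


def align_local(
    query: str,
    term: str,
    match: int = 2,
    mismatch: int = -1,
    gap: int = -1,
) -> AlignmentResult:
    """Smith-Waterman local alignment with traceback statistics.

    Among equal-scoring alignments the one with fewest gaps is preferred, then
    the smallest starting offset (query start, then target start). The DP cell
    value is the lexicographic optimum of (score, -gaps, -q_start, -t_start),
    which is well-defined because score and gap count are additive along the
    traceback.
    """
    if not query or not term:
        raise ValueError("align_local requires non-empty strings")
    nq, nt = len(query), len(term)
    # cell: (score, n_gaps, n_mismatches, n_matches, q_start, t_start)
    prev = [(0, 0, 0, 0, i, 0) for i in range(nq + 1)]
    best = (0, 0, 0, 0, 0, 0, 0, 0)  # + (q_end, t_end)

    def better(a, b):
        # higher score; then fewer gaps; then smaller q_start; then t_start
        ka = (a[0], -a[1], -a[4], -a[5])
        kb = (b[0], -b[1], -b[4], -b[5])
        return ka > kb

    for j in range(1, nt + 1):
        cur = [(0, 0, 0, 0, 0, j)]
        tc = term[j - 1]
        for i in range(1, nq + 1):
            qc = query[i - 1]
            d = prev[i - 1]
            if qc == tc:
                cand = (d[0] + match, d[1], d[2], d[3] + 1, d[4], d[5])
            else:
                cand = (d[0] + mismatch, d[1], d[2] + 1, d[3], d[4], d[5])
            u = prev[i]
            up = (u[0] + gap, u[1] + 1, u[2], u[3], u[4], u[5])
            if better(up, cand):
                cand = up
            left = cur[i - 1]
            lf = (left[0] + gap, left[1] + 1, left[2], left[3], left[4], left[5])
            if better(lf, cand):
                cand = lf
            fresh = (0, 0, 0, 0, i, j)
            if better(fresh, cand):
                cand = fresh
            cur.append(cand)
            cell = cand + (i, j)
            if better(cell, best) or (
                not better(best, cell)
                and (cell[6], cell[7]) < (best[6], best[7])
            ):
                best = cell
        prev = cur
    score, gaps, mms, ms, qs, ts, qe, te = best
    if score <= 0:
        return AlignmentResult(0, 0, 0, 0, (0, 0), (0, 0))
    return AlignmentResult(score, ms, mms, gaps, (qs, qe), (ts, te))


def score_cutoff(query_len: int, term_len: int, params: CutoffParams) -> float:
    """Log-linear acceptance threshold in alignment-score units."""
    if query_len < 1 or term_len < 1:
        raise ValueError("string lengths must be >= 1")
    return params.a * math.log(query_len) + params.b * math.log(term_len) + params.c


# ---------------------------------------------------------------------------
# Decompounding


def decompound(
    word: str, vocab: Vocabulary, params: CutoffParams | None = None
) -> list[tuple[str, str]]:
    """Split a compounded word into longest vocabulary-term matches.

    Greedy left-to-right: at each position take the longest vocabulary term of
    at least ``min_split`` characters that matches exactly; characters covered
    by no split are skipped. Returns ``[(substring, concept_id), ...]`` in text
    order, empty when nothing of sufficient length matches.
    """
    if not word:
        raise ValueError("decompound requires a non-empty word")
    params = params or CutoffParams()
    w = word.lower()
    out: list[tuple[str, str]] = []
    i = 0
    n = len(w)
    while i <= n - params.min_split:
        hit = None
        for j in range(n, i + params.min_split - 1, -1):
            entries = vocab.lookup(w[i:j])
            if entries:
                hit = (w[i:j], entries[0].concept_id, j)
                break
        if hit is None:
            i += 1
        else:
            out.append((hit[0], hit[1]))
            i = hit[2]
    return out


# ---------------------------------------------------------------------------
# Annotation


def _best_fuzzy(
    token: str, vocab: Vocabulary, params: CutoffParams
) -> tuple[VocabEntry, AlignmentResult] | None:
    best: tuple[VocabEntry, AlignmentResult] | None = None
    for term in vocab.terms:
        # a term much longer/shorter than the token cannot clear the cutoff
        if abs(len(term) - len(token)) > max(len(token), len(term)) // 2 + 2:
            continue
        aln = align_local(token, term)
        if aln.n_gaps > params.max_gaps:
            continue
        if aln.score < score_cutoff(len(token), len(term), params):
            continue
        entry = vocab.lookup(term)[0]
        if best is None:
            best = (entry, aln)
            continue
        cur_key = (best[1].score, -best[1].n_gaps)
        new_key = (aln.score, -aln.n_gaps)
        if new_key > cur_key or (
            new_key == cur_key and str(entry.concept_id) < str(best[0].concept_id)
        ):
            best = (entry, aln)
    return best


def annotate_text(
    text: str,
    doc_id: str,
    vocab: Vocabulary,
    params: CutoffParams | None = None,
) -> list[Mention]:
    """Annotate a document with vocabulary concepts.

    For each token the best vocabulary match above the cutoff becomes a
    Mention. Matching routes are tried in order: exact full-token lookup,
    then decompound splits, then fuzzy full-token alignment. Exact matches
    always outrank fuzzy ones, and exact sub-word splits outrank a fuzzy
    match of the whole token — local alignment would otherwise happily
    ignore the trailing half of a compound. At most one concept is reported
    per span (ties broken by lowest concept id).
    """
    params = params or CutoffParams()
    mentions: list[Mention] = []
    for m in _WORD_RE.finditer(text):
        token = m.group(0).lower()
        start = m.start()
        exact = vocab.lookup(token)
        if exact:
            entry = exact[0]
            L = len(token)
            aln = AlignmentResult(2 * L, L, 0, 0, (0, L), (0, L))
            mentions.append(
                Mention(doc_id, (start, m.end()), m.group(0), entry.concept_id,
                        entry.group, aln)
            )
            continue
        splits = decompound(token, vocab, params)
        if not splits:
            hit = _best_fuzzy(token, vocab, params)
            if hit is not None:
                entry, aln = hit
                mentions.append(
                    Mention(doc_id, (start, m.end()), m.group(0),
                            entry.concept_id, entry.group, aln)
                )
            continue
        pos = 0
        for sub, cid in splits:
            rel = token.index(sub, pos)
            pos = rel + len(sub)
            entry = vocab.lookup(sub)[0]
            L = len(sub)
            aln = AlignmentResult(2 * L, L, 0, 0, (rel, rel + L), (0, L))
            span = (start + rel, start + rel + L)
            mentions.append(
                Mention(doc_id, span, text[span[0]:span[1]], cid, entry.group,
                        aln, via_decompound=True)
            )
    return mentions


# ---------------------------------------------------------------------------
# Standoff I/O


def write_mentions(mentions: list[Mention], path) -> None:
    """JSON Lines, one object per mention."""
    import json

    with open(path, "w") as fh:
        for m in mentions:
            fh.write(json.dumps({
                "doc_id": m.doc_id,
                "start": m.char_span[0],
                "end": m.char_span[1],
                "surface": m.surface,
                "concept_id": m.concept_id,
                "group": m.group,
                "score": m.alignment.score,
                "n_gaps": m.alignment.n_gaps,
                "via_decompound": m.via_decompound,
            }) + "\n")


def read_mentions(path) -> list[Mention]:
    import json

    out = []
    with open(path) as fh:
        for line in fh:
            d = json.loads(line)
            aln = AlignmentResult(d["score"], 0, 0, d["n_gaps"], (0, 0), (0, 0))
            out.append(Mention(d["doc_id"], (d["start"], d["end"]), d["surface"],
                               d["concept_id"], d["group"], aln,
                               d["via_decompound"]))
    return out
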