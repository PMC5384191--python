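"""Context classification of concept mentions: current / history / noise.

A mention of a disease, drug or procedure in a note may describe the
patient's present state (real-time), their past (retrospective), or nothing
about the patient at all — negated findings, correspondence, administrative
boilerplate. Only the first two become dated clinical events, so each mention
is classified into ``current``, ``history`` or ``noise`` from the language
surrounding it.

Features are binary word-presence indicators in four positional classes:

(i)   ``pre_para``: up to 3 words immediately before the mention's paragraph;
(ii)  ``para``:     every word of the paragraph;
(iii) ``sent``:     every word of the sentence;
(iv)  ``window``:   the 3 words before and 3 after the mention.

The matched term itself is excluded from classes (ii)-(iv). Features are
idf-scored; a multinomial-on-binary Naive Bayes with additive smoothing uses
the idf as a likelihood exponent, and features enter the model through
sequential forward selection (ranked by summed tf-idf mass) scored by
stratified k-fold cross-validated macro-F1, stopping once no examined
candidate improves the score.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold

from .vocab_annotator import Mention

__all__ = [
    "CLASSES",
    "FeatureVector",
    "LabeledMention",
    "NBModel",
    "extract_features",
    "compute_idf",
    "train_nb",
    "classify_mention",
    "forward_select",
    "pairwise_f1",
    "cv_macro_f1",
]

CLASSES = ("current", "history", "noise")  # fixed tie-break order

_WORD_RE = re.compile(r"\w+", re.UNICODE)
_PARA_RE = re.compile(r"\n\s*\n")
_SENT_END = re.compile(r"[.!?]")


@dataclass(frozen=True)
class FeatureVector:
    """Binary presence features, each prefixed by its positional class."""

    features: frozenset[str]

    def __contains__(self, f: str) -> bool:
        return f in self.features


@dataclass(frozen=True)
class LabeledMention:
    mention: Mention
    label: str

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(f"label must be one of {CLASSES}, got {self.label!r}")


def _words(text: str) -> list[str]:
    return [w.lower() for w in _WORD_RE.findall(text)]


def extract_features(doc: str, mention: Mention) -> FeatureVector:
    """Extract the four positional feature classes around a mention."""
    start, end = mention.char_span
    if not (0 <= start <= end <= len(doc)):
        raise ValueError(f"mention span {mention.char_span} outside document")
    term_words = set(_words(doc[start:end]))

    # paragraph = blank-line delimited block containing the span
    bounds = [0]
    for m in _PARA_RE.finditer(doc):
        bounds.append(m.start())
        bounds.append(m.end())
    bounds.append(len(doc))
    p_start, p_end = 0, len(doc)
    for a, b in zip(bounds[::2], bounds[1::2]):
        if a <= start < b or (start == len(doc) and b == len(doc)):
            p_start, p_end = a, b
            break

    pre_para = _words(doc[:p_start])[-3:]
    para = [w for w in _words(doc[p_start:p_end]) if w not in term_words]

    # sentence containing the span, delimited by ./!/?
    s_start = p_start
    for m in _SENT_END.finditer(doc, p_start, start):
        s_start = m.end()
    s_end_m = _SENT_END.search(doc, end, p_end)
    s_end = s_end_m.end() if s_end_m else p_end
    sent = [w for w in _words(doc[s_start:s_end]) if w not in term_words]

    before = _words(doc[:start])[-3:]
    after = _words(doc[end:])[:3]
    window = [w for w in before + after if w not in term_words]

    feats = (
        {f"pre_para={w}" for w in pre_para}
        | {f"para={w}" for w in para}
        | {f"sent={w}" for w in sent}
        | {f"window={w}" for w in window}
    )
    return FeatureVector(frozenset(feats))


def compute_idf(corpus_features: list[FeatureVector]) -> dict[str, float]:
    """idf(f) = ln(N / df(f)); features are binary per vector (tf in {0,1})."""
    if not corpus_features:
        raise ValueError("compute_idf requires at least one feature vector")
    n = len(corpus_features)
    df: dict[str, int] = {}
    for fv in corpus_features:
        for f in fv.features:
            df[f] = df.get(f, 0) + 1
    return {f: math.log(n / d) for f, d in df.items()}


@dataclass
class NBModel:
    """Per-group Naive Bayes over binary positional features.

    ``log_likelihoods[(f, c)]`` is the smoothed log P(f | c); at prediction
    time each present selected feature contributes ``idf(f) *
    log_likelihood`` — evidence from distinctive words weighs more.
    """

    group: str
    log_priors: dict[str, float]
    log_likelihoods: dict[tuple[str, str], float]
    selected_features: list[str]
    idf_table: dict[str, float]
    smoothing: float = 1.0
    class_counts: dict[str, int] = field(default_factory=dict)
    n_features: int = 0


def train_nb(
    data: list[tuple[FeatureVector, str]],
    smoothing: float = 1.0,
    group: str = "disease",
    selected_features: list[str] | None = None,
    idf_table: dict[str, float] | None = None,
) -> NBModel:
    """Fit the NB model. ``data`` is (feature vector, label) pairs.

    Likelihood of a feature in class c: (count(f,c) + a) / (n_c + a*V) with
    V the total number of distinct candidate features.
    """
    labels = {lab for _, lab in data}
    if len(labels) < 2:
        raise ValueError("training data must contain at least two classes")
    if idf_table is None:
        idf_table = compute_idf([fv for fv, _ in data])
    all_feats = sorted({f for fv, _ in data for f in fv.features})
    if selected_features is None:
        selected_features = all_feats
    V = len(all_feats)
    n = len(data)
    class_counts = {c: sum(1 for _, lab in data if lab == c) for c in CLASSES}
    log_priors = {
        c: math.log(class_counts[c] / n) if class_counts[c] else -math.inf
        for c in CLASSES
    }
    counts: dict[tuple[str, str], int] = {}
    for fv, lab in data:
        for f in fv.features:
            counts[(f, lab)] = counts.get((f, lab), 0) + 1
    log_lik = {}
    for f in selected_features:
        for c in CLASSES:
            num = counts.get((f, c), 0) + smoothing
            den = class_counts[c] + smoothing * V
            log_lik[(f, c)] = math.log(num / den) if den > 0 else -math.inf
    return NBModel(
        group=group,
        log_priors=log_priors,
        log_likelihoods=log_lik,
        selected_features=list(selected_features),
        idf_table={f: idf_table.get(f, 0.0) for f in selected_features},
        smoothing=smoothing,
        class_counts=class_counts,
        n_features=V,
    )


def classify_mention(model: NBModel, fv: FeatureVector) -> tuple[str, dict[str, float]]:
    """Posterior per class and the argmax label (ties: current < history < noise)."""
    present = [f for f in model.selected_features if f in fv.features]
    log_post = {}
    for c in CLASSES:
        lp = model.log_priors.get(c, -math.inf)
        if lp == -math.inf:
            log_post[c] = -math.inf
            continue
        for f in present:
            lp += model.idf_table.get(f, 1.0) * model.log_likelihoods[(f, c)]
        log_post[c] = lp
    mx = max(log_post.values())
    if mx == -math.inf:
        post = {c: 1.0 / len(CLASSES) for c in CLASSES}
    else:
        w = {c: math.exp(v - mx) if v > -math.inf else 0.0 for c, v in log_post.items()}
        z = sum(w.values())
        post = {c: v / z for c, v in w.items()}
    best = max(post.values())
    label = next(c for c in CLASSES if post[c] >= best - 1e-12)
    return label, post


def cv_macro_f1(
    data: list[tuple[FeatureVector, str]],
    selected: list[str],
    folds: int,
    seed: int,
    smoothing: float,
    idf_table: dict[str, float],
) -> float:
    y = np.array([lab for _, lab in data])
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_true: list[str] = []
    y_pred: list[str] = []
    for tr, te in skf.split(np.zeros(len(y)), y):
        train = [data[i] for i in tr]
        if len({lab for _, lab in train}) < 2:
            continue
        model = train_nb(train, smoothing, selected_features=selected,
                         idf_table=idf_table)
        for i in te:
            lab, _ = classify_mention(model, data[i][0])
            y_true.append(y[i])
            y_pred.append(lab)
    if not y_true:
        return 0.0
    return float(f1_score(y_true, y_pred, labels=list(CLASSES), average="macro",
                          zero_division=0))


def forward_select(
    data: list[tuple[FeatureVector, str]],
    folds: int = 10,
    seed: int = 0,
    smoothing: float = 1.0,
    max_features: int | None = None,
    patience: int = 50,
) -> list[str]:
    """Sequential forward feature selection under cross-validation.

    Candidates are ranked by summed tf-idf mass (df * idf, since vectors are
    binary) and examined one at a time; a candidate is admitted when it
    raises the stratified ``folds``-fold CV macro-F1 and skipped otherwise.
    Selection stops — performance has stabilized — once ``patience``
    consecutive candidates (or the rest of the ranking) yield no gain.
    Stopping at the very first non-improving candidate would be degenerate:
    a top-ranked feature that marks the majority class adds nothing even
    when discriminative features for the other classes follow it.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(data) < folds:
        raise ValueError("need at least as many examples as folds")
    idf_table = compute_idf([fv for fv, _ in data])
    df: dict[str, int] = {}
    for fv, _ in data:
        for f in fv.features:
            df[f] = df.get(f, 0) + 1
    if not df:
        raise ValueError("no candidate features in the data")
    ranked = sorted(df, key=lambda f: (-df[f] * idf_table[f], f))
    if max_features is not None:
        ranked = ranked[:max_features]
    selected: list[str] = []
    best = cv_macro_f1(data, selected, folds, seed, smoothing, idf_table)
    stalled = 0
    for f in ranked:
        score = cv_macro_f1(data, selected + [f], folds, seed, smoothing, idf_table)
        if score > best:
            selected.append(f)
            best = score
            stalled = 0
        else:
            stalled += 1
            if stalled >= patience:
                break
    return selected


def pairwise_f1(
    model: NBModel, test: list[tuple[FeatureVector, str]]
) -> dict[str, float | None]:
    """F1 per class pair plus 3-class macro-F1.

    For a pair (A, B) the test set is restricted to examples whose true label
    is A or B and F1 is computed with A as the positive class (a prediction
    counts as positive iff it equals A). A pair absent from the test data is
    reported as None.
    """
    if not test:
        raise ValueError("empty test set")
    preds = [classify_mention(model, fv)[0] for fv, _ in test]
    truths = [lab for _, lab in test]
    out: dict[str, float | None] = {}
    pairs = [("current", "noise"), ("history", "noise"), ("current", "history")]
    for pos, neg in pairs:
        idx = [i for i, t in enumerate(truths) if t in (pos, neg)]
        key = f"{pos}-{neg}"
        if not idx or not any(truths[i] == pos for i in idx):
            out[key] = None
            continue
        yt = [1 if truths[i] == pos else 0 for i in idx]
        yp = [1 if preds[i] == pos else 0 for i in idx]
        out[key] = float(f1_score(yt, yp, zero_division=0))
    out["macro"] = float(
        f1_score(truths, preds, labels=list(CLASSES), average="macro",
                 zero_division=0)
    )
    return out
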