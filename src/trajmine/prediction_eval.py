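"""Forward prediction of patient events from mined trajectories.

Trajectories are evaluated as sequential predictors on held-out patients:
events are revealed one at a time in first-appearance order, every
trajectory whose k-node prefix appears (order-preserved) among the known
events predicts its (k+1)-th node with the corresponding edge probability,
and a prediction is a true positive when the concept occurs later in the
patient's record. Matching is subsequence-based, not contiguous — real
streams interleave several trajectories at once.

The positive predictive value (PPV) is reported overall — over unique
(patient, concept) predicted pairs — and stratified three ways: by the
number of events known when predicting, by the node position in the source
trajectory, and by edge-probability bin (width 0.1). A null model of
label-randomized trajectories with the same length multiset and edge
probabilities calibrates how much of the PPV is sequential structure rather
than marginal concept frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .event_model import EventStream, all_first_appearances
from .trajectory_miner import Trajectory

__all__ = [
    "Prediction",
    "EvalReport",
    "predict_next",
    "stepwise_evaluate",
    "randomize_trajectories",
    "evaluate_with_null",
]


@dataclass(frozen=True)
class Prediction:
    patient_id: str
    concept: str
    trajectory: tuple[str, ...]
    probability: float
    position: int  # 1-based node index of the predicted node, >= 2
    correct: bool | None = None


@dataclass
class EvalReport:
    ppv: float
    n_predictions: int
    n_true_positive: int
    ppv_by_known_events: dict[int, float] = field(default_factory=dict)
    positive_fraction_by_position: dict[int, float] = field(default_factory=dict)
    ppv_by_edge_probability: dict[float, float] = field(default_factory=dict)


def _prefix_subsequence_len(nodes: tuple[str, ...], known: list[str]) -> int:
    """Longest k such that nodes[:k] is an order-preserving subsequence of known."""
    k = 0
    it = iter(known)
    for node in nodes:
        for item in it:
            if item == node:
                k += 1
                break
        else:
            return k
    return k


def predict_next(
    known: list[str], trajectories: list[Trajectory], patient_id: str = ""
) -> list[Prediction]:
    """Predictions fired by trajectories against a known event prefix.

    A trajectory fires when its first k nodes (k >= 1) all appear among the
    known events in the same relative order and node k+1 is not yet known.
    Duplicate predictions of the same concept keep the highest-probability
    source.
    """
    if not known:
        raise ValueError("known events must be non-empty")
    known_set = set(known)
    best: dict[str, Prediction] = {}
    for t in trajectories:
        k = _prefix_subsequence_len(t.nodes, known)
        if k < 1 or k >= len(t.nodes):
            continue
        nxt = t.nodes[k]
        if nxt in known_set:
            continue
        p = Prediction(patient_id, nxt, t.nodes, t.probs[k - 1], k + 1)
        cur = best.get(nxt)
        if cur is None or p.probability > cur.probability:
            best[nxt] = p
    return [best[c] for c in sorted(best)]


def stepwise_evaluate(
    holdout: EventStream,
    trajectories: list[Trajectory],
    training_patients: set[str] | None = None,
) -> EvalReport:
    """Reveal each holdout patient's events one at a time and score predictions.

    ``training_patients``, when given, must be disjoint from the holdout
    patients. Each (patient, concept) pair is scored once, at the first
    reveal step that predicts it (within a step, predict_next already keeps
    the highest-probability source). Scoring the earliest firing keeps a
    prediction's empirical success rate aligned with its edge probability;
    re-scoring the same pair from later, better-informed reveals would
    condition the kept source on the outcome and bias the stratified
    curves. All report statistics are computed over these unique pairs.
    """
    sequences = all_first_appearances(holdout)
    if not sequences:
        raise ValueError("empty holdout stream")
    if training_patients:
        overlap = set(sequences) & training_patients
        if overlap:
            raise ValueError(f"holdout overlaps training patients: {sorted(overlap)[:5]}")

    pair_first: dict[tuple[str, str], Prediction] = {}
    by_known: dict[int, list[bool]] = {}
    by_pos_pos: dict[int, int] = {}
    by_bin: dict[float, list[bool]] = {}
    for pid, seq in sequences.items():
        full = list(seq.sequence)
        # the final round has an empty future: predictions made at the end
        # of the record count as false. Skipping them would drop exactly the
        # patients whose records stop early and bias PPV upward.
        for t_reveal in range(1, len(full) + 1):
            known = full[:t_reveal]
            future = set(full[t_reveal:])
            for p in predict_next(known, trajectories, pid):
                key = (pid, p.concept)
                if key in pair_first:
                    continue
                correct = p.concept in future
                pair_first[key] = Prediction(pid, p.concept, p.trajectory,
                                             p.probability, p.position, correct)
                by_known.setdefault(t_reveal, []).append(correct)
                if correct:
                    by_pos_pos[p.position] = by_pos_pos.get(p.position, 0) + 1
                b = round(min(np.floor(p.probability * 10) / 10, 0.9), 1)
                by_bin.setdefault(b, []).append(correct)

    preds = list(pair_first.values())
    tp = sum(1 for p in preds if p.correct)
    n = len(preds)
    n_pos = sum(by_pos_pos.values())
    return EvalReport(
        ppv=tp / n if n else float("nan"),
        n_predictions=n,
        n_true_positive=tp,
        ppv_by_known_events={
            k: sum(v) / len(v) for k, v in sorted(by_known.items())
        },
        positive_fraction_by_position={
            k: v / n_pos for k, v in sorted(by_pos_pos.items())
        } if n_pos else {},
        ppv_by_edge_probability={
            b: sum(v) / len(v) for b, v in sorted(by_bin.items())
        },
    )


def randomize_trajectories(
    trajectories: list[Trajectory], stream: EventStream, seed: int
) -> list[Trajectory]:
    """Null model: same number and lengths of trajectories, node labels drawn
    from the stream's empirical concept frequencies (without repetition within
    a trajectory), edge probabilities preserved."""
    if not trajectories:
        raise ValueError("no trajectories to randomize")
    rng = np.random.default_rng(seed)
    counts = stream.df.groupby("concept_id", sort=True)["patient_id"].nunique()
    concepts = np.array(counts.index)
    freqs = counts.to_numpy(dtype=float)
    freqs /= freqs.sum()
    longest = max(len(t) for t in trajectories)
    if len(concepts) < longest:
        raise ValueError(
            f"stream has {len(concepts)} distinct concepts; longest trajectory "
            f"needs {longest}"
        )
    null = []
    for t in trajectories:
        labels = rng.choice(concepts, size=len(t.nodes), replace=False, p=freqs)
        null.append(
            Trajectory(
                nodes=tuple(str(c) for c in labels),
                counts=t.counts,
                probs=t.probs,
                n_patients_complete=t.n_patients_complete,
            )
        )
    return null


def evaluate_with_null(
    holdout: EventStream,
    trajectories: list[Trajectory],
    stream: EventStream,
    seed: int,
    training_patients: set[str] | None = None,
) -> tuple[EvalReport, EvalReport]:
    """Evaluate mined trajectories and their randomized null on the same holdout."""
    model = stepwise_evaluate(holdout, trajectories, training_patients)
    null = stepwise_evaluate(
        holdout, randomize_trajectories(trajectories, stream, seed),
        training_patients,
    )
    return model, null
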