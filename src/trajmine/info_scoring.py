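"""Information-gain scoring of trajectories.

A trajectory is informative when knowing its prefix changes the probability
of the next event relative to the cohort background. For each non-initial
node s with prefix b, the per-event gain is the Kullback-Leibler divergence
between the Bernoulli distribution with parameter P(s|b) (the edge
probability into s) and the Bernoulli with the background parameter P(s)
(the fraction of the cohort ever experiencing s):

    gain = p log2(p/q) + (1-p) log2((1-p)/(1-q)),  p = P(s|b), q = P(s)

in bits, with the conventions 0 log 0 = 0 and an explicit +inf when the
background makes the conditional impossible (q in {0,1} with p != q).
The two-term Bernoulli form is used because it is the literal KL between
the two event distributions and is non-negative, vanishing iff p = q. The
trajectory's total gain is the sum over its events; trajectories are ranked
by total, infinities above all finite totals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .event_model import EventStream
from .trajectory_miner import Trajectory

__all__ = [
    "GainScore",
    "background_probability",
    "event_gain",
    "trajectory_gain",
    "rank_trajectories",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EventGain:
    concept: str
    p_cond: float
    p_background: float
    gain: float  # bits, >= 0, may be inf


@dataclass(frozen=True)
class GainScore:
    per_event: tuple[EventGain, ...]
    total: float  # bits


def background_probability(concept: str, stream: EventStream) -> float:
    """Fraction of patients in the stream who ever experience the concept."""
    n = stream.n_patients
    if n == 0:
        raise ValueError("empty event stream")
    carriers = len(stream.patients_with(concept))
    if carriers == 0:
        logger.warning("concept %r unseen in stream; background probability 0", concept)
    return carriers / n


def _plogp(p: float, q: float) -> float:
    if p == 0.0:
        return 0.0
    if q == 0.0:
        return math.inf
    return p * math.log2(p / q)


def event_gain(p_cond: float, p_bg: float) -> float:
    """KL divergence (bits) between Bernoulli(p_cond) and Bernoulli(p_bg)."""
    for name, v in (("p_cond", p_cond), ("p_bg", p_bg)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return _plogp(p_cond, p_bg) + _plogp(1.0 - p_cond, 1.0 - p_bg)


def trajectory_gain(trajectory: Trajectory, stream: EventStream) -> GainScore:
    """Summed per-event information gain of a trajectory against a cohort."""
    per_event = []
    for i, concept in enumerate(trajectory.nodes[1:]):
        p_cond = trajectory.probs[i]
        p_bg = background_probability(concept, stream)
        per_event.append(EventGain(concept, p_cond, p_bg, event_gain(p_cond, p_bg)))
    total = sum(e.gain for e in per_event) if per_event else 0.0
    return GainScore(tuple(per_event), total)


def rank_trajectories(
    trajectories: list[Trajectory], stream: EventStream, top: int | None = None
) -> list[tuple[Trajectory, GainScore]]:
    """Trajectories sorted by total gain, highest first; infinities rank above
    all finite totals (ties broken by node sequence for determinism)."""
    scored = [(t, trajectory_gain(t, stream)) for t in trajectories]
    scored.sort(key=lambda ts: (-ts[1].total, ts[0].nodes))
    return scored[:top] if top is not None else scored
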