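# trajmine

Probabilistic disease and event trajectories mined from free-text clinical
notes.

Most of what an electronic health record knows about a patient is prose:
admission notes, nurse and doctor notes, surgical and discharge reports.
`trajmine` turns that prose into dated concept events and the events into
**trajectories** — ordered concept sequences with per-edge progression
probabilities — that can rank informative disease courses, quantify
confounder-adjusted risks between events, and predict a patient's upcoming
events. Everything is exercisable end-to-end on synthetic corpora and
cohorts with planted ground truth, so the full pipeline is testable without
any patient data.

## The method

1. **Annotation.** Vocabulary terms and synonyms (a concept dictionary with
   `disease` / `drug` / `procedure` groups and a hierarchy, in the spirit of
   a clinical thesaurus such as MeSH) are matched to note text with
   Smith–Waterman local alignment (match 2, mismatch −1, gap −1, at most 2
   gaps), accepting a match when its score clears a log-linear cutoff
   `a·log(query) + b·log(term) + c`. Agglutinated compounds are split by a
   greedy longest-match decompounder (splits ≥ 5 characters).
2. **Context.** Each mention is classified *current* / *history* / *noise*
   from tf-idf-weighted positional word features (paragraph, sentence,
   ±3-word window, paragraph preamble) by a per-group Naïve Bayes model with
   sequential forward feature selection under 10-fold cross-validation.
   Noise mentions (negations, correspondence) never become events.
3. **Events.** Mentions become dated `(patient, date, concept)` events; each
   patient's distinct concepts ordered by first appearance form the
   canonical sequence. A Kolmogorov–Smirnov screen (Bonferroni, 25% family
   level) checks that concept occurrence does not depend on age.
4. **Trajectories.** Frequent concept sets (Eclat, 5% support, ≥ 2 concepts)
   are ordered by first appearance and counted hierarchically: `counts[k]`
   patients realize the k-prefix, and the edge probability is
   `counts[k+1]/counts[k]`. Orderings with all counts > 20 are condensed
   into trajectories with median transit times.
5. **Information gain.** Each non-initial event contributes the
   Kullback–Leibler divergence (bits) between Bernoulli(P(s|b)) — the edge
   probability given the prefix b — and Bernoulli(P(s)), the cohort
   background rate; the trajectory total ranks informative courses.
6. **Confounder adjustment.** For an event pair (x, y), trajectories through
   x and y nominate the intermediate/preceding events z; the back-door
   estimate `P(y|do(x)) = Σ_z P(y|x,z) P(z)` over the stratification by
   realized z-subsets removes spurious risk (raw P(y|x) ≫ adjusted when a
   confounder, not x, drives y).
7. **Prediction.** On held-out patients, events are revealed one at a time;
   any trajectory whose k-node prefix is an order-preserving subsequence of
   the known events predicts its (k+1)-th node. PPV is compared against
   label-randomized null trajectories of the same shape.

## Worked example

The two-patient cohort in which patient 1 experiences events `a, b, c, d`
on consecutive days and patient 2 experiences `a, b, d`:

```python
import trajmine as tm
from trajmine.event_model import all_first_appearances

stream = tm.worked_example_cohort()
seqs = all_first_appearances(stream)
(traj,) = tm.condense(tm.order_and_count(frozenset("abd"), seqs), min_patients=1)
print("trajectory:", " -> ".join(traj.nodes))
print("counts:    ", traj.counts)
print("probs:     ", traj.probs)
print("P(c):      ", tm.background_probability("c", stream))
```

prints

```
trajectory: a -> b -> d
counts:     (2, 2, 2)
probs:      (1.0, 1.0)
P(c):       0.5
```

Both patients realize the prefix `a, b` and both progress to `d`, so
P(d | a, b) = 1 — while only half the cohort ever experiences `c`, so its
background probability is 0.5. The trajectory `a -> b -> c` has edge
probabilities `(1.0, 0.5)` and an information gain of 0 bits: its
conditional probabilities equal the backgrounds, so knowing the prefix adds
nothing.

## Command line

Each stage is a subcommand (`trajmine annotate | mine | score | adjust |
evaluate | simulate | run`). A full synthetic run from one config:

```bash
trajmine run --config pipeline.yaml
```

with, e.g.,

```yaml
seed: 7
out_dir: run
stages: [simulate, mine, score, adjust, evaluate]
simulate: {n_patients: 2000}
evaluate: {holdout: 400}
```

writes `events.tsv`, `trajectories.json`, `scored.json`, `risks.tsv`,
`report.json` and a `manifest.json` of parameter and SHA-256 output hashes
(identical seed ⇒ identical hashes). On the reference synthetic cohort this
run mines 50 trajectories; the top-ranked one covers a planted five-node
chain (total gain ≈ 3.9 bits), the mined model predicts held-out events
with PPV ≈ 0.46 against ≈ 0.15 for the randomized null, and the PPV rises
monotonically with edge probability from ≈ 0.20 (0.1 bin) to ≈ 0.87
(0.8 bin).

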