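# Methods

This note records the models and procedures `trajmine` implements, the
defaults and why they hold, the choices made where the design was genuinely
open, and what the synthetic-data experiments do and do not demonstrate.

## Text to concepts

**Matching.** Tokens (Unicode word boundaries, lower-cased, diacritics
preserved) are matched against vocabulary terms by three routes, tried in
order: exact lookup; greedy longest-match decompounding into consecutive
exact term substrings of ≥ `min_split` = 5 characters; Smith–Waterman local
alignment of the whole token. Exact matches always outrank fuzzy ones, and
exact sub-word splits outrank a fuzzy whole-token match — local alignment
happily ignores the trailing half of a compound, so letting it pre-empt the
decompounder would misreport every compound as a sloppy full-word hit.

**Alignment.** Default weights match 2 / mismatch −1 / gap −1 (one match
weighs two errors); alignments with more than `max_gaps` = 2 gaps are
rejected. Among equal-scoring alignments the implementation prefers fewer
gaps, then the smallest start offset — an arbitrary but fixed tie rule so
annotations are reproducible. The aligner is verified against an
independent dynamic program that tracks, per cell, the best score at every
gap count.

**Acceptance cutoff.** A fuzzy match is accepted when its score reaches
`a·ln(len(query)) + b·ln(len(term)) + c`. The plane's coefficients are
configurable with defaults a = b = 2, c = 0, calibrated so that an exact
match of a 5-character term (score 10) clears its own threshold
(4·ln 5 ≈ 6.4) while a long word must align nearly end-to-end. Raising `c`
can only remove mentions (tested as a monotonicity property).

**Tie-breaking.** Equal-scoring concepts for a span resolve to the lowest
concept id.

## Mention context

Mentions are classified *current* (real-time observation), *history*
(retrospective description) or *noise* (negated findings, correspondence —
text that describes no patient state). Features are binary word-presence
indicators in four positional classes: up to 3 words before the mention's
paragraph; the paragraph; the sentence; the ±3-word window. Paragraphs are
blank-line-delimited, sentences end at `.!?` — conventional rules the
source text format does not dictate. The matched term itself is excluded
from the contextual classes.

The classifier is a per-group Naïve Bayes over **present** selected
features: `P(c | fv) ∝ P(c) · Π_f P(f|c)^idf(f)`, with Laplace-smoothed
likelihoods `(count(f,c)+α)/(n_c+αV)` (α = 1, V = number of candidate
features) and idf = ln(N/df) as an evidence exponent. Keeping vectors
binary while letting idf weight the evidence is one way to combine a
"binary feature vector" with tf-idf scores; it has the useful invariant
that adding a feature never changes predictions on vectors that lack it.
The flip side is that feature *absence* carries no evidence: a vector
sharing no selected feature falls back to the class priors (exact ties
resolve current < history < noise).

**Forward selection.** Candidates are ranked by summed tf-idf mass
(df · idf for binary vectors) and examined in order under stratified
10-fold cross-validated macro-F1; improving candidates are admitted,
non-improving ones skipped, and selection stops once 50 consecutive
candidates (or the rest of the ranking) bring no gain. Stopping at the
*first* zero-gain candidate is degenerate: a top-ranked feature that marks
the majority class adds nothing even when perfectly discriminative features
follow. Whether selection should be re-run inside each fold is ambiguous in
principle; here the ranking is computed once on the full data and the
stopping criterion is cross-validated, which keeps the selected list
deterministic for a given seed.

Pairwise F1 (current–noise, history–noise, current–history) is computed by
restricting the test set to the pair and scoring the first-named class as
positive; a 3-class macro-F1 accompanies it.

## Events and sequences

Noise mentions are dropped; current and history mentions are dated at the
note date (day resolution — the text gives nothing finer) and deduplicated
per (patient, date, concept). History mentions describe the past at an
unknown date, so they are excluded from trajectory construction by default
(configurable). First-appearance sequences order each patient's distinct
concepts by earliest date, same-day ties by concept id. Death and admission
types are ordinary concepts in reserved groups, with death last.

The age screen runs a two-sample Kolmogorov–Smirnov test per concept —
carriers vs non-carriers, which keeps the two samples independent — at the
Bonferroni-corrected threshold α/m with a deliberately generous family
level α = 0.25: the correction is made *sensitive* so that concepts
surviving it can be treated as age-independent when trajectories are drawn
(with m ≈ 1,667 concepts the per-test cut is ≈ 1.5 × 10⁻⁴).

## Trajectory mining

Transactions are each patient's distinct-concept set. Frequent itemsets
come from a depth-first Eclat search over transaction-id sets (minimum
support 5%, minimum two concepts), verified equal to brute-force
enumeration. For each itemset, every fully realized first-appearance
ordering is a candidate; the hierarchical count at prefix length k is the
number of patients whose first-appearance order of the itemset's concepts
*begins* with that k-prefix — patients holding only a subset still count
toward the prefixes they realize, which is exactly what makes edge
probabilities `counts[k+1]/counts[k]` < 1 possible. Orderings with every
count strictly above 20 are kept; retained orderings that are prefixes of
longer retained ones are merged into them. Edge probabilities across
sibling trajectories are deliberately not normalized: a patient can follow
several trajectories at once. Transit times are medians of day differences
between first appearances (midpoint convention for even counts).

## Information gain

For each non-initial trajectory node s with prefix b, the gain is the KL
divergence in bits between Bernoulli(P(s|b)) and Bernoulli(P(s)), where
P(s) is the fraction of the cohort ever experiencing s:

    gain = p·log2(p/q) + (1−p)·log2((1−p)/(1−q)),  p = P(s|b), q = P(s).

The two-term Bernoulli form is used (rather than the single cross term)
because it is the literal KL between the two event distributions, is
non-negative, and vanishes exactly when p = q; on the worked example the
two forms coincide. An impossible background (q ∈ {0,1} with p ≠ q) yields
an explicit `inf`, which ranks above all finite totals. Totals are exact
sums of per-event gains and scale-free in patient counts.

## Confounder adjustment

For a pair (x, y), every retained trajectory passing through x and then y
nominates its other events preceding y as potential confounders — whether
they sit between x and y or before x, since a common cause typically
*precedes* the exposure in first-appearance order. The union of nominated
events forms the pool Z; patients are partitioned by their realized subset
of Z, and

    P(y | do(x)) = Σ_z  P(y | x, stratum z) · P(stratum z)

with P(y|x,z) estimated among x-patients of the stratum (y counted only
after x) and weights estimated cohort-wide, renormalized over realized
strata. The partition form (rather than overlapping per-path subsets)
is what makes the estimate a genuine back-door adjustment: it reduces
exactly to the raw risk when a single stratum exists — the "unconfounded"
identity P(y|do(x)) = P(y|x) — stays inside the convex hull of the stratum
risks, and returns the background rate of y under a planted pure
confounder. Strata with fewer than 5 x-patients (configurable) are pooled
into one rare stratum for variance control. `k` reports the number of
distinct non-empty nominated paths.

Two trajectory sets describing the same outcomes through different
extraneous variables are compared by the R² of their adjusted risks over
shared pairs, plus the R² of the risk *change* regressed on the change in
path count — the first should be high and the second low when adjustment
has removed the influence of the extraneous variables.

## Forward prediction

Events of each held-out patient are revealed one at a time in
first-appearance order. A trajectory fires when its first k nodes form an
order-preserving *subsequence* of the known events (contiguity is not
required — real streams interleave trajectories) and predicts node k+1 with
its edge probability; within a step, duplicate concept predictions keep the
highest-probability source. Two protocol details matter and are deliberate:

* Across steps, each (patient, concept) pair is scored once, at its
  **earliest** firing. Keeping the best-probability source across steps
  instead would condition the kept prediction on later reveals and bias the
  PPV-by-probability curve (late re-predictions of never-occurring concepts
  pile into low bins).
* A final round runs at the end of each record with an empty future, so
  predictions nothing remains to confirm count as false. Skipping that
  round silently drops exactly the patients whose records stop early —
  an optimistic selection worth about +0.10 PPV on the synthetic cohort.

With both rules, a prediction's empirical success rate matches its edge
probability in expectation, which is what makes the PPV-by-edge-probability
curve interpretable. PPV is reported overall and stratified by number of
known events, trajectory node position, and edge-probability bin (width
0.1). The null model redraws each trajectory's node labels (same length,
no repeats within a trajectory) from the cohort's empirical concept
frequencies, preserving edge probabilities — frequency-matched labels make
the null a test of *sequence* information specifically. Null predictions
concentrate at node position 2: random prefixes rarely match deeper.

## Synthetic data

The generators provide every input with known truth; all are byte-
reproducible under a fixed seed.

**Cohorts.** Each patient draws confounder triples first (z with
prevalence p_z; x and y conditionally on z, with an optional direct x→y
effect; insertion order z < x < y, ahead of the chain), then a first-order
Markov chain from the planted initial distribution and transition matrix
(row remainders are stop probabilities), then an optional terminal death
event. Inter-event gaps are geometric in days. The triple needs a marginal
prevalence for z and baseline x/y rates absent z; these are generator
fields (defaults p_z = 0.5, baselines 0.05) the planted-truth record
includes.

**The reference cohort** (`pipeline.default_cohort_spec`) has three
mutually exclusive entry concepts (0.35 / 0.35 / 0.30) opening chains whose
node-probabilities-given-entry step down in tiers staggered across chains
(0.85/0.65/0.45/0.25, 0.75/0.55/0.35/0.15, 0.85/0.65/0.45), one pure
confounder triple (p_z 0.14, P(x|z) 0.75, P(y|z) 0.65, baselines
0.15/0.10, zero direct effect) and death at 0.08. Three properties drive
this design. No concept is universal, as in a real cohort, so a
frequency-sampling null cannot ride on marginal rates. Confounder and
death prevalences sit low enough that their *chance* co-occurrence with
chain concepts stays below the 5% mining support — in a realistically
sparse concept space, chance pairings are not frequent itemsets. And the
tier levels sit mid-bin and jointly cover 0.1–0.8, so the PPV-by-
probability curve is well posed at desk scale: estimate noise shifts an
edge between adjacent occupied bins without creating spurious inversions.
Recovery experiments run at n = 2,000 patients with an independent
1,000-patient holdout cohort from the same process (mirroring an external
validation set), sizes at which binomial noise on heavy edges (≥ 500
traversals) is well inside the ±0.05 assertion bands.

**Corpora.** Documents embed vocabulary terms among distractor words, with
two class-specific cue words around each mention realizing the context
label, a per-character typo (substitution) rate, and a compounding rate
that fuses the term with the following word (gold span covers the term
part). Distractors and cues are screened against the vocabulary — exact,
decompound and fuzzy routes — so in the zero-noise regime the annotator's
recall and precision are exactly 1 by construction; a large distractor pool
keeps any single distractor's tf-idf mass below the cues'. Synthetic
vocabularies are pronounceable random syllable terms ≥ 5 characters.

**What passing does and does not show.** The synthetic corpus has clean
word boundaries, consistent cue vocabulary, and a closed concept
dictionary; real clinical text has morphology, misspellings beyond
substitutions, ambiguous negation scope and out-of-vocabulary synonyms.
The planted cohorts have first-order Markov structure, day-resolved
time, no repeated observations of a concept, and confounders independent
of the chains. Recovery and margin results therefore validate the
*machinery* — counting, probabilities, adjustment, evaluation — not
clinical performance; headline numbers from any particular hospital corpus
are functions of that corpus and are not claimed.

## Pipeline and reproducibility

`trajmine run --config <yaml>` executes simulate → mine → score → adjust →
evaluate with strict config parsing (unknown keys are rejected by name).
Stage defaults are the method's reference values: min split 5, max gaps 2,
alignment 2/−1/−1, 10 CV folds, 5% support, min set size 2, condensation
count 20, Bonferroni level 25%, holdout 1,000. One global seed derives
per-stage seeds (SHA-256, < 2³¹); the manifest records parameters and
SHA-256 hashes of every artifact, and identical config + seed reproduces
identical hashes.

## Known limitations

* Fuzzy matching is O(tokens × terms) per document; fine for desk-scale
  vocabularies, but a production annotator over a full thesaurus would
  need candidate pruning (q-gram or prefix indexes).
* The stratified back-door estimate assumes the nominated events capture
  the confounding; unmeasured confounders and selection bias inherent to
  observational records are out of scope, and no causal validity on real
  data is implied.
* History-context events carry the note date, not the described past date;
  they are excluded from mining by default for exactly that reason.
* The decompounder is greedy left-to-right, not a globally optimal
  segmentation; it mirrors a longest-match convention rather than full
  morphology.
* Day-level resolution collapses multiple same-day notes; intra-day order
  is unrecoverable and ties are broken lexicographically.
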