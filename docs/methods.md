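# Methods

## Estimands

All quantities are defined on *retained* recall sequences: recalls scored
against the studied list, keeping only first-time recalls of non-buffer
targets. Buffers, intrusions and repetitions are excluded, and transitions
are counted on the retained sequence, so a transition "jumps over" an
excluded event — standard practice in free-recall analysis. Matching
between recalled and studied words is exact after normalization
(lowercase, trimmed, ASCII punctuation stripped); no stemming or spelling
correction is attempted, trading leniency for reproducibility.

For a design cell (group g, timepoint t) and valence category v:

| metric | numerator | denominator |
|---|---|---|
| Pstart(v) | lists whose first retained recall is v | lists with nonempty retained sequence |
| Pstay(v) | v→v retained transitions | retained transitions leaving v |
| Pstop(v) | lists whose final retained recall is v | all retained recalls of v |
| terminal(v) | lists whose final retained recall is v | lists with nonempty retained sequence |
| recall%(v) | distinct v targets recalled | studied v targets summed over lists |

Pstop's primary reading is the per-recall hazard ("the probability that a
given recall is the last"); the terminal-share reading, which sums to 1
across categories like Pstart, is exposed as a separate metric because
both readings are defensible and they answer slightly different questions.

Counts are pooled over every list of every participant in the cell before
division (event-level pooling). With only three lists per assessment,
per-participant proportions are too unstable to average; a
participant-weighted mean (`participant_mean_metric`) exists for
sensitivity analyses but is deliberately not the default. Lists with an
empty retained sequence carry no information about dynamics and drop out
of the Pstart/Pstay/Pstop/terminal denominators, but still count in
recall% denominators. No outliers are removed anywhere; an empty pooled
cell raises an explicit undefined-metric error rather than returning NaN.

## Permutation inference

The change statistic is Δg = M(g, T2) − M(g, T1); the interaction
statistic is ΔMBCT − Δcontrol (difference of differences). Null
distributions are built by relabeling design factors with participants as
the exchange units: time labels flip within participants (all lists of an
assessment move together, respecting within-participant dependence) with
probability 1/2, and group labels permute between participants with arm
sizes preserved. The within-group change test flips time only; the
interaction test applies both swaps jointly. A group-swap-only scheme can
be requested through the `scheme` argument.

Monte-Carlo p-values use add-one smoothing, p = (1 + #{|perm| ≥ |obs|}) /
(1 + n_perm), so they are valid and never zero; defaults are 1000
iterations, two-sided. Because relabeling never alters recall content,
each participant's per-timepoint count contributions are computed once and
every replicate is re-summed from them — algebraically identical to
rescoring the relabeled dataset (the suite verifies this equivalence
against `permute_labels` + direct recomputation). Replicates whose
statistic is undefined (a pooled cell emptied by relabeling) are redrawn
and counted; if more than half of n_perm would need redrawing the data are
declared degenerate and the test fails loudly rather than imputing.
`exact_test` enumerates the complete assignment space (identity included,
no smoothing) for up to 2^16 time flips or five million
assignment × flip combinations, and serves as the oracle for the
Monte-Carlo path. Tail comparisons use a 1e-9 float tolerance so discrete
ties are counted identically on both paths.

## Stimulus-list construction

The default list design is 22 words: 6 positive, 6 negative, 6 neutral
targets and 4 neutral buffers controlling primacy and recency, split 2 at
the start and 2 at the end (the total of four is fixed; the symmetric
split is our choice and is configurable). Candidate words come from an
ANEW-style norms table through per-category valence/arousal windows
(positive valence ≥ 6.7, negative ≤ 4.1, neutral 4.5–5.9, arousal windows
near nominal mean ± 2 SD); the windows are configurable because published
designs state target means (7.5/2.6/5.18 valence, 5.8/5.5/3.84 arousal)
rather than cutoffs. Per-list category means must sit within ±0.5 of those
targets, and lists within a set must agree pairwise on mean valence,
arousal, word length and log1p frequency within configurable tolerances.

Construction is stratified sampling per category followed by a seeded
hill-climb of same-category swaps (between lists and against the unused
pool) on a total-violation cost, then shuffle-until-valid ordering of the
18 targets with a 10,000-retry cap. The no-consecutive-same-valence
constraint is enforced over targets only: buffers are neutral, so
including them would make a neutral target adjacent to a buffer generally
unsatisfiable. Everything is deterministic given the seed; infeasible
inputs raise capacity or constraint-failure errors with diagnostics
instead of looping forever. Two word-disjoint list sets support
counterbalanced pre/post administration.

No proprietary norms are bundled; `make_synthetic_norms` generates
synthetic tokens with per-category truncated-normal valence/arousal
matching the nominal means/SDs and category-independent length and
frequency distributions, which makes the balance constraints satisfiable
by design.

## Generative model

Recall is simulated as a category-level Markov chain: first category from
start distribution π (restricted to categories with unrecalled items),
uniform item choice without replacement within category, stop after a
recall from category c with hazard θ_c, otherwise next category from the
c-th row of the stay/switch matrix S. This is a deliberate approximation
of retrieved-context models: it is the minimal process for which
Pstart/Pstay/Pstop are sufficient statistics, so parameter recovery is a
meaningful end-to-end check. It omits serial-position structure, lag
effects, item-level semantics and inter-participant heterogeneity, so
passing recovery and calibration here validates the pipeline's
bookkeeping and inference, not any claim about real recall data.

Depletion rule: while the current category still has unrecalled items its
stay probability is kept as parameterized and only the mass of exhausted
*switch* categories is redistributed among the remaining switch targets
(forced stay if none remain); when the current category itself is
exhausted, the row is renormalized over what remains. Treating the stay
tendency as a property of the ongoing train, not of which other
categories happen to survive, keeps the measured Pstay tracking diag(S)
under partial depletion. The obvious alternative — proportional
renormalization over all non-exhausted categories — leaks an exhausted
category's mass into the stay probability and measurably attenuates
planted stay effects (a planted −0.15 arrives ~0.04 smaller), which
breaks the directional-fidelity property the default design is required
to have; that trade-off decided the rule.

Baseline parameters (the simulated study conditions): π = (0.25, 0.50,
0.25) over (positive, negative, neutral) — a negatively biased starting
context, as expected after a stressor that activates ruminative
tendencies in a partially remitted sample; diag(S) = 0.55 with off-mass
split evenly — within-valence clustering well above the 1/3 chance level,
the "association network" strength the task probes; θ = (0.08, 0.15,
0.08) — negative contexts stickiest. These give ~8 retained recalls per
18-target list, i.e. overall recall in the mid-40% range, the level this
trial design produces, and they are fixed defaults, not fitted values:
the true per-cell parameters of any real study are unknowable from
printed summaries. Group × time effects are planted by shifting stay
diagonals and stop hazards (off-mass renormalized proportionally); the
canonical pattern at magnitude 0.15 moves the active arm's negative stay
down, positive stay up and negative stop down from T1 to T2, with
controls reversed.

The trial simulator draws 29 + 23 participants, assigns arms by a seeded
shuffle (3:2 block randomization with block size 5 is provided separately,
including the hypergeometric partial-block draw), builds two disjoint list
sets of three lists (two visual, one aural, collapsed in analysis),
counterbalances set order across participants, and runs every sequence on
seed-derived substreams — identical designs yield byte-identical event
tables. Optional intrusion/repetition injection rates (default 0) exist
only to exercise the scorer.

## Numerical and validation choices

- Problem sizes: depletion-free recovery uses 500 items/category and
  10,000 sequences (recovery errors land well under 0.02);
  depletion-level agreement is checked against a 20,000-sequence
  Monte-Carlo oracle within 3 combined standard errors; Monte-Carlo vs.
  exact p-values are compared on ≥20 random fixtures of ≤12 participants
  at 3000 iterations within 3 MC standard errors plus the smoothing gap;
  type-I calibration uses 1000 simulated null trials at n = 52 (the
  observed rate sits near 0.05, inside 0.035–0.065); the planted-0.15
  pattern check uses 100 trials (signs + interaction p < 0.05 reproduced
  in ≥90%).
- Degenerate inputs fail loudly: empty cells, all-empty retained
  sequences, undefined observed statistics and >50% undefined replicates
  raise typed errors.
- CSV interchange is comma-separated UTF-8 with headers; labels are
  validated strictly (unknown category/group/timepoint is a schema error,
  never a coercion); `load_study ∘ write_study` is the identity on valid
  datasets, and an optional `modality` column preserves the informational
  presentation tag through round-trips.
- Timepoints are the strings "T1"/"T2"; groups are "MBCT"/"control".

## Limitations

The generator's parameters are illustrative study conditions, not
estimates of any real cohort; empirical p-values and cell means of a real
trial cannot be reproduced without its raw data. The category-Markov model
has no serial-position or semantic structure, so recall% here reflects
only stopping hazards and depletion. Neutral-category tests are computed
but reported in an appendix table, since the primary contrasts of this
design concern negative and positive valence. With three lists per
assessment, per-participant estimates are intentionally avoided
everywhere except the optional sensitivity pooling.
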