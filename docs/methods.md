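# Methods

## Model and objective

An EOA model ranks compounds by a weighted sum of `n` z-scored molecular
descriptors. Only the ordering matters, so there is no intercept and the
overall scale of the weights is irrelevant to the result (it does interact
with the annealing temperature through the objective landscape, not through
the ranking). Higher score = better rank, by convention; ties are broken by
input row order (stable sort), so a ranking is a pure function of
(model, table).

The objective for a training set with `L` actives and `O` inactives is
`primary + secondary`:

- `primary ∈ {0..L}` counts actives in the top `L` ranked places.
- `secondary = 2/(1 + exp(D/τ)) ∈ (0, 1]`, where the displacement `D` sums,
  over misplaced actives, their distance below position `L`, and over
  misplaced inactives, their distance above it. `secondary = 1` iff `D = 0`
  iff separation is perfect; it decreases strictly with `D`.

Properties worth stating precisely, both verified by exhaustive enumeration
in the tests: whenever `primary < L` at least one active sits below `L` and
one inactive above it, so `D ≥ 2` and `secondary < 1`; hence the total
orders any two rankings of the same set lexicographically by
`(primary, −D)`, and its unique global maximum `L + 1` is attained exactly
at perfect separation.

The inverse-sigmoid form of the secondary score is one of several curves
satisfying the contract (bounded, sigmoid-shaped, monotone in displacement,
open interval below 1); the exact curve affects only how sharply credit
decays, which `τ` controls. Default `τ = L` so that a displacement of the
order of the active-set size costs roughly half the secondary credit;
`τ` is exposed everywhere it is consumed.

## Optimization

Metropolis Monte Carlo over (descriptor subset, weights):

- **moves** — with probability 0.5 swap one selected descriptor for a
  uniformly chosen unselected one (its weight redrawn uniformly from
  [−1, 1], the same range used at initialization); otherwise add Gaussian
  noise (σ = 0.1) to one weight. Exactly one change per step. Weights are
  resampled, not carried over, on swap: a fresh descriptor has no reason to
  inherit its predecessor's coefficient.
- **acceptance** — `min(1, exp(Δtotal / RT))`.
- **schedule** — saw-tooth: RT descends `rt_start → rt_end` linearly in
  `rt_step` increments with `steps_per_interval` steps per rung, then
  resets. Defaults: 1.00 → 0.01 by 0.01, 400 steps/rung, i.e. 100 rungs and
  40,000-step cycles; the default budget of 10⁶ steps spans 25 cycles.
  Repeated reheating lets the chain escape the local optima that a single
  cooling pass freezes into.
- **result** — the best-so-far model (ties: earliest found), not the final
  chain state. The trace records per-rung current/best objective and
  acceptance rate. Acceptance rates depend strongly on the data's objective
  landscape; on the synthetic benchmark they are far higher than on real
  descriptor decks, so the trace logs them but nothing asserts a band.

Scores are updated incrementally per move (rank-one update of the score
vector) and re-anchored by a full matrix product every 4,096 steps to keep
floating-point drift bounded. Everything is driven by one
`numpy.random.Generator`, so (data, parameters, seed) determine the output
bit-for-bit.

Validation sets play no role inside the optimizer; they are scored post hoc
with `evaluate_model`, keeping derivation and assessment cleanly separated.

## Preprocessing

Three filters, in order, then z-scoring:

1. constant columns (single unique value);
2. nearly constant columns: modal value covering ≥ 70% of compounds (the
   bound is inclusive; the threshold is configurable);
3. correlated pairs: r² > 0.7, greedy left-to-right — the earlier column in
   table order is kept. Constant columns must go first because r² is
   undefined against zero variance.

Z-scoring uses the population standard deviation (divide by n); rankings
are invariant to that choice, so the simpler convention is used and
recorded here. The default workflow filters and normalizes the parent
table before splitting; for leakage-free protocols the fitted
`ScalerStats` can instead be fitted on a training part and applied to
held-out tables unchanged (this is what the acceptance script does).

## Splits

Each subset draws a fixed number of actives and decoys without replacement
from the parent (subsets are drawn independently and may overlap with each
other), splits each class `train_fraction`/rest, and leaves all unselected
compounds as the test set — which therefore has a realistically tiny active
fraction (~0.5–0.7% for the published compositions the tests reproduce).
The per-class training count is `floor(0.8·n) + 1`: the +1 settles both the
exact-multiple case and the fractional case in favour of training, and this
single rule reproduces every published per-class train/validation count the
package is tested against. Splits are stratified by construction.

Y-scrambling relabels every active as inactive and an equal number of
randomly chosen decoys as active, leaving descriptor values untouched. A
model trained on scrambled labels is then evaluated against the *true*
labels; performance at or below AUC 0.5 is the expected null. On the
synthetic benchmark the scrambled models typically score *below* 0.5: the
optimizer learns to push the (relabeled) true actives out of the top of the
list, anti-correlating with the truth.

The active–decoy separation summary is the mean ± SD of Euclidean distances
over all active×decoy pairs, computed directly in the normalized descriptor
space. A full-rank PCA rotation is an isometry, so this equals the
all-principal-components computation; `via_pca=True` runs the explicit
rotation and the tests confirm parity to 1e-9.

## Metrics

- ROC/AUC go through scikit-learn (`roc_curve` with all thresholds,
  `roc_auc_score`); tied scores produce diagonal segments / half-credit
  pairs. The test suite checks the trapezoidal area against an independent
  brute-force Mann–Whitney pair count on hundreds of tied and untied
  instances.
- `EF_f = (a/A)/f` with the top fraction sized `⌈f·N⌉`. This form (rather
  than `(a/n_top)/(A/N)`) back-calculates published enrichment tables
  exactly: every printed EF₁% value times A times 0.01 recovers an integer
  active count.
- Top-L percentages round half-up to an integer, matching the convention of
  the published tables (e.g. 75/126 = 59.52% → 60%).
- Consensus over several score columns (e.g. two crystal structures) takes
  each compound's most favorable score — max or min depending on the
  declared direction — before computing metrics; idempotent and
  column-order invariant.

## Synthetic benchmark

Decoys are standard normal on every non-constant column; actives are
shifted by `effect_size` SDs along each informative column in the direction
of its planted weight. Redundant columns are a parent column plus
N(0, 0.1) noise (r² ≈ 0.99 with the parent, safely above the 0.7 filter);
constant columns carry one value. The column layout is a deterministic
function of the counts, so train and test draws with different seeds share
a schema.

Defaults are the package's reference study conditions: 50 actives / 500
decoys, 100 descriptors of which 5 informative at effect size 2.0, 10
redundant, 5 constant. Under the equal-covariance Gaussian model the
planted equal-weight scorer has closed-form
`AUC = Φ(effect_size · √(k/2))` for `k` informative columns — ≈ 0.998 at
the defaults, ≈ 0.9999 at effect size 3 — which the tests use as an
analytic oracle.

What the generator does *not* emulate: real descriptor marginals (counts,
heavy tails, discreteness), scaffold/analog structure among actives,
property-matched decoy selection, or correlated informative blocks. Passing
tests therefore demonstrate that the machinery recovers plantable linear
signal and honors its contracts, not that any particular real target is
learnable.

## Problem sizes and numerical choices

The test suite and the acceptance script run the optimizer at 50,000 MC
steps on the 550-compound benchmark (plus a 5,050-compound independent test
draw for generalization checks), which this implementation covers in a few
seconds per run while reliably reaching perfect training separation on
separable instances; the full default budget of 10⁶ steps is retained for
real-size problems. Degenerate inputs are rejected loudly rather than
coerced: single-class sets for any metric, L different from the actual
active count in the objective, zero-spread columns when fitting the scaler,
infeasible subset/model sizes.

## Known limitations

- The correlation filter is greedy and order-dependent by design
  (deterministic, but a different column order can keep a different member
  of a correlated clique).
- The secondary score's exact values are convention-dependent (see above);
  cross-implementation comparisons should compare primary counts and
  screening metrics, not raw totals.
- `EF_f` with `⌈f·N⌉` can slightly exceed `N/A` on tiny libraries where the
  ceiling matters; its exact ceiling is `⌈f·N⌉/(A·f)`.
- The optimizer re-ranks the full training set each step; for very large
  training sets a partial-sort or incremental-rank scheme would be the next
  optimization, not a change of contract.
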