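# Methods

## Problem

A test constructor adapting a questionnaire wants to add items to a short
scale or drop items from a long one, keeping the reliability of the summed
test score as high as possible at every length.  The population quantity to
maximise at each step, the test-score reliability
`rho_XX' = sigma^2_T / sigma^2_X`, is not estimable from a single
administration, so practical selection must rely on per-item statistics.
This package implements four such item-assessment criteria — three
item-score reliability estimators (methods MS, lambda-6, CA) and the
corrected item-total correlation (CITC) — together with the two stepwise
selection procedures that consume them, and a Monte Carlo harness that
measures how closely the resulting item orderings track the ideal ordering
defined by population reliability under a two-parameter logistic (2PL) IRT
model.

## Population model (`itemselect.irt`)

Dichotomous item scores follow the 2PL model
`P_i(theta) = expit(alpha_i (theta - beta_i))` with a normal latent trait
`theta ~ N(mu, sigma^2)`.  Because `E[X_i | theta] = P_i(theta)`, the item
true score equals the response function, and all classical-test-theory
moments reduce to integrals of `P_i` and `P_i P_j` against the latent
density:

- `pi_i = E[P_i]`, observed variance `pi_i (1 - pi_i)`;
- `pi_ij = E[P_i P_j]` (local independence), covariance `pi_ij - pi_i pi_j`;
- item true-score variance, **exact** form: `pi_ii - pi_i^2` with
  `pi_ii = E[P_i^2]`, the probability that an independent replication of
  the item is passed twice.

A first-order delta-method approximation
`(alpha_i P_i(mu)(1 - P_i(mu)))^2 sigma^2` is also provided
(`variance_mode="delta"`).  It evaluates the response-function slope at the
latent mean, where the slope of a centred item is maximal, and therefore
overstates the true-score variance badly for highly discriminating items
(for the two most discriminating items of the small-spread bank it yields a
two-item reliability of 0.73 versus the exact 0.481).  The exact form is the
default and is used for every reference value in the tests; the delta form
exists for comparison with the textbook derivation.

Integrals use Gauss–Hermite quadrature after rescaling to `N(mu, sigma^2)`,
61 nodes by default.  The integrands are smooth and bounded, and doubling
the node count changes subtest reliabilities by less than 1e-6 over the
discrimination range used here (tested).  All moments are computed once per
item bank and cached; the reliability of any subtest is then an O(k^2)
array reduction, which is what makes exhaustive pair searches and greedy
selection over 20-item banks effectively free.

## Item-assessment methods (`itemselect.estimators`)

All estimators consume sufficient statistics only — column means, the
covariance matrix (denominator N-1), and the joint proportion matrix
`X'X / N` — cached on the `ScoreMatrix`.  `PopulationScores` exposes the
same interface with model-implied values, so every estimator and procedure
can also be evaluated free of sampling noise.

- **CITC**: Pearson correlation of `X_i` with the rest score `R(i) = X - X_i`.
- **lambda-6** (Guttman, item version): `1 - eps2_i / var(X_i)` where
  `eps2_i` is the residual variance of the least-squares regression of
  `X_i` on the other items, computed as `1 / [S^{-1}]_{ii}`.  Exactly
  singular covariance matrices raise an error naming the collinear columns.
- **CA** (correction for attenuation): `CITC^2 / alpha_rest` with
  `alpha_rest` the coefficient alpha of the remaining items.  Values above
  1 are possible in samples; they are flagged but never truncated, because
  truncation would create artificial ties in the selection argmax.
- **MS** (Molenaar–Sijtsma): estimates the pass-twice probability `pi_ii`
  from the joint proportions of the target with the items nearest to it in
  the sample popularity ordering, under the double monotonicity model, and
  returns `(pi_hat_ii - p_i^2) / (p_i (1 - p_i))`.

### MS details

The neighbour construction groups items by *distinct* popularity value:

1. items exactly tied with the target sit at its estimated location and are
   used directly, `pi_hat_ii = mean_j pi_hat_ij` over the tied set;
2. otherwise an interior target is interpolated linearly between the
   group-mean joint proportions of the adjacent higher and lower popularity
   groups (a convex combination, since the target's popularity lies between
   the bracketing values);
3. a target at the highest or lowest distinct popularity has no bracket;
   its repeat-pass rate is borrowed from the nearest group as the
   conditional rate `pi_hat_ii = p_i * (group-mean joint) / (group
   popularity)`.

The estimate is clamped to the Frechet-feasible interval
`[max(0, 2 p_i - 1), p_i]`; clamps and tie pooling are counted in
diagnostics.  Two alternatives were evaluated and rejected during design.
Linear *extrapolation* beyond the edge groups (the naive extension of the
interior rule) amplifies sampling noise by the extrapolation ratio and
degrades orderings severely when popularities are nearly equal, exactly the
regime of the simulation design (all item locations are 0, so every
population popularity is 1/2).  Ignoring ties (picking single neighbours by
sorted position with a label tie-break) discards replicate information that
the tied groups carry and was uniformly worse across all six study cells.

## Selection procedures (`itemselect.selection`)

- **bottom-up**: start from a fixed two-item seed; at each step score every
  pool candidate `c` by its assessment *within the provisional test plus
  c*, add the argmax.  For CA the candidate's rest score is exactly the
  current test, so its alpha denominator is shared by all candidates; the
  lambda-6 residual variance is obtained from a Schur complement against
  the current test block.  These closed forms let a step score all
  candidates in one pass over the cached covariance matrix.
- **top-down**: start from the full pool; at each step assess every item
  within the current test and remove the argmin; stop at two items (the
  final decision is made on a three-item test, the smallest on which the
  methods are defined).

Ties break to the smallest original item label, making every run
deterministic.  Each step records all candidates and criterion values, so
traces are fully auditable.  The ideal counterparts replace the sample
criterion with population `rho_XX'`: the bottom-up seed is the pair with
the highest two-item reliability, each addition maximises the enlarged
test's reliability, each ideal removal maximises the remainder's.

For the graded banks used in the study, both ideal orderings are the
reverse of each other over the 18 shared items: addition order
18, 17, ..., 1 (after the seed {19, 20}), removal order 1, 2, ..., 18.

## Concordance (`itemselect.concordance`)

Kendall's tau between a produced ordering and the ideal one is computed by
pair enumeration, `tau = (C - D) / (n(n-1)/2)`; orderings are strict
permutations, so no tie corrections are applied.  Agreement across
replications uses Kendall's `W = 12 S / (m^2 (n^3 - n))`.

Two conventions require care:

- A sample top-down run may remove items the ideal run keeps.  For
  comparisons its ordering is restricted to the reference item set, with
  surviving reference items appended last (they outlasted every removed
  item), ordered by their final-step criterion.
- Cross-replication concordance of bottom-up runs is computed over the
  complete 20-step addition order, the seeded pair occupying steps 1–2;
  top-down concordance uses the 18 removal steps.  Including the fixed seed
  steps raises bottom-up W relative to an 18-step convention because two
  objects are perfectly concordant by construction; it reflects the view
  that the seeded items are part of the addition order a practitioner
  would report.  Kendall's tau against the ideal ordering always uses the
  18 free selection steps.

## Simulation study (`itemselect.study`)

Six cells: N in {200, 1000} crossed with three discrimination spreads.
Each bank has 20 items with locations 0 and discriminations `exp` of an
equidistant 20-point grid on [-0.5, 0.5] (small), [-1, 1] (average) or
[-2, 2] (large); each bank's geometric-median discrimination is exactly 1.
Locations are held at 0 so that discrimination, the parameter that
reliability tracks, is the only varying item property — note this makes all
population popularities equal (1/2), the hardest regime for the MS
popularity ordering.  Latent traits are standard normal; item scores are
conditionally independent Bernoulli draws.

Per replication one data set is generated and analysed by all method x
procedure combinations; bottom-up runs are seeded with the ideal pair
{19, 20} so that all compared orderings range over the same 18 items.
1000 replications per cell (the default `Design`), seeded as
`SeedSequence(base_seed, cell_index, N, replication)` so cells are
reproducible in any execution order.  Outputs per cell: per-combination
tau values (mean, sd), W, per-step 2.5/50/97.5 percentile bands of the
population reliability of the produced subtests, and counters of estimator
fallbacks/clamps.  `run_study` assembles the mean-tau and W tables and the
trajectory bands as CSVs.

What the generator does *not* emulate: multidimensional traits, varying
item locations, guessing, missing data, or polytomous items.  Passing
tests therefore certify the estimators and procedures under a
unidimensional 2PL world with equally difficult items; behaviour under
location spread or model violation is untested here.

## Numerical and degenerate-input choices

- Sample variances and covariances use the N-1 denominator throughout.
- A constant item column makes CITC/MS undefined and raises
  `UndefinedValueError` (at the study's sample sizes a constant column has
  probability ~2^-199 and is treated as an error, never silently resampled).
- Exactly collinear columns raise `SingularCovarianceError` for lambda-6.
- `alpha_rest <= 0` makes CA undefined (incoherent rest score) and raises.
- Selection propagates estimator errors with step context; replications
  are never dropped silently.

## Known limitations

- The MS neighbour construction follows this package's documented rules;
  published descriptions of the Molenaar–Sijtsma approximation leave the
  treatment of extreme and tied items to implementations, and other
  software may differ in those details.  Simulation summaries involving MS
  are correspondingly less portable across implementations than the
  algebraically-defined CA/lambda-6/CITC results.
- Greedy one-step selection is irreversible; no re-entry variant is
  provided.  No stopping rules are applied — runs always complete, and
  consumers may truncate traces at a target length or reliability.
- Standard errors for the estimators are out of scope.
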