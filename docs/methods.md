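# Methods

## The problem

In a two-condition cultural-transmission experiment, each participant learns
two alternative strategies for the same task — one demonstrated by an expert,
one by a peer, in counterbalanced order and content — and then passes exactly
one of them on, either by teaching a novice (the expert-to-novice context) or
by showing a peer (the peer-to-peer context). The observed data are production
counts per condition. The scientific question is the strength of three forces
on that choice: a model-based (prestige/expert) bias, a context-congruence
bias (a preference for the variant learned in a context matching the current
transmission context), and an order (primacy/recency) bias.

## The choice model

Each bias is a number in [-1, 1]; 0 is neutral. Each bias `b` maps affinely to
a weight `w(b) = (1 + b) / 2` in [0, 1]. A variant's unnormalized production
weight is a product of three factors:

- source factor: `w(ExpertBias)` for the expert's variant, `1 - w(ExpertBias)`
  for the peer's;
- congruence factor: `w(CongruentBias)` if the variant's source matches the
  context's congruent source (expert in expert-to-novice, peer in
  peer-to-peer), else its complement;
- order factor: `w(PrimacyBias)` for the last-learned variant, else its
  complement. Note the sign convention is literal here: a *positive*
  `PrimacyBias` favours the *last*-learned variant; `RecencyBias` is its
  negation.

The produced variant is drawn by the Luce choice rule — probability
proportional to weight. When both weights are exactly zero (a measure-zero
corner of the parameter cube, e.g. a maximal expert bias against a maximal
congruence bias in the peer-to-peer context) the probability is defined as
1/2. At a neutral primacy bias the order factor is 1/2 for both variants and
cancels under normalization, so the three-parameter model reduces exactly to
the two-parameter one.

This multiplicative-weight-plus-normalization construction is this package's
resolution of an underdetermined published description in which per-variant
"probabilities" were raw products of biases: those products can be negative
and do not sum to one across the two variants. The affine map preserves the
sign semantics (0 = no bias), the normalization makes the pair of
probabilities coherent, and the resulting model reproduces the published
bias-magnitude estimates within the stated tolerance, which is the evidence
that this is the intended model family.

Useful algebraic identities (all tested to 1e-12): the two complementary
production probabilities sum to one; negating the expert bias exchanges the
roles of expert and peer across contexts; negating the congruence bias is
equivalent to swapping the transmission context (equivalently, the congruent
variant under `-cb` behaves like the incongruent variant under `cb` with the
expert bias also negated); the expert-variant probability is non-decreasing
in the expert bias.

## Simulation

One simulated experiment draws one produced variant per participant (30
expert-to-novice and 32 peer-to-peer by default — the post-exclusion cohort;
the pre-exclusion 32/32 design is a constructor argument away). With a
neutral primacy bias the per-condition expert count is Binomial(n, p) with p
from the choice model, so the batch simulator draws counts directly from the
binomial law per order stratum; a per-participant path exists and is tested
to be distributionally indistinguishable (chi-squared homogeneity of count
histograms at 5000 replicates). Order counterbalancing splits each condition
half and half into expert-variant-learned-first and -last strata, with an odd
condition size placing the extra participant in the first-learned stratum,
deterministically.

Reproducibility contract: grid cell `i` (row-major) always consumes the RNG
substream derived from `(seed, i)` via numpy `SeedSequence` spawn keys, so
results are bit-identical regardless of chunking or execution order.

## Estimation

The estimator is grid-search rejection (a lattice ABC with a 0/1 kernel):
for every lattice cell, simulate S experiments and count those whose count
table matches the observed table cell-for-cell within an integer tolerance.
Defaults follow the study: two-parameter runs use a -1..1 lattice in steps of
0.01 (201 x 201 cells, both endpoints included), S = 5000 and exact matching;
three-parameter runs use steps 0.1/0.1/0.05 and a +/-1 tolerance on each of
the eight context x source x order cells (exact eight-cell coincidences are
too rare to count).

The *match distribution* of a parameter is the multiset holding, for every
matching run, that run's parameter value; its size is the total match count.
Summaries (mean, SD, one-sample t against 0, pairwise two-sample t) are
computed from the weighted moments of this multiset in closed form —
materializing ~150k values would add nothing. The two-sample comparison is
Welch by default with a pooled-variance option; degrees of freedom are
reported alongside, since the multiset-vs-cell-weight reading of "match
distribution" changes df but not means. Fewer than two matches raises an
explicit error rather than returning silent zeros.

## The exact oracle

Because per-stratum expert counts are binomial, the probability that one
simulation matches the observed table is a closed-form product over
conditions (and order strata) of binomial mass on the tolerated count
window; in the eight-cell layout each stratum's count is constrained by two
cells at once, so the window is an intersection of two intervals. Summing
parameter values against these probabilities over the lattice gives the
exact infinite-simulation limit of the Monte-Carlo summary. The oracle
refuses (with an explicit error) the one combination it does not model
exactly — a four-cell table under a non-neutral primacy bias, where the
expert count is a convolution across strata — rather than returning an
approximation.

The oracle and the Monte-Carlo path are verified against each other two
ways: per-cell match rates within 3 binomial SEs at 20 random cells, and
match-weighted means within 3 Monte-Carlo SEs at full scale. The oracle
itself is verified independently by brute-force enumeration over the
stratum-count lattice (eight-cell case) and by pmf completeness: summing the
exact-match probability over every observable four-cell table equals 1.

On the experiment's counts (27/3 and 14/18), the full-scale run gives
match-weighted means of about 0.433 (expert bias) and 0.528 (congruence
bias); the exact weighted means are 0.4322 and 0.5273. The congruence bias
exceeds the expert bias, and roughly 150k of the one billion simulated
experiments match exactly.

## Count statistics

The planned hypothesis tests are equal-expectation goodness-of-fit
chi-squared tests (statistic `(a-b)^2/(a+b)` on 1 df, delegated to scipy and
cross-checked against the closed form) at a Bonferroni-corrected threshold
0.05/3 = 0.0167, plus chi-squared independence tests of the produced variant
against the two counterbalanced order factors (Yates correction off by
default; the published goodness-of-fit values are reproduced exactly without
it, and the printed independence statistics cannot be checked because their
2x2 tables were not published).

## Synthetic cohorts

The generator emulates the design's statistical structure: two conditions,
the four (learning order x strategy order) cells exactly balanced per
condition (hence cohort sizes divisible by 4), the expert's taught content
implied by the two order factors, production drawn from the choice model at
known true biases, and optional exclusions flagged completely at random
within the expert-to-novice condition (the real exclusions were
questionnaire-based — suspicion of confederates — which no generative model
here attempts; random flagging is the neutral emulation). It does not
emulate demographics, dialogue, learning failure, or any content-dependent
behaviour: variants are opaque labels. Passing recovery tests therefore show
that the *estimator* is consistent with the *model*, not that the model
captures everything in real participants.

Parameter recovery is assessed at true biases (0.4, 0.5, 0) with 32
participants per condition over 20 replicate cohorts, estimated on the
0.01-step grid via the exact weighted moments (the infinite-simulation limit
of the stochastic estimator, which is additionally run in full on one cohort
and checked to agree within 3 Monte-Carlo SEs). Mean recovered means land
within 0.1 of the truth; with only 62-ish observations per cohort the
estimator shows the expected mild shrinkage toward 0, and the 0.1-wide
ordering of the two biases is recovered in a majority, not all, of cohorts.

## Numerical choices

- Probabilities from the normalized weight ratio are clipped to [0, 1]:
  `(1+b)/2` arithmetic can overshoot 1 by ~1e-13 at the lattice edge, and
  scipy's binomial pmf returns NaN for p marginally above 1.
- Lattice axes are built with `linspace` (inclusive endpoints; 201 points at
  step 0.01) and clipped to the cube to absorb ulp-level overshoot.
- Weighted SDs use the n-1 (sample) convention to agree with the explicit
  multiset expansion; the oracle's SDs are population SDs of a continuous
  weighting, where the distinction vanishes.
- Simulation sizes in tests mirror the study scale (S = 5000, step 0.01)
  where the claim being tested depends on it; coarser lattices are used
  where only mechanics are under test.

## Known limitations

- The three-parameter analysis of the published study summarized an
  eight-cell supplementary count table that is not reproduced here; the
  machinery (eight-cell layout, tolerance-1 matching, 0.1/0.1/0.05 lattice)
  is fully implemented and verified on synthetic data instead.
- The published t statistics on match distributions depend on the authors'
  realized match multiset (their unnormalized model admits far fewer
  matches) and are computed but not asserted against.
- The rejection estimator's summaries inherit the implicit uniform lattice
  prior; they are descriptive fits, not posterior means under a stated
  prior.
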