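# Methods

This note documents the models, conventions, numerical choices, and known
limitations of `coopsim`, in the spirit of a model-description appendix.

## Game structure variables

A repeated Prisoner's Dilemma design is reduced to nine variables. The
payoff table (R, S, T, P) — reward, sucker, temptation, punishment, with
T > R > P > S and R > (S+T)/2 — enters only through the normalized indices
r1 = (R−P)/(T−S) and r2 = (R−S)/(T−S). Both are invariant to positive
affine rescaling of payoffs, which is what makes experiments run in
different currencies comparable; r1 is the classical "cooperativeness"
index, r2 measures how much a cooperator gains from the opponent
cooperating rather than defecting. Under the PD ordering, 0 < r1 < r2 < 1
and r1 < r2 always.

The continuation probability δ has a dual reading. In indefinitely
repeated games it is the literal per-period continuation probability; for
fixed-length games the package assigns δ = 1 − 1/L from the expected-length
identity E[len] = 1/(1−δ), so a ten-period game has δ = 0.9 and a
two-period game δ = 0.5. This puts both designs on a common "rational
expectation of game length" scale. `error` ∈ [0, 0.5] is the probability a
chosen action is flipped before implementation; `infinite`, `continuous`,
and `risk` are 0/1 design flags. Continuous-time designs are represented on
their discrete subperiod grid (the experimental grid treatment with 8
subperiods), so they simulate as ordinary finite games; `risk` enters only
as an indicator because the risky experiments' expected payoffs constitute
the payoff structure.

The 30 published game structures of the combined experimental literature
are embedded as fixtures with their observed cooperation rates attached as
metadata.

## The two-part choice model

First-period play and later play are modeled separately, because
first-period decisions can depend only on the design, while later decisions
are dominated by the history of the interaction:

- static (t = 1, 10 coefficients):
  `1, r1, r2, risk, error, δ, r1·δ, r2·δ, infinite, continuous`
- dynamic (t > 1, 15 coefficients): the static terms plus
  `δ·infinite, my_prev, other_prev, error·other_prev, t`

The δ·infinite interaction lets δ act differently when it actually governs
termination; error·other_prev captures that a noisily implemented opponent
action is a less reliable signal; t is untransformed (a linear log-odds
time trend). Actions are coded cooperate = 1, periods are 1-based, and lag
columns are always derived from the action stream at load time — input
files never supply them.

Both components are fit by plain (unpenalized) maximum likelihood via
statsmodels' Newton IRLS, tolerance 1e-8 on the log-likelihood change, at
most 100 iterations, with observed-information standard errors. Perfect
separation — possible in small training folds — is detected and handled by
a clearly flagged ridge-penalized fallback (α = 1e-3 on the squared
coefficient norm, standard errors from the penalized Hessian), keeping
every fold's fit finite. Rank-deficient designs raise an error naming the
offending columns; note that the dynamic component has 11 structure-level
columns, so identification requires at least 12 distinct game structures in
training. Variable importance is |coefficient/SE| per feature. Accuracy
discretizes at 0.5 with ties counted as defect, so the rule is
deterministic.

Comparison variants: *static-only* applies the static component at every
period; *dynamic-only* applies the dynamic component at every period,
imputing the missing first-period lags from Bernoulli(0.5) draws
(approximately the overall cooperation split; "period-zero mutual
cooperation" is available as an alternative); *baseline* predicts the
training-set mean cooperation rate everywhere.

## The fEWA learning baseline

The experience-weighted attraction comparator keeps per-strategy
attractions A_C, A_D updated each period as

    A_j(t) = [φ N(t−1) A_j(t−1) + (δ_j + (1−δ_j)·1{j chosen}) π(j, s_opp)]
             / (N(t−1) φ + 1),        N(t) = φ N(t−1) + 1,

with A_j(0) = 0 and N(0) = 1 (neutral prior). The self-tuning functional
forms are used: φ = 1 − S/2 where the surprise index S is the squared
deviation between the opponent's most recent action vector and their
cumulative frequency vector (window 1), and the attention weight δ_j is 1
iff strategy j's foregone payoff is at least the realized payoff. These
forms are the canonical self-tuning parameterization and are a documented
approximation — the source literature's exact appendix forms are not
reproduced here. Payoffs are normalized to (π−S)/(T−S) ∈ [0, 1] before
updates so the single free parameter λ (softmax sensitivity) is comparable
across experiments; conveniently the normalized payoff matrix is
(T', R', P', S') = (1, r2, r2−r1, 0), a function of the indices alone, so
fEWA runs on structures without raw payoff records. λ is fit by a
deterministic bounded 1-D likelihood search over [0, 50]: attraction states
are λ-free, so they are rolled forward once through the observed histories
and the Bernoulli likelihood is maximized over λ.

Because defection weakly dominates within a period, payoff reinforcement
pushes A_D ≥ A_C, and on strongly cooperative data the fitted λ shrinks
toward 0 (predicting near-0.5); this is the known reason fEWA underperforms
structure-aware models at first-period prediction.

## Simulator

`simulate_structure` plays n_pairs independent paired interactions.
Interaction length is a capped geometric draw (continue with probability δ;
cap 38 periods, the longest observed real interaction) for indefinite
games, and exactly round(1/(1−δ)) for finite ones. Each period both agents
draw *intended* actions from their policy; implementation error flips each
with probability `error`. Lag semantics are asymmetric by design: an
agent's own lag is its intended action (players know what they chose), the
opponent's lag is the implemented action (players see only what happened).
Cooperation is scored on intended actions — the decision, which is what
experiments record — while implemented actions drive observation. Whether
real subjects' own re-fed lags were intended or implemented is not
observable from published data; this asymmetric choice is a documented
assumption, and the generator below deliberately overrides it.

Defaults: n_pairs = 1000 (Monte Carlo error on proportions < 0.02), seeded
`numpy` Generator, identical seeds give identical runs. The
`first_period_override` option exogenously forces every agent's period-1
cooperation probability, which is how the forced-first-period
counterfactuals are run.

Reporting horizon for trajectory comparison: 8 periods by default, 7 for
indefinite games with δ = 0.5 (expected length two — data beyond period
seven is too thin), and the true fixed length for finite games shorter than
eight. Applied to the 30 published structures this yields 215
structure-period comparison points, versus the 212 reported in the source
literature; the package surfaces its point count in every report rather
than forcing agreement.

## Validation harness

The cross-validation unit is the game structure: a model must predict a
design it never saw. Individual-level validation conditions on the
empirically observed lags of the held-out structure and scores
probabilities by accuracy and Bernoulli log-likelihood (clipped at 1e-12),
per structure and pooled; aggregate-level validation passes *only the
structure* to the simulator and compares simulated against observed
per-period cooperation (pooled time-series RMSE and Pearson correlation)
and overall means (one point per structure). k-fold sweeps repeat the
aggregate procedure for k from the number of structures down to 2 with
seeded random fold assignments.

Paired model comparisons report the classical paired-differences t-test
*and* a Welch two-sample variant: the procedure stated in the source
literature ("paired sample t-tests, not assuming equal variances") is
internally tensioned — a paired test operates on differences and has no
equal-variance assumption to drop — so both readings are provided.

## Sensitivity analysis

Hypothetical designs are drawn by Latin hypercube sampling with marginals
error ~ U(0, 0.5), δ ~ U(0.45, 0.95), r1, r2 ~ U(0, 1) constrained to
r1 < r2, and infinite, risk ~ Bernoulli(0.5) outside the stratification;
`continuous` is fixed at 0, its empirical mode. Note a mathematical point
about the constraint: conditioning two uniforms on r1 < r2 makes the
marginals the *order statistics* of a uniform pair (means 1/3 and 2/3),
and exact one-draw-per-stratum on both coordinates under a pointwise
ordering would force both variables into the same stratum in every row.
The implementation therefore swaps infeasible stratum pairs and redraws
within strata — realizing the conditional distribution exactly while
keeping r1/r2 stratification approximate (error and δ remain exactly
stratified).

Each sampled design is simulated under the fitted model; the output is
overall mean cooperation across the simulated horizon (termination rules as
above; the ensemble horizon is otherwise unstated in the source and follows
the simulator's standard rules). PRCC is computed by rank-transforming all
columns and correlating the residuals of each input and of the output after
regressing both on the remaining inputs (residual regressions, robust to a
degenerate input that perfectly determines the output); percentile
bootstrap 95% intervals use 1000 resamples by default. SRRC (standardized
rank regression coefficients) is available as a secondary statistic and
agrees in sign with PRCC on well-behaved ensembles.

Inertia — cooperation given own-lag cooperation — is computed from data as
a per-structure count ratio (missing, with a warning, when a structure
never shows lagged cooperation) and from the model as the dynamic
prediction with my_prev = 1 averaged over the structure's empirical
(t, other_prev) distribution, marginalizing out time and the opponent.

## Synthetic ground truth

The generator draws structures with the LHS sampler (with `continuous`
varied at Bernoulli(0.5) rather than fixed at 0 — otherwise that
coefficient's column is identically zero and inestimable) and plays them
with agents that *are* the two-part model at known weights, recording
intended actions. One deliberate deviation from the simulator's default lag
semantics: the generator feeds agents the opponent's *intended* action as
the lag. The fitter derives lags from recorded actions (intended), so with
implemented-action lags under error up to 0.5 the regressors would be
mismeasured and the history coefficients attenuated by roughly (1−2·error)
— parameter recovery would fail for reasons unrelated to the fitter.
Matching the generator's information set to the recorded data makes
full-circle recovery well-posed.

Default weights are calibrated once to the aggregate conditions of the
combined experimental literature: pooled cooperation ≈ 0.40 (the published
structure-mean is ≈ 0.41), a first-period cooperation split near one half,
declining-then-stabilizing trajectories, pooled cooperation increasing in δ
holding payoffs fixed, and a strongly positive δ sensitivity. The dominant
coefficient is the own previous action (+2.8), followed by the opponent's
(+1.6); error and risk are negative; the time trend is a mild −0.06 per
period. Default scale is 30 structures × 50 pairs (≈ 15k decisions):
large enough for 3-SE parameter recovery, small enough for seconds-scale
tests. Synthetic payoff quadruples invert the indices with T = 1, S = 0,
R = r2, P = r2 − r1, attached only when they satisfy the strict PD
conditions (which requires r2 > 1/2).

What the generator does *not* emulate: subject-level heterogeneity,
session and learning-across-interaction effects, population rematching, and
any deviation of real behavior from the logistic functional form. Passing
tests on synthetic data therefore demonstrate the correctness and
self-consistency of the pipeline — recovery, ranking, sensitivity
directions — not the empirical adequacy of the model for human data, which
requires the real combined dataset.

A note on identifiability: r1 and r1·δ are ≈ 0.98 collinear over
δ ∈ [0.45, 0.95], so their individual coefficients (unlike their sum) are
weakly identified at any realistic sample size; recovery is asserted in
standard-error units, and sign recovery only for effects larger than two
standard errors.

## Known limitations

- The fEWA functional forms approximate the canonical self-tuning
  parameterization; the full parametric EWA with free (φ, δ, ρ, N(0)) is
  out of scope.
- The model pools all subjects; no hierarchical or random-effects
  extensions.
- Only fixed-partner matching is simulated: no rematching protocols,
  evolutionary dynamics, or network structure.
- Aggregate validation metrics on the 30 published designs require the
  combined decision-level dataset, which is not redistributed here; the
  reader/dialect layer accepts it directly once obtained.
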