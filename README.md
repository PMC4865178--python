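# coopsim

Predictive modeling and agent-based simulation of human cooperation in
repeated Prisoner's Dilemma experiments.

Behavioral experiments on the repeated Prisoner's Dilemma show that people
often cooperate, but how much — and how cooperation evolves over the
periods of an interaction — depends strongly on the *institutional design*:
the payoff table, the continuation probability, whether repetition is
indefinite, whether choices are implemented noisily, whether payoffs are
risky. `coopsim` is a library and command-line tool for researchers who
want to fit an individual-level choice model to decision data pooled across
such experiments, forecast behavior in *new* game designs from structure
alone, and ask which design levers move cooperation most.

## The model

A game structure is summarized by nine variables: the normalized payoff
indices

    r1 = (R − P) / (T − S),    r2 = (R − S) / (T − S),

the continuation probability δ (for fixed-length games assigned by the
expected-length convention E[len] = 1/(1−δ), so a ten-period game has
δ = 0.9), the implementation-error probability, and indicator flags for
indefinite repetition, continuous-time play, and payoff risk.

The choice model is piecewise-logistic in these features:

    p(C_t) = σ(w_s · X_static)                   t = 1
    p(C_t) = σ(w_d · X_dynamic)                  t > 1

where σ(z) = 1/(1+e^(−z)). The static design (10 terms) is
`1, r1, r2, risk, error, δ, r1·δ, r2·δ, infinite, continuous`; the dynamic
design adds `δ·infinite`, both players' previous actions, an
`error × other_prev` interaction (noisy observation of the opponent), and
the period index `t` (15 terms). Both components are fit by plain maximum
likelihood.

Around this core the package provides:

- **Comparison variants** — static-only, dynamic-only (with first-period
  lag imputation), a constant-rate baseline, and a self-tuning
  experience-weighted attraction (fEWA) learner with a fitted softmax
  sensitivity λ.
- **An agent-based simulator** that plays out interactions from a game
  structure and any of these policies: geometric termination for indefinite
  games, implementation error, lagged-action feedback, and an exogenous
  first-period override for counterfactual experiments.
- **A multi-scale validation harness** where the held-out unit is an entire
  game structure: individual-decision prediction (conditioning on observed
  history), aggregate trajectory forecasting (conditioning on structure
  only), k-fold robustness sweeps, and paired t-test comparisons.
- **Global sensitivity analysis** — Latin hypercube sampling over the
  feasible design space (with the empirical constraint r1 < r2), partial
  rank correlation coefficients with bootstrap confidence intervals, and
  SRRC as a secondary statistic — plus per-structure "inertia" analyses
  (cooperation after cooperating).
- **A ground-truth synthetic data generator** reproducing the data
  hierarchy (structures → paired interactions → periods → simultaneous
  actions), so every stage is testable end to end, and the 30 published
  game structures of the combined experimental literature as built-in
  fixtures (`table2_fixtures()`).

## Worked example

Generate a synthetic study (30 structures, 50 pairs each), fit the model,
and cross-validate it structure-by-structure:

```sh
$ coopsim synth --seed 7 --out-dir data
INFO coopsim: wrote 14532 decisions for 30 structures

$ coopsim fit --decisions data/decisions.csv --structures data/structures.csv --out-dir model
INFO coopsim: fit static (3000 obs) and dynamic (11532 obs) components

$ head -4 model/importance.csv
variable,importance
my_prev,46.85787203675601
other_prev,10.575061976338654
t,6.20950027252977

$ coopsim validate-individual --decisions data/decisions.csv \
      --structures data/structures.csv --out-dir vi --seed 1
INFO coopsim: accuracy t=1 0.624, t>1 0.835
```

Reading the output: the importance scores are |coefficient/SE| for the
dynamic component — a player's *own previous action* dominates everything
else, i.e. cooperation is strongly self-reinforcing. The validation
accuracies are averages over 30 rounds of leave-one-structure-out
prediction: first-period actions (structure information only) are predicted
at 62%, later actions (structure plus observed history) at 84% — each time
for a game design the model never saw during fitting. `vi/summary.json`
also reports the held-out log-likelihoods, and `vi/predictions.csv` the
per-decision probabilities.

Other subcommands: `validate-aggregate` (simulation forecasts of
cooperation trajectories vs observed), `kfold-sweep`, `simulate` (play any
of the 30 built-in structures under a fitted model), `sensitivity`
(LHS + PRCC), and `inertia`. Every run writes a `manifest.json` with the
full configuration, seed, and library versions.

## Data format

Decision tables are CSV with columns `structure_id, interaction_id,
player_id, period, action` (1 = cooperate); lagged-action columns are
always derived from the action stream, never read. Structure tables are
CSV with the nine design variables (and optionally raw `R,S,T,P` payoffs,
validated against the Prisoner's Dilemma ordering T > R > P > S,
R > (S+T)/2). Arbitrary column names are supported through a small YAML/JSON
dialect mapping. See `docs/methods.md` for the scientific details and
modeling assumptions.
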