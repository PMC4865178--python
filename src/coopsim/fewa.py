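"""Self-tuning (functional) experience-weighted attraction learning.

fEWA is the standard behavioral-game-theory comparator for out-of-sample
forecasting.  Each agent keeps a numerical attraction A_j for each strategy
j in {C, D}; after every period both attractions are updated from the
realized payoff and, for the unchosen strategy, the foregone payoff when an
attention condition holds.  Attractions map to choice probabilities through a
logistic (softmax) response with a single free sensitivity parameter lambda,
fit to training data by maximum likelihood.

Functional forms (self-tuning EWA):

* decay / change detection: ``phi = 1 - S/2`` where the surprise index S is
  the squared deviation between the opponent's most recent action vector and
  the cumulative-history frequency vector; a stable opponent gives phi near
  1 (long memory), a shifting opponent gives phi near 0 (fast discounting).
* attention to foregone payoffs: ``delta_j = 1`` iff the foregone payoff of
  strategy j is at least the realized payoff, else 0.
* experience weight: ``N(t) = phi * N(t-1) + 1``, with N(0) = 1 and
  A_j(0) = 0 (neutral prior).

Payoffs are normalized to (pi - S)/(T - S) in [0, 1] before updates, so the
fitted lambda is comparable across experiments run in different currencies;
conveniently this makes the payoff matrix (1, r2, r2 - r1, 0) a function of
the structure's normalized indices alone, so fEWA runs even on structures
that carry no raw payoff quadruple.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.optimize
from scipy.special import expit

from .behavior import Policy
from .core import Dataset, GameStructure, pivot_interactions

__all__ = [
    "FewaState",
    "normalized_payoffs",
    "update",
    "choice_probabilities",
    "fit_lambda",
    "FewaPolicy",
]

#: lambda search interval (inverse normalized-payoff units)
LAMBDA_BOUNDS = (0.0, 50.0)


def normalized_payoffs(g: GameStructure) -> tuple[float, float, float, float]:
    """Normalized (R', S', T', P') = ((pi-S)/(T-S)) payoff quadruple.

    Equal to (r2, 0, 1, r2 - r1) by the definition of the payoff indices.
    """
    if g.payoffs is not None:
        R, S, T, P = g.payoffs
        d = T - S
        return ((R - S) / d, 0.0, 1.0, (P - S) / d)
    return (g.r2, 0.0, 1.0, g.r2 - g.r1)


@dataclass(frozen=True)
class FewaState:
    """Per-agent fEWA state: attractions, experience weight, sensitivity,
    and the opponent-history counts the functional forms need."""

    a_c: float = 0.0
    a_d: float = 0.0
    n: float = 1.0
    lam: float = 1.0
    opp_coop: float = 0.0   # opponent cooperations observed so far
    opp_seen: float = 0.0   # opponent actions observed so far


def _payoff_pair(g: GameStructure, opp_action) -> tuple:
    """Normalized payoffs of (C, D) against the opponent's action."""
    R, S, T, P = normalized_payoffs(g)
    opp = np.asarray(opp_action, dtype=float)
    pi_c = np.where(opp == 1, R, S)
    pi_d = np.where(opp == 1, T, P)
    return pi_c, pi_d


def update(
    state: FewaState, my_action: int, opp_action: int, payoffs=None, g=None
) -> FewaState:
    """One attraction update after observing a period's joint outcome.

    *payoffs* is a raw (R, S, T, P) quadruple (normalized internally);
    alternatively pass the :class:`GameStructure` *g* and the normalized
    matrix is derived from its payoff indices.
    """
    if g is None:
        if payoffs is None:
            raise ValueError("provide either payoffs or a GameStructure")
        R, S, T, P = payoffs
        g = _Payoffs(R, S, T, P)
    pi_c, pi_d = _payoff_pair(g, opp_action)
    pi_c, pi_d = float(pi_c), float(pi_d)

    opp_coop = state.opp_coop + (1.0 if opp_action == 1 else 0.0)
    opp_seen = state.opp_seen + 1.0
    h = opp_coop / opp_seen
    surprise = 2.0 * (h - float(opp_action)) ** 2
    phi = 1.0 - 0.5 * surprise

    realized = pi_c if my_action == 1 else pi_d
    att_c = 1.0 if pi_c >= realized else 0.0
    att_d = 1.0 if pi_d >= realized else 0.0
    reinf_c = (att_c + (1.0 - att_c) * (1.0 if my_action == 1 else 0.0)) * pi_c
    reinf_d = (att_d + (1.0 - att_d) * (1.0 if my_action == 0 else 0.0)) * pi_d

    denom = state.n * phi + 1.0
    return replace(
        state,
        a_c=(phi * state.n * state.a_c + reinf_c) / denom,
        a_d=(phi * state.n * state.a_d + reinf_d) / denom,
        n=phi * state.n + 1.0,
        opp_coop=opp_coop,
        opp_seen=opp_seen,
    )


class _Payoffs:
    """Minimal payoff carrier for the scalar update API."""

    def __init__(self, R, S, T, P):
        self.payoffs = (R, S, T, P)
        d = T - S
        self.r1, self.r2 = (R - P) / d, (R - S) / d


def choice_probabilities(state: FewaState) -> float:
    """Softmax probability of cooperating given the current attractions."""
    return float(expit(state.lam * (state.a_c - state.a_d)))


# ------------------------------------------------------------ vector policy

class FewaPolicy(Policy):
    """fEWA as a vectorized playing/predicting agent."""

    name = "fewa"

    def __init__(self, lam: float):
        if lam < 0:
            raise ValueError("lambda must be nonnegative")
        self.lam = lam

    def start(self, g, n, rng):
        return {
            "a_c": np.zeros(n),
            "a_d": np.zeros(n),
            "n": np.ones(n),
            "opp_coop": np.zeros(n),
            "opp_seen": np.zeros(n),
        }

    def prob(self, g, state, t, my_prev, other_prev, n):
        return expit(self.lam * (state["a_c"] - state["a_d"]))

    def observe(self, g, state, my_action, opp_action, mask=None):
        my = np.asarray(my_action, dtype=float)
        opp = np.asarray(opp_action, dtype=float)
        if mask is None:
            mask = np.isfinite(my) & np.isfinite(opp)
        if not mask.any():
            return
        my, opp = np.where(mask, my, 0.0), np.where(mask, opp, 0.0)
        pi_c, pi_d = _payoff_pair(g, opp)

        opp_coop = state["opp_coop"] + np.where(mask, opp, 0.0)
        opp_seen = state["opp_seen"] + mask
        with np.errstate(invalid="ignore"):
            h = np.where(opp_seen > 0, opp_coop / np.maximum(opp_seen, 1.0), 0.0)
        phi = 1.0 - (h - opp) ** 2  # = 1 - S/2 with window-1 surprise

        realized = np.where(my == 1, pi_c, pi_d)
        att_c = (pi_c >= realized).astype(float)
        att_d = (pi_d >= realized).astype(float)
        reinf_c = (att_c + (1 - att_c) * (my == 1)) * pi_c
        reinf_d = (att_d + (1 - att_d) * (my == 0)) * pi_d

        denom = state["n"] * phi + 1.0
        new_ac = (phi * state["n"] * state["a_c"] + reinf_c) / denom
        new_ad = (phi * state["n"] * state["a_d"] + reinf_d) / denom
        new_n = phi * state["n"] + 1.0

        state["a_c"] = np.where(mask, new_ac, state["a_c"])
        state["a_d"] = np.where(mask, new_ad, state["a_d"])
        state["n"] = np.where(mask, new_n, state["n"])
        state["opp_coop"] = opp_coop
        state["opp_seen"] = opp_seen


# --------------------------------------------------------------- lambda fit

def attraction_diffs(ds: Dataset) -> tuple[np.ndarray, np.ndarray]:
    """Replay every interaction and collect (A_C - A_D, observed action)
    pairs, each attraction difference taken *before* the decision it
    predicts.  The differences do not depend on lambda, so the lambda
    likelihood is a cheap 1-D function of this fixed array."""
    policy = FewaPolicy(lam=1.0)
    rng = np.random.default_rng(0)
    diffs, acts = [], []
    for sid, sub in ds.records.groupby("structure_id", sort=True):
        g = ds.structures[sid]
        _, _, actions = pivot_interactions(sub)
        n_inter, t_max = actions.shape[1], actions.shape[2]
        states = [policy.start(g, n_inter, rng) for _ in range(2)]
        for t in range(t_max):
            alive = np.isfinite(actions[0, :, t])
            for slot in range(2):
                st = states[slot]
                d = st["a_c"][alive] - st["a_d"][alive]
                diffs.append(d)
                acts.append(actions[slot, alive, t])
            for slot in range(2):
                policy.observe(
                    g, states[slot], actions[slot, :, t], actions[1 - slot, :, t]
                )
    return np.concatenate(diffs), np.concatenate(acts)


def fit_lambda(train: Dataset, bounds: tuple[float, float] = LAMBDA_BOUNDS) -> float:
    """Maximum-likelihood response sensitivity on forward-simulated attractions.

    A deterministic 1-D bounded search: attraction states are rolled forward
    through the observed histories, then lambda maximizes the Bernoulli
    log-likelihood of the observed actions under the softmax response.
    """
    d, y = attraction_diffs(train)
    sign = np.where(y == 1, 1.0, -1.0)

    def negll(lam):
        return np.logaddexp(0.0, -lam * sign * d).sum()

    res = scipy.optimize.minimize_scalar(
        negll, bounds=bounds, method="bounded", options={"xatol": 1e-6}
    )
    lam = float(res.x)
    # the optimizer never evaluates exactly at the boundary; keep dominance over lam=0
    if negll(lam) > negll(bounds[0]):
        lam = float(bounds[0])
    return lam
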