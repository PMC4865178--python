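"""Ground-truth synthetic data generator.

Emulates the hierarchy of the combined experimental data — game structures,
paired interactions, periods, simultaneous binary actions — with agents that
*are* the two-part logistic model at known weights.  Because the generating
process matches the fitted model family, the full pipeline (read, fit,
cross-validate, simulate, sensitivity) is testable end to end without any
external data, and parameter recovery has a well-defined truth.

Structures are drawn by the sensitivity module's Latin hypercube sampler
(with the continuous flag varied, unlike the sensitivity default, so every
static coefficient is estimable) and played by the simulator.  The generator
feeds each agent the opponent's *intended* action as the lag, so the
histories agents condition on coincide with the lag columns a fitter derives
from the recorded action stream; see docs/methods.md for why recovery
requires this.  Synthetic payoff quadruples invert (r1, r2) with T = 1,
S = 0, R = r2, P = r2 - r1 and are attached only when they satisfy the
strict Prisoner's Dilemma conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .behavior import FullModel, FullModelPolicy, ModelWeights
from .core import Dataset, GameStructure
from .features import DYNAMIC_FEATURES, STATIC_FEATURES
from .sensitivity import lhs_sample
from .simulate import SimulationConfig, simulate_records

__all__ = ["GroundTruth", "default_ground_truth", "generate", "weights_as_model"]

_EPS = 1e-9


@dataclass(frozen=True)
class GroundTruth:
    """True coefficient vectors and the scale of the synthetic study."""

    static_weights: np.ndarray
    dynamic_weights: np.ndarray
    n_structures: int = 30
    pairs_per_structure: int = 50
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "static_weights", np.asarray(self.static_weights, dtype=float)
        )
        object.__setattr__(
            self, "dynamic_weights", np.asarray(self.dynamic_weights, dtype=float)
        )
        if len(self.static_weights) != len(STATIC_FEATURES):
            raise ValueError("static weights must match the static feature schema")
        if len(self.dynamic_weights) != len(DYNAMIC_FEATURES):
            raise ValueError("dynamic weights must match the dynamic feature schema")


def default_ground_truth(seed: int = 0) -> GroundTruth:
    """Qualitatively realistic weights: own previous action dominates,
    opponent's previous action and the continuation probability and r2 help
    cooperation, error and risk hurt it, and play decays slowly with time."""
    static = dict(
        intercept=-2.9,
        r1=0.8,
        r2=1.6,
        risk=-0.7,
        error=-1.2,
        delta=1.8,
        **{"r1:delta": 0.5, "r2:delta": 0.9},
        infinite=0.5,
        continuous=0.25,
    )
    dynamic = dict(
        intercept=-4.6,
        r1=0.5,
        r2=1.0,
        risk=-0.5,
        error=-0.9,
        delta=1.6,
        **{"r1:delta": 0.3, "r2:delta": 0.6},
        infinite=0.35,
        continuous=0.15,
        **{"delta:infinite": 0.2},
        my_prev=2.8,
        other_prev=1.6,
        **{"error:other_prev": -1.0},
        t=-0.06,
    )
    return GroundTruth(
        static_weights=np.array([static[k] for k in STATIC_FEATURES]),
        dynamic_weights=np.array([dynamic[k] for k in DYNAMIC_FEATURES]),
        seed=seed,
    )


def weights_as_model(gt: GroundTruth) -> FullModel:
    """Wrap ground-truth weight vectors as a FullModel (unit dummy SEs)."""
    return FullModel(
        static=ModelWeights(
            "static", STATIC_FEATURES, gt.static_weights,
            np.ones_like(gt.static_weights), n_obs=0,
        ),
        dynamic=ModelWeights(
            "dynamic", DYNAMIC_FEATURES, gt.dynamic_weights,
            np.ones_like(gt.dynamic_weights), n_obs=0,
        ),
    )


def _synthetic_payoffs(g: GameStructure) -> GameStructure:
    R, S, T, P = g.r2, 0.0, 1.0, g.r2 - g.r1
    pd_ok = (T > R + _EPS > P + 2 * _EPS > S + _EPS) and R > (S + T) / 2 + _EPS
    if not pd_ok:
        return g
    return dc_replace(g, payoffs=(R, S, T, P))


def generate(gt: GroundTruth) -> Dataset:
    """Draw structures, play them out under the ground-truth model, and
    return a standard Dataset (same seed, byte-identical output)."""
    structures = [
        _synthetic_payoffs(g)
        for g in lhs_sample(
            gt.n_structures, seed=gt.seed, continuous=0.5, id_prefix="syn"
        )
    ]
    policy = FullModelPolicy(weights_as_model(gt))
    frames = []
    for i, g in enumerate(structures):
        sim_seed = int(
            np.random.SeedSequence([gt.seed, i]).generate_state(1)[0] % 2**31
        )
        cfg = SimulationConfig(
            n_pairs=gt.pairs_per_structure, seed=sim_seed, opponent_lag="intended"
        )
        frames.append(simulate_records(g, policy, cfg))
    actions = pd.concat(frames, ignore_index=True)
    return Dataset.from_actions(structures, actions)
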