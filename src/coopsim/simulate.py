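"""Agent-based engine that plays out an experiment from a game structure.

Given only a :class:`GameStructure` and a behavioral policy, the simulator
plays ``n_pairs`` independent paired interactions: it draws each
interaction's length (geometric for indefinitely repeated games, fixed
1/(1-delta) for finite ones), has both agents draw intended actions from
their policy each period, applies the structure's implementation error, and
feeds lagged actions forward.  This is what lets a model fitted on *other*
experiments forecast cooperation dynamics for a design it has never seen.

Lag semantics: a player knows what they chose (own lag = intended action)
but only sees what the counterpart's implemented action was (opponent lag =
implemented action).  Cooperation is scored on intended actions — the
decision, which is what experiments record — while implemented actions drive
observation.  Continuous-time designs are represented on their discrete
subperiod grid, so they simulate like ordinary finite games.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .behavior import FullModel, FullModelPolicy, Policy
from .core import GameStructure

__all__ = [
    "SimulationConfig",
    "TrajectorySummary",
    "draw_interaction_length",
    "apply_error",
    "horizon",
    "simulate_structure",
    "simulate_records",
    "forced_first_period_experiment",
]

#: cap on stochastic interaction length (longest observed real interaction)
MAX_PERIODS = 38


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of one simulation run.

    ``n_pairs`` defaults to 1000, putting Monte Carlo error on cooperation
    proportions below about 0.02.  ``first_period_override``, when set,
    replaces every agent's period-1 cooperation probability (the forced
    first-period experiments).  ``opponent_lag`` selects whether the lag fed
    back is the opponent's implemented action (default; what a subject
    observes) or the intended one (used by the synthetic-data generator so
    recorded histories match the histories agents actually conditioned on).
    """

    n_pairs: int = 1000
    max_periods: int = MAX_PERIODS
    seed: int = 0
    first_period_override: float | None = None
    opponent_lag: str = "implemented"

    def __post_init__(self):
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.first_period_override is not None and not (
            0.0 <= self.first_period_override <= 1.0
        ):
            raise ValueError("first_period_override must lie in [0,1]")
        if self.opponent_lag not in ("implemented", "intended"):
            raise ValueError("opponent_lag must be 'implemented' or 'intended'")


@dataclass(frozen=True)
class TrajectorySummary:
    """Per-structure cooperation time series plus the overall mean."""

    structure_id: str
    coop_by_period: np.ndarray
    n_by_period: np.ndarray
    coop_overall: float
    n_pairs: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "structure_id": self.structure_id,
                "period": np.arange(1, len(self.coop_by_period) + 1),
                "coop": self.coop_by_period,
                "n": self.n_by_period,
            }
        )


def draw_interaction_length(
    g: GameStructure, rng: np.random.Generator, max_periods: int = MAX_PERIODS
) -> int:
    """Number of periods of one paired interaction.

    Indefinitely repeated games continue after each period with probability
    delta (a geometric draw, capped); fixed-length games always last their
    expected length 1/(1-delta).
    """
    if g.infinite:
        return int(min(rng.geometric(1.0 - g.delta), max_periods))
    return int(round(1.0 / (1.0 - g.delta)))


def apply_error(intended, error: float, rng: np.random.Generator):
    """Flip each intended action with the structure's error probability."""
    if not 0.0 <= error <= 0.5:
        raise ValueError("error must lie in [0, 0.5]")
    intended = np.asarray(intended)
    if error == 0.0:
        return intended.copy()
    flips = rng.random(intended.shape) < error
    return np.where(flips, 1 - intended, intended)


def horizon(g: GameStructure) -> int:
    """Reporting horizon for trajectory comparison.

    Eight periods by default; seven for indefinitely repeated games with
    delta = 0.5 (expected length two, so data beyond period seven is too
    thin); the true fixed length for finite games shorter than eight.
    """
    if g.infinite:
        return 7 if math.isclose(g.delta, 0.5) else 8
    return min(8, int(round(1.0 / (1.0 - g.delta))))


def _play(g: GameStructure, policy: Policy, cfg: SimulationConfig):
    """Core loop: returns (lengths, intended, implemented), with action
    arrays of shape (2, n_pairs, T_max) NaN-padded past each pair's length."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_pairs
    if g.infinite:
        lengths = np.minimum(rng.geometric(1.0 - g.delta, size=n), cfg.max_periods)
    else:
        lengths = np.full(n, int(round(1.0 / (1.0 - g.delta))))
    t_max = int(lengths.max())

    states = [policy.start(g, n, rng) for _ in range(2)]
    intended = np.full((2, n, t_max), np.nan)
    implemented = np.full((2, n, t_max), np.nan)
    lag_my = [None, None]
    lag_other = [None, None]

    for t in range(1, t_max + 1):
        alive = lengths >= t
        for slot in range(2):
            if t == 1:
                p = policy.prob(g, states[slot], 1, None, None, n)
                if cfg.first_period_override is not None:
                    p = np.full(n, cfg.first_period_override)
            else:
                p = policy.prob(g, states[slot], t, lag_my[slot], lag_other[slot], n)
            act = (rng.random(n) < p).astype(float)
            impl = apply_error(act, g.error, rng)
            intended[slot, alive, t - 1] = act[alive]
            implemented[slot, alive, t - 1] = impl[alive]
        cur_int = [intended[s, :, t - 1] for s in range(2)]
        cur_impl = [implemented[s, :, t - 1] for s in range(2)]
        for slot in range(2):
            opp_obs = cur_impl[1 - slot]
            policy.observe(g, states[slot], cur_int[slot], opp_obs, mask=alive)
        for slot in range(2):
            lag_my[slot] = np.nan_to_num(cur_int[slot])
            opp = cur_impl if cfg.opponent_lag == "implemented" else cur_int
            lag_other[slot] = np.nan_to_num(opp[1 - slot])
    return lengths, intended, implemented


def simulate_structure(
    g: GameStructure, policy: Policy, cfg: SimulationConfig
) -> TrajectorySummary:
    """Simulate ``cfg.n_pairs`` interactions and aggregate cooperation.

    Per-period proportions are over intended actions of pairs still active
    at that period; the overall mean pools every decision.  Two runs with
    the same config (seed included) are identical.
    """
    _, intended, _ = _play(g, policy, cfg)
    active = np.isfinite(intended[0])  # (n, T)
    n_by_period = 2 * active.sum(axis=0)
    coop = np.nansum(intended, axis=(0, 1)) / np.maximum(n_by_period, 1)
    total = n_by_period.sum()
    overall = float(np.nansum(intended) / total)
    return TrajectorySummary(
        structure_id=g.id,
        coop_by_period=coop,
        n_by_period=n_by_period,
        coop_overall=overall,
        n_pairs=cfg.n_pairs,
    )


def simulate_records(
    g: GameStructure, policy: Policy, cfg: SimulationConfig, prefix: str | None = None
) -> pd.DataFrame:
    """Simulate and emit the standard decision-table rows (one per player
    per period), suitable for :meth:`Dataset.from_actions`."""
    _, intended, _ = _play(g, policy, cfg)
    prefix = prefix if prefix is not None else g.id
    ids = np.array([f"{prefix}-i{k:04d}" for k in range(cfg.n_pairs)], dtype=object)
    pair_idx, t_idx = np.nonzero(np.isfinite(intended[0]))
    frames = []
    for slot, pid in enumerate(("a", "b")):
        frames.append(
            pd.DataFrame(
                {
                    "structure_id": g.id,
                    "interaction_id": ids[pair_idx],
                    "player_id": pid,
                    "period": t_idx + 1,
                    "action": intended[slot, pair_idx, t_idx].astype(int),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def forced_first_period_experiment(
    model: FullModel, g: GameStructure, p1: float, cfg: SimulationConfig
) -> float:
    """Pooled cooperation over periods > 1 when period-1 cooperation is
    exogenously forced to probability *p1* (the counterfactual that
    quantifies how strongly first impressions drive later play)."""
    traj = simulate_structure(
        g, FullModelPolicy(model), replace(cfg, first_period_override=p1)
    )
    if len(traj.coop_by_period) < 2:
        raise ValueError("structure plays a single period; no t > 1 outcomes exist")
    w = traj.n_by_period[1:]
    return float((traj.coop_by_period[1:] * w).sum() / w.sum())
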