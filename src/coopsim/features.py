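"""Payoff standardization and design-vector construction.

The choice model is piecewise-logistic: a *static* component for first-period
play driven by game structure alone, and a *dynamic* component for later
periods that adds the previous joint actions and the period index.  This
module owns the fixed feature ordering of both components so fitted
coefficient tables are reproducible and nameable.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core import GameStructure

__all__ = [
    "STATIC_FEATURES",
    "DYNAMIC_FEATURES",
    "DesignVector",
    "payoff_indices",
    "delta_from_finite_length",
    "expected_length",
    "static_design",
    "dynamic_design",
    "static_matrix",
    "dynamic_matrix",
]

#: feature order of the static (first-period) component
STATIC_FEATURES = (
    "intercept",
    "r1",
    "r2",
    "risk",
    "error",
    "delta",
    "r1:delta",
    "r2:delta",
    "infinite",
    "continuous",
)

#: feature order of the dynamic (period > 1) component
DYNAMIC_FEATURES = STATIC_FEATURES + (
    "delta:infinite",
    "my_prev",
    "other_prev",
    "error:other_prev",
    "t",
)


class DesignVector(NamedTuple):
    names: tuple[str, ...]
    x: np.ndarray


def payoff_indices(R: float, S: float, T: float, P: float) -> tuple[float, float]:
    """Normalized payoff indices (r1, r2) from a raw (R, S, T, P) quadruple.

    r1 = (R-P)/(T-S) compares mutual cooperation to mutual defection;
    r2 = (R-S)/(T-S) compares mutual cooperation to being the sole
    cooperator.  Both are invariant to positive affine rescaling of payoffs.
    """
    if T == S:
        raise ValueError("degenerate payoffs: T == S makes the indices undefined")
    if T < S:
        raise ValueError("payoffs must satisfy T > S")
    if not (T > R > P > S and R > (S + T) / 2):
        warnings.warn(
            "payoffs do not satisfy the strict Prisoner's Dilemma ordering",
            stacklevel=2,
        )
    return (R - P) / (T - S), (R - S) / (T - S)


def delta_from_finite_length(L: int) -> float:
    """Continuation probability assigned to a fixed-length game of L periods.

    Uses the expected-length convention E[len] = 1/(1-delta), i.e. a
    ten-period game maps to delta = 0.9.  This treats delta as a rational
    expectation of game length from a first-period perspective, putting
    finite and indefinitely repeated designs on a common scale.
    """
    if L < 1:
        raise ValueError("interaction length must be >= 1")
    return 1.0 - 1.0 / L


def expected_length(delta: float) -> float:
    """Expected interaction length 1/(1-delta) for continuation probability delta."""
    if not 0.0 <= delta < 1.0:
        raise ValueError("delta must lie in [0, 1)")
    return 1.0 / (1.0 - delta)


def static_design(g: GameStructure) -> DesignVector:
    """Design vector of the static component (length 10, intercept first)."""
    x = np.array(
        [
            1.0,
            g.r1,
            g.r2,
            g.risk,
            g.error,
            g.delta,
            g.r1 * g.delta,
            g.r2 * g.delta,
            g.infinite,
            g.continuous,
        ]
    )
    return DesignVector(STATIC_FEATURES, x)


def dynamic_design(
    g: GameStructure, my_prev: int, other_prev: int, t: int
) -> DesignVector:
    """Design vector of the dynamic component (length 15).

    Extends the static features with delta*infinite (the continuation
    probability only governs termination when the game is indefinitely
    repeated), both players' previous actions, the error*other_prev
    interaction (noisier observation of the opponent), and the bare period
    index t.
    """
    if t < 2:
        raise ValueError("dynamic design is defined for periods t >= 2 only")
    if my_prev is None or other_prev is None:
        raise ValueError("dynamic design requires both lagged actions")
    base = static_design(g).x
    extra = np.array(
        [
            g.delta * g.infinite,
            float(my_prev),
            float(other_prev),
            g.error * float(other_prev),
            float(t),
        ]
    )
    return DesignVector(DYNAMIC_FEATURES, np.concatenate([base, extra]))


# -------------------------------------------------------- matrix builders

def _structure_frame(structures: Sequence[GameStructure]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "structure_id": [g.id for g in structures],
            "r1": [g.r1 for g in structures],
            "r2": [g.r2 for g in structures],
            "risk": [float(g.risk) for g in structures],
            "error": [g.error for g in structures],
            "delta": [g.delta for g in structures],
            "infinite": [float(g.infinite) for g in structures],
            "continuous": [float(g.continuous) for g in structures],
        }
    )


def static_matrix(structures: Sequence[GameStructure]) -> np.ndarray:
    """Stack static design vectors for many structures (n x 10)."""
    s = _structure_frame(structures)
    return np.column_stack(
        [
            np.ones(len(s)),
            s["r1"],
            s["r2"],
            s["risk"],
            s["error"],
            s["delta"],
            s["r1"] * s["delta"],
            s["r2"] * s["delta"],
            s["infinite"],
            s["continuous"],
        ]
    )


def dynamic_matrix(
    structures: Sequence[GameStructure],
    records: pd.DataFrame,
) -> np.ndarray:
    """Dynamic design matrix for a decision table (rows with period > 1).

    *records* must carry structure_id, period, my_prev, other_prev; structure
    covariates are joined in.  Returns an (n x 15) array in DYNAMIC_FEATURES
    order, row-aligned with *records*.
    """
    if (records["period"] < 2).any():
        raise ValueError("dynamic_matrix expects records with period > 1 only")
    s = _structure_frame(structures)
    df = records.merge(s, on="structure_id", how="left", validate="many_to_one")
    if df["r1"].isna().any():
        missing = sorted(set(records["structure_id"]) - set(s["structure_id"]))
        raise ValueError(f"records reference structures without covariates: {missing}")
    return np.column_stack(
        [
            np.ones(len(df)),
            df["r1"],
            df["r2"],
            df["risk"],
            df["error"],
            df["delta"],
            df["r1"] * df["delta"],
            df["r2"] * df["delta"],
            df["infinite"],
            df["continuous"],
            df["delta"] * df["infinite"],
            df["my_prev"].astype(float),
            df["other_prev"].astype(float),
            df["error"] * df["other_prev"].astype(float),
            df["period"].astype(float),
        ]
    )
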