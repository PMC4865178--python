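"""Global sensitivity analysis of the fitted model, plus inertia analyses.

The question: which institutional levers move cooperation most?  Thousands
of hypothetical experiment designs are drawn by Latin hypercube sampling
over the feasible ranges of the structural variables, each design is played
out by the simulator under the fitted model, and the partial rank
correlation coefficient (PRCC) of each input with mean cooperation is
estimated with bootstrap confidence intervals.  PRCC is rank-based, hence
robust to any monotone nonlinearity in the input-output map; standardized
rank regression coefficients (SRRC) are available as a secondary statistic.

"Inertia" — the probability of cooperating given cooperation last period —
is computed both from data (a count ratio per structure) and from the model
(dynamic predictions with own lag fixed at cooperate, averaged over the
empirical distribution of period and opponent lag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from scipy.stats import qmc

from .behavior import FullModel, FullModelPolicy
from .core import Dataset, GameStructure
from .features import dynamic_matrix
from .simulate import SimulationConfig, simulate_structure

__all__ = [
    "SENSITIVITY_INPUTS",
    "SensitivityResult",
    "lhs_sample",
    "prcc",
    "srrc",
    "run_analysis",
    "inertia_actual",
    "inertia_predicted",
]

#: input variables of the sensitivity ensemble, in reporting order
SENSITIVITY_INPUTS = ("error", "delta", "infinite", "risk", "r1", "r2")


@dataclass(frozen=True)
class SensitivityResult:
    """Per-input PRCC estimates with bootstrap 95% confidence intervals."""

    names: tuple[str, ...]
    estimate: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_boot: int

    def __post_init__(self):
        if np.any(self.ci_low > self.estimate + 1e-12) or np.any(
            self.estimate - 1e-12 > self.ci_high
        ):
            raise ValueError("confidence interval must contain the point estimate")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.names,
                "estimate": self.estimate,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


# --------------------------------------------------------------------- LHS

def lhs_sample(
    n: int, seed: int, continuous: float = 0.0, id_prefix: str = "lhs"
) -> list[GameStructure]:
    """Latin hypercube sample of *n* hypothetical game structures.

    Marginals: error ~ U(0, 0.5), delta ~ U(0.45, 0.95), r1 ~ U(0, 1),
    r2 ~ U(0, 1) subject to r1 < r2 (always true in the combined data);
    infinite and risk are Bernoulli(0.5) outside the stratification; the
    continuous flag is Bernoulli(*continuous*), default fixed at 0 (its
    empirical mode — the combined data has no within-experiment variation
    on it).

    The r1 < r2 constraint is enforced inside the hypercube: rows violating
    it have their two strata swapped (when the strata themselves forbid the
    ordering) and their positions redrawn within strata.  This realizes the
    uniform pair *conditioned on* r1 < r2 — whose marginals are the order
    statistics of two uniforms, mean 1/3 and 2/3 — while keeping the error
    and delta marginals exactly stratified; the r1/r2 stratification is only
    approximate, which is unavoidable: exact one-draw-per-stratum on both
    coordinates under a pointwise ordering constraint would force both
    variables into the same stratum in every row.
    """
    if n < 2:
        raise ValueError("need n >= 2 samples")
    sampler = qmc.LatinHypercube(d=4, seed=seed)
    u = sampler.random(n)  # columns: error, delta, r1, r2
    rng = np.random.default_rng(seed)

    s1 = np.floor(u[:, 2] * n).astype(int)
    s2 = np.floor(u[:, 3] * n).astype(int)
    r1, r2 = u[:, 2].copy(), u[:, 3].copy()
    for i in range(n):
        if r1[i] < r2[i]:
            continue
        if s1[i] > s2[i]:
            s1[i], s2[i] = s2[i], s1[i]
        if s1[i] < s2[i]:
            r1[i] = (s1[i] + rng.random()) / n
            r2[i] = (s2[i] + rng.random()) / n
        else:  # same stratum: order two fresh draws within it
            a, b = np.sort(rng.random(2))
            r1[i] = (s1[i] + a) / n
            r2[i] = (s2[i] + b) / n

    error = 0.5 * u[:, 0]
    delta = 0.45 + 0.5 * u[:, 1]
    infinite = rng.integers(0, 2, size=n)
    risk = rng.integers(0, 2, size=n)
    cont = (rng.random(n) < continuous).astype(int)

    width = max(5, len(str(n)))
    return [
        GameStructure(
            id=f"{id_prefix}-{i:0{width}d}",
            r1=float(r1[i]),
            r2=float(r2[i]),
            delta=float(delta[i]),
            error=float(error[i]),
            infinite=int(infinite[i]),
            continuous=int(cont[i]),
            risk=int(risk[i]),
        )
        for i in range(n)
    ]


# -------------------------------------------------------------------- PRCC

def _rank_columns(a: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(scipy.stats.rankdata, 0, a)


def _partial_corr_last(z: np.ndarray) -> np.ndarray:
    """Partial correlations of each of the first p columns with the last,
    controlling for the remaining first-p columns: correlate the residuals
    of (column_j ~ others) with the residuals of (last ~ others)."""
    n, q = z.shape
    p = q - 1
    out = np.empty(p)
    for j in range(p):
        others = np.column_stack(
            [np.ones(n)] + [z[:, k] for k in range(p) if k != j]
        )
        beta, *_ = np.linalg.lstsq(others, z[:, [j, p]], rcond=None)
        resid = z[:, [j, p]] - others @ beta
        rx, ry = resid[:, 0], resid[:, 1]
        denom = np.sqrt((rx @ rx) * (ry @ ry))
        out[j] = (rx @ ry) / denom if denom > 0 else 0.0
    return np.clip(out, -1.0, 1.0)


def prcc(
    X: np.ndarray,
    y: np.ndarray,
    names: Sequence[str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> SensitivityResult:
    """Partial rank correlation of each input with the output.

    All columns are rank-transformed; each input's PRCC is the correlation
    between its rank residuals and the output's rank residuals after
    regressing both on the other inputs.  Percentile bootstrap confidence
    intervals over *n_boot* resamples of the design rows.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 2:
        raise ValueError("need more rows than inputs + 2")
    names = tuple(names) if names is not None else tuple(f"x{j}" for j in range(p))
    for j in range(p):
        if np.all(X[:, j] == X[0, j]):
            raise ValueError(f"input column {names[j]!r} is constant")
    if np.all(y == y[0]):
        raise ValueError("output is constant")

    z = _rank_columns(np.column_stack([X, y]))
    est = _partial_corr_last(z)

    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, p))
    data = np.column_stack([X, y])
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        zb = _rank_columns(data[idx])
        if any(np.all(zb[:, j] == zb[0, j]) for j in range(p + 1)):
            boots[b] = est  # degenerate resample: fall back to the point estimate
            continue
        boots[b] = _partial_corr_last(zb)
    lo = np.percentile(boots, 2.5, axis=0)
    hi = np.percentile(boots, 97.5, axis=0)
    return SensitivityResult(
        names=names,
        estimate=est,
        ci_low=np.minimum(lo, est),
        ci_high=np.maximum(hi, est),
        n_boot=n_boot,
    )


def srrc(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Standardized rank regression coefficients (secondary statistic)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rx = _rank_columns(X)
    ry = scipy.stats.rankdata(y)
    rx = (rx - rx.mean(axis=0)) / rx.std(axis=0, ddof=1)
    ry = (ry - ry.mean()) / ry.std(ddof=1)
    design = np.column_stack([np.ones(len(ry)), rx])
    beta, *_ = np.linalg.lstsq(design, ry, rcond=None)
    return beta[1:]


def run_analysis(
    model: FullModel,
    n_samples: int = 4000,
    cfg: SimulationConfig | None = None,
    seed: int = 0,
    n_boot: int = 1000,
    with_srrc: bool = False,
):
    """LHS-and-simulate sensitivity of mean cooperation to the six inputs.

    Each sampled structure is simulated under the fitted model with the
    simulator's standard termination rules; the output variable is overall
    mean cooperation across the simulated horizon.  Returns the PRCC result
    (and the SRRC vector when requested).
    """
    cfg = cfg or SimulationConfig(n_pairs=200)
    structures = lhs_sample(n_samples, seed=seed)
    policy = FullModelPolicy(model)
    X = np.array(
        [[g.error, g.delta, g.infinite, g.risk, g.r1, g.r2] for g in structures]
    )
    y = np.empty(n_samples)
    for i, g in enumerate(structures):
        sim_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % 2**31)
        y[i] = simulate_structure(g, policy, replace(cfg, seed=sim_seed)).coop_overall
    result = prcc(X, y, SENSITIVITY_INPUTS, n_boot=n_boot, seed=seed)
    if with_srrc:
        return result, srrc(X, y)
    return result


# ----------------------------------------------------------------- inertia

def inertia_actual(ds: Dataset) -> pd.Series:
    """Per-structure observed inertia: cooperations following a own-lag
    cooperation, divided by own-lag cooperations.  Structures with no
    lagged cooperation get NaN with a warning."""
    rows = ds.records[ds.records["my_prev"] == 1]
    out = rows.groupby("structure_id")["action"].mean()
    out = out.reindex(sorted(ds.structures))
    if out.isna().any():
        missing = list(out.index[out.isna()])
        warnings.warn(
            f"no lagged cooperation observed in structures {missing}; inertia undefined",
            stacklevel=2,
        )
    out.name = "inertia_actual"
    return out


def inertia_predicted(model: FullModel, g: GameStructure, ds: Dataset) -> float:
    """Model inertia for structure *g*: dynamic prediction with own lag set
    to cooperate, averaged over the structure's empirical distribution of
    (period, opponent lag) — marginalizing out time and the opponent."""
    from .behavior import sigmoid

    rows = ds.records[
        (ds.records["structure_id"] == g.id) & (ds.records["period"] > 1)
    ].copy()
    if len(rows) == 0:
        raise ValueError(f"structure {g.id} has no periods beyond the first")
    rows["my_prev"] = 1.0
    X = dynamic_matrix([g], rows)
    return float(np.mean(sigmoid(X @ model.dynamic.w)))
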