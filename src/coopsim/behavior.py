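"""The two-part logistic choice model and its comparison variants.

The probability a player cooperates is modeled piecewise: at period 1 a
*static* logistic regression on game structure alone; at periods > 1 a
*dynamic* logistic regression on structure, both players' previous actions,
and the period index.  Both components are fit by plain maximum likelihood.

Besides the full two-part model, the standard comparison variants are
provided: static-only (the static component applied at every period),
dynamic-only (the dynamic component applied at every period, with first-period
lags imputed), and a baseline that always predicts the training-set mean
cooperation rate.  All of them implement the common :class:`Policy` interface
consumed by the simulator and the evaluation harness.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import statsmodels.api as sm
from scipy.special import expit

from .core import Dataset, GameStructure
from .features import (
    DYNAMIC_FEATURES,
    STATIC_FEATURES,
    dynamic_design,
    dynamic_matrix,
    static_design,
    static_matrix,
)

__all__ = [
    "sigmoid",
    "ModelWeights",
    "FullModel",
    "VariableImportance",
    "SeparationWarning",
    "fit_component",
    "fit_full_model",
    "predict",
    "variable_importance",
    "comparison_models",
    "Policy",
    "FullModelPolicy",
    "StaticOnlyPolicy",
    "DynamicOnlyPolicy",
    "BaselinePolicy",
]

# IRLS convergence: tolerance on the log-likelihood change, iteration cap
_TOL = 1e-8
_MAXITER = 100
# ridge strength of the penalized fallback under perfect separation
_RIDGE_ALPHA = 1e-3


class SeparationWarning(UserWarning):
    """Perfect separation detected; a penalized fit was substituted."""


def sigmoid(z):
    """Logistic sigmoid 1/(1+exp(-z)), overflow-safe for large |z|."""
    return expit(z)


@dataclass(frozen=True)
class ModelWeights:
    """Fitted coefficients of one logistic component.

    ``component`` is "static" or "dynamic"; ``names``, ``w`` and ``se`` are
    aligned; ``penalized`` flags the ridge fallback used under separation.
    """

    component: str
    names: tuple[str, ...]
    w: np.ndarray
    se: np.ndarray
    n_obs: int
    penalized: bool = False

    def __post_init__(self):
        if not (len(self.w) == len(self.se) == len(self.names)):
            raise ValueError("names, w and se must have equal length")
        object.__setattr__(self, "w", np.asarray(self.w, dtype=float))
        object.__setattr__(self, "se", np.asarray(self.se, dtype=float))

    def to_json(self) -> str:
        return json.dumps(
            {
                "component": self.component,
                "names": list(self.names),
                "w": self.w.tolist(),
                "se": self.se.tolist(),
                "n_obs": self.n_obs,
                "penalized": self.penalized,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "ModelWeights":
        d = json.loads(s)
        return cls(
            component=d["component"],
            names=tuple(d["names"]),
            w=np.array(d["w"]),
            se=np.array(d["se"]),
            n_obs=int(d["n_obs"]),
            penalized=bool(d.get("penalized", False)),
        )


class VariableImportance(NamedTuple):
    names: tuple[str, ...]
    score: np.ndarray


@dataclass(frozen=True)
class FullModel:
    """The two-part model: static (10 coefficients) + dynamic (15)."""

    static: ModelWeights
    dynamic: ModelWeights

    def __post_init__(self):
        if self.static.names != STATIC_FEATURES:
            raise ValueError("static component must use the static feature schema")
        if self.dynamic.names != DYNAMIC_FEATURES:
            raise ValueError("dynamic component must use the dynamic feature schema")

    def to_json(self) -> str:
        return json.dumps(
            {
                "static": json.loads(self.static.to_json()),
                "dynamic": json.loads(self.dynamic.to_json()),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "FullModel":
        d = json.loads(s)
        return cls(
            static=ModelWeights.from_json(json.dumps(d["static"])),
            dynamic=ModelWeights.from_json(json.dumps(d["dynamic"])),
        )


# ------------------------------------------------------------------ fitting

def _check_collinearity(X: np.ndarray, names: Sequence[str]) -> None:
    _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = sorted(names[j] for j in piv[rank:])
        raise ValueError(f"design matrix is collinear in columns {bad}")


def _penalized_fit(X, y, alpha=_RIDGE_ALPHA):
    """Ridge-penalized logistic MLE; finite even under perfect separation."""
    n, p = X.shape

    def negll(w):
        z = X @ w
        # log(1+exp(-z)) stable
        return np.logaddexp(0.0, -np.where(y == 1, z, -z)).sum() + 0.5 * alpha * w @ w

    def grad(w):
        mu = expit(X @ w)
        return X.T @ (mu - y) + alpha * w

    res = scipy.optimize.minimize(
        negll, np.zeros(p), jac=grad, method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    w = res.x
    mu = expit(X @ w)
    H = (X * (mu * (1 - mu))[:, None]).T @ X + alpha * np.eye(p)
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    return w, se


def fit_component(
    X: np.ndarray, y: np.ndarray, names: Sequence[str], component: str = "static"
) -> ModelWeights:
    """Maximum-likelihood logistic fit with observed-information standard errors.

    Deterministic given (X, y).  Perfect separation is flagged with
    :class:`SeparationWarning` and handled by a small-ridge penalized fit so
    coefficients and standard errors stay finite; rank-deficient designs
    raise an error naming the offending columns.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D and row-aligned with y")
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all():
        raise ValueError("outcomes must be binary 0/1")
    if len(classes) < 2:
        raise ValueError("need at least one observation of each class")
    _check_collinearity(X, names)

    penalized = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # statsmodels chatters on separation
            fit = sm.Logit(y, X).fit(
                disp=0, method="newton", tol=_TOL, maxiter=_MAXITER
            )
        w, se = fit.params, fit.bse
        ok = (
            bool(fit.mle_retvals.get("converged", False))
            and np.all(np.isfinite(w))
            and np.all(np.isfinite(se))
            and np.max(np.abs(w)) < 1e3
        )
    except Exception:
        ok = False
    if not ok:
        warnings.warn(
            "perfect separation (or non-convergence) detected; "
            "using ridge-penalized fallback",
            SeparationWarning,
            stacklevel=2,
        )
        w, se = _penalized_fit(X, y)
        penalized = True

    return ModelWeights(
        component=component,
        names=tuple(names),
        w=np.asarray(w),
        se=np.asarray(se),
        n_obs=len(y),
        penalized=penalized,
    )


def _static_rows(ds: Dataset) -> tuple[np.ndarray, np.ndarray]:
    rows = ds.records[ds.records["period"] == 1]
    structures = [ds.structures[s] for s in rows["structure_id"]]
    return static_matrix(structures), rows["action"].to_numpy(dtype=float)


def _dynamic_rows(ds: Dataset) -> tuple[np.ndarray, np.ndarray]:
    rows = ds.records[ds.records["period"] > 1]
    X = dynamic_matrix(list(ds.structures.values()), rows)
    return X, rows["action"].to_numpy(dtype=float)


def fit_full_model(ds: Dataset) -> FullModel:
    """Fit the static component on period-1 decisions and the dynamic
    component on later decisions of *ds*."""
    Xs, ys = _static_rows(ds)
    Xd, yd = _dynamic_rows(ds)
    return FullModel(
        static=fit_component(Xs, ys, STATIC_FEATURES, "static"),
        dynamic=fit_component(Xd, yd, DYNAMIC_FEATURES, "dynamic"),
    )


def predict(
    model: FullModel,
    g: GameStructure,
    my_prev: int | None = None,
    other_prev: int | None = None,
    t: int = 1,
) -> float:
    """Probability of cooperation at period *t* of structure *g*.

    Period 1 uses the static component and ignores any history passed;
    later periods require both lagged actions.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    if t == 1:
        return float(sigmoid(static_design(g).x @ model.static.w))
    if my_prev is None or other_prev is None:
        raise ValueError("predictions at t > 1 require both lagged actions")
    return float(sigmoid(dynamic_design(g, my_prev, other_prev, t).x @ model.dynamic.w))


def variable_importance(m: ModelWeights) -> VariableImportance:
    """Per-feature |coefficient / standard error| (absolute t-statistics)."""
    if np.any(m.se == 0):
        bad = [n for n, s in zip(m.names, m.se) if s == 0]
        raise ValueError(f"zero standard error for {bad}; importance undefined")
    return VariableImportance(m.names, np.abs(m.w / m.se))


# ------------------------------------------------------------------ policies

class Policy:
    """Common interface for anything that can play the game.

    A policy is consulted once per period for a *vector* of ``n`` agents
    facing the same structure.  ``start`` creates per-agent state (None for
    stateless policies); ``prob`` returns each agent's probability of
    cooperating (lags are None at t == 1); ``observe`` feeds back the
    period's own intended action and the opponent's observed action so
    learning policies can update (``mask`` marks agents still playing).
    """

    name = "policy"

    def start(self, g: GameStructure, n: int, rng: np.random.Generator):
        return None

    def prob(self, g, state, t, my_prev, other_prev, n) -> np.ndarray:
        raise NotImplementedError

    def observe(self, g, state, my_action, opp_action, mask=None) -> None:
        pass

    # scalar convenience
    def prob_one(self, g, t, my_prev=None, other_prev=None, rng=None) -> float:
        rng = rng or np.random.default_rng(0)
        state = self.start(g, 1, rng)
        mp = None if my_prev is None else np.array([float(my_prev)])
        op = None if other_prev is None else np.array([float(other_prev)])
        return float(np.broadcast_to(self.prob(g, state, t, mp, op, 1), (1,))[0])


def _dynamic_z_parts(m: ModelWeights, g: GameStructure):
    """Split the dynamic linear predictor into structure-constant and
    history/time terms for fast vectorized evaluation."""
    w = dict(zip(m.names, m.w))
    const = (
        w["intercept"]
        + w["r1"] * g.r1
        + w["r2"] * g.r2
        + w["risk"] * g.risk
        + w["error"] * g.error
        + w["delta"] * g.delta
        + w["r1:delta"] * g.r1 * g.delta
        + w["r2:delta"] * g.r2 * g.delta
        + w["infinite"] * g.infinite
        + w["continuous"] * g.continuous
        + w["delta:infinite"] * g.delta * g.infinite
    )
    return const, w["my_prev"], w["other_prev"] + w["error:other_prev"] * g.error, w["t"]


class FullModelPolicy(Policy):
    """The two-part model as a playing agent."""

    name = "full"

    def __init__(self, model: FullModel):
        self.model = model

    def prob(self, g, state, t, my_prev, other_prev, n):
        if t == 1:
            return np.full(n, sigmoid(static_design(g).x @ self.model.static.w))
        const, wm, wo, wt = _dynamic_z_parts(self.model.dynamic, g)
        z = const + wm * np.asarray(my_prev, float) + wo * np.asarray(other_prev, float) + wt * t
        return sigmoid(z)


class StaticOnlyPolicy(Policy):
    """The static component applied at every period (history-blind)."""

    name = "static_only"

    def __init__(self, model: FullModel):
        self.model = model

    def prob(self, g, state, t, my_prev, other_prev, n):
        return np.full(n, sigmoid(static_design(g).x @ self.model.static.w))


class DynamicOnlyPolicy(Policy):
    """The dynamic component applied at every period.

    At period 1 the missing lags are imputed: by default drawn from
    Bernoulli(0.5) (roughly the overall cooperation split in the combined
    data); alternatively "period zero" mutual cooperation.
    """

    name = "dynamic_only"

    def __init__(self, model: FullModel, imputation: str = "bernoulli"):
        if imputation not in ("bernoulli", "mutual_cooperation"):
            raise ValueError("imputation must be 'bernoulli' or 'mutual_cooperation'")
        self.model = model
        self.imputation = imputation

    def start(self, g, n, rng):
        return {"rng": rng}

    def prob(self, g, state, t, my_prev, other_prev, n):
        if t == 1:
            rng = (state or {}).get("rng") or np.random.default_rng(0)
            if self.imputation == "bernoulli":
                my_prev = rng.integers(0, 2, size=n).astype(float)
                other_prev = rng.integers(0, 2, size=n).astype(float)
            else:
                my_prev = np.ones(n)
                other_prev = np.ones(n)
        const, wm, wo, wt = _dynamic_z_parts(self.model.dynamic, g)
        z = const + wm * np.asarray(my_prev, float) + wo * np.asarray(other_prev, float) + wt * t
        return sigmoid(z)


class BaselinePolicy(Policy):
    """Constant prediction at the training-set mean cooperation rate."""

    name = "baseline"

    def __init__(self, p: float):
        if not 0.0 <= p <= 1.0:
            raise ValueError("baseline rate must be a probability")
        self.p = p

    def prob(self, g, state, t, my_prev, other_prev, n):
        return np.full(n, self.p)


def comparison_models(train: Dataset) -> dict[str, Policy]:
    """Fit the full model once and derive the standard comparison set.

    Returns policies keyed "full", "static_only", "dynamic_only", "baseline".
    The fEWA learning baseline lives in :mod:`coopsim.fewa` because it needs
    its own sensitivity-parameter fit.
    """
    if train.n_decisions == 0:
        raise ValueError("training data is empty")
    model = fit_full_model(train)
    return {
        "full": FullModelPolicy(model),
        "static_only": StaticOnlyPolicy(model),
        "dynamic_only": DynamicOnlyPolicy(model),
        "baseline": BaselinePolicy(float(train.records["action"].mean())),
    }
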