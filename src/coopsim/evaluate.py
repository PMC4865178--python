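"""Multi-scale validation: held-out-structure prediction of individual
actions, simulation-based prediction of aggregate cooperation, k-fold
robustness, and the metric/paired-test bookkeeping.

The unit of cross-validation is an entire game structure: a model is fit on
the remaining structures and must predict a design it has never seen.  Two
regimes are distinguished.  *Individual-level* validation conditions each
prediction on the empirically observed history (lags) of the test data and
scores probabilities against the actual binary decisions.  *Aggregate-level*
validation is stricter: only the game structure is passed, trajectories are
produced by forward simulation, and the simulated per-period cooperation
proportions are compared with the observed ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .behavior import Policy
from .core import Dataset, pivot_interactions
from .simulate import SimulationConfig, horizon, simulate_structure

__all__ = [
    "accuracy",
    "log_likelihood",
    "FoldPlan",
    "loocv_plan",
    "random_folds",
    "MetricReport",
    "predict_records",
    "loocv_individual",
    "observed_trajectory",
    "aggregate_validation",
    "kfold_sweep",
    "paired_comparison",
    "PairedTestResult",
]

_CLIP = 1e-12

ModelFactory = Callable[[Dataset], Policy]


def accuracy(p: np.ndarray, y: np.ndarray) -> float:
    """Fraction classified correctly at the 0.5 threshold.

    A prediction counts as Cooperate iff p > 0.5; the tie p == 0.5 counts
    as Defect so the rule is deterministic.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(p) == 0:
        raise ValueError("empty input")
    if len(p) != len(y):
        raise ValueError("p and y must have equal length")
    return float(((p > 0.5).astype(float) == y).mean())


def log_likelihood(p: np.ndarray, y: np.ndarray) -> float:
    """Sum of Bernoulli log-likelihoods, with p clipped away from {0, 1}."""
    p = np.clip(np.asarray(p, dtype=float), _CLIP, 1 - _CLIP)
    y = np.asarray(y, dtype=float)
    return float((y * np.log(p) + (1 - y) * np.log(1 - p)).sum())


# ------------------------------------------------------------------ folds

@dataclass(frozen=True)
class FoldPlan:
    """Partition of structures into test folds (LOOCV iff k == n)."""

    assignments: dict[str, int]
    k: int

    def __post_init__(self):
        folds = set(self.assignments.values())
        if folds != set(range(self.k)):
            raise ValueError("fold indices must be exactly 0..k-1")

    def test_ids(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.assignments.items() if f == fold)

    @property
    def is_loocv(self) -> bool:
        return self.k == len(self.assignments)


def loocv_plan(structure_ids: Iterable[str]) -> FoldPlan:
    ids = sorted(structure_ids)
    return FoldPlan({s: i for i, s in enumerate(ids)}, k=len(ids))


def random_folds(structure_ids: Iterable[str], k: int, seed: int) -> FoldPlan:
    """Random fold assignment with an explicit, recorded seed."""
    ids = sorted(structure_ids)
    if not 2 <= k <= len(ids):
        raise ValueError("k must lie in [2, number of structures]")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    assignments = {}
    for fold, chunk in enumerate(np.array_split(perm, k)):
        for j in chunk:
            assignments[ids[j]] = fold
    return FoldPlan(assignments, k=k)


# ------------------------------------------------------------- predictions

def predict_records(policy: Policy, ds: Dataset, seed: int = 0) -> pd.DataFrame:
    """Per-decision cooperation probabilities, conditioning on the
    empirically observed lags of each interaction.

    Interactions are replayed period by period so learning policies (fEWA)
    can update their state from observed play; stateless policies simply see
    the recorded lags.  Returns the records frame with a ``p_hat`` column.
    """
    rng = np.random.default_rng(seed)
    out = []
    for sid, sub in ds.records.groupby("structure_id", sort=True):
        g = ds.structures[sid]
        inter_ids, players, actions = pivot_interactions(sub)
        n_inter, t_max = actions.shape[1], actions.shape[2]
        states = [policy.start(g, n_inter, rng) for _ in range(2)]
        p_piv = np.full((2, n_inter, t_max), np.nan)
        for t in range(1, t_max + 1):
            alive = np.isfinite(actions[0, :, t - 1])
            for slot in range(2):
                if t == 1:
                    p = policy.prob(g, states[slot], 1, None, None, n_inter)
                else:
                    my_prev = actions[slot, :, t - 2]
                    other_prev = actions[1 - slot, :, t - 2]
                    p = policy.prob(g, states[slot], t, my_prev, other_prev, n_inter)
                p_piv[slot, alive, t - 1] = np.broadcast_to(p, (n_inter,))[alive]
            for slot in range(2):
                policy.observe(
                    g,
                    states[slot],
                    actions[slot, :, t - 1],
                    actions[1 - slot, :, t - 1],
                    mask=alive,
                )
        slot_i, inter_i, t_i = np.nonzero(np.isfinite(p_piv))
        out.append(
            pd.DataFrame(
                {
                    "interaction_id": np.asarray(inter_ids, dtype=object)[inter_i],
                    "player_id": players[slot_i, inter_i],
                    "period": t_i + 1,
                    "p_hat": p_piv[slot_i, inter_i, t_i],
                }
            )
        )
    preds = pd.concat(out, ignore_index=True)
    merged = ds.records.merge(
        preds, on=["interaction_id", "player_id", "period"], how="left", validate="one_to_one"
    )
    if merged["p_hat"].isna().any():
        raise RuntimeError("internal error: some records received no prediction")
    return merged


# ------------------------------------------------------------------ report

@dataclass
class MetricReport:
    """Per-structure metric table plus cross-structure summaries."""

    per_structure: pd.DataFrame
    summary: dict
    points: pd.DataFrame | None = None

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "summary": {k: float(v) for k, v in self.summary.items()},
                "per_structure": self.per_structure.to_dict(orient="index"),
            },
            default=float,
        )


def _individual_metrics(preds: pd.DataFrame) -> pd.DataFrame:
    rows = {}
    for sid, sub in preds.groupby("structure_id", sort=True):
        t1 = sub[sub["period"] == 1]
        tg = sub[sub["period"] > 1]
        rows[sid] = {
            "accuracy_t1": accuracy(t1["p_hat"], t1["action"]),
            "loglik_t1": log_likelihood(t1["p_hat"], t1["action"]),
            "n_t1": len(t1),
            "accuracy_tgt1": accuracy(tg["p_hat"], tg["action"]) if len(tg) else np.nan,
            "loglik_tgt1": log_likelihood(tg["p_hat"], tg["action"]) if len(tg) else 0.0,
            "n_tgt1": len(tg),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def loocv_individual(
    ds: Dataset, model_factory: ModelFactory, seed: int = 0
) -> tuple[pd.DataFrame, MetricReport]:
    """Leave-one-structure-out prediction of individual decisions.

    Each structure's decisions are predicted exactly once, by a model that
    saw no rows from that structure; predictions at t > 1 condition on the
    empirically observed lags.  Metrics are computed per structure and then
    averaged across structures (so each experimental design counts equally),
    with pooled versions alongside.
    """
    ids = sorted(ds.structures)
    if len(ids) < 2:
        raise ValueError("need at least two structures for cross-validation")
    all_preds = []
    for i, sid in enumerate(ids):
        train = ds.subset([s for s in ids if s != sid])
        policy = model_factory(train)
        fold_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % 2**31)
        all_preds.append(predict_records(policy, ds.subset([sid]), seed=fold_seed))
    preds = pd.concat(all_preds, ignore_index=True)
    per = _individual_metrics(preds)
    t1 = preds[preds["period"] == 1]
    tg = preds[preds["period"] > 1]
    summary = {
        "accuracy_t1": per["accuracy_t1"].mean(),
        "accuracy_tgt1": per["accuracy_tgt1"].mean(),
        "loglik_t1": per["loglik_t1"].mean(),
        "loglik_tgt1": per["loglik_tgt1"].mean(),
        "pooled_accuracy_t1": accuracy(t1["p_hat"], t1["action"]),
        "pooled_accuracy_tgt1": accuracy(tg["p_hat"], tg["action"]),
        "pooled_loglik_t1": log_likelihood(t1["p_hat"], t1["action"]),
        "pooled_loglik_tgt1": log_likelihood(tg["p_hat"], tg["action"]),
    }
    return preds, MetricReport(per_structure=per, summary=summary)


# --------------------------------------------------------------- aggregate

def observed_trajectory(ds: Dataset, structure_id: str, h: int) -> pd.DataFrame:
    """Observed per-period cooperation of one structure over periods 1..h."""
    sub = ds.records[ds.records["structure_id"] == structure_id]
    sub = sub[sub["period"] <= h]
    out = (
        sub.groupby("period")["action"]
        .agg(coop="mean", n="size")
        .reset_index()
    )
    return out


def aggregate_validation(
    ds: Dataset,
    model_factory: ModelFactory,
    cfg: SimulationConfig,
    plan: FoldPlan | None = None,
) -> MetricReport:
    """Forecast each held-out structure from its design alone and compare
    simulated with observed cooperation.

    For every fold the model is refit without the test structures, then each
    test structure is simulated.  Time-series RMSE/correlation pool all
    (structure, period) points inside the reporting horizon; average-level
    RMSE/correlation compare one overall mean per structure.  The number of
    pooled time points is surfaced in the summary rather than forced to any
    expected value.
    """
    ids = sorted(ds.structures)
    plan = plan or loocv_plan(ids)
    points = []
    per_rows = {}
    for fold in range(plan.k):
        test_ids = plan.test_ids(fold)
        train = ds.subset([s for s in ids if s not in set(test_ids)])
        policy = model_factory(train)
        for sid in test_ids:
            g = ds.structures[sid]
            h = horizon(g)
            sim_seed = int(
                np.random.SeedSequence([cfg.seed, ids.index(sid)]).generate_state(1)[0]
                % 2**31
            )
            traj = simulate_structure(g, policy, replace(cfg, seed=sim_seed))
            obs = observed_trajectory(ds, sid, h)
            sim_coop = traj.coop_by_period
            for _, row in obs.iterrows():
                t = int(row["period"])
                if t <= len(sim_coop):
                    points.append(
                        {
                            "structure_id": sid,
                            "period": t,
                            "sim": float(sim_coop[t - 1]),
                            "obs": float(row["coop"]),
                            "n_obs": int(row["n"]),
                        }
                    )
            obs_avg = float(
                ds.records.loc[ds.records["structure_id"] == sid, "action"].mean()
            )
            per_rows[sid] = {
                "sim_avg": traj.coop_overall,
                "obs_avg": obs_avg,
                "sq_err_avg": (traj.coop_overall - obs_avg) ** 2,
            }
    pts = pd.DataFrame(points)
    per = pd.DataFrame.from_dict(per_rows, orient="index")
    err = pts["sim"] - pts["obs"]
    summary = {
        "rmse_time": float(np.sqrt((err**2).mean())),
        "cor_time": _safe_corr(pts["sim"], pts["obs"]),
        "rmse_avg": float(np.sqrt(per["sq_err_avg"].mean())),
        "cor_avg": _safe_corr(per["sim_avg"], per["obs_avg"]),
        "n_points": float(len(pts)),
        "n_structures": float(len(per)),
    }
    return MetricReport(per_structure=per, summary=summary, points=pts)


def _safe_corr(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def kfold_sweep(
    ds: Dataset,
    model_factory: ModelFactory,
    cfg: SimulationConfig,
    k_values: Sequence[int],
    seeds: Sequence[int] = (0,),
) -> pd.DataFrame:
    """Aggregate validation repeated across fold counts and fold-assignment
    seeds; one row of metrics per (k, seed)."""
    ids = sorted(ds.structures)
    rows = []
    for k in k_values:
        for seed in seeds:
            plan = (
                loocv_plan(ids) if k == len(ids) else random_folds(ids, k, seed)
            )
            rep = aggregate_validation(ds, model_factory, cfg, plan)
            rows.append({"k": k, "fold_seed": seed, **rep.summary})
    return pd.DataFrame(rows)


# ------------------------------------------------------------ paired tests

@dataclass(frozen=True)
class PairedTestResult:
    """Classical paired-differences t-test plus a Welch two-sample variant.

    The stated procedure ("paired sample t-tests, not assuming equal
    variances") is internally tensioned — a paired test operates on
    differences and has no equal-variance assumption to drop — so both
    readings are reported.
    """

    paired_t: float
    paired_p_two: float
    paired_p_greater: float
    welch_t: float
    welch_p_two: float
    n: int
    degenerate: bool = False


def paired_comparison(metric_a, metric_b) -> PairedTestResult:
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need equal-length paired vectors with n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        t = 0.0 if np.allclose(d, 0.0) else np.inf * np.sign(d.mean())
        return PairedTestResult(
            paired_t=float(t),
            paired_p_two=1.0 if t == 0 else 0.0,
            paired_p_greater=0.5 if t == 0 else (0.0 if t > 0 else 1.0),
            welch_t=float("nan"),
            welch_p_two=float("nan"),
            n=len(a),
            degenerate=True,
        )
    tt = scipy.stats.ttest_rel(a, b)
    one_sided = tt.pvalue / 2 if tt.statistic > 0 else 1 - tt.pvalue / 2
    wt = scipy.stats.ttest_ind(a, b, equal_var=False)
    return PairedTestResult(
        paired_t=float(tt.statistic),
        paired_p_two=float(tt.pvalue),
        paired_p_greater=float(one_sided),
        welch_t=float(wt.statistic),
        welch_p_two=float(wt.pvalue),
        n=len(a),
    )
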