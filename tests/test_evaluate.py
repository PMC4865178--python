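"""Cross-validation harness: metrics, fold plans, leakage, paired tests."""

import numpy as np
import pandas as pd
import pytest

from coopsim import (
    BaselinePolicy,
    Dataset,
    GameStructure,
    SimulationConfig,
    accuracy,
    aggregate_validation,
    comparison_models,
    fit_full_model,
    kfold_sweep,
    log_likelihood,
    loocv_individual,
    loocv_plan,
    paired_comparison,
    predict_records,
    random_folds,
)
from coopsim.behavior import Policy
from coopsim.evaluate import FoldPlan


class TestAccuracy:
    def test_correct_and_incorrect(self):
        assert accuracy([0.9, 0.2], [1, 0]) == 1.0
        assert accuracy([0.9, 0.2], [0, 1]) == 0.0

    def test_tie_counts_as_defect(self):
        y = np.array([1, 0, 0, 1, 0])
        assert accuracy(np.full(5, 0.5), y) == pytest.approx((y == 0).mean())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy([], [])


class TestLogLikelihood:
    def test_half_probability_closed_form(self):
        assert log_likelihood(np.full(10, 0.5), np.ones(10)) == pytest.approx(10 * np.log(0.5))

    def test_confident_correct_predictions_approach_zero(self):
        y = np.array([1.0, 0.0])
        assert log_likelihood([1 - 1e-9, 1e-9], y) == pytest.approx(0.0, abs=1e-6)

    def test_matches_elementwise_loop_oracle(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.01, 0.99, 200)
        y = (rng.random(200) < 0.5).astype(float)
        expected = sum(
            np.log(pi) if yi == 1 else np.log(1 - pi) for pi, yi in zip(p, y)
        )
        assert log_likelihood(p, y) == pytest.approx(expected)


class TestFoldPlans:
    def test_loocv_is_singleton_partition(self):
        plan = loocv_plan(["a", "b", "c"])
        assert plan.is_loocv and plan.k == 3
        assert sorted(sum((plan.test_ids(f) for f in range(3)), [])) == ["a", "b", "c"]

    def test_random_folds_partition(self):
        ids = [f"s{i}" for i in range(10)]
        plan = random_folds(ids, 3, seed=0)
        assert sorted(sum((plan.test_ids(f) for f in range(3)), [])) == sorted(ids)

    def test_bad_fold_indices_rejected(self):
        with pytest.raises(ValueError):
            FoldPlan({"a": 0, "b": 2}, k=2)


class TestIndividualLoocv:
    def test_constant_half_policy_gives_closed_form_loglik(self, small_ds):
        preds, rep = loocv_individual(small_ds, lambda tr: BaselinePolicy(0.5))
        n = small_ds.n_decisions
        total = rep.summary["pooled_loglik_t1"] + rep.summary["pooled_loglik_tgt1"]
        assert total == pytest.approx(n * np.log(0.5))

    def test_each_structure_predicted_once(self, small_ds):
        preds, _ = loocv_individual(small_ds, lambda tr: BaselinePolicy(0.5))
        assert len(preds) == small_ds.n_decisions
        assert preds.groupby("structure_id").size().to_dict() == (
            small_ds.records.groupby("structure_id").size().to_dict()
        )

    def test_full_model_beats_baseline_on_ground_truth_data(self, small_ds):
        _, full = loocv_individual(small_ds, lambda tr: comparison_models(tr)["full"])
        _, base = loocv_individual(small_ds, lambda tr: comparison_models(tr)["baseline"])
        assert full.summary["accuracy_tgt1"] > base.summary["accuracy_tgt1"]

    def test_pooled_accuracy_is_record_weighted_mean(self, small_ds):
        _, rep = loocv_individual(small_ds, lambda tr: comparison_models(tr)["full"])
        per = rep.per_structure
        weighted = (per["accuracy_tgt1"] * per["n_tgt1"]).sum() / per["n_tgt1"].sum()
        assert rep.summary["pooled_accuracy_tgt1"] == pytest.approx(weighted)

    def test_no_leakage_from_held_out_structure(self, small_ds):
        """Perturbing a test structure's actions never changes the weights
        fit on the training fold."""
        ids = sorted(small_ds.structures)
        held, rest = ids[0], ids[1:]
        w1 = fit_full_model(small_ds.subset(rest)).dynamic.w
        corrupted = Dataset(
            structures=small_ds.structures,
            records=small_ds.records.assign(
                action=lambda d: np.where(
                    d["structure_id"] == held, 1 - d["action"], d["action"]
                )
            ),
        )
        w2 = fit_full_model(corrupted.subset(rest)).dynamic.w
        np.testing.assert_array_equal(w1, w2)


class _ObservedMeanPolicy(Policy):
    """Plays each structure's observed cooperation metadata exactly."""

    def prob(self, g, state, t, my_prev, other_prev, n):
        return np.full(n, g.cooperation)


class TestAggregateValidation:
    def test_identical_sim_and_obs_gives_zero_rmse_unit_cor(self):
        """Structures whose play is deterministic (all-C or all-D) are
        reproduced exactly by a policy playing the observed rate, so the
        time-series error vanishes and correlation is 1."""
        structs = [
            GameStructure(id="c1", r1=0.3, r2=0.6, delta=0.75, error=0.0,
                          infinite=0, continuous=0, risk=0, cooperation=1.0),
            GameStructure(id="c0", r1=0.3, r2=0.6, delta=0.75, error=0.0,
                          infinite=0, continuous=0, risk=0, cooperation=0.0),
        ]
        rows = []
        for g, act in (("c1", 1), ("c0", 0)):
            for k in range(3):
                for t in (1, 2, 3, 4):
                    for p in ("a", "b"):
                        rows.append((g, f"{g}-{k}", p, t, act))
        ds = Dataset.from_actions(
            structs, pd.DataFrame(rows, columns=[
                "structure_id", "interaction_id", "player_id", "period", "action"])
        )
        rep = aggregate_validation(
            ds, lambda tr: _ObservedMeanPolicy(), SimulationConfig(n_pairs=20, seed=0)
        )
        assert rep.summary["rmse_time"] == 0.0
        assert rep.summary["cor_time"] == pytest.approx(1.0)
        assert rep.summary["rmse_avg"] == 0.0

    def test_full_model_beats_baseline_on_declining_dynamics(self, small_ds):
        cfg = SimulationConfig(n_pairs=200, seed=1)
        full = aggregate_validation(small_ds, lambda tr: comparison_models(tr)["full"], cfg)
        base = aggregate_validation(small_ds, lambda tr: comparison_models(tr)["baseline"], cfg)
        assert full.summary["cor_time"] > base.summary["cor_time"]
        assert full.summary["rmse_time"] < base.summary["rmse_time"]

    def test_kfold_at_n_structures_reproduces_loocv(self, small_ds):
        cfg = SimulationConfig(n_pairs=100, seed=2)
        factory = lambda tr: comparison_models(tr)["full"]
        table = kfold_sweep(small_ds, factory, cfg, k_values=[len(small_ds.structures)])
        loocv = aggregate_validation(small_ds, factory, cfg, loocv_plan(small_ds.structures))
        row = table.iloc[0]
        assert row["rmse_time"] == pytest.approx(loocv.summary["rmse_time"])
        assert row["cor_time"] == pytest.approx(loocv.summary["cor_time"])

    def test_kfold_metrics_finite_down_to_two_folds(self, small_ds):
        cfg = SimulationConfig(n_pairs=100, seed=3)
        factory = lambda tr: comparison_models(tr)["full"]
        table = kfold_sweep(small_ds, factory, cfg, k_values=[5, 3, 2])
        assert np.isfinite(table[["rmse_time", "cor_time", "rmse_avg", "cor_avg"]]).all().all()


class TestPairedComparison:
    def test_identical_vectors_are_degenerate_zero(self):
        r = paired_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.paired_t == 0.0 and r.degenerate

    def test_hand_computed_three_element_example(self):
        # d = (1, 2, 3): mean 2, sd 1, t = 2 / (1/sqrt(3)) = 2*sqrt(3)
        r = paired_comparison([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert r.paired_t == pytest.approx(2 * np.sqrt(3))
        assert 0 < r.paired_p_two < 0.2
        assert r.paired_p_greater == pytest.approx(r.paired_p_two / 2)

    def test_constant_difference_p_shrinks_with_n(self):
        rng = np.random.default_rng(0)
        ps = []
        for n in (5, 50, 500):
            b = rng.normal(size=n)
            ps.append(paired_comparison(b + 1.0 + rng.normal(0, 0.1, n), b).paired_p_two)
        assert ps[0] > ps[1] > ps[2]
        assert ps[2] < 1e-10


def test_predict_records_aligns_with_input_rows(small_ds, fitted_model):
    from coopsim.behavior import FullModelPolicy

    preds = predict_records(FullModelPolicy(fitted_model), small_ds)
    assert len(preds) == small_ds.n_decisions
    assert preds["p_hat"].between(0, 1).all()
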