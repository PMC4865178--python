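"""Latin hypercube sampling, PRCC/SRRC, and the inertia analyses."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from coopsim import (
    Dataset,
    GameStructure,
    SimulationConfig,
    fit_full_model,
    inertia_actual,
    inertia_predicted,
    lhs_sample,
    prcc,
    run_analysis,
    srrc,
)
from coopsim.behavior import ModelWeights, FullModel
from coopsim.features import DYNAMIC_FEATURES, STATIC_FEATURES
from coopsim.synth import weights_as_model


class TestLhsSample:
    def test_one_sample_per_stratum_for_unconstrained_marginals(self):
        n = 64
        structs = lhs_sample(n, seed=5)
        for vals, lo, hi in (
            ([g.error for g in structs], 0.0, 0.5),
            ([g.delta for g in structs], 0.45, 0.95),
        ):
            strata = np.floor((np.array(vals) - lo) / (hi - lo) * n).astype(int)
            assert sorted(strata) == list(range(n))

    def test_constrained_pair_has_order_statistic_marginals(self):
        """Conditioning two uniforms on r1 < r2 makes their marginals the
        order statistics of a uniform pair, with means 1/3 and 2/3."""
        structs = lhs_sample(3000, seed=6)
        r1 = np.array([g.r1 for g in structs])
        r2 = np.array([g.r2 for g in structs])
        assert r1.mean() == pytest.approx(1 / 3, abs=0.02)
        assert r2.mean() == pytest.approx(2 / 3, abs=0.02)
        # stratification is only approximately preserved under the constraint
        assert len(np.unique(np.floor(r1 * 3000))) > 2000

    def test_r1_strictly_below_r2(self):
        assert all(g.r1 < g.r2 for g in lhs_sample(500, seed=1))

    def test_same_seed_reproduces_sample(self):
        assert lhs_sample(50, seed=9) == lhs_sample(50, seed=9)

    def test_continuous_fixed_at_zero_by_default(self):
        assert all(g.continuous == 0 for g in lhs_sample(50, seed=2))
        varied = lhs_sample(200, seed=2, continuous=0.5)
        assert 0 < sum(g.continuous for g in varied) < 200


def _naive_prcc(X, y):
    """Explicit rank-regression-residual correlation, naive loops."""
    Z = np.column_stack([X, y])
    R = np.apply_along_axis(scipy.stats.rankdata, 0, Z)
    p = X.shape[1]
    out = []
    for j in range(p):
        others = np.column_stack(
            [np.ones(len(y))] + [R[:, k] for k in range(p) if k != j]
        )
        bx, *_ = np.linalg.lstsq(others, R[:, j], rcond=None)
        by, *_ = np.linalg.lstsq(others, R[:, -1], rcond=None)
        rx, ry = R[:, j] - others @ bx, R[:, -1] - others @ by
        out.append(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    return np.array(out)


class TestPrcc:
    def test_matches_naive_oracle_to_1e10(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            X = rng.random((50, 4))
            y = rng.random(50)
            res = prcc(X, y, n_boot=10, seed=trial)
            assert np.abs(res.estimate - _naive_prcc(X, y)).max() < 1e-10

    def test_monotone_input_dominates(self):
        rng = np.random.default_rng(0)
        X = rng.random((300, 3))
        y = np.exp(X[:, 0])  # strictly monotone in input 0 only
        res = prcc(X, y, n_boot=100, seed=0)
        assert res.estimate[0] > 0.99
        assert np.abs(res.estimate[1:]).max() < 0.2

    def test_permuted_output_cis_cover_zero(self):
        rng = np.random.default_rng(1)
        X = rng.random((200, 3))
        y = X @ np.array([1.0, 0.5, -0.5])
        res = prcc(X, rng.permutation(y), n_boot=300, seed=1)
        assert np.all(res.ci_low <= 0) and np.all(res.ci_high >= 0)

    def test_invariant_to_monotone_transforms(self):
        rng = np.random.default_rng(2)
        X = rng.random((100, 3))
        y = X @ np.array([2.0, -1.0, 0.3]) + rng.normal(0, 0.2, 100)
        a = prcc(X, y, n_boot=10, seed=0).estimate
        X2 = X.copy()
        X2[:, 0] = np.exp(X2[:, 0])          # monotone input transform
        b = prcc(X2, y**3 + 5, n_boot=10, seed=0).estimate  # monotone output transform
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_constant_column_named_in_error(self):
        X = np.column_stack([np.ones(50), np.random.default_rng(0).random(50)])
        with pytest.raises(ValueError, match="'frozen'"):
            prcc(X, np.arange(50.0), names=("frozen", "ok"), n_boot=10)

    def test_ci_width_shrinks_like_root_n(self):
        rng = np.random.default_rng(4)
        widths = []
        for n in (500, 2000, 8000):
            X = rng.random((n, 3))
            y = X @ np.array([1.0, -0.5, 0.2]) + rng.normal(0, 1.0, n)
            res = prcc(X, y, n_boot=200, seed=0)
            widths.append((res.ci_high - res.ci_low).mean())
        assert widths[0] > widths[1] > widths[2]
        # quadrupling n should halve the width, within generous slack
        assert widths[0] / widths[1] == pytest.approx(2.0, rel=0.5)
        assert widths[1] / widths[2] == pytest.approx(2.0, rel=0.5)


class TestRunAnalysis:
    def test_input_blind_model_shows_no_sensitivity(self):
        zero = FullModel(
            static=ModelWeights("static", STATIC_FEATURES, np.zeros(10), np.ones(10), 0),
            dynamic=ModelWeights("dynamic", DYNAMIC_FEATURES, np.zeros(15), np.ones(15), 0),
        )
        res = run_analysis(zero, n_samples=150, cfg=SimulationConfig(n_pairs=100),
                           seed=0, n_boot=200)
        assert np.all(res.ci_low <= 0) and np.all(res.ci_high >= 0)

    def test_delta_effect_recovered_with_ci_excluding_zero(self, ground_truth):
        res = run_analysis(weights_as_model(ground_truth), n_samples=300,
                           cfg=SimulationConfig(n_pairs=100), seed=1, n_boot=200)
        j = res.names.index("delta")
        assert res.estimate[j] > 0 and res.ci_low[j] > 0

    def test_srrc_sign_pattern_matches_prcc(self, ground_truth):
        res, s = run_analysis(weights_as_model(ground_truth), n_samples=300,
                              cfg=SimulationConfig(n_pairs=100), seed=2,
                              n_boot=50, with_srrc=True)
        big = np.abs(res.estimate) > 0.1
        assert np.all(np.sign(s[big]) == np.sign(res.estimate[big]))


class TestInertia:
    def test_hand_counted_toy_sequences(self, toy_structure):
        # player a: C,C,D -> cooperated after cooperating 1 of 2 times
        # player b: C,D,D -> 0 of 1; pooled structure inertia = 1/3
        rows = [
            ("toy", "i1", "a", 1, 1), ("toy", "i1", "b", 1, 1),
            ("toy", "i1", "a", 2, 1), ("toy", "i1", "b", 2, 0),
            ("toy", "i1", "a", 3, 0), ("toy", "i1", "b", 3, 0),
        ]
        ds = Dataset.from_actions(
            [toy_structure],
            pd.DataFrame(rows, columns=["structure_id", "interaction_id",
                                        "player_id", "period", "action"]),
        )
        assert inertia_actual(ds)["toy"] == pytest.approx(1 / 3)

    def test_all_cooperate_gives_unit_inertia(self, toy_structure):
        rows = [("toy", "i1", p, t, 1) for t in (1, 2, 3) for p in ("a", "b")]
        ds = Dataset.from_actions(
            [toy_structure],
            pd.DataFrame(rows, columns=["structure_id", "interaction_id",
                                        "player_id", "period", "action"]),
        )
        assert inertia_actual(ds)["toy"] == 1.0

    def test_matches_naive_loop_oracle(self, small_ds):
        got = inertia_actual(small_ds)
        for sid in small_ds.structures:
            num = den = 0
            for r in small_ds.records.itertuples():
                if r.structure_id == sid and r.my_prev == 1:
                    den += 1
                    num += r.action
            assert got[sid] == pytest.approx(num / den)

    def test_marginalization_collapses_when_model_ignores_time_and_opponent(self, small_ds):
        w = np.zeros(15)
        names = DYNAMIC_FEATURES
        w[names.index("intercept")] = -1.0
        w[names.index("my_prev")] = 2.0
        m = FullModel(
            static=ModelWeights("static", STATIC_FEATURES, np.zeros(10), np.ones(10), 0),
            dynamic=ModelWeights("dynamic", names, w, np.ones(15), 0),
        )
        g = next(iter(small_ds.structures.values()))
        from coopsim import predict

        assert inertia_predicted(m, g, small_ds) == pytest.approx(
            predict(m, g, my_prev=1, other_prev=0, t=2)
        )

    def test_predicted_tracks_actual_on_ground_truth_data(self, synth_ds, fitted_model):
        actual = inertia_actual(synth_ds)
        predicted = pd.Series(
            {sid: inertia_predicted(fitted_model, synth_ds.structures[sid], synth_ds)
             for sid in sorted(synth_ds.structures)}
        )
        joined = pd.concat([actual, predicted], axis=1).dropna()
        assert joined.corr().iloc[0, 1] > 0.9
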