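import numpy as np
import pytest

from f1ci import ProbabilityTable, normalize
from f1ci.confusion_io import ConfusionCounts
from f1ci.delta_ci import var_macro, var_macro_star, var_micro
from f1ci.point_metrics import macro_f1, macro_f1_star, micro_f1
from f1ci.simulation import (
    ScenarioSpec,
    batch_estimates,
    builtin_scenarios,
    coverage_study,
    coverage_table,
    scenario_by_name,
    simulate_tables,
)


class TestScenarios:
    def test_true_scores_match_analytic_recomputation(self):
        for sc in builtin_scenarios():
            assert sc.true_scores["miF1"] == micro_f1(sc.p_true)
            assert sc.true_scores["maF1"] == macro_f1(sc.p_true)
            assert sc.true_scores["maF1star"] == macro_f1_star(sc.p_true)[0]

    @pytest.mark.parametrize(
        "name, expected",
        [
            ("1", (0.80, 0.80, 0.80)),
            ("2", (0.72, 0.50, 0.51)),
            ("3", (0.48, 0.44, 0.55)),
        ],
    )
    def test_builtin_truths(self, name, expected):
        sc = scenario_by_name(name)
        got = (
            sc.true_scores["miF1"],
            sc.true_scores["maF1"],
            sc.true_scores["maF1star"],
        )
        assert got == pytest.approx(expected, abs=0.005)

    def test_scenario1_is_symmetric(self):
        sc = scenario_by_name("1")
        np.testing.assert_allclose(np.diag(sc.p_true.p), 8 / 30)
        assert sc.p_true.p.sum() == pytest.approx(1.0, abs=1e-12)


class TestSimulateTables:
    def test_each_table_sums_to_n(self):
        sc = scenario_by_name("2")
        tabs = simulate_tables(sc.p_true, n=37, reps=200, seed=3)
        assert tabs.shape == (200, 3, 3)
        np.testing.assert_array_equal(tabs.sum(axis=(1, 2)), 37)

    def test_degenerate_distribution_concentrates(self):
        p = np.zeros((3, 3))
        p[1, 1] = 1.0
        pt = ProbabilityTable(p)
        tabs = simulate_tables(pt, n=50, reps=20, seed=0)
        assert (tabs[:, 1, 1] == 50).all()

    def test_seed_reproducibility(self):
        sc = scenario_by_name("1")
        a = simulate_tables(sc.p_true, 100, 50, seed=11)
        b = simulate_tables(sc.p_true, 100, 50, seed=11)
        np.testing.assert_array_equal(a, b)
        c = simulate_tables(sc.p_true, 100, 50, seed=12)
        assert not np.array_equal(a, c)

    def test_cell_mean_matches_multinomial_moment(self):
        sc = scenario_by_name("1")
        n, reps = 5000, 10_000
        tabs = simulate_tables(sc.p_true, n, reps, seed=5)
        p11_hat = tabs[:, 0, 0].mean() / n
        p = 8 / 30
        assert abs(p11_hat - p) < 3 * np.sqrt(p * (1 - p) / (n * reps))


class TestBatchEstimates:
    def test_matches_scalar_path(self, rng):
        sc = scenario_by_name("3")
        n = 200
        tabs = simulate_tables(sc.p_true, n, 20, seed=9)
        be = batch_estimates(tabs, n)
        for k, tab in enumerate(tabs):
            pt = normalize(ConfusionCounts(tab, sc.p_true.class_labels))
            assert be["miF1"]["estimate"][k] == pytest.approx(micro_f1(pt))
            assert be["miF1"]["variance"][k] == pytest.approx(var_micro(pt, n))
            assert be["maF1"]["estimate"][k] == pytest.approx(macro_f1(pt))
            assert be["maF1"]["variance"][k] == pytest.approx(
                var_macro(pt, n), rel=1e-10
            )
            assert be["maF1star"]["estimate"][k] == pytest.approx(
                macro_f1_star(pt)[0]
            )
            assert be["maF1star"]["variance"][k] == pytest.approx(
                var_macro_star(pt, n), rel=1e-10
            )

    def test_undefined_replicates_are_nan(self):
        # class 3 never predicted nor true in the second table
        tabs = np.array(
            [
                [[5, 1, 0], [1, 5, 1], [0, 1, 6]],
                [[10, 2, 0], [3, 5, 0], [0, 0, 0]],
            ]
        )
        be = batch_estimates(tabs, 20)
        assert np.isfinite(be["maF1"]["estimate"][0])
        assert np.isnan(be["maF1"]["estimate"][1])
        assert np.isnan(be["maF1star"]["estimate"][1])
        assert np.isfinite(be["miF1"]["estimate"]).all()


class TestCoverage:
    def test_bookkeeping_and_determinism(self):
        sc = scenario_by_name("2")
        res1 = coverage_study(sc, n=25, reps=4000, seed=21)
        res2 = coverage_study(sc, n=25, reps=4000, seed=21)
        assert res1 == res2
        for r in res1.values():
            assert r.reps_evaluable <= r.reps_requested
            assert 0.0 <= r.coverage <= 1.0
            denom = r.reps_evaluable
            assert r.mc_standard_error == pytest.approx(
                np.sqrt(r.coverage * (1 - r.coverage) / denom)
            )
        # small-n maF1* replicates with a zero margin must exist and be dropped
        assert res1["maF1star"].reps_evaluable < res1["maF1star"].reps_requested

    def test_noncover_policy_penalizes_undefined(self):
        sc = scenario_by_name("2")
        drop = coverage_study(sc, n=25, reps=4000, seed=21)["maF1star"]
        pen = coverage_study(
            sc, n=25, reps=4000, seed=21, undefined_policy="noncover"
        )["maF1star"]
        assert pen.reps_covering == drop.reps_covering
        assert pen.coverage < drop.coverage

    def test_degenerate_truth_boundary_coverage_is_one(self):
        p = np.zeros((2, 2))
        p[0, 0] = 1.0
        spec = ScenarioSpec("point_mass", ProbabilityTable(p), {"miF1": 1.0})
        res = coverage_study(spec, n=50, reps=500, seed=1, measures=("miF1",))
        assert res["miF1"].coverage == 1.0

    def test_nominal_coverage_at_large_n(self):
        sc = scenario_by_name("1")
        res = coverage_study(sc, n=5000, reps=20_000, seed=4)
        for r in res.values():
            assert r.coverage == pytest.approx(0.95, abs=3 * r.mc_standard_error + 0.002)

    def test_small_n_undercoverage_trend(self):
        sc = scenario_by_name("2")
        small = coverage_study(sc, n=25, reps=20_000, seed=4)["maF1"]
        large = coverage_study(sc, n=5000, reps=20_000, seed=4)["maF1"]
        assert small.coverage < large.coverage

    def test_estimator_consistency_at_large_n(self):
        sc = scenario_by_name("1")
        n, reps = 5000, 10_000
        tabs = simulate_tables(sc.p_true, n, reps, seed=8)
        est = batch_estimates(tabs, n)["miF1"]["estimate"]
        mc_se = est.std(ddof=1) / np.sqrt(reps)
        assert abs(est.mean() - sc.true_scores["miF1"]) < 3 * mc_se

    def test_coverage_table_shape_and_determinism(self):
        df1 = coverage_table(n_grid=(25, 100), reps=1500, seed=13)
        df2 = coverage_table(n_grid=(25, 100), reps=1500, seed=13)
        assert df1.shape == (2, 9)
        assert ((df1.fillna(-1) >= -1) & (df1.fillna(2) <= 2)).all().all()
        assert df1.equals(df2)
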