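"""Prior sampling, rejection, model choice, GOF and posterior adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from cycadiv import coalsim
from cycadiv.abcinf import (
    Prior,
    PriorSet,
    Rejection,
    SimTable,
    adjust_parameters,
    build_reference_table,
    default_priors,
    goodness_of_fit,
    model_posterior,
    prune_correlated,
    rejection,
    sample_priors,
    weighted_interval,
)
from cycadiv.coalsim import SimConfig


def fake_table(stats: np.ndarray, models=None, params: np.ndarray | None = None,
               stat_names=None, param_names=None) -> SimTable:
    n, s = stats.shape
    stat_names = stat_names or [f"x{j}" for j in range(s)]
    models = models if models is not None else ["M"] * n
    cols = {"model": models}
    param_names = param_names or []
    if params is not None:
        param_names = param_names or [f"p{j}" for j in range(params.shape[1])]
        for j, name in enumerate(param_names):
            cols[name] = params[:, j]
    for j, name in enumerate(stat_names):
        cols[name] = stats[:, j]
    return SimTable(pd.DataFrame(cols), stat_names, param_names)


class TestSamplePriors:
    def test_uniform_mean_law_of_large_numbers(self):
        ps = default_priors()
        ps.priors["mu"] = Prior("uniform", 0.0, 1.0)
        draws = sample_priors(ps, 10_000, seed=1)
        assert abs(draws["mu"].mean() - 0.5) < 0.02

    def test_time_ordering_always_satisfied(self):
        draws = sample_priors(default_priors(), 5000, seed=2)
        assert (draws["t1"] <= draws["t2"]).all()
        assert (draws["t2"] <= draws["t3"]).all()

    def test_loguniform_log_draws_are_uniform(self):
        draws = sample_priors(default_priors(), 4000, seed=3)
        z = (np.log10(draws["m_CT1"]) + 8.0) / 8.0  # map [1e-8, 1] -> [0, 1]
        assert kstest(z, "uniform").pvalue > 0.01

    def test_reproducible(self):
        a = sample_priors(default_priors(), 50, seed=9)
        b = sample_priors(default_priors(), 50, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError):
            Prior("uniform", 1.0, 1.0)
        with pytest.raises(ValueError):
            Prior("loguniform", 0.0, 1.0)


class TestBuildReferenceTable:
    @pytest.fixture(scope="class")
    def small_table(self):
        cfg = SimConfig(n_CR=5, n_CT=3, n_loci=30, seed=0)
        return build_reference_table(["CG", "PC", "CI", "SC"], default_priors(),
                                     cfg, 25, seed=17)

    def test_row_count(self, small_table):
        assert len(small_table.table) == 100
        assert small_table.table["model"].value_counts().tolist() == [25] * 4

    def test_no_undefined_statistics(self, small_table):
        assert np.isfinite(small_table.stats()).all()

    def test_identical_seed_identical_table(self):
        cfg = SimConfig(n_CR=4, n_CT=3, n_loci=15, seed=0)
        a = build_reference_table(["CG"], default_priors(), cfg, 10, seed=5)
        b = build_reference_table(["CG"], default_priors(), cfg, 10, seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_save_load_round_trip(self, small_table, tmp_path):
        tsv, meta = tmp_path / "t.tsv", tmp_path / "t.json"
        small_table.save(tsv, meta)
        back = SimTable.load(tsv, meta)
        assert back.stat_names == small_table.stat_names
        np.testing.assert_allclose(back.stats(), small_table.stats())


class TestPruneCorrelated:
    def test_duplicate_column_kept_once(self, rng):
        x = rng.normal(size=(200, 1))
        tab = fake_table(np.hstack([x, x, rng.normal(size=(200, 1))]))
        assert prune_correlated(tab) == ["x0", "x2"]

    def test_near_linear_dependency_dropped(self, rng):
        x = rng.normal(size=200)
        tab = fake_table(np.column_stack([x, 2 * x + rng.normal(0, 1e-8, 200)]))
        assert prune_correlated(tab) == ["x0"]

    def test_independent_columns_all_retained(self, rng):
        tab = fake_table(rng.normal(size=(500, 5)))
        assert prune_correlated(tab) == [f"x{j}" for j in range(5)]

    def test_constant_column_dropped_first(self, rng):
        tab = fake_table(np.column_stack([np.ones(100), rng.normal(size=100)]))
        assert prune_correlated(tab) == ["x1"]


class TestRejection:
    def test_exact_match_gets_distance_zero_weight_one(self, rng):
        X = rng.normal(size=(50, 4))
        tab = fake_table(X)
        rej = rejection(X[7], tab, k=10)
        assert rej.index[0] == 7
        assert rej.distance[0] == 0.0
        assert rej.weight[0] == pytest.approx(1.0)

    def test_k_equal_to_all_rows(self, rng):
        X = rng.normal(size=(30, 3))
        tab = fake_table(X)
        rej = rejection(X.mean(0), tab, k=30)
        assert len(rej.index) == 30

    def test_k_too_large_errors(self, rng):
        tab = fake_table(rng.normal(size=(10, 2)))
        with pytest.raises(ValueError, match="exceeds"):
            rejection(np.zeros(2), tab, k=11)

    def test_five_row_toy_matches_brute_force_sort(self):
        X = np.array([[0.0], [1.0], [2.0], [5.0], [10.0]])
        tab = fake_table(X)
        obs = np.array([1.9])
        rej = rejection(obs, tab, k=3)
        mad = np.median(np.abs(X - np.median(X)))
        d = np.abs((X[:, 0] - 1.9) / mad)
        assert list(rej.index) == list(np.argsort(d, kind="stable")[:3])
        dk = np.sort(d)[2]
        np.testing.assert_allclose(rej.weight, 1 - (np.sort(d)[:3] / dk) ** 2)

    def test_row_order_invariance(self, rng):
        X = rng.normal(size=(40, 3))
        tab = fake_table(X)
        perm = rng.permutation(40)
        tab2 = fake_table(X[perm])
        obs = rng.normal(size=3)
        a = rejection(obs, tab, k=12)
        b = rejection(obs, tab2, k=12)
        np.testing.assert_allclose(np.sort(a.distance), np.sort(b.distance))


class TestModelPosterior:
    def _result(self, weights_by_model):
        models, weights = [], []
        for m, ws in weights_by_model.items():
            models += [m] * len(ws)
            weights += list(ws)
        n = len(models)
        tab = fake_table(np.zeros((n, 1)), models=models)
        rej = Rejection(index=np.arange(n), distance=np.zeros(n),
                        weight=np.array(weights, float), stat_names=["x0"],
                        scale=np.ones(1))
        return model_posterior(tab, rej)

    def test_equal_weights_give_uniform_posterior_and_unit_bf(self):
        res = self._result({m: [1.0] for m in ["CG", "PC", "CI", "SC"]})
        for m in res.posterior:
            assert res.posterior[m] == pytest.approx(0.25)
            assert res.bayes_factor[m] == pytest.approx(1.0)

    def test_weight_shares_are_posteriors(self):
        res = self._result({"A": [60.0], "B": [30.0], "C": [9.0], "D": [1.0]})
        assert res.posterior == pytest.approx(
            {"A": 0.6, "B": 0.3, "C": 0.09, "D": 0.01})

    def test_splitting_a_model_preserves_total_mass(self):
        merged = self._result({"A": [40.0, 20.0], "B": [40.0]})
        split = self._result({"A1": [40.0], "A2": [20.0], "B": [40.0]})
        assert (split.posterior["A1"] + split.posterior["A2"]
                == pytest.approx(merged.posterior["A"]))

    def test_posteriors_sum_to_one(self, rng):
        res = self._result({m: rng.random(5) for m in "WXYZ"})
        assert sum(res.posterior.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_model_warns(self):
        with pytest.warns(UserWarning, match="zero retained"):
            res = self._result({"A": [1.0], "B": [0.0]})
        assert res.posterior["B"] == 0.0


class TestGoodnessOfFit:
    def test_duplicated_row_fits_well(self, rng):
        X = rng.normal(size=(300, 4))
        tab = fake_table(X)
        g = goodness_of_fit(X[5], tab, k=1, n_null=200, seed=1)
        assert g.p_value >= 0.95

    def test_distant_observation_rejected(self, rng):
        X = rng.normal(size=(300, 4))
        tab = fake_table(X)
        g = goodness_of_fit(np.full(4, 100.0), tab, k=10, n_null=200, seed=1)
        assert g.p_value <= 0.01

    def test_null_cap_warns(self, rng):
        tab = fake_table(rng.normal(size=(50, 2)))
        with pytest.warns(UserWarning, match="capped"):
            goodness_of_fit(np.zeros(2), tab, k=5, n_null=100, seed=0)


class TestWeightedInterval:
    def test_interpolated_median_convention(self):
        lo, med, hi = weighted_interval(np.array([10, 20, 30, 40.0]),
                                        np.ones(4))
        assert med == pytest.approx(25.0)

    def test_point_mass(self):
        lo, med, hi = weighted_interval(np.array([1.0, 7.0, 3.0]),
                                        np.array([0.0, 5.0, 0.0]))
        assert (lo, med, hi) == (7.0, 7.0, 7.0)

    def test_matches_resampling_quantiles(self, rng):
        x = rng.normal(size=200)
        w = rng.random(200)
        lo, med, hi = weighted_interval(x, w)
        resamp = rng.choice(x, size=1_000_000, p=w / w.sum())
        for got, q in [(lo, 0.025), (med, 0.5), (hi, 0.975)]:
            ref = np.quantile(resamp, q)
            assert got == pytest.approx(ref, abs=0.01 * (x.max() - x.min()))

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_interval(np.array([1.0]), np.array([0.0]))


class TestAdjustParameters:
    def _table_with_params(self, rng, n=5000, slope=2.0, noise=1.0,
                           informative=True):
        x = rng.normal(size=(n, 3))
        theta = np.exp(slope * x[:, 0] + rng.normal(0, noise, n)) if informative \
            else np.exp(rng.normal(0, 1, n))
        return fake_table(x, params=theta[:, None], param_names=["theta"])

    def test_weighted_median_equal_weights(self):
        _, med, _ = weighted_interval(np.array([1.0, 2.0, 3.0]), np.ones(3))
        assert med == 2.0

    def test_uninformative_statistics_leave_summary_unchanged(self, rng):
        tab = self._table_with_params(rng, n=2000, informative=False)
        obs = np.zeros(3)
        rej = rejection(obs, tab, k=500)
        raw = adjust_parameters(tab, rej, method="rejection")
        adj = adjust_parameters(tab, rej, method="loclinear")
        m_raw = raw.summary.loc["theta", "median"]
        m_adj = adj.summary.loc["theta", "median"]
        assert abs(m_adj - m_raw) / m_raw < 0.05

    def test_loclinear_recovers_linear_signal(self, rng):
        # theta = exp(a * x0 + eps): at the observation x0 = 1 the adjusted
        # log-posterior median must sit near a * 1 within 5% of the span
        tab = self._table_with_params(rng, n=5000, slope=2.0, noise=0.3)
        obs = np.array([1.0, 0.0, 0.0])
        rej = rejection(obs, tab, k=1000)
        adj = adjust_parameters(tab, rej, method="loclinear")
        assert np.log(adj.summary.loc["theta", "median"]) == pytest.approx(
            2.0, abs=0.1)

    def test_needs_enough_rows(self, rng):
        tab = self._table_with_params(rng, n=100)
        rej = rejection(np.zeros(3), tab, k=20)
        with pytest.raises(ValueError, match="50"):
            adjust_parameters(tab, rej, method="loclinear")

    def test_neuralnet_runs_and_respects_log_scale(self, rng):
        tab = self._table_with_params(rng, n=400, slope=1.0, noise=0.5)
        rej = rejection(np.array([0.5, 0, 0]), tab, k=200)
        adj = adjust_parameters(tab, rej, method="neuralnet", seed=0)
        assert (adj.sample["theta"] > 0).all()
        s = adj.summary.loc["theta"]
        assert s["lo"] <= s["median"] <= s["hi"]
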