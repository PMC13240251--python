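import numpy as np
import pytest

import spadspec as sp
from spadspec.indices import compute_index_table
from spadspec.models import fit_rf, fit_single_index, predict_single_index, spxy_split
from spadspec.preprocess import apply_chain

from ._spxy_oracle import spxy_oracle_train_indices


class TestSpxySplit:
    def test_partition_sizes(self):
        rng = np.random.default_rng(0)
        X, y = rng.normal(size=(10, 3)), rng.normal(size=10)
        split = spxy_split(X, y, test_fraction=0.2)
        assert len(split.train_ids) == 8 and len(split.test_ids) == 2
        assert set(split.train_ids) | set(split.test_ids) == set(range(10))
        assert set(split.train_ids) & set(split.test_ids) == set()

    def test_farthest_pair_always_in_train(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            X, y = rng.normal(size=(12, 2)), rng.normal(size=12)
            from scipy.spatial.distance import pdist, squareform

            dX = squareform(pdist(X))
            dY = np.abs(y[:, None] - y[None, :])
            d = dX / dX.max() + dY / dY.max()
            i, j = np.unravel_index(np.argmax(d), d.shape)
            split = spxy_split(X, y, 0.2)
            assert i in split.train_ids and j in split.train_ids

    def test_matches_bruteforce_oracle_small_n(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(5, 9))
            X = rng.normal(size=(n, int(rng.integers(1, 4))))
            y = rng.normal(size=n)
            n_train = int(round(0.8 * n))
            n_train = min(max(n_train, 2), n - 1)
            split = spxy_split(X, y, test_fraction=0.2)
            oracle = spxy_oracle_train_indices(X.tolist(), y.tolist(), n_train)
            assert split.train_ids == oracle

    def test_permutation_invariant_up_to_relabeling(self):
        rng = np.random.default_rng(3)
        X, y = rng.normal(size=(15, 4)), rng.normal(size=15)
        ids = [f"s{i}" for i in range(15)]
        perm = rng.permutation(15)
        a = spxy_split(X, y, 0.2, ids=ids)
        b = spxy_split(X[perm], y[perm], 0.2, ids=[ids[p] for p in perm])
        assert set(a.train_ids) == set(b.train_ids)

    def test_degenerate_identical_data_rejected(self):
        X = np.ones((6, 2))
        y = np.ones(6)
        with pytest.raises(ValueError, match="degenerate"):
            spxy_split(X, y)


class TestSingleIndexFits:
    def test_exact_linear_data(self):
        x = np.linspace(0.1, 2.0, 20)
        rep = fit_single_index(x, 2 * x + 1, "linear")
        assert rep.train_metrics.r2 == pytest.approx(1.0)
        assert rep.train_metrics.rmse == pytest.approx(0.0, abs=1e-9)
        assert rep.params["slope"] == pytest.approx(2.0)

    def test_quadratic_nests_linear(self):
        rng = np.random.default_rng(4)
        x = np.linspace(-1, 1, 50)
        y = 3 * x**2 + x + rng.normal(0, 0.1, 50) + 10
        r_lin = fit_single_index(x, y, "linear").train_metrics.r2
        r_quad = fit_single_index(x, y, "quadratic").train_metrics.r2
        assert r_lin <= r_quad + 1e-12

    def test_exponential_recovers_parameters(self):
        x = np.linspace(0.1, 2.0, 40)
        y = 5.0 * np.exp(0.7 * x)
        rep = fit_single_index(x, y, "exponential")
        assert rep.params["a"] == pytest.approx(5.0, rel=1e-6)
        assert rep.params["b"] == pytest.approx(0.7, rel=1e-6)

    def test_power_recovers_parameters(self):
        x = np.linspace(0.5, 3.0, 40)
        y = 2.0 * x**1.5
        rep = fit_single_index(x, y, "power")
        assert rep.params["a"] == pytest.approx(2.0, rel=1e-6)
        assert rep.params["b"] == pytest.approx(1.5, rel=1e-6)

    def test_power_not_fittable_on_nonpositive_index(self):
        x = np.array([-0.3, 0.2, 0.5, 0.9, 1.3])
        rep = fit_single_index(x, np.abs(x) * 10 + 40, "power")
        assert rep.status == "not_fittable"
        assert rep.train_metrics is None

    def test_in_sample_r2_equals_squared_pearson_of_fit(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0.5, 2, 60)
        y = 30 + 12 * x + rng.normal(0, 1, 60)
        rep = fit_single_index(x, y, "linear")
        fitted = predict_single_index(rep, x)
        assert rep.train_metrics.r2 == pytest.approx(
            sp.pearson_r(fitted, y) ** 2, abs=1e-9
        )


class TestRandomForest:
    @pytest.fixture(scope="class")
    def v12_tables(self):
        cfg = sp.GeneratorConfig(
            groups=(sp.GroupSpec("V12", "apical", 100, 50.6, 4.3),), seed=11
        )
        samples, _ = sp.generate_dataset(cfg)
        proc = apply_chain(samples, "SG-MSC")
        table = compute_index_table(proc)
        split = spxy_split(
            table.values.to_numpy(), proc.spad, 0.2, ids=list(table.values.index)
        )
        return table, proc.spad, split

    def test_reproducible_under_fixed_seed(self, v12_tables):
        table, spad, split = v12_tables
        grid = (50,)
        a = fit_rf(table, spad, split, n_trees_grid=grid, mtry_values=[4, 8], seed=7)
        b = fit_rf(table, spad, split, n_trees_grid=grid, mtry_values=[4, 8], seed=7)
        assert a.params == b.params
        assert a.test_metrics.r2 == b.test_metrics.r2

    def test_learns_spad_signal(self, v12_tables):
        table, spad, split = v12_tables
        rep = fit_rf(table, spad, split, n_trees_grid=(100,), mtry_values=[7], seed=0)
        assert rep.test_metrics.r2 >= 0.6
        assert rep.test_metrics.rpd >= 1.4

    def test_permuted_labels_destroy_signal(self, v12_tables):
        table, spad, split = v12_tables
        rng = np.random.default_rng(0)
        rep = fit_rf(
            table,
            rng.permutation(spad),
            split,
            n_trees_grid=(100,),
            mtry_values=[7],
            seed=0,
        )
        assert rep.test_metrics.r2 < 0.15

    def test_more_trees_do_not_hurt_training_fit(self, v12_tables):
        table, spad, split = v12_tables
        small = fit_rf(table, spad, split, n_trees_grid=(5,), mtry_values=[7], seed=0)
        big = fit_rf(table, spad, split, n_trees_grid=(500,), mtry_values=[7], seed=0)
        assert big.train_metrics.r2 >= small.train_metrics.r2 - 0.02

    def test_single_tree_ensemble_equals_that_tree(self, v12_tables):
        from sklearn.ensemble import RandomForestRegressor

        table, spad, split = v12_tables
        X = table.values.to_numpy()
        pos = {sid: i for i, sid in enumerate(table.values.index)}
        tr = np.array([pos[s] for s in split.train_ids])
        rf = RandomForestRegressor(
            n_estimators=1, max_features=5, bootstrap=True, random_state=3
        ).fit(X[tr], spad[tr])
        # the tree-average prediction with T=1 is the single tree's output
        np.testing.assert_allclose(
            rf.predict(X), rf.estimators_[0].predict(X), atol=1e-12
        )
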