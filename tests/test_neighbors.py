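import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from dendromass import (
    METRICS, WEIGHTINGS, KNNBiomassRegressor, KNNConfig, NeighborSet,
    TreeDataset, find_neighbors, generate, loocv_predict, weighted_estimate,
)


def _nbs(distances, biomass):
    d = np.asarray(distances, float)
    return NeighborSet(indices=np.arange(d.size), record_ids=np.arange(d.size),
                       distances=d, biomass=np.asarray(biomass, float))


def _ds_from_columns(**cols):
    n = len(next(iter(cols.values())))
    base = {"record_id": np.arange(n), "dbh": np.full(n, 5.0),
            "dm": np.full(n, 1.0), "ht": np.full(n, 6.0), "hc": np.full(n, 1.0),
            "da": np.full(n, 0.6), "db": np.full(n, 0.5), "w": np.full(n, 10.0)}
    base.update(cols)
    return TreeDataset(records=pd.DataFrame(base)).validate()


class TestWeightedEstimate:
    @pytest.mark.parametrize("weighting", WEIGHTINGS)
    def test_single_neighbor_returns_its_biomass(self, weighting):
        assert weighted_estimate(_nbs([0.7], [12.3]), weighting) == 12.3

    def test_hand_computed_weighted_means(self):
        nbs = _nbs([1.0, 2.0], [10.0, 20.0])
        assert weighted_estimate(nbs, "inv_d") == pytest.approx(40.0 / 3.0)
        assert weighted_estimate(nbs, "inv_d2") == pytest.approx(12.0)

    def test_equidistant_neighbors_give_arithmetic_mean(self):
        nbs = _nbs([0.4, 0.4, 0.4], [3.0, 6.0, 12.0])
        for weighting in WEIGHTINGS:
            assert weighted_estimate(nbs, weighting) == pytest.approx(7.0)

    def test_zero_distance_falls_back_to_exact_matches(self):
        nbs = _nbs([0.0, 0.0, 1.0], [4.0, 8.0, 100.0])
        for weighting in WEIGHTINGS:
            assert weighted_estimate(nbs, weighting) == pytest.approx(6.0)


class TestFindNeighbors:
    def test_two_records_are_mutual_neighbors(self):
        ds = _ds_from_columns(dbh=np.array([5.0, 9.0]), w=np.array([3.0, 7.0]))
        cfg = KNNConfig(metric="euclidean", k_neighbors=1, variables=("dbh",))
        assert find_neighbors(0, ds, cfg).indices[0] == 1
        assert find_neighbors(1, ds, cfg).indices[0] == 0

    def test_distance_ties_break_by_record_position(self):
        # records 3 and 7 both at distance 2 from the query at position 0
        dbh = np.array([5.0, 1.0, 9.5, 7.0, 1.5, 9.0, 1.2, 3.0])
        ds = _ds_from_columns(dbh=dbh)
        cfg = KNNConfig(metric="euclidean", k_neighbors=1, variables=("dbh",))
        nbs = find_neighbors(0, ds, cfg)
        assert nbs.indices[0] == 3
        assert nbs.distances[0] == 2.0

    def test_query_never_among_its_own_neighbors(self, ds50):
        cfg = KNNConfig(metric="chebyshev", k_neighbors=5)
        for i in (0, 17, 49):
            assert i not in find_neighbors(i, ds50, cfg).indices

    @pytest.mark.parametrize("metric", METRICS)
    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_matches_exhaustive_sort_oracle(self, metric, k):
        ds = generate(n=30, seed=5)
        X = ds.records[["dbh", "ht"]].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cfg = KNNConfig(metric=metric, k_neighbors=k, variables=("dbh", "ht"))
        for i in range(30):
            # independent oracle: per-pair distances, python sort
            dists = []
            for j in range(30):
                if j == i:
                    continue
                delta = np.abs(X[i] - X[j])
                d = {"euclidean": np.sqrt((delta**2).sum()),
                     "quadratic_euclidean": (delta**2).sum(),
                     "manhattan": delta.sum(),
                     "chebyshev": delta.max()}[metric]
                dists.append((d, j))
            expected = [j for _, j in sorted(dists, key=lambda t: (t[0], t[1]))][:k]
            assert list(find_neighbors(i, ds, cfg).indices) == expected

    def test_k_must_leave_room_for_the_query(self, tiny_ds):
        cfg = KNNConfig(metric="euclidean", k_neighbors=3, variables=("dbh",))
        with pytest.raises(ValueError, match="k_neighbors"):
            find_neighbors(0, tiny_ds, cfg)


class TestLOOCV:
    def test_identical_features_swap_biomass(self):
        ds = _ds_from_columns(w=np.array([5.0, 7.0]))
        cfg = KNNConfig(metric="euclidean", k_neighbors=1, variables=("dbh",))
        preds = loocv_predict(ds, cfg)
        np.testing.assert_allclose(preds.predicted, [7.0, 5.0])

    def test_prediction_is_convex_combination_of_neighbors(self, ds50):
        cfg = KNNConfig(metric="manhattan", k_neighbors=5)
        preds = loocv_predict(ds50, cfg)
        w = ds50.records["w"].to_numpy()
        for i in range(ds50.n):
            nbs = find_neighbors(i, ds50, cfg)
            assert nbs.biomass.min() - 1e-12 <= preds.predicted[i] <= nbs.biomass.max() + 1e-12

    def test_no_leakage_of_the_query_biomass(self, ds50):
        cfg = KNNConfig(metric="euclidean", k_neighbors=3)
        before = loocv_predict(ds50, cfg).predicted
        df = ds50.records.copy()
        df.loc[11, "w"] = df.loc[11, "w"] * 100
        after = loocv_predict(TreeDataset(records=df), cfg).predicted
        assert after[11] == before[11]

    def test_shuffling_records_preserves_prediction_pairs(self, ds50):
        cfg = KNNConfig(metric="chebyshev", k_neighbors=3)
        base = loocv_predict(ds50, cfg)
        rng = np.random.default_rng(8)
        perm = rng.permutation(ds50.n)
        shuffled = TreeDataset(records=ds50.records.iloc[perm])
        out = loocv_predict(shuffled, cfg)
        pairs = sorted(zip(base.actual, base.predicted))
        pairs_shuffled = sorted(zip(out.actual, out.predicted))
        np.testing.assert_allclose(pairs, pairs_shuffled, rtol=1e-12)

    def test_full_neighborhood_with_equal_distances_is_loo_mean(self):
        w = np.array([2.0, 4.0, 9.0, 13.0])
        ds = _ds_from_columns(w=w)  # all features identical => all distances 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cfg = KNNConfig(metric="euclidean", k_neighbors=3, variables=("dbh",))
        preds = loocv_predict(ds, cfg)
        expected = [(w.sum() - wi) / 3 for wi in w]
        np.testing.assert_allclose(preds.predicted, expected)

    def test_log_scale_predictions_flagged_and_back_transformable(self, ds50):
        cfg = KNNConfig(metric="euclidean", k_neighbors=3, use_log=True)
        preds = loocv_predict(ds50, cfg)
        assert preds.scale == "log"
        back = preds.back_transformed()
        assert back.scale == "original"
        np.testing.assert_allclose(back.actual, ds50.records["w"], rtol=1e-12)


class TestEstimatorInterface:
    def test_clone_and_params_roundtrip(self):
        est = KNNBiomassRegressor(n_neighbors=3, metric="manhattan", weighting="inv_d2")
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_predict_on_new_points_uses_training_neighbors(self):
        X = np.array([[1.0], [2.0], [10.0]])
        y = np.array([10.0, 20.0, 99.0])
        est = KNNBiomassRegressor(n_neighbors=2, metric="euclidean",
                                  weighting="inv_d").fit(X, y)
        # query at 0: d = (1, 2) to the two nearest -> (10/1 + 20/2) / 1.5
        assert est.predict([[0.0]])[0] == pytest.approx(40.0 / 3.0)

    def test_exact_training_point_returns_its_biomass(self):
        X = np.array([[1.0], [2.0], [3.0]])
        y = np.array([5.0, 6.0, 7.0])
        est = KNNBiomassRegressor(n_neighbors=2, metric="euclidean").fit(X, y)
        assert est.predict([[2.0]])[0] == 6.0

    def test_noncanonical_k_warns_but_runs(self, ds50):
        with pytest.warns(UserWarning, match="canonical"):
            cfg = KNNConfig(metric="euclidean", k_neighbors=4)
        preds = loocv_predict(ds50, cfg)
        assert preds.n == 50
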