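import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from ciliatecomm.beta import DistanceMatrix, bray_curtis, euclidean_1d
from ciliatecomm.drivers import (
    distance_decay,
    env_distance,
    geo_distance,
    mantel,
    mantel_panel,
)
from ciliatecomm.simulate import SimScenario, simulate_filtered
from ciliatecomm.tables import EnvTable, ValidationError


def _dm(X, ids=None):
    ids = ids or [f"s{i}" for i in range(len(X))]
    return DistanceMatrix(ids, squareform(pdist(np.asarray(X, float))), "euclidean")


class TestMantel:
    def test_identical_matrices_r_one_minimal_p(self):
        rng = np.random.default_rng(0)
        d = _dm(rng.normal(size=(10, 3)))
        res = mantel(d, d, n_perm=199, seed=0)
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert res.p == pytest.approx(1 / 200)

    def test_mismatched_ids_listed(self):
        d1 = _dm(np.random.default_rng(1).normal(size=(5, 2)))
        d2 = _dm(np.random.default_rng(2).normal(size=(5, 2)), ids=[f"x{i}" for i in range(5)])
        with pytest.raises(ValidationError, match="x0"):
            mantel(d1, d2)

    def test_r_matches_scikit_bio(self):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(3)
        d1, d2 = _dm(rng.normal(size=(12, 4))), _dm(rng.normal(size=(12, 4)))
        ours = mantel(d1, d2, n_perm=99, seed=0)
        r_ref, _, _ = skbio_dist.mantel(
            skbio_dist.DistanceMatrix(d1.values, d1.ids),
            skbio_dist.DistanceMatrix(d2.values, d2.ids),
            method="pearson", permutations=0,
        )
        assert ours.r == pytest.approx(r_ref, abs=1e-10)

    def test_spearman_matches_scikit_bio(self):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(4)
        d1, d2 = _dm(rng.normal(size=(10, 3))), _dm(rng.normal(size=(10, 3)))
        ours = mantel(d1, d2, n_perm=99, seed=0, method="spearman")
        r_ref, _, _ = skbio_dist.mantel(
            skbio_dist.DistanceMatrix(d1.values, d1.ids),
            skbio_dist.DistanceMatrix(d2.values, d2.ids),
            method="spearman", permutations=0,
        )
        assert ours.r == pytest.approx(r_ref, abs=1e-10)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(5)
        d1, d2 = _dm(rng.normal(size=(10, 3))), _dm(rng.normal(size=(10, 3)))
        assert mantel(d1, d2, n_perm=99, seed=0).r == pytest.approx(
            mantel(d2, d1, n_perm=99, seed=0).r, abs=1e-12
        )

    def test_detects_swc_filtering_in_simulation(self):
        hits = 0
        for rep in range(20):
            scn = SimScenario(
                n_species=100, n_sites=12, env_filter_strength=8.0, seed=500 + rep
            )
            ab, env = simulate_filtered(scn)
            res = mantel(bray_curtis(ab), env_distance(env, "SWC"), n_perm=99, seed=rep)
            hits += res.p < 0.05
        assert hits >= 18  # >= 90% power


class TestGeoDistance:
    def test_identical_points_zero(self):
        meta = pd.DataFrame({"latitude": [29.0, 29.0], "longitude": [89.0, 89.0]},
                            index=["a", "b"])
        assert geo_distance(meta).values[0, 1] == 0.0

    def test_half_circumference(self):
        meta = pd.DataFrame({"latitude": [0.0, 0.0], "longitude": [0.0, 180.0]},
                            index=["a", "b"])
        assert geo_distance(meta).values[0, 1] == pytest.approx(
            np.pi * 6371.0, rel=1e-6
        )

    def test_one_degree_meridian_arc(self):
        meta = pd.DataFrame({"latitude": [28.5, 29.5], "longitude": [89.0, 89.0]},
                            index=["a", "b"])
        assert geo_distance(meta).values[0, 1] == pytest.approx(111.2, abs=0.1)

    def test_missing_coordinates_rejected(self):
        meta = pd.DataFrame({"latitude": [29.0, np.nan], "longitude": [89.0, 89.0]},
                            index=["a", "b"])
        with pytest.raises(ValidationError, match="b"):
            geo_distance(meta)

    def test_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            meta = pd.DataFrame(
                {
                    "latitude": rng.uniform(-89, 89, 3),
                    "longitude": rng.uniform(-180, 180, 3),
                },
                index=list("abc"),
            )
            d = geo_distance(meta).values
            assert d[0, 1] <= d[0, 2] + d[2, 1] + 1e-9
            assert np.allclose(d, d.T)


class TestDistanceDecay:
    def test_exactly_linear_relation_recovered(self):
        x = np.array([0.0, 1.0, 2.0, 4.0, 7.0])
        ids = [f"s{i}" for i in range(5)]
        d_pred = euclidean_1d(ids, x)
        d_comm = DistanceMatrix(ids, 0.1 * d_pred.values + 0.0, "bc-like")
        fit = distance_decay(d_comm, d_pred, n_perm=99, seed=0)
        assert fit.r == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(0.1, abs=1e-12)

    def test_constant_predictor_flagged(self):
        ids = list("abcd")
        d_pred = euclidean_1d(ids, [3.0, 3.0, 3.0, 3.0])
        rng = np.random.default_rng(7)
        d_comm = _dm(rng.normal(size=(4, 2)), ids=ids)
        fit = distance_decay(d_comm, d_pred)
        assert fit.defined is False

    def test_null_response_rarely_significant(self):
        rng = np.random.default_rng(8)
        hits = 0
        for rep in range(20):
            ids = [f"s{i}" for i in range(12)]
            d_comm = _dm(rng.normal(size=(12, 3)), ids=ids)
            d_pred = euclidean_1d(ids, rng.uniform(0, 10, 12))
            hits += distance_decay(d_comm, d_pred, n_perm=99, seed=rep).p <= 0.05
        assert hits <= 2  # <= 10% of null replicates

    def test_swc_decay_stronger_than_unlinked_ph(self):
        scn = SimScenario(n_species=100, n_sites=12, env_filter_strength=8.0, seed=9)
        ab, env = simulate_filtered(scn)
        d = bray_curtis(ab)
        fit_swc = distance_decay(d, env_distance(env, "SWC"), n_perm=99, seed=0)
        fit_ph = distance_decay(d, env_distance(env, "pH"), n_perm=99, seed=0)
        assert abs(fit_swc.r) > abs(fit_ph.r)


def test_mantel_panel_ranks_swc_first_under_filtering():
    scn = SimScenario(n_species=100, n_sites=12, env_filter_strength=8.0, seed=10)
    ab, env = simulate_filtered(scn)
    panel = mantel_panel(
        bray_curtis(ab), env, ["SWC", "pH", "TN"], n_perm=99, seed=0
    ).set_index("factor")
    assert panel.loc["SWC", "r"] > panel.loc["pH", "r"]
    assert panel.loc["SWC", "p"] < 0.05


def test_env_missing_values_excluded_pairwise():
    factors = pd.DataFrame(
        {"SWC": [10.0, np.nan, 30.0], "pH": [7.0, 7.5, 8.0]},
        index=["a", "b", "c"],
    )
    env = EnvTable(factors)
    d = env_distance(env, "SWC")
    assert d.ids == ["a", "c"]
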