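"""EM mixture fitting: oracles, BIC selection, labelling rule table."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal
from sklearn.metrics import adjusted_rand_score

from penguinflow.em_behaviour import (
    RIDGE,
    ClusterModel,
    LabelRules,
    Scaling,
    em_iteration,
    fit_em,
    label_clusters,
    merge_minor_classes,
    n_params,
    scale_center,
    select_k,
    select_variables,
)


# ----------------------------------------------------------------- variables

def test_variable_sets():
    assert select_variables("diving") == ["vedba", "pitch", "sd_heave_2s", "depth_change"]
    assert select_variables("surface") == ["vedba", "pitch", "sd_heave_10s", "sd_roll_30s"]
    assert select_variables("land_ice") == select_variables("surface")
    with pytest.raises(ValueError):
        select_variables("benthic")


# ------------------------------------------------------------- scale/centre

def test_scale_center_population_sd():
    X = np.array([[1.0], [2.0], [3.0]])
    Xs, sc = scale_center(X)
    np.testing.assert_allclose(Xs[:, 0], [-1.2247448, 0.0, 1.2247448], atol=1e-6)
    np.testing.assert_allclose(sc.inverse(Xs), X, atol=1e-12)


def test_scale_center_constant_column():
    X = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
    Xs, _ = scale_center(X)
    np.testing.assert_array_equal(Xs[:, 1], 0.0)


def test_scale_center_rejects_bad_input():
    with pytest.raises(ValueError):
        scale_center(np.array([[1.0]]))
    with pytest.raises(ValueError, match="all-missing"):
        scale_center(np.full((5, 2), np.nan))


# ------------------------------------------------------------------ EM core

def _two_cluster_data(rng, n=2000, delta=10.0, d=2):
    half = n // 2
    X = np.vstack([
        rng.normal(0, 1, (half, d)),
        rng.normal(delta, 1, (n - half, d)),
    ])
    truth = np.r_[np.zeros(half, int), np.ones(n - half, int)]
    return X, truth


def test_one_iteration_matches_dense_oracle(rng):
    """E-step responsibilities and M-step equal a brute-force recomputation."""
    n, d, K = 200, 2, 2
    X = rng.normal(0, 1, (n, d))
    weights = np.array([0.4, 0.6])
    means = np.array([[0.5, -0.2], [-0.3, 0.8]])
    covs = np.array([np.eye(d) * 0.9, np.eye(d) * 1.4])

    ll, resp, nk, w2, m2, c2 = em_iteration(X, weights, means, covs)

    dens = np.column_stack([
        weights[k] * multivariate_normal(means[k], covs[k]).pdf(X) for k in range(K)
    ])
    resp_o = dens / dens.sum(axis=1, keepdims=True)
    ll_o = np.log(dens.sum(axis=1)).sum()
    np.testing.assert_allclose(resp, resp_o, atol=1e-10)
    assert ll == pytest.approx(ll_o, abs=1e-8)
    for k in range(K):
        nk_o = resp_o[:, k].sum()
        mean_o = (resp_o[:, k][:, None] * X).sum(axis=0) / nk_o
        diff = X - mean_o
        cov_o = (resp_o[:, k][:, None] * diff).T @ diff / nk_o + RIDGE * np.eye(d)
        np.testing.assert_allclose(w2[k], nk_o / n, atol=1e-10)
        np.testing.assert_allclose(m2[k], mean_o, atol=1e-10)
        np.testing.assert_allclose(c2[k], cov_o, atol=1e-10)


def test_k1_closed_form(rng):
    X = rng.normal(2.0, 1.5, (300, 2))
    model = fit_em(X, K=1, seed=0, n_starts=1)
    np.testing.assert_allclose(model.means[0], X.mean(axis=0), atol=1e-8)
    cov_mle = np.cov(X, rowvar=False, ddof=0) + RIDGE * np.eye(2)
    np.testing.assert_allclose(model.covariances[0], cov_mle, atol=1e-6)
    ll_closed = multivariate_normal(X.mean(axis=0), cov_mle).logpdf(X).sum()
    assert model.loglik == pytest.approx(ll_closed, rel=1e-6)


def test_well_separated_two_clusters(rng):
    X, truth = _two_cluster_data(rng)
    Xs, sc = scale_center(X)
    model = fit_em(Xs, K=2, seed=11)
    assign = model.predict(Xs)
    assert adjusted_rand_score(truth, assign) >= 0.99
    # recovered means within 0.1 (in within-cluster SD units) of the truth
    rec = np.sort(sc.inverse(model.means)[:, 0])
    np.testing.assert_allclose(rec, [0.0, 10.0], atol=0.1)


def test_fit_em_deterministic(rng):
    X, _ = _two_cluster_data(rng, n=400)
    m1 = fit_em(X, K=2, seed=5)
    m2 = fit_em(X, K=2, seed=5)
    assert m1.loglik == m2.loglik
    np.testing.assert_array_equal(m1.means, m2.means)


def test_loglik_monotone_within_run(rng):
    X, _ = _two_cluster_data(rng, n=600, delta=3.0)
    weights = np.full(2, 0.5)
    means = X[[0, 1]].copy()
    covs = np.repeat((np.cov(X, rowvar=False) + RIDGE * np.eye(2))[None], 2, axis=0)
    lls = []
    for _ in range(40):
        ll, _, _, weights, means, covs = em_iteration(X, weights, means, covs)
        lls.append(ll)
    assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))


def test_fit_em_contract_errors(rng):
    X = rng.normal(0, 1, (10, 4))
    with pytest.raises(ValueError, match="too few"):
        fit_em(X, K=3, seed=0)
    with pytest.raises(ValueError):
        fit_em(rng.normal(0, 1, (50, 2)), K=0, seed=0)


def test_bic_formula(rng):
    X, _ = _two_cluster_data(rng, n=500)
    model = fit_em(X, K=2, seed=3)
    p = n_params(2, 2)
    assert p == 1 + 4 + 6
    assert model.bic == pytest.approx(-2 * model.loglik + p * np.log(500))


# ------------------------------------------------------------------ select_k

def test_k_bounds_by_subset(rng):
    X = rng.normal(0, 1, (400, 4))
    m = select_k(X, "diving", True, seed=0, n_starts=2, short_iter=5)
    assert 3 <= m.K <= 8
    m = select_k(X, "surface", True, seed=0, n_starts=2, short_iter=5)
    assert 2 <= m.K <= 5
    m = select_k(X, "surface", False, seed=0, n_starts=2, short_iter=5)
    assert 2 <= m.K <= 8


def test_select_k_small_n_fallback(rng):
    # n too small for the diving minimum of K=3: largest feasible K is used
    X = rng.normal(0, 1, (10, 4))
    m = select_k(X, "diving", True, seed=0, n_starts=2)
    assert m.K == 2
    # not even K=1 feasible
    with pytest.raises(ValueError):
        select_k(rng.normal(0, 1, (4, 4)), "diving", True, seed=0)


# ------------------------------------------------------------------ labelling

def _toy_model(centroids, variables, sizes=None):
    K, d = centroids.shape
    return ClusterModel(
        subset="", K=K, weights=np.full(K, 1 / K), means=np.asarray(centroids, float),
        covariances=np.repeat(np.eye(d)[None], K, axis=0), loglik=0.0, bic=0.0,
        n_obs=100, scaling=None, variables=variables,
        cluster_sizes=np.asarray(sizes if sizes is not None else np.full(K, 10.0)),
    )


def test_diving_label_rules():
    # columns: vedba, pitch, sd_heave_2s, depth_change
    cents = np.array([
        [0.25, -55.0, 0.2, 1.2],    # descending: depth increasing fast
        [0.30, 55.0, 0.2, -1.1],    # ascending
        [0.80, -10.0, 0.5, 0.0],    # hunting: most dynamic
        [0.20, 0.0, 0.1, 0.05],     # cruising
        [0.22, 2.0, 0.1, 0.0],      # second cruise-like cluster
    ])
    model = _toy_model(cents, select_variables("diving"), sizes=[10, 10, 10, 40, 5])
    out = label_clusters(model, "diving", "adelie")
    assert out == {0: "descend", 1: "ascend", 2: "hunt",
                   3: "swim_cruise", 4: "swim_cruise_2"}


def test_surface_label_rules_little_still():
    cents = np.array([
        [0.02, 10.0, 0.05, 2.0],   # floating motionless
        [0.15, 5.0, 0.1, 6.0],     # slow swimming
        [0.9, 10.0, 0.5, 5.0],     # porpoising
        [0.4, 0.0, 0.2, 25.0],     # preen/flap: high roll variability
    ])
    model = _toy_model(cents, select_variables("surface"))
    out = label_clusters(model, "surface", "little")
    assert out == {0: "still", 1: "slow_surface_swim",
                   2: "swim_porpoise", 3: "preen_flap_water"}
    out_a = label_clusters(model, "surface", "adelie")
    assert out_a[0] == "slow_surface_swim"  # no 'still' for Adelie


def test_land_label_rules():
    cents = np.array([
        [0.5, 80.0, 0.3, 5.0],
        [0.05, 80.0, 0.05, 3.0],
        [0.1, 5.0, 0.1, 3.0],
        [0.4, 45.0, 0.2, 30.0],
    ])
    model = _toy_model(cents, select_variables("land_ice"))
    out = label_clusters(model, "land_ice", "adelie")
    assert out == {0: "walk", 1: "stand", 2: "lie_toboggan", 3: "preen_flap_land"}


def test_label_mapping_total():
    rules = LabelRules()
    cents = np.zeros((4, 4))
    model = _toy_model(cents, select_variables("diving"))
    out = label_clusters(model, "diving", "adelie", rules)
    assert set(out) == {0, 1, 2, 3}  # every cluster mapped


def test_empty_model_rejected():
    model = _toy_model(np.zeros((1, 4)), select_variables("diving"))
    model.cluster_sizes = None
    with pytest.raises(ValueError, match="empty"):
        label_clusters(model, "diving", "adelie")


def test_merge_minor_classes():
    labels = np.array(["swim_cruise_2", "hunt", "swim_cruise_2", "descend"])
    merged = merge_minor_classes(labels)
    assert "swim_cruise_2" not in merged
    assert (merged == np.array(["swim_cruise", "hunt", "swim_cruise", "descend"])).all()
    # identity without the variant, counts conserved
    other = np.array(["hunt", "descend"])
    np.testing.assert_array_equal(merge_minor_classes(other), other)
    assert len(merged) == len(labels)
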