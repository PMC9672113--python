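"""Unsupervised behaviour detection: EM-fitted Gaussian mixtures per trip subset.

For every trip and coarse subset a full-covariance multivariate Gaussian
mixture is fitted by Expectation-Maximisation over a subset-specific variable
set, restarted from random row-sampled centres, with the cluster count chosen
by BIC inside behaviourally motivated bounds (3-8 clusters while diving, 2-5
at the surface/on ice when dives are present, 2-8 otherwise).  Clusters are
then mapped to named behaviours by a deterministic rule table on the unscaled
cluster centroids — the reproducible stand-in for visual assessment of each
trip's clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

log = logging.getLogger(__name__)

VARIABLES = {
    "diving": ["vedba", "pitch", "sd_heave_2s", "depth_change"],
    "surface": ["vedba", "pitch", "sd_heave_10s", "sd_roll_30s"],
    "land_ice": ["vedba", "pitch", "sd_heave_10s", "sd_roll_30s"],
}

K_BOUNDS = {
    "diving": (3, 8),
    "surface": (2, 5),
    "land_ice": (2, 5),
    "surface_only": (2, 8),  # no dives detected in the trip
}

RIDGE = 1e-6


def select_variables(subset: str) -> list[str]:
    """Ordered EM variable list for a coarse subset."""
    try:
        return list(VARIABLES[subset])
    except KeyError:
        raise ValueError(f"unknown subset {subset!r}") from None


@dataclass
class Scaling:
    center: np.ndarray
    scale: np.ndarray

    def transform(self, X):
        return (X - self.center) / self.scale

    def inverse(self, Xs):
        return Xs * self.scale + self.center


def scale_center(X: np.ndarray):
    """Column-standardise (mean 0, population SD 1); constant columns stay 0."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("need a 2-D array with n >= 2")
    if np.isnan(X).all(axis=0).any():
        raise ValueError("all-missing column")
    center = np.nanmean(X, axis=0)
    scale = np.nanstd(X, axis=0)
    zero = scale == 0
    if zero.any():
        log.warning("zero-variance column(s) at %s left at 0", np.flatnonzero(zero))
        scale = np.where(zero, 1.0, scale)
    scaling = Scaling(center=center, scale=scale)
    return scaling.transform(X), scaling


@dataclass
class ClusterModel:
    """Fitted Gaussian mixture for one trip subset."""

    subset: str
    K: int
    weights: np.ndarray          # (K,)
    means: np.ndarray            # (K, d), on the scaled space
    covariances: np.ndarray      # (K, d, d)
    loglik: float
    bic: float
    n_obs: int
    scaling: Scaling | None = None
    variables: list[str] = field(default_factory=list)
    cluster_sizes: np.ndarray | None = None  # responsibility mass per cluster
    n_iter: int = 0
    converged: bool = False
    labels: dict[int, str] | None = None     # cluster -> behaviour, once mapped

    @property
    def means_unscaled(self) -> np.ndarray:
        if self.scaling is None:
            return self.means
        return self.scaling.inverse(self.means)

    def log_prob(self, X: np.ndarray) -> np.ndarray:
        """Per-sample, per-component weighted log density, (n, K)."""
        return _weighted_log_prob(X, self.weights, self.means, self.covariances)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.log_prob(X), axis=1)


def n_params(K: int, d: int) -> int:
    return K - 1 + K * d + K * d * (d + 1) // 2


def _weighted_log_prob(X, weights, means, covs):
    n, d = X.shape
    K = len(weights)
    out = np.empty((n, K))
    for k in range(K):
        L = np.linalg.cholesky(covs[k])
        diff = X - means[k]
        sol = np.linalg.solve(L, diff.T)
        maha = np.sum(sol ** 2, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        out[:, k] = (
            np.log(weights[k]) - 0.5 * (d * np.log(2 * np.pi) + logdet + maha)
        )
    return out


def em_iteration(X, weights, means, covs):
    """One EM sweep: E-step responsibilities and M-step weighted MLE + ridge.

    Returns (loglik-at-input-parameters, responsibilities, component masses,
    new weights, new means, new covariances).
    """
    n, d = X.shape
    wlp = _weighted_log_prob(X, weights, means, covs)
    norm = logsumexp(wlp, axis=1)
    ll = float(norm.sum())
    resp = np.exp(wlp - norm[:, None])
    nk = resp.sum(axis=0)
    new_weights = nk / n
    new_means = (resp.T @ X) / nk[:, None]
    new_covs = np.empty_like(covs)
    for k in range(len(weights)):
        diff = X - new_means[k]
        new_covs[k] = (resp[:, k][:, None] * diff).T @ diff / nk[k]
        new_covs[k].flat[:: d + 1] += RIDGE
    return ll, resp, nk, new_weights, new_means, new_covs


def _em_single(X, K, rng, max_iter, tol, init=None):
    n, d = X.shape
    pooled = np.cov(X, rowvar=False, ddof=0) + RIDGE * np.eye(d)
    if init is None:
        idx = rng.choice(n, size=K, replace=False)
        means = X[idx].copy()
        covs = np.repeat(pooled[None], K, axis=0)
        weights = np.full(K, 1.0 / K)
    else:
        weights, means, covs = (a.copy() for a in init)

    prev_ll = -np.inf
    nk = np.full(K, n / K)
    for it in range(1, max_iter + 1):
        ll, resp, nk_new, w_new, m_new, c_new = em_iteration(X, weights, means, covs)
        # EM guarantee: the log-likelihood never decreases -- for the exact
        # M-step.  The diagonal ridge makes each sweep maximise a regularised
        # Q instead, so near-singular components can shave off a few units;
        # any decrease ends the run on the previous (better) parameters, and
        # only a gross decrease (a real defect) trips the assertion.
        assert ll >= prev_ll - max(5.0, 1e-4 * abs(prev_ll)), "EM log-likelihood decreased"
        if ll < prev_ll:
            return prev_ll, weights, means, covs, nk, it, True

        degenerate = np.flatnonzero(nk_new < 1.0)  # weight below 1/n
        if degenerate.size:
            log.debug("reinitialising %d degenerate component(s)", degenerate.size)
            for k in degenerate:
                means[k] = X[int(rng.integers(n))]
                covs[k] = pooled
            weights = np.maximum(nk_new, 1.0)
            weights = weights / weights.sum()
            prev_ll = -np.inf
            continue

        weights, means, covs, nk = w_new, m_new, c_new, nk_new
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < tol * max(1.0, abs(ll)):
            return ll, weights, means, covs, nk, it, True
        prev_ll = ll
    return prev_ll, weights, means, covs, nk, max_iter, False


def fit_em(
    Xs: np.ndarray,
    K: int,
    seed,
    n_starts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
    subset: str = "",
    scaling: Scaling | None = None,
    variables: list[str] | None = None,
    short_iter: int | None = None,
) -> ClusterModel:
    """Best-of-`n_starts` EM fit of a K-component full-covariance mixture.

    Each start draws K distinct rows as initial centres, uses the pooled
    covariance and uniform weights, and iterates E (log-sum-exp
    responsibilities) and M (weighted MLE with a 1e-6 diagonal ridge) steps
    until the relative log-likelihood change falls below `tol`.

    With `short_iter` set, every start runs only that many burn-in iterations
    and the best one is polished to convergence (the standard small-EM
    strategy); by default every start runs to convergence.
    """
    Xs = np.asarray(Xs, dtype=float)
    n, d = Xs.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if n <= K * d:
        raise ValueError(f"too few observations (n={n}) for K={K}, d={d}")
    rng = np.random.default_rng(seed)
    best = None
    per_start_iter = max_iter if short_iter is None else min(short_iter, max_iter)
    for _ in range(n_starts):
        res = _em_single(Xs, K, rng, max_iter, tol) if short_iter is None else \
            _em_single(Xs, K, rng, per_start_iter, tol)
        if best is None or res[0] > best[0]:
            best = res
    if short_iter is not None and not best[6]:
        init = (best[1], best[2], best[3])
        best = _em_single(Xs, K, rng, max_iter, tol, init=init)
    ll, weights, means, covs, nk, n_iter, converged = best
    bic = -2.0 * ll + n_params(K, d) * np.log(n)
    return ClusterModel(
        subset=subset, K=K, weights=weights, means=means, covariances=covs,
        loglik=ll, bic=bic, n_obs=n, scaling=scaling,
        variables=variables or [], cluster_sizes=nk,
        n_iter=n_iter, converged=converged,
    )


def select_k(
    Xs: np.ndarray,
    subset_type: str,
    dives_present: bool,
    seed,
    n_starts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
    **model_kwargs,
) -> ClusterModel:
    """Fit every K in the subset's bounds and return the lowest-BIC model."""
    if subset_type == "diving":
        k_min, k_max = K_BOUNDS["diving"]
    elif subset_type in ("surface", "land_ice"):
        k_min, k_max = K_BOUNDS[subset_type] if dives_present else K_BOUNDS["surface_only"]
    else:
        raise ValueError(f"unknown subset {subset_type!r}")
    n, d = np.asarray(Xs).shape
    feasible = [K for K in range(k_min, k_max + 1) if n > K * d]
    if not feasible:
        fallback = [K for K in range(1, k_min) if n > K * d]
        if not fallback:
            raise ValueError(f"too few observations (n={n}) for any cluster count")
        log.warning("n=%d too small for K>=%d; falling back to K=%d", n, k_min, fallback[-1])
        feasible = [fallback[-1]]
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    ss = seed.spawn(len(feasible))
    best = None
    for K, child in zip(feasible, ss):
        model = fit_em(
            Xs, K, child, n_starts=n_starts, max_iter=max_iter, tol=tol,
            subset=subset_type, **model_kwargs,
        )
        if best is None or model.bic < best.bic:
            best = model
    return best


# --------------------------------------------------------------------------
# cluster -> behaviour rule table

LITTLE_ONLY = {"still"}
LAND_CLASSES = {"walk", "stand", "lie_toboggan", "preen_flap_land"}


@dataclass(frozen=True)
class LabelRules:
    """Thresholds of the centroid rule table (units of the unscaled variables).

    Per-cluster thresholds (rather than winner-take-all comparisons) keep the
    mapping stable when BIC splits one behaviour across several clusters:
    every sub-cluster of, say, a descent still maps to `descend`.
    """

    depth_change_ms: float = 0.5     # minimum |mean depth change| for descend/ascend
    hunt_vedba_g: float = 0.5        # prey-pursuit dynamics floor (diving)
    still_vedba_g: float = 0.06      # "floating motionless" ceiling
    preen_roll_sd_deg: float = 12.0  # roll variability floor for preening/flapping
    porpoise_vedba_g: float = 0.45   # energetic surface travel floor
    walk_pitch_deg: float = 60.0
    lie_pitch_deg: float = 20.0
    land_vedba_high_g: float = 0.2   # walk vs stand split


def label_clusters(
    model: ClusterModel, subset: str, species: str, rules: LabelRules | None = None
) -> dict[int, str]:
    """Deterministic mapping cluster index -> behaviour name.

    Diving: the strongest positive mean depth-change centroid (descending
    birds meet rising pressure) with a head-down posture is `descend`, the
    strongest negative one with head-up posture `ascend`; the most dynamic
    remainder is `hunt`; other clusters are `swim_cruise`, extras
    `swim_cruise_2`.  Surface and land/ice rules are centroid thresholds on
    VeDBA, roll variability and pitch.
    """
    if rules is None:
        rules = LabelRules()
    if model.K == 0 or model.cluster_sizes is None:
        raise ValueError("empty model")
    cols = {v: i for i, v in enumerate(model.variables)}
    cent = model.means_unscaled
    K = model.K
    out: dict[int, str] = {}

    if subset == "diving":
        dz = cent[:, cols["depth_change"]]
        vedba = cent[:, cols["vedba"]]
        unassigned = set(range(K))
        for k in range(K):
            # a descending bird meets rising pressure: positive depth change
            if dz[k] > rules.depth_change_ms:
                out[k] = "descend"
                unassigned.discard(k)
            elif dz[k] < -rules.depth_change_ms:
                out[k] = "ascend"
                unassigned.discard(k)
        for k in sorted(unassigned):
            if vedba[k] > rules.hunt_vedba_g:
                out[k] = "hunt"
                unassigned.discard(k)
        if unassigned:
            k_main = max(unassigned, key=lambda k: model.cluster_sizes[k])
            out[k_main] = "swim_cruise"
            unassigned.discard(k_main)
        for k in unassigned:
            out[k] = "swim_cruise_2"

    elif subset == "surface":
        vedba = cent[:, cols["vedba"]]
        sd_roll = cent[:, cols["sd_roll_30s"]]
        for k in range(K):
            if species == "little" and vedba[k] < rules.still_vedba_g:
                out[k] = "still"
            elif sd_roll[k] > rules.preen_roll_sd_deg:
                out[k] = "preen_flap_water"
            elif vedba[k] > rules.porpoise_vedba_g:
                out[k] = "swim_porpoise"
            else:
                out[k] = "slow_surface_swim"

    elif subset == "land_ice":
        vedba = cent[:, cols["vedba"]]
        pitch = cent[:, cols["pitch"]]
        for k in range(K):
            if pitch[k] > rules.walk_pitch_deg:
                out[k] = "walk" if vedba[k] >= rules.land_vedba_high_g else "stand"
            elif pitch[k] <= rules.lie_pitch_deg:
                out[k] = "lie_toboggan"
            else:
                out[k] = "preen_flap_land"
    else:
        raise ValueError(f"unknown subset {subset!r}")

    model.labels = out
    return out


def merge_minor_classes(labels):
    """Fold the rare 'swim/cruise type 2' variant into 'swim_cruise'."""
    arr = np.asarray(labels, dtype=object)
    return np.where(arr == "swim_cruise_2", "swim_cruise", arr)


def behaviour_vocabulary(species: str) -> list[str]:
    """Fine behaviour classes of a species (12 for Adelie, 10 for little)."""
    from penguinflow.synthetic_data import default_config

    return sorted(default_config(species).behaviour_grammar)
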