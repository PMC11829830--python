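"""Feature-space Gaussian mixture model for out-of-distribution scoring.

A GMM with full covariances is fitted by EM on the molecule feature
vectors of the training set (taken from the last hidden layer of one
trained backbone model). A test structure is scored by the negative
log-likelihood of its feature vector under the mixture: larger NLL means
the features lie further from the training distribution, i.e. larger
uncertainty. The NLL is a rank score only — it is never mapped to an
energy variance.

The EM loop is implemented here (k-means initialization of the means,
log-sum-exp responsibilities, ridge-regularized covariance updates) so the
per-iteration NLL trace and restart-on-degeneracy behaviour are explicit;
the component count is selected by the Bayesian information criterion.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

logger = logging.getLogger("pesuq")


class GMMFitError(RuntimeError):
    pass


@dataclasses.dataclass
class GMMModel:
    """Fitted mixture: weights ω_i, means μ_i, covariances Σ_i, BIC."""

    weights: np.ndarray       # (N,)
    means: np.ndarray         # (N, D)
    covariances: np.ndarray   # (N, D, D)
    n_components: int
    bic: float
    log_likelihood: float     # total ln L̂ on the training features
    n_samples: int
    nll_trace: np.ndarray     # mean NLL per EM iteration (non-increasing)
    seed: int = 0

    def n_parameters(self) -> int:
        d = self.means.shape[1]
        return self.n_components * (d + d * (d + 1) // 2) + (
            self.n_components - 1
        )

    def save(self, path):
        chol = np.array(
            [np.linalg.cholesky(c) for c in self.covariances]
        )
        np.savez_compressed(
            path,
            weights=self.weights,
            means=self.means,
            cov_chol=chol,
            bic=self.bic,
            log_likelihood=self.log_likelihood,
            n_samples=self.n_samples,
            nll_trace=self.nll_trace,
            seed=self.seed,
        )

    @classmethod
    def load(cls, path) -> "GMMModel":
        with np.load(path, allow_pickle=False) as d:
            chol = d["cov_chol"]
            covs = np.array([c @ c.T for c in chol])
            return cls(
                weights=d["weights"].copy(),
                means=d["means"].copy(),
                covariances=covs,
                n_components=len(d["weights"]),
                bic=float(d["bic"]),
                log_likelihood=float(d["log_likelihood"]),
                n_samples=int(d["n_samples"]),
                nll_trace=d["nll_trace"].copy(),
                seed=int(d["seed"]),
            )


def _component_logpdf(x: np.ndarray, mean: np.ndarray, cov: np.ndarray):
    """Multivariate normal log-density via Cholesky, batched over rows."""
    from scipy.linalg import solve_triangular

    d = len(mean)
    chol = np.linalg.cholesky(cov)
    diff = x - mean
    sol = solve_triangular(chol, diff.T, lower=True)
    maha = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


def _weighted_log_prob(x: np.ndarray, weights, means, covs) -> np.ndarray:
    """(n_samples, n_components) array of ln ω_i + ln N(x|μ_i, Σ_i)."""
    return np.column_stack(
        [
            np.log(w) + _component_logpdf(x, m, c)
            for w, m, c in zip(weights, means, covs)
        ]
    )


def fit_gmm(
    features: np.ndarray,
    n_components: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    ridge: float = 1e-6,
    max_restarts: int = 5,
) -> GMMModel:
    """Fit a full-covariance GMM by EM with k-means initialization.

    Convergence is declared when the mean per-sample log-likelihood
    improves by less than ``tol``. A component whose responsibility mass
    drops below 2 samples triggers a re-seeded restart (up to
    ``max_restarts``, then GMMFitError).
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ValueError("features must be 2-D (n_samples, n_features)")
    n, d = x.shape
    if n < n_components:
        raise ValueError("need at least one sample per component")
    last_err = None
    for attempt in range(max_restarts):
        try:
            return _fit_once(
                x, n_components, seed + 1000 * attempt, tol, max_iter, ridge
            )
        except GMMFitError as err:
            last_err = err
            logger.warning("GMM restart %d: %s", attempt + 1, err)
    raise GMMFitError(
        f"GMM failed after {max_restarts} restarts: {last_err}"
    )


def _fit_once(x, n_components, seed, tol, max_iter, ridge):
    n, d = x.shape
    ridge_mat = ridge * np.eye(d)
    if n_components == 1:
        means = x.mean(0, keepdims=True)
    else:
        km = KMeans(
            n_clusters=n_components, random_state=seed % 2**31, n_init=10
        ).fit(x)
        means = km.cluster_centers_.copy()
    weights = np.full(n_components, 1.0 / n_components)
    cov0 = np.cov(x.T, bias=True).reshape(d, d) + ridge_mat
    covs = np.array([cov0.copy() for _ in range(n_components)])
    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        log_prob = _weighted_log_prob(x, weights, means, covs)
        log_norm = logsumexp(log_prob, axis=1)
        mean_ll = float(log_norm.mean())
        trace.append(-mean_ll)
        resp = np.exp(log_prob - log_norm[:, None])
        nk = resp.sum(0)
        if np.any(nk < 2.0):
            raise GMMFitError(
                f"component collapsed (mass {nk.min():.3f} < 2)"
            )
        weights = nk / n
        means = (resp.T @ x) / nk[:, None]
        for k in range(n_components):
            diff = x - means[k]
            covs[k] = (resp[:, k][:, None] * diff).T @ diff / nk[k] + ridge_mat
        if mean_ll - prev < tol and np.isfinite(prev):
            break
        prev = mean_ll
    log_prob = _weighted_log_prob(x, weights, means, covs)
    total_ll = float(logsumexp(log_prob, axis=1).sum())
    k_params = n_components * (d + d * (d + 1) // 2) + (n_components - 1)
    bic = k_params * np.log(n) - 2.0 * total_ll
    return GMMModel(
        weights=weights,
        means=means,
        covariances=covs,
        n_components=n_components,
        bic=float(bic),
        log_likelihood=total_ll,
        n_samples=n,
        nll_trace=np.array(trace),
        seed=seed,
    )


def select_gmm_bic(
    features: np.ndarray,
    candidate_range=range(1, 21),
    seed: int = 0,
    **fit_kwargs,
) -> GMMModel:
    """Fit every candidate component count, return the BIC minimizer.

    Ties (within floating-point equality) resolve to the smallest N.
    """
    candidates = list(candidate_range)
    if not candidates:
        raise ValueError("empty candidate range")
    best = None
    failures = []
    for n_comp in candidates:
        try:
            model = fit_gmm(features, n_comp, seed=seed, **fit_kwargs)
        except (GMMFitError, ValueError) as err:
            failures.append((n_comp, str(err)))
            continue
        if best is None or model.bic < best.bic:
            best = model
    if best is None:
        raise GMMFitError(f"all candidate fits failed: {failures}")
    logger.info(
        "BIC selected N=%d (bic=%.1f) from %s", best.n_components,
        best.bic, candidates,
    )
    return best


def gmm_nll(model: GMMModel, feature: np.ndarray):
    """NLL of feature vector(s) under the mixture (log-sum-exp form).

    Accepts a single vector (returns a float) or a matrix of row vectors
    (returns an array). Larger NLL = larger uncertainty.
    """
    x = np.asarray(feature, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != model.means.shape[1]:
        raise ValueError(
            f"feature dimension {x.shape[1]} != model dimension "
            f"{model.means.shape[1]}"
        )
    nll = -logsumexp(
        _weighted_log_prob(x, model.weights, model.means, model.covariances),
        axis=1,
    )
    return float(nll[0]) if single else nll
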