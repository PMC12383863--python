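"""Constrained-covariance Gaussian mixture models fitted by EM.

Implements the three diagonal/spherical covariance families of the mclust
taxonomy used for bivariate T-score clustering:

* ``EII`` — spherical, equal volume: one scalar variance shared by all
  components (Sigma_k = lambda * I).
* ``VII`` — spherical, varying volume: one scalar variance per component
  (Sigma_k = lambda_k * I).
* ``EEI`` — diagonal, equal volume and shape: one diagonal variance vector
  shared by all components (Sigma_k = diag(lambda_1..lambda_d)).

Model comparison uses the mclust sign convention
``BIC = 2*loglik - m*ln(n)`` (larger is better), with ``m`` the number of
free parameters.  EM is run from several k-means initializations; the
best-likelihood solution is kept.  Components are always reported in
ascending order of their first-dimension (internalizing) mean, so with two
components index 0 is the lower-severity ("LOW") cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import KMeans

__all__ = [
    "FAMILIES",
    "MixtureModel",
    "ClusterAssignment",
    "MixtureFitError",
    "n_free_params",
    "bic_mclust",
    "fit_mixture",
    "select_model",
    "map_assign",
]

FAMILIES = ("EII", "VII", "EEI")
_VAR_FLOOR = 1e-6


class MixtureFitError(RuntimeError):
    """All EM restarts ended in a degenerate solution."""


def n_free_params(family: str, K: int, d: int) -> int:
    """Free-parameter count: (K-1) weights + K*d means + variance terms.

    Variance terms: EII 1, VII K, EEI d.
    """
    if K < 1 or d < 1:
        raise ValueError("K and d must be >= 1")
    base = (K - 1) + K * d
    if family == "EII":
        return base + 1
    if family == "VII":
        return base + K
    if family == "EEI":
        return base + d
    raise ValueError(f"unknown family {family!r}; supported: {FAMILIES}")


def bic_mclust(loglik: float, m: int, n: int) -> float:
    """BIC in the mclust convention, 2*loglik - m*ln(n) (larger is better)."""
    if n < 1 or m < 0:
        raise ValueError("need n >= 1 and m >= 0")
    return 2.0 * loglik - m * np.log(n)


@dataclass
class MixtureModel:
    family: str
    K: int
    weights: np.ndarray          # (K,)
    means: np.ndarray            # (K, d)
    variances: np.ndarray        # (K, d) diagonal covariances (expanded form)
    loglik: float
    m: int
    n: int
    bic: float
    converged: bool = True
    n_iter: int = 0
    loglik_path: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def d(self) -> int:
        return self.means.shape[1]


@dataclass
class ClusterAssignment:
    labels: np.ndarray            # MAP component index, ordered as in model
    responsibilities: np.ndarray  # (n, K), rows sum to 1
    names: tuple[str, ...]        # per-component label, e.g. ("LOW", "HIGH")

    def label_names(self) -> np.ndarray:
        return np.asarray(self.names)[self.labels]


def _log_gaussian_diag(X: np.ndarray, means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """(n, K) log density of diagonal Gaussians."""
    n, d = X.shape
    diff = X[:, None, :] - means[None, :, :]           # (n, K, d)
    inv = 1.0 / variances                              # (K, d)
    quad = np.einsum("nkd,kd->nk", diff ** 2, inv)
    logdet = np.log(variances).sum(axis=1)             # (K,)
    return -0.5 * (quad + logdet + d * np.log(2.0 * np.pi))


def _e_step(X, weights, means, variances):
    log_prob = _log_gaussian_diag(X, means, variances) + np.log(weights)
    norm = logsumexp(log_prob, axis=1)
    resp = np.exp(log_prob - norm[:, None])
    return resp, float(norm.sum())


def _m_step(X, resp, family):
    n, d = X.shape
    nk = resp.sum(axis=0)                              # (K,)
    if (nk < 1e-10).any():
        return None
    weights = nk / n
    means = (resp.T @ X) / nk[:, None]
    diff2 = (X[:, None, :] - means[None, :, :]) ** 2   # (n, K, d)
    if family == "EII":
        lam = float(np.einsum("nk,nkd->", resp, diff2) / (n * d))
        variances = np.full((len(nk), d), max(lam, _VAR_FLOOR))
    elif family == "VII":
        lam_k = np.einsum("nk,nkd->k", resp, diff2) / (d * nk)
        variances = np.maximum(lam_k, _VAR_FLOOR)[:, None] * np.ones((1, d))
    else:  # EEI
        lam_d = np.einsum("nk,nkd->d", resp, diff2) / n
        variances = np.ones((len(nk), 1)) * np.maximum(lam_d, _VAR_FLOOR)[None, :]
    return weights, means, variances


def _em_once(X, K, family, init_resp, tol, max_iter):
    resp = init_resp
    path = []
    prev = -np.inf
    weights = means = variances = None
    for it in range(max_iter):
        params = _m_step(X, resp, family)
        if params is None:
            return None
        weights, means, variances = params
        resp, loglik = _e_step(X, weights, means, variances)
        path.append(loglik)
        if np.isfinite(prev) and loglik - prev <= tol * max(1.0, abs(loglik)):
            return weights, means, variances, loglik, np.array(path), True, it + 1
        prev = loglik
    return weights, means, variances, prev, np.array(path), False, max_iter


def fit_mixture(
    X: np.ndarray,
    K: int,
    family: str = "EII",
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_restarts: int = 10,
) -> MixtureModel:
    """Fit a K-component mixture of the given family by restarted EM.

    Each restart is seeded by a k-means hard partition converted to one-hot
    responsibilities.  The log-likelihood is non-decreasing within a run;
    the best converged run over all restarts is returned, with components
    sorted by ascending first-dimension mean.
    """
    X = np.asarray(X, float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (n x d)")
    n, d = X.shape
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; supported: {FAMILIES}")
    if K < 1 or n <= K:
        raise ValueError("need n > K >= 1")

    rng = np.random.default_rng(seed)
    best = None
    for r in range(n_restarts):
        if K == 1:
            resp = np.ones((n, 1))
        else:
            km_seed = int(rng.integers(0, 2**31 - 1))
            labels = KMeans(n_clusters=K, n_init=1, random_state=km_seed).fit_predict(X)
            resp = np.zeros((n, K))
            resp[np.arange(n), labels] = 1.0
            if (resp.sum(axis=0) == 0).any():
                continue
        res = _em_once(X, K, family, resp, tol, max_iter)
        if res is None:
            continue
        if best is None or res[3] > best[3]:
            best = res
        if K == 1:
            break  # closed form; restarts are identical
    if best is None:
        raise MixtureFitError(f"all {n_restarts} restarts degenerate ({family}, K={K})")

    weights, means, variances, loglik, path, converged, n_iter = best
    order = np.argsort(means[:, 0], kind="stable")
    m = n_free_params(family, K, d)
    return MixtureModel(
        family=family,
        K=K,
        weights=weights[order],
        means=means[order],
        variances=variances[order],
        loglik=loglik,
        m=m,
        n=n,
        bic=bic_mclust(loglik, m, n),
        converged=converged,
        n_iter=n_iter,
        loglik_path=path,
    )


def select_model(
    X: np.ndarray,
    K_range=range(1, 6),
    families=FAMILIES,
    seed: int = 0,
    **fit_kwargs,
) -> tuple[MixtureModel, pd.DataFrame]:
    """Fit every (family, K) and pick the best model by mclust BIC.

    Ties break toward fewer free parameters, then smaller K.  Returns the
    winning model and the full ranking table (failed fits are omitted).
    """
    rows, models = [], {}
    for family in families:
        for K in K_range:
            try:
                model = fit_mixture(X, K, family, seed=seed, **fit_kwargs)
            except (MixtureFitError, ValueError):
                continue
            models[(family, K)] = model
            rows.append(
                {"family": family, "K": K, "loglik": model.loglik,
                 "m": model.m, "bic": model.bic}
            )
    if not models:
        raise MixtureFitError("no (family, K) combination could be fitted")
    ranking = (
        pd.DataFrame(rows)
        .sort_values(["bic", "m", "K"], ascending=[False, True, True])
        .reset_index(drop=True)
    )
    top = ranking.iloc[0]
    return models[(top["family"], int(top["K"]))], ranking


def map_assign(model: MixtureModel, X: np.ndarray) -> ClusterAssignment:
    """MAP cluster labels and posterior responsibilities under ``model``.

    With two components the ordered components are named LOW/HIGH by
    ascending internalizing (first-dimension) mean; otherwise C1..CK.
    """
    X = np.asarray(X, float)
    resp, _ = _e_step(X, model.weights, model.means, model.variances)
    labels = resp.argmax(axis=1)
    if model.K == 2:
        names: tuple[str, ...] = ("LOW", "HIGH")
    else:
        names = tuple(f"C{i + 1}" for i in range(model.K))
    return ClusterAssignment(labels=labels, responsibilities=resp, names=names)
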