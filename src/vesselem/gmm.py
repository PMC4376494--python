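"""Gaussian-mixture pixel classification fitted by expectation maximisation.

The segmentation stage models the distance-map values with a K=2 mixture of
Gaussians.  The E-step computes posterior responsibilities by Bayes' theorem,
the M-step re-estimates means, covariances and mixing coefficients from
responsibility-weighted moments, and the loop is guaranteed (up to covariance
flooring) not to decrease the log-likelihood.

All densities are evaluated in log space with log-sum-exp normalisation, so
exact-zero plateaus in the distance map cannot produce NaNs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .errors import InvalidInputError, NumericalError

__all__ = [
    "PixelDataset",
    "MixtureParameters",
    "ResponsibilityMatrix",
    "EMFitResult",
    "log_likelihood",
    "e_step",
    "m_step",
    "fit_em",
    "classify",
]

logger = logging.getLogger(__name__)

#: covariance eigenvalue floor, as a fraction of the global data variance
COV_FLOOR_FRACTION = 1e-6


@dataclass
class PixelDataset:
    """M x D matrix of per-pixel feature values (D = 1 for the distance map)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        if values.ndim != 2:
            raise InvalidInputError("values must be an M x D matrix")
        if not np.all(np.isfinite(values)):
            raise InvalidInputError("values contain non-finite entries")
        self.values = values

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass
class MixtureParameters:
    """Means, covariances and mixing coefficients of a K-component Gaussian mixture."""

    means: np.ndarray        # K x D
    covariances: np.ndarray  # K x D x D
    mixing: np.ndarray       # K, on the simplex

    def __post_init__(self) -> None:
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        cov = np.asarray(self.covariances, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None, None]
        self.covariances = cov
        self.mixing = np.asarray(self.mixing, dtype=float)
        k = self.means.shape[0]
        if self.covariances.shape[0] != k or self.mixing.shape != (k,):
            raise InvalidInputError("inconsistent component counts")
        if np.any(self.mixing < -1e-12) or abs(self.mixing.sum() - 1.0) > 1e-9:
            raise InvalidInputError("mixing coefficients must lie on the simplex")

    @property
    def k(self) -> int:
        return self.means.shape[0]


@dataclass
class ResponsibilityMatrix:
    """M x K posterior membership probabilities; rows sum to 1."""

    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)

    @property
    def component_totals(self) -> np.ndarray:
        """Effective number of pixels per component (column sums)."""
        return self.gamma.sum(axis=0)


@dataclass
class EMFitResult:
    params: MixtureParameters
    responsibilities: ResponsibilityMatrix
    log_likelihood_trace: list = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = False


def _component_log_pdfs(data: PixelDataset, params: MixtureParameters) -> np.ndarray:
    """M x K matrix of per-component Gaussian log-densities."""
    x = data.values
    m, d = x.shape
    out = np.empty((m, params.k))
    for k in range(params.k):
        cov = params.covariances[k]
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(f"singular covariance for component {k}") from exc
        diff = x - params.means[k]
        sol = np.linalg.solve(chol, diff.T)
        maha = np.sum(sol ** 2, axis=0)
        log_det = 2.0 * np.sum(np.log(np.diag(chol)))
        out[:, k] = -0.5 * (d * np.log(2.0 * np.pi) + log_det + maha)
    return out


def log_likelihood(data: PixelDataset, params: MixtureParameters) -> float:
    """Sum over pixels of ``ln sum_k pi_k N(x_i | mu_k, Sigma_k)``."""
    log_pdf = _component_log_pdfs(data, params)
    with np.errstate(divide="ignore"):
        log_mix = np.log(params.mixing)
    return float(np.sum(logsumexp(log_pdf + log_mix, axis=1)))


def e_step(data: PixelDataset, params: MixtureParameters) -> ResponsibilityMatrix:
    """Posterior responsibilities by Bayes' theorem, computed in log space."""
    log_pdf = _component_log_pdfs(data, params)
    with np.errstate(divide="ignore"):
        log_num = log_pdf + np.log(params.mixing)
    log_norm = logsumexp(log_num, axis=1, keepdims=True)
    gamma = np.exp(log_num - log_norm)
    return ResponsibilityMatrix(gamma=gamma)


def _floor_covariance(cov: np.ndarray, floor: float) -> np.ndarray:
    """Raise eigenvalues of a symmetric matrix to at least ``floor``."""
    cov = 0.5 * (cov + cov.T)
    vals, vecs = np.linalg.eigh(cov)
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


def m_step(data: PixelDataset, resp: ResponsibilityMatrix) -> MixtureParameters:
    """Maximise the expected complete-data log-likelihood.

    Means are responsibility-weighted averages, covariances the matching
    weighted scatter (eigenvalue-floored), and mixing coefficients the average
    responsibility per component.
    """
    x = data.values
    gamma = resp.gamma
    m, d = x.shape
    k = gamma.shape[1]
    global_var = float(np.mean(np.var(x, axis=0)))
    floor = COV_FLOOR_FRACTION * max(global_var, 1e-300)

    nk = gamma.sum(axis=0)
    means = np.empty((k, d))
    covs = np.empty((k, d, d))
    for j in range(k):
        if nk[j] <= 0:
            # dead component: park it on the least-claimed data point; its
            # mixing weight stays at the true (zero) average responsibility
            logger.warning("m_step: component %d received no responsibility; "
                           "reinitialising from the least-claimed pixel", j)
            idx = int(np.argmin(gamma.max(axis=1)))
            means[j] = x[idx]
            covs[j] = _floor_covariance(np.eye(d) * max(global_var, floor), floor)
            continue
        mu = gamma[:, j] @ x / nk[j]
        diff = x - mu
        cov = (gamma[:, j] * diff.T) @ diff / nk[j]
        means[j] = mu
        covs[j] = _floor_covariance(cov, floor)
    mixing = nk / nk.sum()
    return MixtureParameters(means=means, covariances=covs, mixing=mixing)


def _quantile_init(x: np.ndarray, k: int) -> MixtureParameters:
    d = x.shape[1]
    if k == 1:
        qs = np.array([0.5])
    elif k == 2:
        qs = np.array([0.25, 0.90])
    else:
        qs = np.linspace(0.25, 0.90, k)
    means = np.quantile(x, qs, axis=0)
    # zero-inflated data (distance-map plateaus) can collapse the quantiles;
    # spread degenerate means over the data range instead
    if k > 1 and np.allclose(means[0], means[-1]):
        lo, hi = x.min(axis=0), x.max(axis=0)
        means = lo + (hi - lo) * np.linspace(0.0, 1.0, k)[:, None]
    global_var = np.var(x, axis=0)
    floor = COV_FLOOR_FRACTION * max(float(global_var.mean()), 1e-300)
    cov = _floor_covariance(np.diag(np.maximum(global_var, floor)), floor)
    covs = np.repeat(cov[None], k, axis=0)
    return MixtureParameters(means=means, covariances=covs, mixing=np.full(k, 1.0 / k))


def _kmeans_init(x: np.ndarray, k: int, rng: np.random.Generator) -> MixtureParameters:
    m, d = x.shape
    centers = x[rng.choice(m, size=k, replace=False)]
    labels = np.zeros(m, dtype=int)
    for _ in range(25):
        dist = np.linalg.norm(x[:, None, :] - centers[None], axis=2)
        new_labels = dist.argmin(axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            sel = labels == j
            if sel.any():
                centers[j] = x[sel].mean(axis=0)
    global_var = np.var(x, axis=0)
    floor = COV_FLOOR_FRACTION * max(float(global_var.mean()), 1e-300)
    covs = []
    mixing = np.empty(k)
    for j in range(k):
        sel = labels == j
        mixing[j] = max(sel.sum(), 1) / m
        cov = np.cov(x[sel].T, bias=True) if sel.sum() > 1 else np.diag(global_var)
        covs.append(_floor_covariance(np.atleast_2d(cov), floor))
    mixing /= mixing.sum()
    return MixtureParameters(means=centers, covariances=np.stack(covs), mixing=mixing)


def fit_em(data: PixelDataset, k: int = 2, init: str = "quantile",
           tol: float = 1e-6, max_iter: int = 200,
           seed: int | None = 0) -> EMFitResult:
    """Fit a K-component Gaussian mixture by EM.

    Parameters
    ----------
    data : PixelDataset
    k : int
        Component count; data must contain at least ``k`` points.
    init : {"quantile", "kmeans"}
        "quantile" places means at fixed data quantiles (deterministic);
        "kmeans" runs a short seeded Lloyd iteration.
    tol : float
        Relative log-likelihood change below which the fit stops.
    max_iter : int
    seed : int
        Seed for the "kmeans" initialisation; ignored by "quantile".
    """
    if data.m < k:
        raise InvalidInputError(f"need at least k={k} data points, got {data.m}")
    x = data.values
    if init == "quantile":
        params = _quantile_init(x, k)
    elif init == "kmeans":
        params = _kmeans_init(x, k, np.random.default_rng(seed))
    else:
        raise InvalidInputError(f"unknown init policy {init!r}")

    trace: list[float] = []
    resp = e_step(data, params)
    converged = False
    n_iter = 0
    ll_prev = -np.inf
    for n_iter in range(1, max_iter + 1):
        params = m_step(data, resp)
        resp = e_step(data, params)
        ll = log_likelihood(data, params)
        trace.append(ll)
        if np.isfinite(ll_prev) and abs(ll - ll_prev) < tol * abs(ll):
            converged = True
            break
        ll_prev = ll
    return EMFitResult(params=params, responsibilities=resp,
                       log_likelihood_trace=trace, n_iterations=n_iter,
                       converged=converged)


def vessel_component(params: MixtureParameters) -> int:
    """Index of the vessel component: the one with the larger mean value."""
    return int(np.argmax(params.means[:, 0]))


def classify(resp: ResponsibilityMatrix, params: MixtureParameters,
             shape: tuple) -> np.ndarray:
    """Binary vessel mask from a fitted 2-component mixture.

    A pixel is labelled vessel when its responsibility for the larger-mean
    component is >= 0.5 (ties go to vessel).
    """
    if params.k != 2:
        raise InvalidInputError("classification requires exactly K=2 components")
    vc = vessel_component(params)
    labels = resp.gamma[:, vc] >= 0.5
    return labels.reshape(shape)
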