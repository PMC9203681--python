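"""Zero-inflated Poisson mixture regression (ZIPMRM).

The response u is a nonnegative count.  With probability ``psi`` it is a
structural zero; otherwise it comes from a K-component Poisson regression
mixture in which component q has rate lambda_q = exp(beta0q + v1' beta_q)
(log link on the regressor covariates v1) and the component weights are a
multinomial-logit function of the concomitant covariates v2,

    pi_q|v2 = softmax_q(gamma0q + v2' gamma_q),

with the last component's coefficients fixed at zero for identifiability.
Fitting is by EM over the latent component indicator and structural-zero
indicator; the M-step solves per-component weighted Poisson regressions by
Newton iteration and a weighted multinomial-logit update for the
concomitant coefficients.

For classification, one ZIPMRM is fitted per class and observations are
assigned by the Bayes posterior over the class-conditional densities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

logger = logging.getLogger("biosigfusion")

_LOG_TINY = -745.0  # log of the smallest positive double


@dataclass
class CountResponse:
    """Count responses with regressor (v1) and concomitant (v2) covariates."""

    u: np.ndarray
    v1: np.ndarray | None = None
    v2: np.ndarray | None = None
    label: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u)
        if np.any(self.u < 0) or not np.all(self.u == np.floor(self.u)):
            raise ValueError("responses must be nonnegative integers")
        self.u = self.u.astype(int)
        n = self.u.size
        self.v1 = _as_covariates(self.v1, n)
        self.v2 = _as_covariates(self.v2, n)


def _as_covariates(v, n: int) -> np.ndarray:
    if v is None:
        return np.empty((n, 0))
    v = np.atleast_2d(np.asarray(v, dtype=float))
    if v.shape[0] != n:
        v = v.T
    if not np.all(np.isfinite(v)):
        raise ValueError("covariates must be finite")
    return v


@dataclass
class ZIPMRMParams:
    """Parameter set Phi: per-component Poisson-regression coefficients,
    concomitant multinomial-logit coefficients (last component zero) and
    the structural-zero mass psi."""

    beta0: np.ndarray              # (K,)
    beta: np.ndarray               # (K, p1)
    gamma0: np.ndarray             # (K,), gamma0[K-1] == 0
    gamma: np.ndarray              # (K, p2), gamma[K-1] == 0
    psi: float = 0.0
    loglik: float = float("nan")
    n_iter: int = 0
    converged: bool = False
    loglik_path: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.beta0 = np.atleast_1d(np.asarray(self.beta0, dtype=float))
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.gamma0 = np.atleast_1d(np.asarray(self.gamma0, dtype=float))
        self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        if not 0.0 <= self.psi <= 1.0:
            raise ValueError("psi must lie in [0, 1]")
        if abs(self.gamma0[-1]) > 1e-12 or np.any(np.abs(self.gamma[-1]) > 1e-12):
            raise ValueError("last component's concomitant coefficients must be 0")

    @property
    def K(self) -> int:
        return self.beta0.size


# ---------------------------------------------------------------------------
# Densities
# ---------------------------------------------------------------------------

def poisson_pmf(u, lam) -> np.ndarray | float:
    """Poisson pmf e^-lam lam^u / u! restricted to nonnegative integers
    (zero elsewhere, per the indicator); computed in log space."""
    u_arr = np.asarray(u, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("rate must be positive")
    valid = (u_arr >= 0) & (u_arr == np.floor(u_arr))
    uv = np.where(valid, u_arr, 0.0)
    logp = uv * np.log(lam) - lam - gammaln(uv + 1.0)
    out = np.where(valid, np.exp(logp), 0.0)
    return float(out) if np.isscalar(u) and np.ndim(lam) == 0 else out


def concomitant_weights(
    v2: np.ndarray, gamma0: np.ndarray, gamma: np.ndarray
) -> np.ndarray:
    """Softmax component weights pi_q|v2; rows sum to 1."""
    v2 = np.atleast_2d(np.asarray(v2, dtype=float))
    eta = gamma0[None, :] + v2 @ np.atleast_2d(gamma).T
    eta = eta - eta.max(axis=1, keepdims=True)
    w = np.exp(eta)
    return w / w.sum(axis=1, keepdims=True)


def component_rates(params: ZIPMRMParams, v1: np.ndarray) -> np.ndarray:
    """lambda_iq = exp(beta0q + v1_i' beta_q), shape (n, K)."""
    v1 = np.atleast_2d(np.asarray(v1, dtype=float))
    eta = params.beta0[None, :] + v1 @ params.beta.T
    return np.exp(np.clip(eta, -700, 700))


def zipmrm_density(u, v1, v2, params: ZIPMRMParams) -> np.ndarray:
    """psi 1{u=0} + (1 - psi) sum_q pi_q|v2 Poisson(u; lambda_q): the dual
    zero-generating / counting mechanism."""
    u = np.atleast_1d(np.asarray(u))
    n = u.size
    v1 = _as_covariates(v1, n)
    v2 = _as_covariates(v2, n)
    lam = component_rates(params, v1)
    piw = concomitant_weights(v2, params.gamma0, params.gamma)
    pois = np.stack(
        [poisson_pmf(u, lam[:, q]) for q in range(params.K)], axis=1
    )
    mix = (piw * pois).sum(axis=1)
    return params.psi * (u == 0) + (1.0 - params.psi) * mix


def mixture_moments(
    params: ZIPMRMParams, v1, v2
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and variance of the pure (psi = 0) Poisson mixture per
    observation: E = sum pi_q lambda_q, Var = E + y with the overdispersion
    excess y = sum pi_q lambda_q^2 - E^2 (zero iff all rates coincide)."""
    n = np.atleast_2d(np.asarray(v1, dtype=float)).shape[0] if v1 is not None else 1
    v1 = _as_covariates(v1, n)
    v2 = _as_covariates(v2, n)
    lam = component_rates(params, v1)
    piw = concomitant_weights(v2, params.gamma0, params.gamma)
    mean = (piw * lam).sum(axis=1)
    y = (piw * lam**2).sum(axis=1) - mean**2
    return mean, mean + y


# ---------------------------------------------------------------------------
# Count discretisation
# ---------------------------------------------------------------------------

def discretize_counts(
    features: np.ndarray, levels: int = 16
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-frequency binning of continuous features into counts
    {0, ..., levels-1}.  Returns (counts, edges); reuse the edges on
    held-out data with :func:`apply_count_bins` so no test statistics leak
    into the binning."""
    if levels < 2:
        raise ValueError("need at least 2 levels")
    X = np.atleast_2d(np.asarray(features, dtype=float))
    qs = np.arange(1, levels) / levels
    edges = np.quantile(X, qs, axis=0).T  # (F, levels-1)
    for j in range(X.shape[1]):
        if np.all(X[:, j] == X[0, j]):
            logger.warning("constant feature %d discretises to all zeros", j)
    return apply_count_bins(X, edges), edges


def apply_count_bins(features: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Monotone lookup of counts from previously derived bin edges."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    counts = np.empty(X.shape, dtype=int)
    for j in range(X.shape[1]):
        counts[:, j] = np.searchsorted(edges[j], X[:, j], side="left")
    return counts


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

def _poisson_newton(
    X: np.ndarray, u: np.ndarray, w: np.ndarray, coef: np.ndarray,
    max_iter: int = 50, tol: float = 1e-10,
) -> np.ndarray:
    """Weighted Poisson regression (log link) by Newton iteration."""
    coef = coef.copy()
    for _ in range(max_iter):
        eta = np.clip(X @ coef, -30, 30)
        lam = np.exp(eta)
        grad = X.T @ (w * (u - lam))
        H = (X * (w * lam)[:, None]).T @ X
        H[np.diag_indices_from(H)] += 1e-10
        step = np.linalg.solve(H, grad)
        # dampen overly long steps for stability
        norm = np.linalg.norm(step)
        if norm > 10.0:
            step *= 10.0 / norm
        coef += step
        if np.linalg.norm(step) < tol:
            break
    return coef


def _concomitant_update(
    X2: np.ndarray, resp: np.ndarray, gamma0: np.ndarray, gamma: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Maximise sum_iq resp_iq log pi_q|v2_i over the logit coefficients
    (last component fixed at zero)."""
    n, K = resp.shape
    p2 = X2.shape[1]
    if p2 == 0:
        mass = resp.sum(axis=0)
        mass = np.maximum(mass, 1e-12)
        piw = mass / mass.sum()
        g0 = np.log(piw / piw[-1])
        return g0, np.zeros((K, 0))

    def negll(theta):
        th = theta.reshape(K - 1, p2 + 1)
        eta = np.zeros((n, K))
        eta[:, : K - 1] = th[:, 0][None, :] + X2 @ th[:, 1:].T
        logpi = eta - logsumexp(eta, axis=1, keepdims=True)
        val = -(resp * logpi).sum()
        piw = np.exp(logpi)
        s = resp.sum(axis=1, keepdims=True)
        diff = resp - s * piw  # (n, K)
        grad = np.empty((K - 1, p2 + 1))
        grad[:, 0] = -diff[:, : K - 1].sum(axis=0)
        grad[:, 1:] = -(diff[:, : K - 1].T @ X2)
        return val, grad.ravel()

    theta0 = np.concatenate(
        [np.column_stack([gamma0[: K - 1], gamma[: K - 1]]).ravel()]
    )
    res = minimize(negll, theta0, jac=True, method="L-BFGS-B")
    th = res.x.reshape(K - 1, p2 + 1)
    g0 = np.concatenate([th[:, 0], [0.0]])
    g = np.vstack([th[:, 1:], np.zeros(p2)])
    return g0, g


def observed_loglik(data: CountResponse, params: ZIPMRMParams) -> float:
    dens = zipmrm_density(data.u, data.v1, data.v2, params)
    return float(np.sum(np.log(np.maximum(dens, np.exp(_LOG_TINY)))))


def fit_zipmrm(
    data: CountResponse,
    K: int = 2,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int | None = 0,
    fit_psi: bool = True,
) -> ZIPMRMParams:
    """EM fit of the ZIPMRM.

    The E-step computes, per observation, the posterior probability of
    being a structural zero and the component responsibilities; the M-step
    updates psi, runs per-component weighted Poisson Newton regressions,
    and refits the concomitant multinomial logit.  The observed-data
    log-likelihood is non-decreasing; stopping is on relative change below
    ``tol`` or ``max_iter`` sweeps.  With ``fit_psi=False`` psi stays 0 and
    the model reduces to a plain Poisson mixture regression.
    """
    u = data.u.astype(float)
    n = u.size
    if n < 20 * K:
        logger.warning("only %d observations for K=%d components", n, K)
    rng = np.random.default_rng(seed)
    X1 = np.column_stack([np.ones(n), data.v1])
    p2 = data.v2.shape[1]

    # init: split responses by quantile groups
    order = np.argsort(u + 1e-9 * rng.standard_normal(n))
    groups = np.array_split(order, K)
    beta0 = np.array(
        [np.log(np.mean(u[g]) + 0.5) for g in groups], dtype=float
    )
    coefs = np.column_stack([beta0, np.zeros((K, data.v1.shape[1]))])
    gamma0 = np.zeros(K)
    gamma = np.zeros((K, p2))
    psi = 0.05 if fit_psi else 0.0

    def make_params(ll=float("nan"), it=0, conv=False, path=None):
        return ZIPMRMParams(
            beta0=coefs[:, 0].copy(), beta=coefs[:, 1:].copy(),
            gamma0=gamma0.copy(), gamma=gamma.copy(), psi=psi,
            loglik=ll, n_iter=it, converged=conv,
            loglik_path=None if path is None else np.asarray(path),
        )

    path = [observed_loglik(data, make_params())]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        params = make_params()
        # ---- E step ----------------------------------------------------
        lam = component_rates(params, data.v1)
        logpois = (
            u[:, None] * np.log(lam) - lam - gammaln(u + 1.0)[:, None]
        )
        piw = concomitant_weights(data.v2, gamma0, gamma)
        log_mix_q = np.log(np.maximum(piw, 1e-300)) + logpois
        log_mix = logsumexp(log_mix_q, axis=1)
        mix = np.exp(np.maximum(log_mix, _LOG_TINY))
        denom = psi * (u == 0) + (1.0 - psi) * mix
        denom = np.maximum(denom, np.exp(_LOG_TINY))
        p_struct = np.where(u == 0, psi / denom, 0.0)
        resp = (
            (1.0 - psi)
            * np.exp(log_mix_q - log_mix[:, None])
            * (mix / denom)[:, None]
        )  # (n, K), rows sum to 1 - p_struct
        # ---- M step ----------------------------------------------------
        if fit_psi:
            psi = float(np.mean(p_struct))
        for q in range(K):
            if resp[:, q].sum() < 1e-8:
                qn = float(rng.uniform(0.1, 0.9))
                coefs[q] = 0.0
                coefs[q, 0] = np.log(np.quantile(u, qn) + 0.5)
                logger.warning("re-seeded empty component %d", q)
                continue
            coefs[q] = _poisson_newton(X1, u, resp[:, q], coefs[q])
        gamma0, gamma = _concomitant_update(data.v2, resp, gamma0, gamma)
        ll = observed_loglik(data, make_params())
        if ll < path[-1] - 1e-9:
            logger.warning(
                "observed log-likelihood decreased by %.3g at sweep %d",
                path[-1] - ll, it,
            )
        rel = abs(ll - path[-1]) / (abs(path[-1]) + 1e-12)
        path.append(ll)
        if rel < tol:
            converged = True
            break
    return make_params(ll=path[-1], it=it, conv=converged, path=path)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def predict_zipmrm(
    params_by_class: dict,
    u,
    v1=None,
    v2=None,
    priors: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Bayes posterior over classes for count responses.

    Returns (predicted labels, posterior matrix with one column per class
    in sorted label order).  If every class density underflows for an
    observation the posterior is uniform there (flagged by a warning).
    """
    classes = sorted(params_by_class)
    u = np.atleast_1d(np.asarray(u))
    logpost = np.empty((u.size, len(classes)))
    for j, c in enumerate(classes):
        dens = zipmrm_density(u, v1, v2, params_by_class[c])
        prior = 1.0 / len(classes) if priors is None else priors[c]
        logpost[:, j] = np.log(np.maximum(dens, 1e-300)) + np.log(prior)
    bad = np.all(logpost <= _LOG_TINY, axis=1)
    if np.any(bad):
        logger.warning("all-class density underflow for %d rows", int(bad.sum()))
        logpost[bad] = 0.0
    logpost -= logsumexp(logpost, axis=1, keepdims=True)
    post = np.exp(logpost)
    pred = np.array([classes[j] for j in np.argmax(post, axis=1)])
    return pred, post


class ZIPMRMClassifier:
    """Generative classifier over multi-feature count vectors.

    Each class gets its own ZIPMRM fitted on the long format (one count per
    observation-feature pair) with feature-identity dummies as both the
    regressor and concomitant covariates, so per-feature rates and
    component weights are captured by a single regression fit per class.
    Class posteriors multiply the per-feature densities (conditional
    independence given the class).
    """

    def __init__(self, K: int = 2, max_iter: int = 100, tol: float = 1e-6,
                 seed: int = 0, fit_psi: bool = True):
        self.K = K
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed
        self.fit_psi = fit_psi
        self.params_: dict = {}
        self.priors_: dict = {}

    @staticmethod
    def _long_format(U: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n, F = U.shape
        u_long = U.ravel()
        dummies = np.tile(np.eye(F)[:, 1:], (n, 1))  # drop-first encoding
        return u_long, dummies

    def fit(self, U: np.ndarray, labels: Sequence) -> "ZIPMRMClassifier":
        U = np.atleast_2d(np.asarray(U))
        labels = np.asarray(labels)
        for c in np.unique(labels):
            rows = U[labels == c]
            u_long, dummies = self._long_format(rows)
            data = CountResponse(u=u_long, v1=dummies, v2=dummies)
            self.params_[c] = fit_zipmrm(
                data, K=self.K, max_iter=self.max_iter, tol=self.tol,
                seed=self.seed, fit_psi=self.fit_psi,
            )
            self.priors_[c] = float(np.mean(labels == c))
        return self

    def predict_proba(self, U: np.ndarray) -> np.ndarray:
        U = np.atleast_2d(np.asarray(U))
        classes = sorted(self.params_)
        n, F = U.shape
        logpost = np.empty((n, len(classes)))
        for j, c in enumerate(classes):
            u_long, dummies = self._long_format(U)
            dens = zipmrm_density(u_long, dummies, dummies, self.params_[c])
            logd = np.log(np.maximum(dens, 1e-300)).reshape(n, F).sum(axis=1)
            logpost[:, j] = logd + np.log(self.priors_[c])
        logpost -= logsumexp(logpost, axis=1, keepdims=True)
        return np.exp(logpost)

    def predict(self, U: np.ndarray) -> np.ndarray:
        classes = sorted(self.params_)
        post = self.predict_proba(U)
        return np.array([classes[j] for j in np.argmax(post, axis=1)])
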