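"""Fusion Hybrid Model: finite-mixture modelling of normalised observations.

The fusion model treats each normalised data point ``z`` as a draw from

    f(z; Psi) = (1 - pi) f0(z; Psi0) + pi f1(z; Psi1)

where ``f0`` is a normal (NUDGE) or a Q-component normal mixture
(eNUDGE, GNG) capturing the central bulk, and ``f1`` captures
overdispersed, potentially interesting observations: a uniform on the data
range (NUDGE/eNUDGE) or a pair of exponential tails anchored just outside
zero (GNG, the "gamma-normal-gamma" class).  Fitting maximises a *weighted*
log-likelihood

    ml(Psi) = sum_k wei_k log f(z_k; Psi),   0 < wei_k <= 1,

with weights derived from an SVD-based intensity of the source windows so
that faint epochs contribute less.  Within eNUDGE/GNG the component count Q
is selected by BIC; the overall class winner by AIC.  Normal components far
from the bulk (|mu_q| + 2 sigma_q > 1.5 IQR) are flagged *differential*, a
per-observation local false-discovery-rate score

    FDR(z_k) = f_nondiff(z_k) / f(z_k)

is computed, and observation k is retained when FDR(z_k)/wei_k <= y0.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger("biosigfusion")

MODEL_CLASSES = ("NUDGE", "eNUDGE", "GNG")

# EM defaults
DEFAULT_EPS = 1e-8
DEFAULT_MAX_ITER = 1000
#: Huber-style down-weighting knee of the intensity weight function.
DEFAULT_G = 1.5
#: Default retention threshold on FDR(z)/wei.
DEFAULT_Y0 = 0.05
SIGMA_FLOOR_FRAC = 1e-4  # sigma floor as a fraction of the data SD
_TINY = 1e-300


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class FHMParams:
    """Full parameter set Psi of a fusion mixture.

    ``pi`` is the mixing weight of the overdispersion part f1.  The normal
    bulk f0 has Q components (means/sigmas/gammas).  Exactly one of the f1
    parameterisations is populated: ``uniform_bounds`` (i, j) for
    NUDGE/eNUDGE, or the exponential-tail parameters for GNG, where
    ``xi1``/``xi2`` are plug-in tail anchor locations held fixed during EM.
    """

    pi: float
    means: np.ndarray
    sigmas: np.ndarray
    gammas: np.ndarray
    uniform_bounds: tuple[float, float] | None = None
    rho: float | None = None
    beta1: float | None = None
    beta2: float | None = None
    xi1: float | None = None
    xi2: float | None = None

    def __post_init__(self) -> None:
        self.means = np.atleast_1d(np.asarray(self.means, dtype=float))
        self.sigmas = np.atleast_1d(np.asarray(self.sigmas, dtype=float))
        self.gammas = np.atleast_1d(np.asarray(self.gammas, dtype=float))
        if np.any(self.sigmas <= 0):
            raise ValueError("all sigmas must be positive")
        if abs(self.gammas.sum() - 1.0) > 1e-12:
            raise ValueError("component weights gamma must sum to 1")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must lie in [0, 1]")
        has_u = self.uniform_bounds is not None
        has_e = self.rho is not None
        if has_u == has_e:
            raise ValueError(
                "exactly one of uniform_bounds / exponential tails required"
            )
        if has_u and not self.uniform_bounds[0] < self.uniform_bounds[1]:
            raise ValueError("uniform bounds must satisfy i < j")
        if has_e:
            if not 0.0 <= self.rho <= 1.0:
                raise ValueError("rho must lie in [0, 1]")
            for v in (self.beta1, self.beta2, self.xi1, self.xi2):
                if v is None or v <= 0:
                    raise ValueError("beta1, beta2, xi1, xi2 must be > 0")

    @property
    def Q(self) -> int:
        return self.means.size

    def as_vector(self) -> np.ndarray:
        """Flat parameter vector used by the EM stop rule."""
        parts = [np.array([self.pi]), self.means, self.sigmas, self.gammas]
        if self.uniform_bounds is not None:
            parts.append(np.asarray(self.uniform_bounds, dtype=float))
        else:
            parts.append(np.array([self.rho, self.beta1, self.beta2]))
        return np.concatenate(parts)


def n_free_params(model_class: str, Q: int) -> int:
    """Free-parameter counts used by BIC/AIC (tail anchors are plug-ins):
    NUDGE 5, eNUDGE 3Q+3, GNG 3Q+4."""
    if model_class == "NUDGE":
        return 5
    if model_class == "eNUDGE":
        return 3 * Q + 3
    if model_class == "GNG":
        return 3 * Q + 4
    raise ValueError(f"unknown model class {model_class!r}")


@dataclass
class FittedFHM:
    """A fitted fusion mixture plus the feature-calling artefacts."""

    params: FHMParams
    model_class: str
    weights: np.ndarray
    loglik: float
    bic: float
    aic: float
    n_iter: int
    converged: bool
    loglik_path: np.ndarray = field(repr=False, default=None)
    differential_flags: np.ndarray | None = None
    fdr: np.ndarray | None = None
    retained_mask: np.ndarray | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        for k, v in list(d.items()):
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        for k, v in list(d["params"].items()):
            if isinstance(v, np.ndarray):
                d["params"][k] = v.tolist()
        text = json.dumps(d, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# Intensity weighting
# ---------------------------------------------------------------------------

def estimate_tail_locations(z: Sequence[float]) -> tuple[float, float]:
    """Plug-in GNG tail anchors: xi1 = |max of negative z|, xi2 = min of
    positive z.  Requires at least one value on each side of zero."""
    z = np.asarray(z, dtype=float)
    neg = z[z < 0]
    pos = z[z > 0]
    if neg.size == 0 or pos.size == 0:
        raise ValueError(
            "GNG tail anchors need both negative and positive observations"
        )
    return float(abs(neg.max())), float(abs(pos.min()))


def observation_weights(v: Sequence[float], g: float = DEFAULT_G) -> np.ndarray:
    """One-sided Huber-style weight: 1 above the knee ``-g``, ``g/|v|``
    at or below it.  Continuous at the knee; values lie in (0, 1]."""
    if g <= 0:
        raise ValueError("g must be positive")
    v = np.asarray(v, dtype=float)
    wei = np.ones_like(v)
    low = v <= -g
    wei[low] = g / np.abs(v[low])
    return wei


def svd_intensity(window_matrix: np.ndarray) -> np.ndarray:
    """Per-observation intensity score from a rank-1 SVD summary.

    Each observation (row) is mean-centred, the matrix decomposed by SVD,
    and the observation's magnitude along the leading singular direction
    (|U_k1| * s_1) taken as its intensity.  The returned ``v`` is the
    z-scored log intensity, so faint epochs get negative scores and are
    down-weighted by :func:`observation_weights`.
    """
    X = np.asarray(window_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least a 2x2 observations-by-samples matrix")
    Xc = X - X.mean(axis=1, keepdims=True)
    if not np.any(Xc):
        return np.zeros(X.shape[0])
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    mag = np.abs(U[:, 0]) * s[0]
    mag = np.maximum(mag, mag.max() * 1e-12 + _TINY)
    logmag = np.log(mag)
    sd = logmag.std()
    if sd == 0:
        return np.zeros(X.shape[0])
    return (logmag - logmag.mean()) / sd


# ---------------------------------------------------------------------------
# Densities
# ---------------------------------------------------------------------------

def density_f1(z, params: FHMParams, model_class: str) -> np.ndarray:
    """Overdispersion density: uniform on [i, j] (NUDGE/eNUDGE) or a
    rho-blend of exponential tails anchored at -xi1 and +xi2 (GNG)."""
    z = np.asarray(z, dtype=float)
    if model_class in ("NUDGE", "eNUDGE"):
        if params.uniform_bounds is None:
            raise ValueError("uniform bounds required for NUDGE/eNUDGE")
        i, j = params.uniform_bounds
        out = np.where((z >= i) & (z <= j), 1.0 / (j - i), 0.0)
    elif model_class == "GNG":
        if params.rho is None:
            raise ValueError("exponential tail parameters required for GNG")
        out = np.zeros_like(z)
        left = z < -params.xi1
        right = z > params.xi2
        out[left] = (
            params.rho / params.beta1
            * np.exp(-((-z[left]) - params.xi1) / params.beta1)
        )
        out[right] = (
            (1.0 - params.rho) / params.beta2
            * np.exp(-(z[right] - params.xi2) / params.beta2)
        )
    else:
        raise ValueError(f"unknown model class {model_class!r}")
    return out


def density_f0(z, params: FHMParams) -> np.ndarray:
    """Central bulk: single normal (Q=1) or gamma-weighted normal mixture."""
    z = np.asarray(z, dtype=float)
    out = np.zeros_like(z)
    for mu, sig, gam in zip(params.means, params.sigmas, params.gammas):
        out += gam * stats.norm.pdf(z, loc=mu, scale=sig)
    return out


def mixture_density(z, params: FHMParams, model_class: str) -> np.ndarray:
    """Full fusion density (1 - pi) f0 + pi f1; integrates to 1."""
    return (1.0 - params.pi) * density_f0(z, params) + params.pi * density_f1(
        z, params, model_class
    )


def weighted_loglik(
    z, wei, params: FHMParams, model_class: str
) -> float:
    """Weighted log-likelihood sum_k wei_k log f(z_k; Psi).  A zero density
    at a positively weighted point yields -inf (flagged by a warning)."""
    z = np.asarray(z, dtype=float)
    wei = np.asarray(wei, dtype=float)
    if z.shape != wei.shape:
        raise ValueError("z and wei must be aligned")
    f = mixture_density(z, params, model_class)
    bad = (f <= 0) & (wei > 0)
    if np.any(bad):
        warnings.warn("zero mixture density at a weighted observation")
        return float("-inf")
    return float(np.sum(wei * np.log(np.maximum(f, _TINY))))


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

def _init_params(
    z: np.ndarray, model_class: str, Q: int, rng: np.random.Generator
) -> FHMParams:
    sd = float(z.std()) or 1.0
    qs = (np.arange(Q) + 0.5) / Q
    means = np.quantile(z, qs) + 0.01 * sd * rng.standard_normal(Q)
    sigmas = np.full(Q, sd)
    gammas = np.full(Q, 1.0 / Q)
    if model_class == "GNG":
        xi1, xi2 = estimate_tail_locations(z)
        return FHMParams(
            pi=0.1, means=means, sigmas=sigmas, gammas=gammas,
            rho=0.5, beta1=sd, beta2=sd, xi1=xi1, xi2=xi2,
        )
    lo, hi = float(z.min()), float(z.max())
    if lo == hi:
        lo, hi = lo - 1.0, hi + 1.0
    return FHMParams(
        pi=0.1, means=means, sigmas=sigmas, gammas=gammas,
        uniform_bounds=(lo, hi),
    )


def em_fit(
    z: Sequence[float],
    wei: Sequence[float] | None = None,
    model_class: str = "eNUDGE",
    Q: int = 1,
    eps: float = DEFAULT_EPS,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int | None = 0,
) -> FittedFHM:
    """Weighted EM fit of one model class at fixed Q.

    The uniform bounds (NUDGE/eNUDGE) and the GNG tail anchors xi1/xi2 are
    plug-ins fixed at the data range / nearest-to-zero points; pi, the
    normal components, and the GNG tail blend/scales are re-estimated each
    sweep.  Stops when the parameter-vector change drops below ``eps`` or
    after ``max_iter`` sweeps; the weighted log-likelihood path is recorded
    and is non-decreasing (up to a 1e-9 slack from the sigma floor).
    """
    if model_class not in MODEL_CLASSES:
        raise ValueError(f"unknown model class {model_class!r}")
    if model_class == "NUDGE" and Q != 1:
        raise ValueError("NUDGE forces Q = 1")
    z = np.asarray(z, dtype=float)
    wei = np.ones_like(z) if wei is None else np.asarray(wei, dtype=float)
    if z.shape != wei.shape:
        raise ValueError("z and wei must be aligned")
    n_free = n_free_params(model_class, Q)
    if z.size < 10 * n_free:
        warnings.warn(
            f"only {z.size} observations for {n_free} free parameters; "
            "estimates may be unstable"
        )
    rng = np.random.default_rng(seed)
    params = _init_params(z, model_class, Q, rng)
    sigma_floor = SIGMA_FLOOR_FRAC * (float(z.std()) or 1.0)
    wsum = wei.sum()

    path = [weighted_loglik(z, wei, params, model_class)]
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        prev_vec = params.as_vector()
        # ---- E step ----------------------------------------------------
        f1 = density_f1(z, params, model_class)
        comp = np.stack(
            [
                gam * stats.norm.pdf(z, mu, sig)
                for mu, sig, gam in zip(
                    params.means, params.sigmas, params.gammas
                )
            ]
        )  # (Q, n)
        f = (1.0 - params.pi) * comp.sum(axis=0) + params.pi * f1
        f = np.maximum(f, _TINY)
        tau1 = params.pi * f1 / f
        tau0 = (1.0 - params.pi) * comp / f  # (Q, n)
        # ---- M step ----------------------------------------------------
        pi_new = float(np.sum(wei * tau1) / wsum)
        resp0 = wei * tau0  # (Q, n)
        mass_q = resp0.sum(axis=1)
        mass_q = np.maximum(mass_q, 1e-12)
        gammas = mass_q / mass_q.sum()
        means = (resp0 @ z) / mass_q
        sigmas = np.sqrt(
            np.maximum(
                (resp0 * (z[None, :] - means[:, None]) ** 2).sum(axis=1)
                / mass_q,
                sigma_floor**2,
            )
        )
        if np.any(sigmas <= sigma_floor):
            logger.debug("sigma floor applied at iteration %d", n_iter)
        kwargs: dict = {}
        if model_class == "GNG":
            r1 = wei * tau1
            left = z < -params.xi1
            right = z > params.xi2
            m_left = float(r1[left].sum())
            m_right = float(r1[right].sum())
            if m_left + m_right > 0:
                rho = m_left / (m_left + m_right)
            else:
                rho = params.rho
            beta1 = (
                float((r1[left] * ((-z[left]) - params.xi1)).sum() / m_left)
                if m_left > 0 else params.beta1
            )
            beta2 = (
                float((r1[right] * (z[right] - params.xi2)).sum() / m_right)
                if m_right > 0 else params.beta2
            )
            kwargs = dict(
                rho=min(max(rho, 0.0), 1.0),
                beta1=max(beta1, 1e-8),
                beta2=max(beta2, 1e-8),
                xi1=params.xi1,
                xi2=params.xi2,
            )
        else:
            kwargs = dict(uniform_bounds=params.uniform_bounds)
        params = FHMParams(
            pi=min(max(pi_new, 0.0), 1.0),
            means=means, sigmas=sigmas, gammas=gammas, **kwargs,
        )
        ll = weighted_loglik(z, wei, params, model_class)
        if ll < path[-1] - 1e-9:
            logger.warning(
                "weighted log-likelihood decreased by %.3g at iteration %d",
                path[-1] - ll, n_iter,
            )
        path.append(ll)
        if np.linalg.norm(params.as_vector() - prev_vec) < eps:
            converged = True
            break

    ll = path[-1]
    m = z.size
    bic = 2.0 * ll - n_free * np.log(m)
    aic = 2.0 * ll - 2.0 * n_free
    return FittedFHM(
        params=params,
        model_class=model_class,
        weights=wei,
        loglik=ll,
        bic=float(bic),
        aic=float(aic),
        n_iter=n_iter,
        converged=converged,
        loglik_path=np.asarray(path),
    )


# ---------------------------------------------------------------------------
# Model selection and feature calling
# ---------------------------------------------------------------------------

def label_differential(fitted: FittedFHM, z: Sequence[float]) -> np.ndarray:
    """Flag normal component q as differential iff
    |mu_q| + 2 sigma_q > 1.5 IQR(z)."""
    z = np.asarray(z, dtype=float)
    iqr = float(np.subtract(*np.percentile(z, [75, 25])))
    p = fitted.params
    return np.abs(p.means) + 2.0 * p.sigmas > 1.5 * iqr


def fdr_scores(z: Sequence[float], fitted: FittedFHM) -> np.ndarray:
    """Local FDR analogue: density of the non-differential normal part over
    the full mixture density, per observation."""
    if fitted.differential_flags is None:
        raise ValueError("differential flags must be assigned first")
    z = np.asarray(z, dtype=float)
    p = fitted.params
    f = mixture_density(z, p, fitted.model_class)
    f_norm = np.zeros_like(z)
    for mu, sig, gam, diff in zip(
        p.means, p.sigmas, p.gammas, fitted.differential_flags
    ):
        if not diff:
            f_norm += (1.0 - p.pi) * gam * stats.norm.pdf(z, mu, sig)
    out = np.zeros_like(z)
    ok = f > 0
    if np.any(~ok):
        logger.warning("zero mixture density: FDR set to 0 there")
    out[ok] = f_norm[ok] / f[ok]
    return out


def select_observations(
    fdr: Sequence[float], wei: Sequence[float], y0: float = DEFAULT_Y0
) -> np.ndarray:
    """Retain observation k iff FDR(z_k) / wei_k <= y0 (down-weighted
    observations need proportionally stronger evidence)."""
    if y0 <= 0:
        raise ValueError("y0 must be positive")
    fdr = np.asarray(fdr, dtype=float)
    wei = np.asarray(wei, dtype=float)
    if fdr.shape != wei.shape:
        raise ValueError("fdr and wei must be aligned")
    return fdr / wei <= y0


def select_model(
    z: Sequence[float],
    wei: Sequence[float] | None = None,
    Q_max: int = 3,
    y0: float = DEFAULT_Y0,
    seed: int | None = 0,
    eps: float = DEFAULT_EPS,
    max_iter: int = DEFAULT_MAX_ITER,
) -> FittedFHM:
    """Fit all three model classes, pick Q by BIC within eNUDGE/GNG, the
    overall winner by AIC (ties toward fewer parameters), and populate the
    differential flags, FDR scores and retained-observation mask."""
    if Q_max < 1:
        raise ValueError("Q_max must be >= 1")
    z = np.asarray(z, dtype=float)
    wei = np.ones_like(z) if wei is None else np.asarray(wei, dtype=float)
    champions: list[FittedFHM] = []
    failures: dict[str, str] = {}
    for model_class in MODEL_CLASSES:
        qs = [1] if model_class == "NUDGE" else list(range(1, Q_max + 1))
        best: FittedFHM | None = None
        for Q in qs:
            try:
                fit = em_fit(
                    z, wei, model_class, Q, eps=eps, max_iter=max_iter,
                    seed=seed,
                )
            except ValueError as exc:  # e.g. GNG with one-sided data
                failures[f"{model_class}/Q={Q}"] = str(exc)
                continue
            if best is None or fit.bic > best.bic + 1e-12:
                best = fit
        if best is not None:
            champions.append(best)
    if not champions:
        raise RuntimeError(f"all model fits failed: {failures}")
    # AIC winner; ties broken toward fewer free parameters
    champions.sort(
        key=lambda f: (
            -f.aic, n_free_params(f.model_class, f.params.Q)
        )
    )
    winner = champions[0]
    winner.differential_flags = label_differential(winner, z)
    winner.fdr = fdr_scores(z, winner)
    winner.retained_mask = select_observations(winner.fdr, wei, y0)
    return winner
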