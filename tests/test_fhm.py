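"""Fusion-mixture unit tests: densities against hand arithmetic, EM
against simulated generators, the intensity weight function, and the
differential/FDR feature-calling rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from biosigfusion import fhm
from biosigfusion.synthetic_data import gen_mixture_sample


def _uniform_params(pi=0.2, means=(-1.0, 1.0), sigmas=(0.5, 0.5),
                    gammas=(0.5, 0.5), bounds=(-6.0, 6.0)):
    return fhm.FHMParams(
        pi=pi, means=list(means), sigmas=list(sigmas), gammas=list(gammas),
        uniform_bounds=bounds,
    )


# ---------------------------------------------------------------------------
# Tail locations and weights
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "z,expected",
    [
        ([-2.5, -0.3, 0.4, 1.1], (0.3, 0.4)),
        ([-1.0, 2.0], (1.0, 2.0)),
        ([-0.7, 0.7, -3.0, 3.0], (0.7, 0.7)),   # symmetric about 0
    ],
)
def test_tail_locations(z, expected):
    assert fhm.estimate_tail_locations(z) == pytest.approx(expected)


def test_tail_locations_one_sided_error():
    with pytest.raises(ValueError):
        fhm.estimate_tail_locations([0.5, 1.0, 2.0])


def test_observation_weights_hand_values():
    w = fhm.observation_weights(np.array([0.0, -1.5, -3.0]), g=1.5)
    np.testing.assert_allclose(w, [1.0, 1.0, 0.5])


@settings(derandomize=True, max_examples=50)
@given(v=st.floats(-1e6, 1e6, allow_nan=False))
def test_observation_weights_bounded_and_continuous(v):
    w = fhm.observation_weights(np.array([v]))[0]
    assert 0.0 < w <= 1.0
    # continuity at the knee
    eps = 1e-9
    w_lo = fhm.observation_weights(np.array([-1.5 - eps]))[0]
    w_hi = fhm.observation_weights(np.array([-1.5 + eps]))[0]
    assert abs(w_lo - w_hi) < 1e-6


# ---------------------------------------------------------------------------
# SVD intensity
# ---------------------------------------------------------------------------

def test_svd_intensity_identical_rows_equal_weights():
    X = np.tile([1.0, 2.0, 3.0], (4, 1))
    v = fhm.svd_intensity(X)
    assert np.allclose(v, v[0])
    w = fhm.observation_weights(v)
    assert np.allclose(w, w[0])


def test_svd_intensity_faint_row_is_minimum():
    base = np.array([1.0, -2.0, 3.0])
    X = np.vstack([base, 2.0 * base, 1e-3 * base])
    v = fhm.svd_intensity(X)
    assert np.argmin(v) == 2


def test_svd_intensity_scale_invariant():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((5, 8))
    np.testing.assert_allclose(
        fhm.svd_intensity(X), fhm.svd_intensity(2.0 * X), atol=1e-10
    )


def test_svd_intensity_zero_matrix():
    assert np.all(fhm.svd_intensity(np.zeros((3, 4))) == 0.0)


# ---------------------------------------------------------------------------
# Densities
# ---------------------------------------------------------------------------

def test_uniform_f1_hand_value():
    p = _uniform_params(bounds=(-2.0, 2.0))
    assert fhm.density_f1(np.array([0.0]), p, "eNUDGE")[0] == pytest.approx(0.25)
    assert fhm.density_f1(np.array([2.5]), p, "eNUDGE")[0] == 0.0


def test_gng_f1_gap_and_tail():
    p = fhm.FHMParams(
        pi=0.3, means=[0.0], sigmas=[1.0], gammas=[1.0],
        rho=1.0, beta1=2.0, beta2=1.0, xi1=1.0, xi2=0.5,
    )
    # between the anchors both indicators are off
    assert fhm.density_f1(np.array([0.2]), p, "GNG")[0] == 0.0
    # left tail: (rho/beta1) exp(-(|z| - xi1)/beta1) at z = -3
    expected = 0.5 * np.exp(-1.0)
    assert fhm.density_f1(np.array([-3.0]), p, "GNG")[0] == pytest.approx(expected)


def test_f0_hand_values():
    p1 = _uniform_params(means=(0.0,), sigmas=(1.0,), gammas=(1.0,))
    assert fhm.density_f0(np.array([0.0]), p1)[0] == pytest.approx(
        1.0 / np.sqrt(2 * np.pi)
    )
    from scipy import stats
    p2 = _uniform_params(means=(-1.0, 1.0), sigmas=(1.0, 1.0), gammas=(0.3, 0.7))
    expected = 0.3 * stats.norm.pdf(0, -1, 1) + 0.7 * stats.norm.pdf(0, 1, 1)
    assert fhm.density_f0(np.array([0.0]), p2)[0] == pytest.approx(expected)


def test_mixture_density_boundaries():
    z = np.linspace(-3, 3, 7)
    p0 = _uniform_params(pi=0.0)
    np.testing.assert_allclose(
        fhm.mixture_density(z, p0, "eNUDGE"), fhm.density_f0(z, p0)
    )
    p1 = _uniform_params(pi=1.0)
    np.testing.assert_allclose(
        fhm.mixture_density(z, p1, "eNUDGE"), fhm.density_f1(z, p1, "eNUDGE")
    )


@pytest.mark.parametrize("model_class", ["eNUDGE", "GNG"])
def test_density_integrates_to_one(model_class):
    if model_class == "GNG":
        p = fhm.FHMParams(
            pi=0.25, means=[-0.5, 0.5], sigmas=[0.7, 1.2], gammas=[0.4, 0.6],
            rho=0.3, beta1=1.5, beta2=0.8, xi1=0.6, xi2=0.9,
        )
    else:
        p = _uniform_params(pi=0.25)
    grid = np.linspace(-30, 30, 120_001)
    integral = np.trapezoid(fhm.mixture_density(grid, p, model_class), grid)
    assert integral == pytest.approx(1.0, abs=1e-4)


# ---------------------------------------------------------------------------
# Weighted log-likelihood
# ---------------------------------------------------------------------------

def test_weighted_loglik_reductions(rng):
    p = _uniform_params()
    z = rng.normal(0, 1, 50)
    full = fhm.weighted_loglik(z, np.ones(50), p, "eNUDGE")
    plain = float(np.sum(np.log(fhm.mixture_density(z, p, "eNUDGE"))))
    assert full == pytest.approx(plain, rel=1e-12)
    half = fhm.weighted_loglik(z, np.full(50, 0.5), p, "eNUDGE")
    assert half == pytest.approx(0.5 * full, rel=1e-12)


def test_weighted_loglik_single_point():
    p = _uniform_params(pi=0.0, means=(0.0,), sigmas=(1.0,), gammas=(1.0,))
    got = fhm.weighted_loglik(np.array([0.0]), np.array([0.5]), p, "eNUDGE")
    assert got == pytest.approx(0.5 * np.log(1.0 / np.sqrt(2 * np.pi)))


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

def test_em_single_normal_nudge_pi_small():
    rng = np.random.default_rng(4)
    z = rng.normal(0, 1, 2000)
    fit = fhm.em_fit(z, None, "NUDGE", Q=1, seed=4)
    assert fit.params.pi <= 0.05
    assert np.all(np.diff(fit.loglik_path) > -1e-9)


def test_em_enudge_parameter_recovery():
    true = _uniform_params(pi=0.2, means=(-1.0, 1.0), sigmas=(0.5, 0.5))
    z = gen_mixture_sample(true, "eNUDGE", 5000, seed=1)
    fit = fhm.em_fit(z, None, "eNUDGE", Q=2, seed=1)
    assert abs(fit.params.pi - 0.2) < 0.05
    np.testing.assert_allclose(
        np.sort(fit.params.means), [-1.0, 1.0], atol=0.1
    )


def test_em_eps_infinite_stops_after_one_iteration(rng):
    z = rng.normal(0, 1, 200)
    fit = fhm.em_fit(z, None, "eNUDGE", Q=1, eps=np.inf, seed=0)
    assert fit.n_iter == 1
    assert fit.converged


def test_em_gng_monotone(rng):
    z = np.concatenate([rng.normal(0, 1, 800), rng.exponential(2, 100) + 2,
                        -rng.exponential(2, 100) - 2])
    fit = fhm.em_fit(z, None, "GNG", Q=1, seed=2)
    assert np.all(np.diff(fit.loglik_path) > -1e-9)
    assert 0.0 <= fit.params.pi <= 1.0


def test_em_weights_enter_likelihood(rng):
    z = rng.normal(0, 1, 500)
    wei = fhm.observation_weights(rng.normal(-1, 1, 500))
    fit = fhm.em_fit(z, wei, "eNUDGE", Q=1, seed=0)
    assert fit.loglik == pytest.approx(
        fhm.weighted_loglik(z, wei, fit.params, "eNUDGE"), rel=1e-9
    )


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

def test_select_model_single_normal_prefers_q1():
    rng = np.random.default_rng(9)
    z = rng.normal(0, 1, 1500)
    win = fhm.select_model(z, None, Q_max=3, seed=9)
    assert win.params.Q == 1
    assert win.retained_mask is not None and win.fdr is not None


def test_select_model_bic_recovers_three_components():
    hits = 0
    for rep in range(6):
        rng = np.random.default_rng(100 + rep)
        z = np.concatenate([
            rng.normal(-4, 0.8, 500), rng.normal(0, 0.8, 500),
            rng.normal(4, 0.8, 500),
        ])
        best_q, best_bic = None, -np.inf
        for Q in range(1, 5):
            fit = fhm.em_fit(z, None, "eNUDGE", Q=Q, seed=rep,
                             max_iter=300)
            if fit.bic > best_bic:
                best_q, best_bic = Q, fit.bic
        hits += best_q == 3
    assert hits >= 5


# ---------------------------------------------------------------------------
# Differential labelling / FDR / retention
# ---------------------------------------------------------------------------

def _fitted(params, model_class="eNUDGE", n=11):
    return fhm.FittedFHM(
        params=params, model_class=model_class, weights=np.ones(n),
        loglik=0.0, bic=0.0, aic=0.0, n_iter=1, converged=True,
    )


def test_differential_flag_hand_cases():
    z = np.linspace(-1, 1, 11) * 2  # IQR = 2
    iqr = np.subtract(*np.percentile(z, [75, 25]))
    assert iqr == pytest.approx(2.0)
    p = _uniform_params(means=(2.0, 0.0), sigmas=(1.0, 0.1), gammas=(0.5, 0.5))
    flags = fhm.label_differential(_fitted(p), z)
    # |2| + 2*1 = 4 > 3 -> differential; |0| + 0.2 <= 3 -> not
    assert flags.tolist() == [True, False]


def test_differential_degenerate_iqr_zero():
    z = np.zeros(20)
    p = _uniform_params(means=(0.0,), sigmas=(0.5,), gammas=(1.0,),
                        bounds=(-1.0, 1.0))
    assert fhm.label_differential(_fitted(p), z).tolist() == [True]


def test_fdr_all_one_when_nothing_differential():
    z = np.linspace(-10, 10, 21)
    p = _uniform_params(pi=0.0, means=(0.0,), sigmas=(1.0,), gammas=(1.0,))
    f = _fitted(p)
    f.differential_flags = np.array([False])
    np.testing.assert_allclose(fhm.fdr_scores(z, f), 1.0, atol=1e-12)


def test_fdr_zero_when_all_differential():
    z = np.linspace(-2, 2, 9)
    p = _uniform_params(means=(0.0,), sigmas=(1.0,), gammas=(1.0,))
    f = _fitted(p)
    f.differential_flags = np.array([True])
    np.testing.assert_allclose(fhm.fdr_scores(z, f), 0.0)


def test_fdr_hand_mixture():
    # pi=0.5, one non-differential N(0,1), uniform f1 on [-2,2]; z=0
    from scipy import stats
    p = _uniform_params(pi=0.5, means=(0.0,), sigmas=(1.0,), gammas=(1.0,),
                        bounds=(-2.0, 2.0))
    f = _fitted(p)
    f.differential_flags = np.array([False])
    fnorm = 0.5 * stats.norm.pdf(0)
    ftot = 0.5 * stats.norm.pdf(0) + 0.5 * 0.25
    got = fhm.fdr_scores(np.array([0.0]), f)[0]
    assert got == pytest.approx(fnorm / ftot, rel=1e-12)


def test_select_observations_rules():
    fdr = np.array([0.1, 0.1])
    wei = np.array([1.0, 0.25])
    mask = fhm.select_observations(fdr, wei, y0=0.2)
    assert mask.tolist() == [True, False]  # 0.4 > 0.2 for the faint one
    assert fhm.select_observations(fdr, wei, y0=np.inf).all()


def test_select_observations_monotone_in_y0(rng):
    fdr = rng.uniform(0, 2, 100)
    wei = fhm.observation_weights(rng.normal(-1, 1, 100))
    prev = 0
    for y0 in (0.01, 0.05, 0.2, 1.0, 5.0):
        kept = int(fhm.select_observations(fdr, wei, y0).sum())
        assert kept >= prev
        prev = kept
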