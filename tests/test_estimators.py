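"""Unit and property tests for the second-step ATE estimators."""

import numpy as np
import pytest

from naipw import (
    Dataset,
    DegenerateTreatmentError,
    NuisanceEstimates,
    PositivityError,
    WeightName,
    aipw_variance,
    gdr_estimate,
    ipw_estimate,
    naipw_variance,
    naive_ate,
    nipw_estimate,
    sr_estimate,
    weights_aipw,
    weights_naipw,
    weights_trimmed,
)
from conftest import random_problem


# ---------------------------------------------------------------------------
# worked four-unit example (hand-computed expected values)

def test_point_estimators_on_worked_example(d4):
    ds, nu = d4
    assert naive_ate(ds, nu).beta_hat == pytest.approx(1.0)
    assert sr_estimate(ds, nu).beta_hat == pytest.approx(1.0)
    assert ipw_estimate(ds, nu).beta_hat == pytest.approx(-0.1875)
    assert nipw_estimate(ds, nu).beta_hat == pytest.approx(-3 / 13)


def test_weight_schemes_on_worked_example(d4):
    ds, nu = d4
    wa = weights_aipw(nu, ds)
    assert np.allclose(wa.h1, [0.8, 0.5, 0.5, 0.2])
    assert np.allclose(wa.h0, [0.2, 0.5, 0.5, 0.8])
    assert wa.gamma == pytest.approx(0.8125)
    wn = weights_naipw(ds, nu)
    assert wn.gamma == pytest.approx(0.8125)
    assert wn.lam == pytest.approx(0.8125)
    assert np.allclose(wn.h1, [0.65, 0.40625, 0.40625, 0.1625])
    wt = weights_trimmed(ds, nu, eps=0.3)
    assert np.allclose(wt.h1, [0.8, 0.5, 0.5, 0.1625])


def test_gdr_on_worked_example(d4):
    ds, nu = d4
    assert gdr_estimate(ds, nu, weights_aipw(nu, ds)).beta_hat == pytest.approx(0.0)
    assert gdr_estimate(ds, nu, weights_naipw(ds, nu)).beta_hat == pytest.approx(-3 / 13)


def test_variances_on_worked_example(d4):
    ds, nu = d4
    res = aipw_variance(ds, nu, beta_hat=0.0)
    assert res.se_hat**2 == pytest.approx(0.4453125)
    assert np.allclose(res.psi * ds.n, [2.25, -1.0, -1.0, -0.25])
    wn = weights_naipw(ds, nu)
    resn = naipw_variance(ds, nu, wn, beta_hat=-3 / 13)
    assert resn.se_hat**2 == pytest.approx(0.674556, abs=1e-6)
    assert np.allclose(
        resn.psi, [0.692308, -0.307692, -0.307692, -0.076923], atol=1e-6
    )


# ---------------------------------------------------------------------------
# degenerate / invalid inputs

def test_degenerate_treatment_rejected():
    with pytest.raises(DegenerateTreatmentError):
        Dataset(W=np.zeros((3, 1)), A=np.ones(3), Y=np.zeros(3))


def test_exact_zero_or_one_propensity_raises(d4):
    ds, nu = d4
    # bypass the constructor floor to simulate a raw 0/1 propensity
    bad = NuisanceEstimates(nu.q1, nu.q0, nu.g)
    object.__setattr__(bad, "g", np.array([0.8, 0.5, 0.5, 0.0]))
    with pytest.raises(PositivityError, match="unit 3"):
        ipw_estimate(ds, bad)


def test_trimmed_eps_out_of_range(d4):
    ds, nu = d4
    with pytest.raises(ValueError):
        weights_trimmed(ds, nu, eps=0.7)


# ---------------------------------------------------------------------------
# simple algebraic identities

def test_sr_and_naive_zero_when_predictions_equal(d4):
    ds, _ = d4
    nu = NuisanceEstimates(q1=np.full(4, 2.0), q0=np.full(4, 2.0), g=np.full(4, 0.4))
    assert naive_ate(ds, nu).beta_hat == 0.0
    assert sr_estimate(ds, nu).beta_hat == 0.0


def test_nipw_constant_g_equals_arm_mean_difference(d4):
    ds, nu = d4
    nu_c = NuisanceEstimates(nu.q1, nu.q0, np.full(4, 0.3))
    t = ds.A == 1
    expect = ds.Y[t].mean() - ds.Y[~t].mean()
    assert nipw_estimate(ds, nu_c).beta_hat == pytest.approx(expect)


def test_perfect_outcome_fit_reduces_gdr_to_sr():
    rng = np.random.default_rng(0)
    ds, nu = random_problem(rng)
    q1 = np.where(ds.A == 1, ds.Y, rng.normal(size=ds.n))
    q0 = np.where(ds.A == 0, ds.Y, rng.normal(size=ds.n))
    nu_fit = NuisanceEstimates(q1, q0, nu.g)
    sr = sr_estimate(ds, nu_fit).beta_hat
    for ws in (weights_aipw(nu_fit, ds), weights_naipw(ds, nu_fit),
               weights_trimmed(ds, nu_fit, eps=0.2)):
        assert gdr_estimate(ds, nu_fit, ws).beta_hat == pytest.approx(sr)


def test_naipw_equals_nipw_for_constant_outcome_predictions():
    rng = np.random.default_rng(1)
    for _ in range(20):
        ds, nu = random_problem(rng)
        nu_c = NuisanceEstimates(
            np.full(ds.n, 1.7), np.full(ds.n, -0.3), nu.g
        )
        b_naipw = gdr_estimate(ds, nu_c, weights_naipw(ds, nu_c)).beta_hat
        b_nipw = nipw_estimate(ds, nu_c).beta_hat
        assert b_naipw == pytest.approx(b_nipw, abs=1e-12)


# ---------------------------------------------------------------------------
# GDR vs independent literal implementations (dual-route check)

def _aipw_literal(ds, nu):
    # independent transliteration of the AIPW sum, unit by unit
    total = 0.0
    for i in range(ds.n):
        a, y, q1, q0, g = ds.A[i], ds.Y[i], nu.q1[i], nu.q0[i], nu.g[i]
        total += a * (y - q1) / g - (1 - a) * (y - q0) / (1 - g) + (q1 - q0)
    return total / ds.n


def _naipw_literal(ds, nu):
    # ratio (self-normalized) form, unit by unit
    num1 = den1 = num0 = den0 = sr = 0.0
    for i in range(ds.n):
        a, y, q1, q0, g = ds.A[i], ds.Y[i], nu.q1[i], nu.q0[i], nu.g[i]
        num1 += a * (y - q1) / g
        den1 += a / g
        num0 += (1 - a) * (y - q0) / (1 - g)
        den0 += (1 - a) / (1 - g)
        sr += q1 - q0
    return num1 / den1 - num0 / den0 + sr / ds.n


def test_gdr_matches_literal_forms_on_random_instances():
    rng = np.random.default_rng(7)
    for _ in range(1000):
        ds, nu = random_problem(rng, n=int(rng.integers(4, 40)))
        b_aipw = gdr_estimate(ds, nu, weights_aipw(nu, ds)).beta_hat
        assert abs(b_aipw - _aipw_literal(ds, nu)) < 1e-12 * max(1, abs(b_aipw))
        b_naipw = gdr_estimate(ds, nu, weights_naipw(ds, nu)).beta_hat
        assert abs(b_naipw - _naipw_literal(ds, nu)) < 1e-12 * max(1, abs(b_naipw))


# ---------------------------------------------------------------------------
# normalization and boundedness properties

def test_normalized_weights_sum_to_one_and_adjustment_bounded():
    rng = np.random.default_rng(11)
    for _ in range(50):
        ds, nu = random_problem(rng)
        ws = weights_naipw(ds, nu)
        w1n = ds.A / nu.g / np.sum(ds.A / nu.g)
        w0n = (1 - ds.A) / (1 - nu.g) / np.sum((1 - ds.A) / (1 - nu.g))
        assert np.sum(w1n) == pytest.approx(1.0)
        assert np.sum(w0n) == pytest.approx(1.0)
        b = gdr_estimate(ds, nu, ws).beta_hat
        sr = sr_estimate(ds, nu).beta_hat
        bound = np.max(np.abs(ds.Y - nu.q1)) + np.max(np.abs(ds.Y - nu.q0))
        assert abs(b - sr) <= bound + 1e-12


def test_trimmed_weights_branch_selection():
    rng = np.random.default_rng(3)
    ds, nu = random_problem(rng)
    # no propensity extreme enough: trimmed == aipw
    nu_mid = NuisanceEstimates(nu.q1, nu.q0, np.clip(nu.g, 0.3, 0.7))
    wt = weights_trimmed(ds, nu_mid, eps=0.1)
    wa = weights_aipw(nu_mid, ds)
    assert np.allclose(wt.h1, wa.h1) and np.allclose(wt.h0, wa.h0)
    # every propensity below eps: h1 matches the fully normalized scheme
    nu_low = NuisanceEstimates(nu.q1, nu.q0, rng.uniform(0.005, 0.05, ds.n))
    wt_low = weights_trimmed(ds, nu_low, eps=0.1)
    wn_low = weights_naipw(ds, nu_low)
    assert np.allclose(wt_low.h1, wn_low.h1)
    assert wt.name is WeightName.TRIMMED


def test_trimmed_default_eps_is_inverse_sqrt_n():
    rng = np.random.default_rng(5)
    ds, nu = random_problem(rng, n=64)
    # with default eps = 1/8, units with g < 1/8 get normalized
    wt = weights_trimmed(ds, nu)
    wn = weights_naipw(ds, nu)
    low = nu.g < 0.125
    assert np.allclose(wt.h1[low], wn.h1[low])
    assert np.allclose(wt.h1[~low], nu.g[~low])


# ---------------------------------------------------------------------------
# influence-function variances

def test_influence_contributions_center_and_match_se():
    rng = np.random.default_rng(13)
    for _ in range(50):
        ds, nu = random_problem(rng)
        ws = weights_naipw(ds, nu)
        beta = gdr_estimate(ds, nu, ws).beta_hat
        res = naipw_variance(ds, nu, ws, beta)
        assert abs(res.psi.sum()) < 1e-10 * ds.n
        assert res.se_hat**2 == pytest.approx(np.sum(res.psi**2))
        beta_a = gdr_estimate(ds, nu, weights_aipw(nu, ds)).beta_hat
        res_a = aipw_variance(ds, nu, beta_a)
        assert abs(res_a.psi.sum()) < 1e-10 * ds.n


def test_variance_zero_under_degenerate_influence():
    # perfect outcome fit and constant treatment-effect prediction
    rng = np.random.default_rng(17)
    ds, nu = random_problem(rng)
    # q1 = Y + c(1-A), q0 = Y - cA: zero residuals on both arms, q1-q0 = c
    c = 1.5
    q1 = ds.Y + c * (1 - ds.A)
    q0 = ds.Y - c * ds.A
    nu_fit = NuisanceEstimates(q1, q0, nu.g)
    assert np.allclose(np.where(ds.A == 1, ds.Y - nu_fit.q1, 0), 0)
    assert np.allclose(np.where(ds.A == 0, ds.Y - nu_fit.q0, 0), 0)
    beta = gdr_estimate(ds, nu_fit, weights_aipw(nu_fit, ds)).beta_hat
    assert aipw_variance(ds, nu_fit, beta).se_hat == pytest.approx(0.0, abs=1e-12)
    ws = weights_naipw(ds, nu_fit)
    beta_n = gdr_estimate(ds, nu_fit, ws).beta_hat
    assert naipw_variance(ds, nu_fit, ws, beta_n).se_hat == pytest.approx(0.0, abs=1e-12)


def test_aipw_variance_scales_quadratically():
    rng = np.random.default_rng(19)
    ds, nu = random_problem(rng)
    beta = gdr_estimate(ds, nu, weights_aipw(nu, ds)).beta_hat
    v1 = aipw_variance(ds, nu, beta).se_hat ** 2
    k = 3.0
    ds_k = Dataset(ds.W, ds.A, k * ds.Y)
    nu_k = NuisanceEstimates(k * nu.q1, k * nu.q0, nu.g)
    v_k = aipw_variance(ds_k, nu_k, k * beta).se_hat ** 2
    assert v_k == pytest.approx(k**2 * v1)


def test_literal_variance_form_differs_but_close(d4):
    ds, nu = d4
    # with q1-q0 constant the two forms coincide
    eif = aipw_variance(ds, nu, 0.0, variance_form="eif").se_hat
    lit = aipw_variance(ds, nu, 0.0, variance_form="literal").se_hat
    assert eif == pytest.approx(lit)
    rng = np.random.default_rng(23)
    ds2, nu2 = random_problem(rng)
    beta = gdr_estimate(ds2, nu2, weights_aipw(nu2, ds2)).beta_hat
    eif2 = aipw_variance(ds2, nu2, beta, variance_form="eif").se_hat
    lit2 = aipw_variance(ds2, nu2, beta, variance_form="literal").se_hat
    assert eif2 != lit2


# ---------------------------------------------------------------------------
# unbiasedness of the weighting denominators at the true propensity

def test_weight_denominator_unbiasedness_at_true_propensity():
    """E[A - h1] = 0 and E[(1-A) - h0] = 0 when g is the truth."""
    rng = np.random.default_rng(29)
    m, n = 400, 200
    d_a1 = np.empty(m)
    d_a0 = np.empty(m)
    d_n1 = np.empty(m)
    d_n0 = np.empty(m)
    for j in range(m):
        g_true = rng.uniform(0.15, 0.85, n)
        A = (rng.uniform(size=n) < g_true).astype(float)
        if A.sum() in (0, n):
            continue
        ds = Dataset(np.zeros((n, 1)), A, rng.normal(size=n))
        nu = NuisanceEstimates(np.zeros(n), np.zeros(n), g_true)
        wa = weights_aipw(nu, ds)
        wn = weights_naipw(ds, nu)
        d_a1[j] = np.mean(A - wa.h1)
        d_a0[j] = np.mean((1 - A) - wa.h0)
        d_n1[j] = np.mean(A - wn.h1)
        d_n0[j] = np.mean((1 - A) - wn.h0)
    for d in (d_a1, d_a0, d_n1, d_n0):
        mcse = d.std() / np.sqrt(m)
        assert abs(d.mean()) < 3 * mcse + 1e-12


def test_weight_variance_law_for_constant_propensity():
    """Var(A/g) -> 1/g - 1; the normalized version is never larger."""
    rng = np.random.default_rng(31)
    n = 200_000
    for g in (0.2, 0.5, 0.8):
        A = (rng.uniform(size=n) < g).astype(float)
        w = A / g
        assert np.var(w) == pytest.approx(1 / g - 1, rel=0.02)
        # E[A/g] = 1 at the truth, so the normalized-weight variance matches
        # the closed form (1/g - 1)/E^2[A/g]
        assert np.mean(w) == pytest.approx(1.0, abs=0.01)
        w_norm = w / np.mean(w)
        assert np.var(w_norm) == pytest.approx((1 / g - 1) / np.mean(w) ** 2, rel=0.02)
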