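"""Second-step ATE estimators: naive, SR, IPW, nIPW and the GDR family.

The target is the average treatment effect β = E[Y¹ − Y⁰].  All estimators
here consume a :class:`~naipw.datatypes.Dataset` and first-step nuisance
predictions (Q̂(1,W), Q̂(0,W), ĝ(W)) and differ only in how they combine
them:

* the *naive* contrast averages Q̂ within each observed arm,
* *SR* (single robust) is the plug-in mean of Q̂(1,W) − Q̂(0,W),
* *IPW* and its Hájek normalization *nIPW* weight outcomes by inverse
  (estimated) treatment probabilities,
* the *general doubly robust* (GDR) estimator adds a weighted residual
  correction to SR,

      β̂_GDR = (1/n) Σ_i [ A_i(y_i−Q̂¹_i)/h¹_i − (1−A_i)(y_i−Q̂⁰_i)/h⁰_i ] + β̂_SR,

  indexed by per-unit denominators (h¹, h⁰).  Choosing h¹=ĝ, h⁰=1−ĝ gives
  AIPW; choosing the self-normalized h¹=ĝ·Ê[A/ĝ], h⁰=(1−ĝ)·Ê[(1−A)/(1−ĝ)]
  gives nAIPW, whose correction terms are convex combinations of residuals
  and therefore bounded — the property that tames empirical positivity
  violations (propensity estimates numerically near 0 or 1).

Asymptotic variances come from the influence-function representation; see
:func:`aipw_variance` and :func:`naipw_variance`.
"""

from __future__ import annotations

from typing import Literal

import numpy as np

from .datatypes import (
    Dataset,
    EstimateResult,
    NuisanceEstimates,
    PositivityError,
    WeightName,
    WeightScheme,
)

__all__ = [
    "naive_ate",
    "sr_estimate",
    "ipw_estimate",
    "nipw_estimate",
    "weights_aipw",
    "weights_naipw",
    "weights_trimmed",
    "gdr_estimate",
    "aipw_estimate",
    "naipw_estimate",
    "aipw_variance",
    "naipw_variance",
]


def _check_shapes(ds: Dataset, nu: NuisanceEstimates) -> None:
    if ds.n != nu.n:
        raise ValueError(f"dataset has n={ds.n} but nuisance estimates have n={nu.n}")


def _check_positivity(g: np.ndarray) -> None:
    bad = np.flatnonzero((g <= 0.0) | (g >= 1.0))
    if bad.size:
        raise PositivityError(f"positivity violated at unit {bad[0]}: g={g[bad[0]]}")


def naive_ate(ds: Dataset, nu: NuisanceEstimates) -> EstimateResult:
    """Mean of Q̂¹ over the treated minus mean of Q̂⁰ over the controls.

    Biased under confounding (selection bias); included as the baseline
    contrast.  No standard error is attached.
    """
    _check_shapes(ds, nu)
    t = ds.A == 1
    beta = float(nu.q1[t].mean() - nu.q0[~t].mean())
    return EstimateResult("naive", beta, ds.n)


def sr_estimate(ds: Dataset, nu: NuisanceEstimates) -> EstimateResult:
    """Single robust (outcome regression plug-in): (1/n) Σ (Q̂¹_i − Q̂⁰_i)."""
    _check_shapes(ds, nu)
    return EstimateResult("sr", float(np.mean(nu.q1 - nu.q0)), ds.n)


def ipw_estimate(ds: Dataset, nu: NuisanceEstimates) -> EstimateResult:
    """Horvitz–Thompson inverse probability weighting.

    β̂ = (1/n) Σ [ A_i y_i/ĝ_i − (1−A_i) y_i/(1−ĝ_i) ].  Raises
    :class:`PositivityError` if any ĝ_i is exactly 0 or 1 — never clips
    silently.
    """
    _check_shapes(ds, nu)
    _check_positivity(nu.g)
    A, Y, g = ds.A, ds.Y, nu.g
    beta = float(np.mean(A * Y / g - (1 - A) * Y / (1 - g)))
    return EstimateResult("ipw", beta, ds.n)


def nipw_estimate(ds: Dataset, nu: NuisanceEstimates) -> EstimateResult:
    """Hájek-normalized IPW: weights renormalized to sum to 1 within arms.

    Not unbiased even at the true propensity, but far less sensitive to
    extreme ĝ than plain IPW.
    """
    _check_shapes(ds, nu)
    _check_positivity(nu.g)
    A, Y, g = ds.A, ds.Y, nu.g
    w1 = A / g
    w0 = (1 - A) / (1 - g)
    beta = float(np.sum(w1 * Y) / np.sum(w1) - np.sum(w0 * Y) / np.sum(w0))
    return EstimateResult("nipw", beta, ds.n)


def _norm_constants(A: np.ndarray, g: np.ndarray) -> tuple:
    gamma = float(np.mean(A / g))
    lam = float(np.mean((1 - A) / (1 - g)))
    return gamma, lam


def weights_aipw(nu: NuisanceEstimates, ds: Dataset | None = None) -> WeightScheme:
    """Plain inverse-propensity denominators h¹ = ĝ, h⁰ = 1 − ĝ.

    The normalization constants γ, λ are computed and recorded (they are
    needed by diagnostics) but do not enter h.  When ``ds`` is omitted the
    constants are recorded as NaN.
    """
    g = nu.g
    if ds is not None:
        gamma, lam = _norm_constants(ds.A, g)
    else:
        gamma, lam = float("nan"), float("nan")
    return WeightScheme(WeightName.AIPW, g.copy(), 1.0 - g, gamma, lam)


def weights_naipw(ds: Dataset, nu: NuisanceEstimates) -> WeightScheme:
    """Self-normalized (Hájek) denominators.

    γ = (1/n) Σ A_i/ĝ_i, λ = (1/n) Σ (1−A_i)/(1−ĝ_i); h¹ = ĝ·γ,
    h⁰ = (1−ĝ)·λ.  At the true propensity E[A/g] = 1, so γ, λ → 1 and
    the scheme collapses to AIPW asymptotically.
    """
    _check_shapes(ds, nu)
    gamma, lam = _norm_constants(ds.A, nu.g)
    if gamma <= 0.0 or lam <= 0.0:
        raise RuntimeError("internal error: non-positive normalization constant")
    return WeightScheme(WeightName.NAIPW, nu.g * gamma, (1.0 - nu.g) * lam, gamma, lam)


def weights_trimmed(
    ds: Dataset, nu: NuisanceEstimates, eps: float | None = None
) -> WeightScheme:
    """Hybrid scheme: normalize only where the propensity is extreme.

    h¹_i = ĝ_i·γ when ĝ_i < eps, else ĝ_i; h⁰_i = (1−ĝ_i)·λ when
    ĝ_i > 1−eps, else 1−ĝ_i.  Default threshold eps = n^{-1/2}.  Ties at
    ĝ = eps take the untrimmed branch (strict inequality triggers
    normalization).
    """
    _check_shapes(ds, nu)
    if eps is None:
        eps = ds.n ** -0.5
    if not (0.0 < eps < 0.5):
        raise ValueError(f"trimming threshold eps must lie in (0, 0.5); got {eps}")
    gamma, lam = _norm_constants(ds.A, nu.g)
    g = nu.g
    h1 = np.where(g < eps, g * gamma, g)
    h0 = np.where(g > 1.0 - eps, (1.0 - g) * lam, 1.0 - g)
    return WeightScheme(WeightName.TRIMMED, h1, h0, gamma, lam)


def gdr_estimate(ds: Dataset, nu: NuisanceEstimates, ws: WeightScheme) -> EstimateResult:
    """General doubly robust estimator for an arbitrary weight scheme.

    β̂ = (1/n) Σ [ A_i(y_i−Q̂¹_i)/h¹_i − (1−A_i)(y_i−Q̂⁰_i)/h⁰_i ] + β̂_SR.

    With AIPW weights this is the classical AIPW estimator; with nAIPW
    weights the identity ĝ_i·γ = ĝ_i·(1/n)Σ_j A_j/ĝ_j makes it equal the
    ratio (self-normalized) form exactly.
    """
    _check_shapes(ds, nu)
    if ds.n != len(ws.h1):
        raise ValueError("weight scheme length mismatch")
    A, Y = ds.A, ds.Y
    adj = np.mean(A * (Y - nu.q1) / ws.h1 - (1 - A) * (Y - nu.q0) / ws.h0)
    beta = float(adj + np.mean(nu.q1 - nu.q0))
    name = {"aipw": "aipw", "naipw": "naipw", "trimmed": "gdr_trimmed"}[ws.name.value]
    return EstimateResult(name, beta, ds.n)


def aipw_estimate(ds: Dataset, nu: NuisanceEstimates, se: bool = True) -> EstimateResult:
    """AIPW point estimate, with influence-function SE by default."""
    res = gdr_estimate(ds, nu, weights_aipw(nu, ds))
    if not se:
        return res
    return aipw_variance(ds, nu, res.beta_hat)


def naipw_estimate(ds: Dataset, nu: NuisanceEstimates, se: bool = True) -> EstimateResult:
    """nAIPW point estimate, with influence-function SE by default."""
    ws = weights_naipw(ds, nu)
    res = gdr_estimate(ds, nu, ws)
    if not se:
        return res
    return naipw_variance(ds, nu, ws, res.beta_hat)


VarianceForm = Literal["eif", "literal"]


def aipw_variance(
    ds: Dataset,
    nu: NuisanceEstimates,
    beta_hat: float,
    variance_form: VarianceForm = "eif",
) -> EstimateResult:
    """Influence-function variance of the AIPW estimator.

    σ̂² = (1/n²) Σ ψ̃_i² with

        ψ̃_i = A_i(y_i−Q̂¹_i)/ĝ_i − (1−A_i)(y_i−Q̂⁰_i)/(1−ĝ_i)
              + (Q̂¹_i − Q̂⁰_i) − β̂.

    ``variance_form="eif"`` (default) uses the per-unit term Q̂¹_i − Q̂⁰_i as
    dictated by the efficient influence function; ``"literal"`` replaces it
    with the scalar average β̂_SR, an algebraically distinct variant kept for
    comparison.  Returns ``psi = ψ̃/n`` so that se² = Σ psi².
    """
    _check_shapes(ds, nu)
    A, Y, g = ds.A, ds.Y, nu.g
    resid = A * (Y - nu.q1) / g - (1 - A) * (Y - nu.q0) / (1 - g)
    if variance_form == "eif":
        center = nu.q1 - nu.q0
    elif variance_form == "literal":
        center = np.full(ds.n, np.mean(nu.q1 - nu.q0))
    else:
        raise ValueError(f"unknown variance_form {variance_form!r}")
    psi_tilde = resid + center - beta_hat
    psi = psi_tilde / ds.n
    se = float(np.sqrt(np.sum(psi**2)))
    return EstimateResult("aipw", float(beta_hat), ds.n, se_hat=se, psi=psi)


def naipw_variance(
    ds: Dataset,
    nu: NuisanceEstimates,
    ws: WeightScheme,
    beta_hat: float,
    variance_form: VarianceForm = "eif",
) -> EstimateResult:
    """Influence-function variance of the nAIPW estimator.

    σ̂² = Σ ψ_i² with

        ψ_i = A_i(y_i−Q̂¹_i)w_i(1)/Σ_j A_j w_j(1)
             − (1−A_i)(y_i−Q̂⁰_i)w_i(0)/Σ_j (1−A_j) w_j(0)
             + (Q̂¹_i − Q̂⁰_i − β̂)/n,

    w(1) = 1/ĝ, w(0) = 1/(1−ĝ).  The ψ_i sum to zero by construction: the
    two ratio terms total β̂ − β̂_SR while the centering terms total
    (β̂_SR − β̂).  Form ``"literal"`` uses β̂_SR in place of the per-unit
    Q̂¹_i − Q̂⁰_i.
    """
    _check_shapes(ds, nu)
    if ws.name is not WeightName.NAIPW:
        raise ValueError("naipw_variance requires nAIPW weights")
    A, Y, g = ds.A, ds.Y, nu.g
    w1 = A / g
    w0 = (1 - A) / (1 - g)
    term1 = A * (Y - nu.q1) * (1 / g) / np.sum(w1)
    term0 = (1 - A) * (Y - nu.q0) * (1 / (1 - g)) / np.sum(w0)
    if variance_form == "eif":
        center = nu.q1 - nu.q0
    elif variance_form == "literal":
        center = np.full(ds.n, np.mean(nu.q1 - nu.q0))
    else:
        raise ValueError(f"unknown variance_form {variance_form!r}")
    psi = term1 - term0 + (center - beta_hat) / ds.n
    se = float(np.sqrt(np.sum(psi**2)))
    return EstimateResult("naipw", float(beta_hat), ds.n, se_hat=se, psi=psi)
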