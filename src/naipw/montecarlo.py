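"""Monte Carlo benchmarking of the ATE estimators, plus diagnostics.

Covers four related studies:

* :func:`run_mc` — repeated-sampling comparison of the estimators on the
  synthetic design, summarized by bias, MC standard deviation, RMSE and the
  mean asymptotic SE:

      bias  δ̂ = β − (1/m) Σ_j β̂_j
      MCstd σ̂_MC = sqrt( (1/m) Σ_j (β̂_j − μ̂)² )      (1/m convention)
      RMSE       = sqrt( σ̂²_MC + δ̂² )

* :func:`positivity_stress` — the empirical positivity scenario: one
  treated unit's propensity is overwritten with 10^{-s}; AIPW acquires an
  unbounded additive term (1/n)·10^s·(Y_k − Q̂¹_k) while nAIPW converges to
  a finite limit Y_k − Q̂¹_k + mean(Q̂¹) for its treated component.

* :func:`orthogonality_check` — finite-difference Gateaux derivative of the
  empirical nAIPW estimating function along a nuisance perturbation; near
  zero at the true nuisance (Neyman orthogonality).

* :func:`remainder_probe` — sample analogue of the Hölder bound on the
  second-order remainder (the product of root-mean-square nuisance errors),
  used to inspect rate double robustness empirically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np

from .datatypes import Dataset, EstimateResult, NuisanceEstimates
from .estimators import (
    aipw_estimate,
    gdr_estimate,
    ipw_estimate,
    naipw_estimate,
    naive_ate,
    nipw_estimate,
    sr_estimate,
    weights_aipw,
    weights_naipw,
    weights_trimmed,
)
from .nn import NNConfig, crossfit_nuisance, fit_nuisance
from .simulate import DGPConfig, DGPSpec, build_dgp, generate_dataset, true_nuisance

logger = logging.getLogger(__name__)

ESTIMATOR_NAMES = ("naive", "sr", "ipw", "nipw", "aipw", "naipw", "gdr_trimmed")

# Reported summaries cap extreme replicate estimates at this magnitude; raw
# estimates are always retained uncapped.
ESTIMATE_CAP = 10.0


def _estimate_one(name: str, ds: Dataset, nu: NuisanceEstimates) -> EstimateResult:
    if name == "naive":
        return naive_ate(ds, nu)
    if name == "sr":
        return sr_estimate(ds, nu)
    if name == "ipw":
        return ipw_estimate(ds, nu)
    if name == "nipw":
        return nipw_estimate(ds, nu)
    if name == "aipw":
        return aipw_estimate(ds, nu)
    if name == "naipw":
        return naipw_estimate(ds, nu)
    if name == "gdr_trimmed":
        return gdr_estimate(ds, nu, weights_trimmed(ds, nu))
    raise ValueError(f"unknown estimator {name!r}")


def estimate_all(
    ds: Dataset, nu: NuisanceEstimates, estimators: Sequence[str]
) -> List[EstimateResult]:
    """Compute the requested estimators on one dataset."""
    return [_estimate_one(name, ds, nu) for name in estimators]


@dataclass(frozen=True)
class MetricsRow:
    """Replicated-sampling summary for one estimator in one scenario."""

    estimator: str
    bias: float
    mc_std: float
    rmse: float
    mean_se: float
    m: int
    n: int
    p: int
    capped_mean: float = float("nan")
    n_failures: int = 0
    scenario: Dict = field(default_factory=dict)


def compute_metrics(
    estimates: Sequence[float],
    ses: Optional[Sequence[float]],
    beta_true: float,
    estimator: str = "",
    n: int = 0,
    p: int = 0,
    n_failures: int = 0,
    **scenario,
) -> MetricsRow:
    """Bias / MC std / RMSE with the 1/m variance convention.

    ``bias = beta_true − mean(estimates)`` (note the sign: positive bias
    means underestimation).  ``rmse² = bias² + mc_std²`` by construction.
    """
    est = np.asarray(estimates, dtype=float)
    if est.ndim != 1 or len(est) < 2:
        raise ValueError("need at least two replicate estimates")
    if ses is not None:
        ses_arr = np.asarray(ses, dtype=float)
        if len(ses_arr) != len(est):
            raise ValueError("estimates and ses length mismatch")
        mean_se = float(np.mean(ses_arr))
    else:
        mean_se = float("nan")
    m = len(est)
    mu = est.mean()
    bias = float(beta_true - mu)
    mc_std = float(np.sqrt(np.mean((est - mu) ** 2)))
    rmse = float(np.sqrt(mc_std**2 + bias**2))
    capped = float(np.mean(np.clip(est, -ESTIMATE_CAP, ESTIMATE_CAP)))
    return MetricsRow(
        estimator=estimator, bias=bias, mc_std=mc_std, rmse=rmse,
        mean_se=mean_se, m=m, n=n, p=p, capped_mean=capped,
        n_failures=n_failures, scenario=dict(scenario),
    )


def run_mc(
    dgp_cfg: DGPConfig,
    nn_cfg: Optional[NNConfig] = None,
    estimators: Sequence[str] = ("aipw", "naipw"),
    m: int = 100,
    seed: int = 0,
    nuisance_mode: str = "oracle",
    folds: int = 5,
) -> List[MetricsRow]:
    """Repeated-sampling study on one frozen synthetic world.

    The structural plans are realized once from ``dgp_cfg``; replicate j
    redraws the data with seed ``seed + j`` and obtains nuisance estimates
    per ``nuisance_mode`` ("oracle" plugs in the true surfaces, "nn" fits
    the two networks in-sample, "crossfit-nn" fits them out-of-fold).
    Replicates that fail (degenerate arm, non-finite loss) are logged and
    excluded; more than 20% failures aborts the study.
    """
    if m < 2:
        raise ValueError("need m >= 2 replicates")
    if nuisance_mode not in ("oracle", "nn", "crossfit-nn"):
        raise ValueError(f"unknown nuisance_mode {nuisance_mode!r}")
    if nuisance_mode != "oracle" and nn_cfg is None:
        raise ValueError("nn_cfg required for NN nuisance modes")
    spec = build_dgp(dgp_cfg)
    betas: Dict[str, List[float]] = {name: [] for name in estimators}
    ses: Dict[str, List[float]] = {name: [] for name in estimators}
    failures = 0
    for j in range(m):
        rep_seed = seed + j
        try:
            ds = generate_dataset(spec, seed=rep_seed)
            if nuisance_mode == "oracle":
                nu = true_nuisance(spec, ds)
            elif nuisance_mode == "nn":
                rep_cfg = _reseed(nn_cfg, rep_seed)
                nu = fit_nuisance(ds, rep_cfg)
            else:
                rep_cfg = _reseed(nn_cfg, rep_seed)
                nu = crossfit_nuisance(ds, rep_cfg, folds=folds, seed=rep_seed)
            for res in estimate_all(ds, nu, estimators):
                betas[res.estimator].append(res.beta_hat)
                ses[res.estimator].append(res.se_hat if res.se_hat is not None else np.nan)
        except (ValueError, RuntimeError, FloatingPointError) as exc:
            failures += 1
            logger.warning("replicate %d failed: %s", j, exc)
            if failures > 0.2 * m:
                raise RuntimeError(f"more than 20% of replicates failed ({failures}/{m})")
    rows = []
    for name in estimators:
        se_list = ses[name]
        has_se = not np.isnan(se_list).all() if se_list else False
        rows.append(
            compute_metrics(
                betas[name],
                se_list if has_se else None,
                spec.true_ate,
                estimator=name,
                n=dgp_cfg.n,
                p=dgp_cfg.p,
                nuisance_mode=nuisance_mode,
                l1_strength=(nn_cfg.l1_strength if nn_cfg else None),
                n_failures=failures,
            )
        )
    return rows


def _reseed(cfg: NNConfig, seed: int) -> NNConfig:
    return NNConfig(
        hidden_widths=cfg.hidden_widths,
        l1_strength=cfg.l1_strength,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate,
        momentum_beta1=cfg.momentum_beta1,
        adam_beta2=cfg.adam_beta2,
        seed=int(seed) % (2**31 - 1),
        a_in_features=cfg.a_in_features,
    )


@dataclass(frozen=True)
class StressReport:
    """Trajectories of AIPW and nAIPW as one propensity is driven to 0."""

    s_grid: np.ndarray
    unit: int
    aipw_estimates: np.ndarray
    naipw_estimates: np.ndarray
    naipw_treated: np.ndarray       # treated component β̂₁ per s
    naipw_limit: float              # analytic large-s limit of β̂₁
    remainder_proxy: Dict[str, np.ndarray]


def positivity_stress(
    ds: Dataset,
    nu: NuisanceEstimates,
    s_grid: Sequence[int],
    unit: Optional[int] = None,
) -> StressReport:
    """Inject an extreme propensity 10^{-s} at one treated unit.

    For each exponent s the chosen treated unit's ĝ is overwritten and both
    AIPW and nAIPW recomputed.  The report carries the analytic nAIPW
    treated-component limit  Y_k − Q̂¹_k + mean(Q̂¹)  for comparison, and a
    remainder proxy |mean(g_orig/h1 − 1)··rms(residual)| per scheme.
    """
    s_grid = np.asarray(list(s_grid), dtype=int)
    if (s_grid < 1).any():
        raise ValueError("stress exponents must be >= 1")
    treated = np.flatnonzero(ds.A == 1)
    if unit is None:
        unit = int(treated[0])
    elif ds.A[unit] != 1:
        raise ValueError(f"unit {unit} is not treated")
    aipw_traj = np.empty(len(s_grid))
    naipw_traj = np.empty(len(s_grid))
    naipw_b1 = np.empty(len(s_grid))
    rem_aipw = np.empty(len(s_grid))
    rem_naipw = np.empty(len(s_grid))
    g_orig = nu.g.copy()
    resid1 = ds.A * (ds.Y - nu.q1)
    for idx, s in enumerate(s_grid):
        g_mod = g_orig.copy()
        g_mod[unit] = 10.0 ** (-int(s))
        nu_mod = nu.replace_g(g_mod)
        aipw_traj[idx] = aipw_estimate(ds, nu_mod, se=False).beta_hat
        ws = weights_naipw(ds, nu_mod)
        naipw_traj[idx] = gdr_estimate(ds, nu_mod, ws).beta_hat
        # treated component of the nAIPW decomposition
        w1 = ds.A / g_mod
        naipw_b1[idx] = float(np.sum(resid1 / g_mod) / np.sum(w1) + np.mean(nu.q1))
        rem_aipw[idx] = abs(float(np.mean(g_orig / g_mod - 1.0)))
        rem_naipw[idx] = abs(float(np.mean(g_orig / ws.h1 - 1.0)))
    limit = float(ds.Y[unit] - nu.q1[unit] + np.mean(nu.q1))
    return StressReport(
        s_grid=s_grid,
        unit=unit,
        aipw_estimates=aipw_traj,
        naipw_estimates=naipw_traj,
        naipw_treated=naipw_b1,
        naipw_limit=limit,
        remainder_proxy={"aipw": rem_aipw, "naipw": rem_naipw},
    )


def _naipw_score_mean(ds: Dataset, q1, q0, g) -> float:
    """Empirical nAIPW estimating function (β term omitted — constant)."""
    A, Y = ds.A, ds.Y
    gamma = np.mean(A / g)
    lam = np.mean((1 - A) / (1 - g))
    return float(
        np.mean(
            q1 + A * (Y - q1) / (g * gamma) - q0 - (1 - A) * (Y - q0) / ((1 - g) * lam)
        )
    )


def orthogonality_check(
    ds: Dataset,
    nu: NuisanceEstimates,
    direction: NuisanceEstimates,
    h: float = 1e-3,
) -> float:
    """Central-difference Gateaux derivative of the estimating function.

    Evaluates the empirical nAIPW score at η + ε·(η̃ − η) for ε = ±h along
    the perturbation ``direction`` (interpreted as η̃) and returns the slope
    at ε = 0.  At the true nuisance the population derivative is zero
    (Neyman orthogonality), so the empirical slope shrinks as O(n^{-1/2}).
    A direction that would push g outside (0,1) is rescaled with a warning.
    """
    dq1 = direction.q1 - nu.q1
    dq0 = direction.q0 - nu.q0
    dg = (direction.g - nu.g).copy()
    if np.allclose(dq1, 0) and np.allclose(dq0, 0) and np.allclose(dg, 0):
        return 0.0
    margin = np.minimum(nu.g, 1.0 - nu.g)
    # propensities pinned at the numerical floor admit no meaningful
    # perturbation; drop the direction there rather than crushing it globally
    pinned = margin <= 1e-9
    if pinned.any() and (dg[pinned] != 0).any():
        logger.warning("zeroing g-perturbation at %d floored units", int(pinned.sum()))
        dg[pinned] = 0.0
    move = h * np.abs(dg)
    viol = move >= margin
    if viol.any():
        scale = float(np.min(0.5 * margin[viol] / move[viol]))
        logger.warning("perturbation rescaled by %.3g to keep g inside (0,1)", scale)
        dq1, dq0, dg = scale * dq1, scale * dq0, scale * dg
    f_plus = _naipw_score_mean(ds, nu.q1 + h * dq1, nu.q0 + h * dq0, nu.g + h * dg)
    f_minus = _naipw_score_mean(ds, nu.q1 - h * dq1, nu.q0 - h * dq0, nu.g - h * dg)
    return (f_plus - f_minus) / (2.0 * h)


def remainder_probe(
    spec: DGPSpec,
    n_grid: Sequence[int],
    m: int = 5,
    seed: int = 0,
    nn_cfg: Optional[NNConfig] = None,
    nuisance_fn: Optional[Callable[[Dataset], NuisanceEstimates]] = None,
) -> List[Dict]:
    """Empirical Hölder bound on the second-order remainder, per sample size.

    For each n the probe draws ``m`` datasets, obtains nuisance estimates
    (the two networks by default, or ``nuisance_fn``), and evaluates

        rms(g/ĝ − 1)·rms(Q¹ − Q̂¹) + rms((1−g)/(1−ĝ) − 1)·rms(Q⁰ − Q̂⁰)

    against the true surfaces.  Purely diagnostic: a shrinking product is
    the empirical signature of rate double robustness.
    """
    n_grid = list(n_grid)
    if any(b > a for a, b in zip(n_grid[1:], n_grid[:-1])):
        raise ValueError("n_grid must be non-decreasing")
    rows = []
    for n in n_grid:
        cfg = DGPConfig(
            n=int(n),
            block_size=spec.config.block_size,
            rho=spec.config.rho,
            coef_conf=spec.config.coef_conf,
            coef_iv=spec.config.coef_iv,
            coef_conf_y=spec.config.coef_conf_y,
            coef_y=spec.config.coef_y,
            noise_sd=spec.config.noise_sd,
            select_frac=spec.config.select_frac,
            step_variant=spec.config.step_variant,
            seed=spec.config.seed,
        )
        spec_n = DGPSpec(
            config=cfg, fa_plan=spec.fa_plan, ga_plan=spec.ga_plan,
            fy_plan=spec.fy_plan, gy_plan=spec.gy_plan,
            coef_fa=spec.coef_fa, coef_ga=spec.coef_ga,
            coef_fy=spec.coef_fy, coef_gy=spec.coef_gy,
            true_ate=spec.true_ate, intercept_y=spec.intercept_y,
        )
        vals = []
        for j in range(m):
            ds = generate_dataset(spec_n, seed=seed + 1000 * j + n)
            truth = true_nuisance(spec_n, ds)
            if nuisance_fn is not None:
                nu = nuisance_fn(ds)
            elif nn_cfg is not None:
                nu = fit_nuisance(ds, _reseed(nn_cfg, seed + j))
            else:
                nu = truth
            err_g1 = np.sqrt(np.mean((truth.g / nu.g - 1.0) ** 2))
            err_g0 = np.sqrt(np.mean(((1 - truth.g) / (1 - nu.g) - 1.0) ** 2))
            err_q1 = np.sqrt(np.mean((truth.q1 - nu.q1) ** 2))
            err_q0 = np.sqrt(np.mean((truth.q0 - nu.q0) ** 2))
            vals.append(err_g1 * err_q1 + err_g0 * err_q0)
        rows.append({
            "n": int(n),
            "remainder_mean": float(np.mean(vals)),
            "remainder_sd": float(np.std(vals)),
            "m": m,
        })
    return rows
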