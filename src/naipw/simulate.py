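"""Synthetic observational-data generator for benchmarking ATE estimators.

The design draws four independent covariate blocks — confounders X_c,
instrumental variables X_iv, outcome predictors X_y and irrelevant noise
X_irr — each multivariate normal with AR(1) correlation Σ_{kj} = ρ^{|j−k|}
(ρ = 0.5 by default).  Treatment is logistic,

    A ~ Bernoulli( expit(η) ),   η = f_a(X_c)·γ_c + g_a(X_iv)·γ_iv,

and the outcome is linear in treatment with additive nonlinear structure,

    Y = 3 + A + f_y(X_c)·γ'_c + g_y(X_y)·γ_y + ε,   ε ~ N(0, σ²),

so the true ATE is exactly 1 for every configuration.  The structural
functions f_a, g_a, f_y, g_y each select 20% of their block's columns,
pair them, and apply a randomly chosen nonlinear/interaction transform from
a fixed menu of five (exponential interaction, logistic ratio, scaled
product, scaled sum, and a product of step functions).  Instrumental
variables drive treatment only; strong IV coefficients push propensities
toward 0/1, producing the empirical positivity violations the weighting
estimators must cope with.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List, Tuple

import numpy as np
from scipy.special import expit

from .datatypes import Dataset, NuisanceEstimates

FUNCTION_IDS = ("l1", "l2", "l3", "l4", "l5")

# Overflow guard for the exponential interaction; affects a negligible
# fraction of draws at the default correlation.
_EXP_CLIP = 10.0


def step_g(x: np.ndarray) -> np.ndarray:
    """Four-level step: −2 on (−∞,−1], −1 on (−1,0], 1 on (0,2), 3 on [2,∞)."""
    x = np.asarray(x, dtype=float)
    return np.select(
        [x <= -1, x <= 0, x < 2], [-2.0, -1.0, 1.0], default=3.0
    )


def step_h(x: np.ndarray) -> np.ndarray:
    """Three-level step: −5 on (−∞,0], −2 on (0,1), 3 on [1,∞)."""
    x = np.asarray(x, dtype=float)
    return np.select([x <= 0, x < 1], [-5.0, -2.0], default=3.0)


def indicator_g(x: np.ndarray) -> np.ndarray:
    return (np.asarray(x, dtype=float) >= 0).astype(float)


def indicator_h(x: np.ndarray) -> np.ndarray:
    return (np.asarray(x, dtype=float) >= 1).astype(float)


def nonlinear_apply(
    function_id: str,
    x1: np.ndarray,
    x2: np.ndarray,
    step_variant: str = "step",
) -> np.ndarray:
    """Evaluate one of the five pairwise transforms.

    l1: exp(x1·x2)/2 (argument clipped at 10)
    l2: x1 / (1 + exp(x2))
    l3: x1·x2/10 + 2/3
    l4: (x1 + x2 + 3)/2
    l5: g(x1)·h(x2), with g,h the step functions above, or the indicator
        pair I(x1≥0)·I(x2≥1) when ``step_variant="indicator"``.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("x1 and x2 must have equal length")
    if function_id == "l1":
        return np.exp(np.minimum(x1 * x2, _EXP_CLIP)) / 2.0
    if function_id == "l2":
        return x1 / (1.0 + np.exp(np.minimum(x2, _EXP_CLIP)))
    if function_id == "l3":
        return x1 * x2 / 10.0 + 2.0 / 3.0
    if function_id == "l4":
        return (x1 + x2 + 3.0) / 2.0
    if function_id == "l5":
        if step_variant == "indicator":
            return indicator_g(x1) * indicator_h(x2)
        return step_g(x1) * step_h(x2)
    raise ValueError(f"unknown function id {function_id!r}")


@dataclass(frozen=True)
class DGPConfig:
    """Knobs of the simulated world.

    Defaults mirror the benchmark design: four blocks of ``block_size``
    covariates (p = 4·block_size), AR(1) correlation ``rho`` = 0.5, all
    structural coefficients 0.25, unit outcome noise, and 20% of each
    block's columns feeding the structural functions.
    """

    n: int = 750
    block_size: int = 8
    rho: float = 0.5
    coef_conf: float = 0.25       # γ_c, confounder effect on treatment
    coef_iv: float = 0.25         # γ_iv, instrument effect on treatment
    coef_conf_y: float = 0.25     # γ'_c, confounder effect on outcome
    coef_y: float = 0.25          # γ_y, predictor effect on outcome
    noise_sd: float = 1.0
    select_frac: float = 0.2
    step_variant: str = "step"
    seed: int = 0

    def __post_init__(self):
        if self.block_size < 1 or self.n < 2:
            raise ValueError("need block_size >= 1 and n >= 2")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")
        if not 0.0 < self.select_frac <= 1.0:
            raise ValueError("select_frac must lie in (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def p(self) -> int:
        return 4 * self.block_size


# One structural-function term: covariate pair (block-local indices) plus
# the transform applied to it.
PlanEntry = Tuple[int, int, str]


@dataclass(frozen=True)
class DGPSpec:
    """A frozen simulated world: realized structural plans and coefficients.

    ``fa_plan``/``ga_plan`` enter the treatment model (confounder and IV
    blocks); ``fy_plan``/``gy_plan`` enter the outcome model (confounder and
    y-predictor blocks).  The noise block never appears in any plan.  The
    true ATE is the fixed unit treatment coefficient.
    """

    config: DGPConfig
    fa_plan: List[PlanEntry]
    ga_plan: List[PlanEntry]
    fy_plan: List[PlanEntry]
    gy_plan: List[PlanEntry]
    coef_fa: List[float]
    coef_ga: List[float]
    coef_fy: List[float]
    coef_gy: List[float]
    true_ate: float = 1.0
    intercept_y: float = 3.0

    # block start offsets into the full covariate matrix
    def block_offset(self, block: str) -> int:
        b = self.config.block_size
        return {"conf": 0, "iv": b, "ypred": 2 * b, "noise": 3 * b}[block]


def _ar1_cov(size: int, rho: float) -> np.ndarray:
    idx = np.arange(size)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def generate_covariates(cfg: DGPConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw the n×p covariate matrix: four independent AR(1) MVN blocks."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    cov = _ar1_cov(cfg.block_size, cfg.rho)
    # Cholesky is guaranteed for |rho|<1 but guard against numerical edge
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(cov)
        L = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
    blocks = [rng.standard_normal((cfg.n, cfg.block_size)) @ L.T for _ in range(4)]
    return np.concatenate(blocks, axis=1)


def _draw_plan(rng: np.random.Generator, block_size: int, select_frac: float) -> List[PlanEntry]:
    k = int(np.ceil(select_frac * block_size))
    if k < 1:
        raise ValueError("select_frac selects zero columns")
    cols = rng.choice(block_size, size=k, replace=False)
    pairs = []
    for i in range(0, k - 1, 2):
        pairs.append((int(cols[i]), int(cols[i + 1])))
    if k == 1 or k % 2 == 1:
        # odd leftover pairs with the first selected column
        pairs.append((int(cols[-1]), int(cols[0])))
    return [(a, b, str(rng.choice(FUNCTION_IDS))) for a, b in pairs]


def build_dgp(cfg: DGPConfig) -> DGPSpec:
    """Realize one simulated world (structural plans + coefficients)."""
    rng = np.random.default_rng(cfg.seed)
    fa = _draw_plan(rng, cfg.block_size, cfg.select_frac)
    ga = _draw_plan(rng, cfg.block_size, cfg.select_frac)
    fy = _draw_plan(rng, cfg.block_size, cfg.select_frac)
    gy = _draw_plan(rng, cfg.block_size, cfg.select_frac)
    return DGPSpec(
        config=cfg,
        fa_plan=fa,
        ga_plan=ga,
        fy_plan=fy,
        gy_plan=gy,
        coef_fa=[cfg.coef_conf] * len(fa),
        coef_ga=[cfg.coef_iv] * len(ga),
        coef_fy=[cfg.coef_conf_y] * len(fy),
        coef_gy=[cfg.coef_y] * len(gy),
    )


def _eval_plan(
    spec: DGPSpec, W: np.ndarray, plan: List[PlanEntry], coefs: List[float], block: str
) -> np.ndarray:
    off = spec.block_offset(block)
    out = np.zeros(W.shape[0])
    for (i, j, fid), c in zip(plan, coefs):
        out += c * nonlinear_apply(fid, W[:, off + i], W[:, off + j], spec.config.step_variant)
    return out


def treatment_logit(spec: DGPSpec, W: np.ndarray) -> np.ndarray:
    """η = f_a(X_c)·γ_c + g_a(X_iv)·γ_iv."""
    return _eval_plan(spec, W, spec.fa_plan, spec.coef_fa, "conf") + _eval_plan(
        spec, W, spec.ga_plan, spec.coef_ga, "iv"
    )


def outcome_signal(spec: DGPSpec, W: np.ndarray) -> np.ndarray:
    """Noise-free control outcome: 3 + f_y(X_c)·γ'_c + g_y(X_y)·γ_y."""
    return (
        spec.intercept_y
        + _eval_plan(spec, W, spec.fy_plan, spec.coef_fy, "conf")
        + _eval_plan(spec, W, spec.gy_plan, spec.coef_gy, "ypred")
    )


def generate_dataset(spec: DGPSpec, seed: int | None = None) -> Dataset:
    """Draw one dataset from the frozen world.

    Re-draws up to 10 times if a finite sample leaves one treatment arm
    empty (possible only at tiny n or extreme coefficients).
    """
    cfg = spec.config
    base_seed = cfg.seed if seed is None else seed
    for attempt in range(10):
        rng = np.random.default_rng((base_seed, attempt))
        W = generate_covariates(cfg, rng)
        g = expit(treatment_logit(spec, W))
        A = (rng.uniform(size=cfg.n) < g).astype(float)
        if 0 < A.sum() < cfg.n:
            eps = rng.normal(0.0, cfg.noise_sd, size=cfg.n)
            Y = outcome_signal(spec, W) + spec.true_ate * A + eps
            return Dataset(W, A, Y)
    raise RuntimeError("degenerate treatment arm in 10 consecutive draws")


def true_nuisance(spec: DGPSpec, ds: Dataset) -> NuisanceEstimates:
    """Oracle nuisance: evaluate the true g and Q surfaces on the data.

    q1 − q0 is identically the true ATE (additive treatment effect).
    """
    if ds.p != spec.config.p:
        raise ValueError("dataset covariate dimension does not match spec")
    g = expit(treatment_logit(spec, ds.W))
    q0 = outcome_signal(spec, ds.W)
    q1 = q0 + spec.true_ate
    return NuisanceEstimates(q1=q1, q0=q0, g=g)


# ---------------------------------------------------------------------------
# YAML round-trip (spec files written next to simulated CSVs for oracle reuse)

def spec_to_dict(spec: DGPSpec) -> dict:
    d = {
        "config": asdict(spec.config),
        "fa_plan": [list(e) for e in spec.fa_plan],
        "ga_plan": [list(e) for e in spec.ga_plan],
        "fy_plan": [list(e) for e in spec.fy_plan],
        "gy_plan": [list(e) for e in spec.gy_plan],
        "coef_fa": list(spec.coef_fa),
        "coef_ga": list(spec.coef_ga),
        "coef_fy": list(spec.coef_fy),
        "coef_gy": list(spec.coef_gy),
        "true_ate": spec.true_ate,
        "intercept_y": spec.intercept_y,
    }
    return d


def spec_from_dict(d: dict) -> DGPSpec:
    cfg = DGPConfig(**d["config"])
    return DGPSpec(
        config=cfg,
        fa_plan=[(int(a), int(b), str(f)) for a, b, f in d["fa_plan"]],
        ga_plan=[(int(a), int(b), str(f)) for a, b, f in d["ga_plan"]],
        fy_plan=[(int(a), int(b), str(f)) for a, b, f in d["fy_plan"]],
        gy_plan=[(int(a), int(b), str(f)) for a, b, f in d["gy_plan"]],
        coef_fa=[float(c) for c in d["coef_fa"]],
        coef_ga=[float(c) for c in d["coef_ga"]],
        coef_fy=[float(c) for c in d["coef_fy"]],
        coef_gy=[float(c) for c in d["coef_gy"]],
        true_ate=float(d["true_ate"]),
        intercept_y=float(d["intercept_y"]),
    )
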