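"""First-step nuisance models: two feed-forward networks with L1 penalties.

The outcome surface E[Y|A,W] and the propensity score E[A|W] are fitted by
two separate multilayer perceptrons (no parameter sharing):

    E[Y|A,W] = β₀ + β·A + W·α + H(W)·Γ_Y        (squared-error loss)
    E[A|W]   = expit( β₀' + W·α' + H'(W)·Γ_A )  (Bernoulli log-loss)

Each network has ReLU hidden layers plus a *linear skip connection* W·α
straight from the standardized inputs to the output head.  By default the
treatment enters the outcome network only through the linear β·A term
(a partially linear surface, so Q̂(1,W) − Q̂(0,W) is constant); setting
``a_in_features=True`` appends A to the network inputs instead, allowing
heterogeneous surfaces.

Both losses carry an L1 penalty C_L1·Σ|ω| over connection weights (not
biases), optimized by Adam.  L1 strength is the lever that tempers extreme
propensity predictions: with no regularization a sufficiently wide network
can near-perfectly predict treatment, driving ĝ toward 0/1 and wrecking
inverse-probability weighting downstream.

Training is fully deterministic given the seed.  Covariates are
standardized internally (train-fold statistics only under cross-fitting).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.special import expit

from .datatypes import Dataset, NuisanceEstimates

__all__ = [
    "NNConfig",
    "OutcomeModel",
    "PropensityModel",
    "fit_outcome_model",
    "fit_propensity_model",
    "predict_nuisance",
    "crossfit_nuisance",
]


@dataclass(frozen=True)
class NNConfig:
    """Hyperparameters shared by the two nuisance networks.

    ``hidden_widths=None`` means "three hidden layers as wide as the input"
    (resolved at fit time).  ``batch_size=None`` resolves to 3·p.  The
    default grid of interest for ``l1_strength`` is {0.01, 0.1}.
    """

    hidden_widths: Optional[Sequence[int]] = None
    l1_strength: float = 0.01
    epochs: int = 200
    batch_size: Optional[int] = None
    learning_rate: float = 0.01
    momentum_beta1: float = 0.95
    adam_beta2: float = 0.999
    seed: int = 0
    a_in_features: bool = False

    def __post_init__(self):
        if self.hidden_widths is not None:
            hw = tuple(int(w) for w in self.hidden_widths)
            if len(hw) == 0 or any(w < 1 for w in hw):
                raise ValueError("hidden_widths must be non-empty positive integers")
            object.__setattr__(self, "hidden_widths", hw)
        if self.l1_strength < 0:
            raise ValueError("l1_strength must be >= 0")
        if self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("epochs must be >= 1 and learning_rate > 0")
        if not 0.0 <= self.momentum_beta1 < 1.0:
            raise ValueError("momentum_beta1 must lie in [0, 1)")

    def resolve(self, p: int, n: int) -> tuple:
        widths = self.hidden_widths if self.hidden_widths is not None else (p, p, p)
        batch = self.batch_size if self.batch_size is not None else 3 * p
        batch = max(1, min(batch, n))
        return tuple(widths), batch


class _MLP:
    """Minimal ReLU MLP with a linear input→output skip path.

    Parameters: hidden layers (Wk, bk), output head (gamma, c) on the last
    hidden activation, skip weights alpha on the raw inputs; the scalar
    output is  z = H·gamma + X·alpha + c  (+ beta·A for the partially
    linear outcome head, handled by the caller via an extra linear column).
    """

    def __init__(self, d_in: int, widths: Sequence[int], d_lin: int, rng: np.random.Generator):
        self.Ws: List[np.ndarray] = []
        self.bs: List[np.ndarray] = []
        prev = d_in
        for w in widths:
            # He initialization for ReLU layers
            self.Ws.append(rng.normal(0.0, np.sqrt(2.0 / prev), size=(prev, w)))
            self.bs.append(np.zeros(w))
            prev = w
        self.gamma = rng.normal(0.0, np.sqrt(1.0 / prev), size=prev)
        self.alpha = np.zeros(d_in)       # skip path
        self.lin = np.zeros(d_lin)        # extra linear features (treatment)
        self.c = 0.0

    def params(self) -> List[np.ndarray]:
        out = []
        for W, b in zip(self.Ws, self.bs):
            out.extend([W, b])
        out.extend([self.gamma, self.alpha, self.lin])
        out.append(np.array([self.c]))
        return out

    def set_params(self, flat: List[np.ndarray]) -> None:
        k = 0
        for i in range(len(self.Ws)):
            self.Ws[i] = flat[k]
            self.bs[i] = flat[k + 1]
            k += 2
        self.gamma, self.alpha, self.lin = flat[k], flat[k + 1], flat[k + 2]
        self.c = float(flat[k + 3][0])

    def forward(self, X: np.ndarray, X_lin: np.ndarray):
        acts = [X]
        H = X
        for W, b in zip(self.Ws, self.bs):
            H = np.maximum(H @ W + b, 0.0)
            acts.append(H)
        z = H @ self.gamma + X @ self.alpha + X_lin @ self.lin + self.c
        return z, acts

    def gradients(self, X, X_lin, dz):
        """Backprop: dz is dLoss/dz per unit (already averaged upstream)."""
        z, acts = self._cache
        H_last = acts[-1]
        g_gamma = H_last.T @ dz
        g_alpha = X.T @ dz
        g_lin = X_lin.T @ dz
        g_c = np.array([dz.sum()])
        grads_W = [None] * len(self.Ws)
        grads_b = [None] * len(self.Ws)
        delta = np.outer(dz, self.gamma)
        for i in range(len(self.Ws) - 1, -1, -1):
            delta = delta * (acts[i + 1] > 0)
            grads_W[i] = acts[i].T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.Ws[i].T
        flat = []
        for gW, gb in zip(grads_W, grads_b):
            flat.extend([gW, gb])
        flat.extend([g_gamma, g_alpha, g_lin, g_c])
        return flat


def _l1_subgrad(model: _MLP) -> List[np.ndarray]:
    """Subgradient of Σ|ω| over connection weights; biases unpenalized."""
    out = []
    for W, b in zip(model.Ws, model.bs):
        out.extend([np.sign(W), np.zeros_like(b)])
    out.extend([np.sign(model.gamma), np.sign(model.alpha), np.sign(model.lin)])
    out.append(np.zeros(1))
    return out


def _train(
    model: _MLP,
    X: np.ndarray,
    X_lin: np.ndarray,
    y: np.ndarray,
    cfg: NNConfig,
    batch: int,
    loss_kind: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Adam loop; returns per-epoch mean training loss (penalty excluded)."""
    n = len(y)
    params = model.params()
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    b1, b2, lr = cfg.momentum_beta1, cfg.adam_beta2, cfg.learning_rate
    eps = 1e-8
    # objective: mean data loss + C·Σ|ω| — penalty weighted against the
    # per-sample average loss, the scale at which the {0.01, 0.1} grid bites
    lam = cfg.l1_strength
    trace = np.empty(cfg.epochs)
    t = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            Xb, Xlb, yb = X[idx], X_lin[idx], y[idx]
            z, acts = model.forward(Xb, Xlb)
            model._cache = (z, acts)
            if loss_kind == "mse":
                err = z - yb
                loss = float(np.mean(err**2))
                dz = 2.0 * err / len(idx)
            else:  # bernoulli log-loss on the logit z
                pz = expit(z)
                loss = float(
                    -np.mean(yb * np.log(np.clip(pz, 1e-12, None))
                             + (1 - yb) * np.log(np.clip(1 - pz, 1e-12, None)))
                )
                dz = (pz - yb) / len(idx)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite {loss_kind} loss at epoch {epoch}; "
                    "lower the learning rate or increase regularization"
                )
            grads = model.gradients(Xb, Xlb, dz)
            sub = _l1_subgrad(model)
            t += 1
            new_params = []
            for i, (p, g, s) in enumerate(zip(params, grads, sub)):
                g = g + lam * s  # each step estimates the full-objective gradient
                m[i] = b1 * m[i] + (1 - b1) * g
                v[i] = b2 * v[i] + (1 - b2) * g**2
                mhat = m[i] / (1 - b1**t)
                vhat = v[i] / (1 - b2**t)
                new_params.append(p - lr * mhat / (np.sqrt(vhat) + eps))
            params = new_params
            model.set_params(params)
            ep_loss += loss * len(idx)
        trace[epoch] = ep_loss / n
    return trace


@dataclass
class _Standardizer:
    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "_Standardizer":
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd < 1e-12] = 1.0
        return cls(mu, sd)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.scale


@dataclass
class OutcomeModel:
    """Fitted outcome network exposing ``predict(a, W)``."""

    _net: _MLP
    _std: _Standardizer
    a_in_features: bool
    training_loss_trace: np.ndarray

    def predict(self, a: int, W: np.ndarray) -> np.ndarray:
        X = self._std.transform(np.asarray(W, dtype=float))
        n = X.shape[0]
        a_col = np.full((n, 1), float(a))
        if self.a_in_features:
            z, _ = self._net.forward(np.hstack([X, a_col]), np.zeros((n, 0)))
        else:
            z, _ = self._net.forward(X, a_col)
        return z


@dataclass
class PropensityModel:
    """Fitted propensity network exposing ``predict(W)`` (probabilities)."""

    _net: _MLP
    _std: _Standardizer
    training_loss_trace: np.ndarray

    def predict(self, W: np.ndarray) -> np.ndarray:
        X = self._std.transform(np.asarray(W, dtype=float))
        z, _ = self._net.forward(X, np.zeros((X.shape[0], 0)))
        return expit(z)


def fit_outcome_model(ds: Dataset, cfg: NNConfig) -> OutcomeModel:
    """Fit E[Y|A,W] by the squared-error loss with L1 penalty."""
    widths, batch = cfg.resolve(ds.p, ds.n)
    std = _Standardizer.fit(ds.W)
    X = std.transform(ds.W)
    rng = np.random.default_rng((cfg.seed, 1))
    a_col = ds.A.reshape(-1, 1)
    if cfg.a_in_features:
        net = _MLP(ds.p + 1, widths, 0, rng)
        trace = _train(net, np.hstack([X, a_col]), np.zeros((ds.n, 0)), ds.Y, cfg, batch, "mse", rng)
    else:
        net = _MLP(ds.p, widths, 1, rng)
        trace = _train(net, X, a_col, ds.Y, cfg, batch, "mse", rng)
    return OutcomeModel(net, std, cfg.a_in_features, trace)


def fit_propensity_model(ds: Dataset, cfg: NNConfig) -> PropensityModel:
    """Fit E[A|W] by the Bernoulli log-loss with L1 penalty."""
    widths, batch = cfg.resolve(ds.p, ds.n)
    std = _Standardizer.fit(ds.W)
    X = std.transform(ds.W)
    rng = np.random.default_rng((cfg.seed, 2))
    net = _MLP(ds.p, widths, 0, rng)
    trace = _train(net, X, np.zeros((ds.n, 0)), ds.A, cfg, batch, "bernoulli", rng)
    return PropensityModel(net, std, trace)


def predict_nuisance(om: OutcomeModel, pm: PropensityModel, ds: Dataset) -> NuisanceEstimates:
    """Evaluate both fitted models on a dataset; propensities are floored."""
    q1 = om.predict(1, ds.W)
    q0 = om.predict(0, ds.W)
    g = pm.predict(ds.W)
    return NuisanceEstimates(q1=q1, q0=q0, g=g)


def fit_nuisance(ds: Dataset, cfg: NNConfig) -> NuisanceEstimates:
    """Fit both networks on the full sample and predict in-sample."""
    om = fit_outcome_model(ds, cfg)
    pm = fit_propensity_model(ds, cfg)
    return predict_nuisance(om, pm, ds)


def crossfit_nuisance(
    ds: Dataset, cfg: NNConfig, folds: int = 5, seed: int | None = None
) -> NuisanceEstimates:
    """K-fold cross-fitting: each unit predicted by models trained without it.

    Units are partitioned by a seeded shuffle; fold k's predictions come
    from networks fitted on the remaining K−1 folds (standardization
    statistics from the training folds only).  ``fold_id`` records the
    assignment.
    """
    if folds < 2:
        raise ValueError("cross-fitting requires folds >= 2")
    if seed is None:
        seed = cfg.seed
    n = ds.n
    rng = np.random.default_rng((seed, 17))
    perm = rng.permutation(n)
    fold_id = np.empty(n, dtype=int)
    for k in range(folds):
        fold_id[perm[k::folds]] = k
    q1 = np.empty(n)
    q0 = np.empty(n)
    g = np.empty(n)
    for k in range(folds):
        test = fold_id == k
        train = ~test
        A_tr = ds.A[train]
        if A_tr.sum() == 0 or A_tr.sum() == train.sum():
            raise ValueError(
                f"training split for fold {k} has an empty treatment arm; use fewer folds"
            )
        ds_tr = Dataset(ds.W[train], A_tr, ds.Y[train])
        fold_cfg = NNConfig(
            hidden_widths=cfg.hidden_widths,
            l1_strength=cfg.l1_strength,
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            learning_rate=cfg.learning_rate,
            momentum_beta1=cfg.momentum_beta1,
            adam_beta2=cfg.adam_beta2,
            seed=int((seed * 1000003 + k) % (2**31 - 1)),
            a_in_features=cfg.a_in_features,
        )
        om = fit_outcome_model(ds_tr, fold_cfg)
        pm = fit_propensity_model(ds_tr, fold_cfg)
        Wk = ds.W[test]
        q1[test] = om.predict(1, Wk)
        q0[test] = om.predict(0, Wk)
        g[test] = pm.predict(Wk)
    return NuisanceEstimates(q1=q1, q0=q0, g=g, fold_id=fold_id)
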