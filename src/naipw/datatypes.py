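"""Core containers for doubly robust ATE estimation.

The estimation problem is observational: for each of n units we see
covariates ``W`` (n x p), a binary treatment ``A`` and a continuous outcome
``Y``.  First-step models supply per-unit nuisance predictions — the outcome
surfaces Q(1,W), Q(0,W) and the propensity score g(W) = E[A|W] — and the
second step plugs them into the estimators in :mod:`naipw.estimators`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

# Machine floor keeping propensities strictly inside (0,1); guards against
# division by a rounded 0 or 1 only — it is not statistical trimming.
G_FLOOR = 1e-12


class DegenerateTreatmentError(ValueError):
    """Raised when one treatment arm is empty."""


class PositivityError(ValueError):
    """Raised when a propensity estimate is exactly 0 or 1."""


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class Dataset:
    """Observed data O = (Y, A, W) for n units.

    Parameters
    ----------
    W : (n, p) float array
        Adjusting covariates.
    A : (n,) array of 0/1
        Treatment indicator; both arms must be non-empty.
    Y : (n,) float array
        Outcome.
    """

    W: np.ndarray
    A: np.ndarray
    Y: np.ndarray

    def __post_init__(self):
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2:
            raise ValueError(f"W must be a 2-d matrix, got shape {W.shape}")
        A = _as_1d(self.A, "A")
        Y = _as_1d(self.Y, "Y")
        n = W.shape[0]
        if not (len(A) == len(Y) == n):
            raise ValueError(
                f"row mismatch: W has {n} rows, A has {len(A)}, Y has {len(Y)}"
            )
        for name, arr in (("W", W), ("A", A), ("Y", Y)):
            if not np.isfinite(arr).all():
                raise ValueError(f"{name} contains NaN or Inf")
        if not np.isin(A, (0.0, 1.0)).all():
            bad = np.flatnonzero(~np.isin(A, (0.0, 1.0)))[0]
            raise ValueError(f"A must be binary 0/1; offending row {bad}")
        if A.sum() == 0 or A.sum() == n:
            raise DegenerateTreatmentError("degenerate treatment vector: one arm is empty")
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "Y", Y)

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def p(self) -> int:
        return self.W.shape[1]


@dataclass(frozen=True)
class NuisanceEstimates:
    """Per-unit first-step predictions Q̂(1,W), Q̂(0,W) and ĝ(W).

    ``g`` is floored into [G_FLOOR, 1 - G_FLOOR] on construction so the
    weighting estimators never divide by a literal 0 or 1 produced by
    rounding.  ``fold_id`` records cross-fitting provenance when present.
    """

    q1: np.ndarray
    q0: np.ndarray
    g: np.ndarray
    fold_id: Optional[np.ndarray] = None

    def __post_init__(self):
        q1 = _as_1d(self.q1, "q1")
        q0 = _as_1d(self.q0, "q0")
        g = _as_1d(self.g, "g")
        if not (len(q1) == len(q0) == len(g)):
            raise ValueError("q1, q0, g must have equal length")
        for name, arr in (("q1", q1), ("q0", q0), ("g", g)):
            if not np.isfinite(arr).all():
                raise ValueError(f"{name} contains NaN or Inf")
        g = np.clip(g, G_FLOOR, 1.0 - G_FLOOR)
        object.__setattr__(self, "q1", q1)
        object.__setattr__(self, "q0", q0)
        object.__setattr__(self, "g", g)
        if self.fold_id is not None:
            fid = np.asarray(self.fold_id, dtype=int)
            if len(fid) != len(g):
                raise ValueError("fold_id length mismatch")
            object.__setattr__(self, "fold_id", fid)

    @property
    def n(self) -> int:
        return len(self.g)

    def replace_g(self, g: np.ndarray) -> "NuisanceEstimates":
        return NuisanceEstimates(self.q1, self.q0, g, self.fold_id)


class WeightName(str, Enum):
    AIPW = "aipw"
    NAIPW = "naipw"
    TRIMMED = "trimmed"


@dataclass(frozen=True)
class WeightScheme:
    """Denominators h1, h0 of the general doubly robust estimator.

    ``gamma`` and ``lam`` are the Hájek normalization constants
    γ = Ê[A/ĝ] and λ = Ê[(1−A)/(1−ĝ)]; the plain AIPW scheme records them
    without using them in h1/h0.
    """

    name: WeightName
    h1: np.ndarray
    h0: np.ndarray
    gamma: float
    lam: float

    def __post_init__(self):
        h1 = _as_1d(self.h1, "h1")
        h0 = _as_1d(self.h0, "h0")
        if len(h1) != len(h0):
            raise ValueError("h1, h0 length mismatch")
        if (h1 <= 0).any() or (h0 <= 0).any():
            raise ValueError("degenerate weight: h1 and h0 must be strictly positive")
        object.__setattr__(self, "h1", h1)
        object.__setattr__(self, "h0", h0)


@dataclass(frozen=True)
class EstimateResult:
    """A point estimate β̂ with optional asymptotic SE and influence terms.

    When influence contributions ``psi`` are present they are centred
    (sum zero up to numerical tolerance) and ``se_hat**2 == sum(psi**2)``.
    """

    estimator: str
    beta_hat: float
    n: int
    se_hat: Optional[float] = None
    psi: Optional[np.ndarray] = field(default=None, repr=False)

    def ci(self, level: float = 0.95) -> tuple:
        """Normal-quantile confidence interval β̂ ± z·SE (z=1.96 at 95%)."""
        if self.se_hat is None:
            raise ValueError("no standard error available for this estimator")
        from scipy.stats import norm  # local import; scipy optional elsewhere

        z = norm.ppf(0.5 + level / 2.0)
        return (self.beta_hat - z * self.se_hat, self.beta_hat + z * self.se_hat)
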