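# naipw — normalized doubly robust estimation of average treatment effects

`naipw` estimates the average treatment effect (ATE)

        β = E[Y¹ − Y⁰]

from observational data (covariates W, binary treatment A, continuous
outcome Y), for analysts who must adjust for confounding with flexible
machine-learning first-step models. Its core is the **normalized augmented
inverse probability weighting (nAIPW)** estimator, a Hájek-normalized
member of the general doubly robust (GDR) family

        β̂_GDR = (1/n) Σᵢ [ Aᵢ(yᵢ − Q̂¹ᵢ)/h¹ᵢ − (1−Aᵢ)(yᵢ − Q̂⁰ᵢ)/h⁰ᵢ ] + β̂_SR,

where Q̂ᵃ(W) ≈ E[Y|A=a,W], ĝ(W) ≈ E[A|W], and β̂_SR = (1/n)Σ(Q̂¹ᵢ − Q̂⁰ᵢ).
Taking h¹ = ĝ, h⁰ = 1−ĝ gives the classical AIPW estimator; taking the
self-normalized denominators

        h¹ = ĝ·Ê[A/ĝ],      h⁰ = (1−ĝ)·Ê[(1−A)/(1−ĝ)]

gives nAIPW. Both are doubly robust and Neyman-orthogonal, but nAIPW's
correction terms are convex combinations of residuals, so the estimator
stays bounded when estimated propensity scores approach 0 or 1 — the
*empirical positivity violations* that flexible treatment models (wide
neural networks, strong instrumental variables) routinely produce, and
under which AIPW's bias and variance explode.

The package provides:

- all the classical comparators (naive, outcome-regression plug-in "SR",
  IPW, Hájek nIPW, AIPW, nAIPW, and a trimmed hybrid scheme) with
  influence-function standard errors for AIPW and nAIPW;
- first-step nuisance estimation by two separate ReLU networks with linear
  skip connections and L1-penalized losses, with K-fold cross-fitting;
- a synthetic-data generator with four covariate blocks (confounders,
  instruments, outcome predictors, noise), AR(1) within-block correlation,
  logistic treatment and nonlinear outcome structure, true ATE = 1;
- a Monte Carlo harness (bias / MC std / RMSE / mean SE), a
  positivity-stress scenario, an orthogonality (Gateaux derivative) check
  and a second-order-remainder probe.

## Worked example

```python
import numpy as np
from naipw import (DGPConfig, NNConfig, build_dgp, generate_dataset,
                   crossfit_nuisance, estimate_all)

spec = build_dgp(DGPConfig(n=750, block_size=8, coef_iv=1.5, seed=21))
ds = generate_dataset(spec, seed=6)
nu = crossfit_nuisance(ds, NNConfig(l1_strength=0.1, seed=6), folds=5, seed=6)
for r in estimate_all(ds, nu, ["sr", "nipw", "aipw", "naipw"]):
    se = f"  SE {r.se_hat:.3f}" if r.se_hat is not None else ""
    print(f"{r.estimator:>6s}  {r.beta_hat:+.3f}{se}")
```

prints

```
    sr  +0.681
  nipw  +0.979
  aipw  +1.094  SE 0.185
 naipw  +1.090  SE 0.184
```

The true ATE in this simulated world is 1. On this draw the
outcome-regression plug-in (`sr`) under-corrects the confounding while the
weighting estimators land near the truth; a 95% interval is
`beta_hat ± 1.96·se_hat`. With moderate L1 regularization (0.1) the two
doubly robust estimators nearly coincide. Dropping the regularization
(`l1_strength=0.0`) lets the propensity network saturate and separates
them sharply across replicates — AIPW's replicate distribution acquires
enormous outliers while nAIPW's stays bounded, the pattern quantified by
`naipw mc` and the test suite's dispersion comparison.

The same workflow is available from the shell:

```sh
naipw simulate --n 750 --coef-iv 1.5 --seed 21 --out data.csv --spec-out spec.yaml
naipw estimate --data data.csv --nuisance crossfit-nn --folds 5 --seed 0 --out results.csv
naipw mc --n 750 --m 100 --nuisance oracle --seed 1 --out metrics.csv
naipw stress --data data.csv --spec spec.yaml --out stress.csv
```

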