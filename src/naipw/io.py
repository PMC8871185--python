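"""CSV / YAML readers and writers for datasets, results and configs."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd
import yaml

from .datatypes import Dataset, EstimateResult
from .montecarlo import MetricsRow
from .nn import NNConfig
from .simulate import DGPConfig, DGPSpec, spec_from_dict, spec_to_dict

Z95 = 1.96  # normal quantile for 95% intervals


def read_dataset_csv(path) -> Dataset:
    """Read a dataset CSV with columns ``y``, ``a``, ``x1..xp``.

    Validates the header, binariness of ``a`` and absence of missing
    values, reporting offending row numbers (1-based, excluding header).
    """
    df = pd.read_csv(path)
    cols = list(df.columns)
    if len(cols) < 3 or cols[0] != "y" or cols[1] != "a":
        raise ValueError(
            f"{path}: expected header starting with 'y,a,x1,...', got {cols[:3]}"
        )
    expected_x = [f"x{i}" for i in range(1, len(cols) - 1)]
    if cols[2:] != expected_x:
        raise ValueError(f"{path}: covariate columns must be named x1..x{len(cols)-2}")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax()) + 1
        raise ValueError(f"{path}: missing value at data row {row}")
    a = df["a"].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isin(a, (0.0, 1.0)))
    if bad.size:
        raise ValueError(
            f"{path}: treatment column 'a' must be 0/1; value {a[bad[0]]} at data row {bad[0] + 1}"
        )
    return Dataset(
        W=df[expected_x].to_numpy(dtype=float),
        A=a,
        Y=df["y"].to_numpy(dtype=float),
    )


def write_dataset_csv(ds: Dataset, path) -> None:
    df = pd.DataFrame(ds.W, columns=[f"x{i}" for i in range(1, ds.p + 1)])
    df.insert(0, "a", ds.A.astype(int))
    df.insert(0, "y", ds.Y)
    df.to_csv(path, index=False)


def write_results_csv(results: Sequence[EstimateResult], path) -> None:
    """One row per estimator: beta_hat, se_hat and the 95% normal CI."""
    if not results:
        raise ValueError("no results to write")
    rows = []
    for r in results:
        if r.se_hat is not None:
            lo, hi = r.beta_hat - Z95 * r.se_hat, r.beta_hat + Z95 * r.se_hat
        else:
            lo = hi = None
        rows.append({
            "estimator": r.estimator,
            "beta_hat": r.beta_hat,
            "se_hat": r.se_hat,
            "ci_low": lo,
            "ci_high": hi,
            "n": r.n,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_metrics_csv(rows: Sequence[MetricsRow], path) -> None:
    recs = []
    for r in rows:
        rec = asdict(r)
        rec.update(rec.pop("scenario"))
        recs.append(rec)
    pd.DataFrame(recs).to_csv(path, index=False)


def write_dgp_spec_yaml(spec: DGPSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(spec_to_dict(spec), sort_keys=False))


def read_dgp_spec_yaml(path) -> DGPSpec:
    return spec_from_dict(yaml.safe_load(Path(path).read_text()))


def write_nn_config_yaml(cfg: NNConfig, path) -> None:
    d = asdict(cfg)
    if d["hidden_widths"] is not None:
        d["hidden_widths"] = list(d["hidden_widths"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def read_nn_config_yaml(path) -> NNConfig:
    return NNConfig(**yaml.safe_load(Path(path).read_text()))


def read_dgp_config_yaml(path) -> DGPConfig:
    return DGPConfig(**yaml.safe_load(Path(path).read_text()))
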