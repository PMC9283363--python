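"""Preprocessing of glycan peak areas.

Pipeline order is fixed: total-area normalization -> natural log ->
empirical-Bayes batch correction (ComBat) -> rank-based inverse normal
transformation.  Each step checks the table's processing state, so the
steps cannot be reordered or repeated by accident.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .tables import BatchDesign, PeakTable

__all__ = [
    "normalize_total_area",
    "log_transform",
    "combat_correct",
    "rank_inverse_normal",
    "rank_normalize",
    "run_preprocessing",
]

logger = logging.getLogger(__name__)


def normalize_total_area(table: PeakTable) -> PeakTable:
    """Express each peak as a percentage of the sample's total area.

    value[i, j] = 100 * area[i, j] / sum_j area[i, j]; row sums are 100
    within 1e-9 afterwards.
    """
    table.require_state("raw")
    arr = table.values.to_numpy(dtype=float)
    if np.any(arr < 0):
        raise ValueError("raw areas must be nonnegative")
    totals = arr.sum(axis=1)
    zero = totals <= 0
    if zero.any():
        bad = [table.sample_ids[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"samples with zero total area: {bad}")
    out = 100.0 * arr / totals[:, None]
    return table.with_values(
        pd.DataFrame(out, index=table.values.index, columns=table.values.columns),
        state="percent",
    )


def log_transform(table: PeakTable, zero_policy: str = "half_min") -> PeakTable:
    """Natural log of peak percentages.

    Exact zeros are rare in integrated chromatograms but possible; policy
    ``half_min`` (default) replaces zeros in a peak column with half that
    column's smallest positive value before logging, ``error`` raises.
    """
    table.require_state("percent")
    arr = table.values.to_numpy(dtype=float).copy()
    if np.any(arr < 0):
        raise ValueError("percent values must be nonnegative")
    zeros = arr == 0
    if zeros.any():
        if zero_policy == "error":
            raise ValueError(f"{int(zeros.sum())} zero values present")
        if zero_policy != "half_min":
            raise ValueError(f"unknown zero_policy {zero_policy!r}")
        for j in np.flatnonzero(zeros.any(axis=0)):
            col = arr[:, j]
            positive = col[col > 0]
            if len(positive) == 0:
                raise ValueError(
                    f"peak {table.peak_ids[j]!r} is all-zero; cannot impute"
                )
            arr[zeros[:, j], j] = positive.min() / 2.0
    return table.with_values(
        pd.DataFrame(np.log(arr), index=table.values.index, columns=table.values.columns),
        state="log",
    )


def combat_correct(table: PeakTable, design: BatchDesign) -> PeakTable:
    """Parametric empirical-Bayes batch correction of log peak values.

    Per peak the values are standardized against the batch-free model, the
    per-batch location (gamma) and scale (delta^2) are shrunk toward
    batch-level hyperpriors, and the adjusted values are back-transformed
    (the Johnson-Li-Rabinovic ComBat model).  A single batch is a no-op:
    the input is returned unchanged with a warning.
    """
    table.require_state("log")
    batch = design.batch.reindex(table.sample_ids)
    if batch.isna().any():
        missing = batch.index[batch.isna()].tolist()
        raise ValueError(f"samples missing a batch assignment: {missing[:5]}")
    if batch.nunique() == 1:
        logger.warning("single batch: ComBat correction is a no-op")
        return table.with_values(table.values.copy(), state="batch_corrected")

    import anndata
    import scanpy as sc

    obs = pd.DataFrame({"batch": batch.astype(str).to_numpy()}, index=table.sample_ids)
    if design.covariates is not None:
        cov = design.covariates.reindex(table.sample_ids)
        obs = pd.concat([obs, cov], axis=1)
        covariate_keys = list(design.covariates.columns)
    else:
        covariate_keys = None
    adata = anndata.AnnData(
        X=table.values.to_numpy(dtype=float).copy(),
        obs=obs,
        var=pd.DataFrame(index=table.peak_ids),
    )
    corrected = sc.pp.combat(adata, key="batch", covariates=covariate_keys, inplace=False)
    return table.with_values(
        pd.DataFrame(
            np.asarray(corrected, dtype=float),
            index=table.values.index,
            columns=table.values.columns,
        ),
        state="batch_corrected",
    )


def rank_inverse_normal(values) -> np.ndarray:
    """Rank-based inverse normal transformation of one variable.

    Maps average ranks through the standard normal quantile function,
    ``Phi^{-1}((rank - 0.5) / n)``, then re-centres and rescales to mean 0
    and SD 1.  Ties receive identical outputs (average ranks; deterministic,
    unlike random tie-breaking).  Monotone in the input.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D vector of length >= 2")
    if np.any(~np.isfinite(x)):
        raise ValueError("non-finite values present")
    if np.ptp(x) == 0:
        raise ValueError("constant vector: ranks are undefined")
    ranks = stats.rankdata(x, method="average")
    z = stats.norm.ppf((ranks - 0.5) / len(x))
    z = z - z.mean()
    return z / z.std(ddof=0)


def rank_normalize(table: PeakTable) -> PeakTable:
    """Apply the rank-based inverse normal transformation to every peak."""
    table.require_state("batch_corrected")
    arr = table.values.to_numpy(dtype=float)
    out = np.column_stack([rank_inverse_normal(arr[:, j]) for j in range(arr.shape[1])])
    return table.with_values(
        pd.DataFrame(out, index=table.values.index, columns=table.values.columns),
        state="rank_normal",
    )


def run_preprocessing(
    table: PeakTable,
    design: BatchDesign | None = None,
    until: str = "rank_normal",
) -> PeakTable:
    """Run the pipeline from a raw table up to the requested state."""
    order = ["percent", "log", "batch_corrected", "rank_normal"]
    if until not in order:
        raise ValueError(f"until must be one of {order}")
    out = normalize_total_area(table)
    if until == "percent":
        return out
    out = log_transform(out)
    if until == "log":
        return out
    if design is None:
        raise ValueError("batch design required for batch correction")
    out = combat_correct(out, design)
    if until == "batch_corrected":
        return out
    return rank_normalize(out)
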