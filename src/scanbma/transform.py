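"""Data transformations applied before network inference.

Two sources of variation in perturbation time-series are not regulatory
signal and are removed before fitting:

1. *Time adjustment* — a trajectory shared by all replicates (e.g. the
   transcriptome-wide transient following drug application) is removed by
   subtracting, for each gene and time point, the mean across replicates.

2. *Self-detrending* — each gene's first-order autoregressive dependence on
   itself is removed by taking residuals from the no-intercept regression
   X[i,t,s] = alpha_i * X[i,t-1,s] + delta, fitted by least squares over all
   S*(T-1) lagged pairs.  The output loses the first time point.

The pipeline applies them in that order; the self-regression is therefore
estimated on time-adjusted values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import ExpressionTimeSeries

__all__ = [
    "SelfTrendFit",
    "time_adjust",
    "fit_self_trend",
    "self_detrend",
    "transform_pipeline",
    "apply_transform",
    "TRANSFORM_MODES",
]

TRANSFORM_MODES = ("none", "time", "time+self")


@dataclass(frozen=True)
class SelfTrendFit:
    """No-intercept least-squares fit of a gene on its own lagged values."""

    alpha_hat: float
    residual_variance: float


def time_adjust(ts: ExpressionTimeSeries) -> ExpressionTimeSeries:
    """Subtract the per-(gene, time) mean across replicates.

    After adjustment the replicate mean at every (gene, time) is zero; with a
    single replicate everything becomes exactly zero.
    """
    adjusted = ts.values - ts.values.mean(axis=2, keepdims=True)
    return ExpressionTimeSeries(ts.gene_ids, ts.times, ts.replicate_ids, adjusted)


def fit_self_trend(ts: ExpressionTimeSeries, gene: int | str) -> SelfTrendFit:
    """Estimate alpha_i for one gene from all S*(T-1) lagged pairs.

    alpha_hat = sum_t,s X[t]*X[t-1] / sum_t,s X[t-1]^2 (no intercept).  A gene
    whose lagged values are identically zero gets alpha_hat = 0 by convention.
    """
    i = gene if isinstance(gene, int) else ts.gene_index(gene)
    x = ts.values[i]  # (T, S)
    lagged = x[:-1, :]
    current = x[1:, :]
    denom = float(np.sum(lagged * lagged))
    if denom == 0.0:
        warnings.warn(
            f"gene {ts.gene_ids[i]!r}: lagged values identically zero; "
            "self-trend coefficient set to 0", stacklevel=2,
        )
        alpha = 0.0
    else:
        alpha = float(np.sum(current * lagged) / denom)
    resid = current - alpha * lagged
    dof = max(1, resid.size - 1)
    return SelfTrendFit(alpha_hat=alpha, residual_variance=float(np.sum(resid**2) / dof))


def self_detrend(ts: ExpressionTimeSeries) -> ExpressionTimeSeries:
    """Replace each gene by the residuals of its lag-1 self regression.

    Output has T-1 time points (the input's t = 2..T).  Residuals satisfy the
    no-intercept normal equation: for every gene the inner product with the
    lagged input values is 0.
    """
    alphas = np.array([fit_self_trend(ts, i).alpha_hat for i in range(ts.n_genes)])
    resid = ts.values[:, 1:, :] - alphas[:, None, None] * ts.values[:, :-1, :]
    return ExpressionTimeSeries(ts.gene_ids, ts.times[1:], ts.replicate_ids, resid)


def transform_pipeline(ts: ExpressionTimeSeries) -> ExpressionTimeSeries:
    """Time adjustment followed by self-detrending.

    Requires at least 3 input time points: detrending drops one, and the
    downstream lagged regression needs at least 2.
    """
    if ts.n_times < 3:
        raise ValueError(
            f"transform pipeline needs >= 3 time points "
            f"(got {ts.n_times}): self-detrending drops one and the lagged "
            "regression needs at least 2"
        )
    return self_detrend(time_adjust(ts))


def apply_transform(ts: ExpressionTimeSeries, mode: str) -> ExpressionTimeSeries:
    """Apply one of the named transform modes: none, time, time+self."""
    if mode == "none":
        return ts
    if mode == "time":
        return time_adjust(ts)
    if mode == "time+self":
        return transform_pipeline(ts)
    raise ValueError(f"unknown transform mode {mode!r}; choose from {TRANSFORM_MODES}")
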