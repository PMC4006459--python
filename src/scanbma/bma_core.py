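"""Model scoring for Bayesian model averaging over lagged regressions.

For a target gene i the candidate models are subsets M_k of potential
regulators h, entering the linear model

    X[i,t,s] = b0 + sum_{h in M_k} b_h * X[h,t-1,s] + eps,   eps ~ N(0, s2)

Under Zellner's g-prior b | s2 ~ N(0, g*s2*(X'X)^-1) with a flat prior on
(b0, log s2), the Bayes factor of M_k against the null (intercept-only)
model has the closed form

    2*log BF_k = (n - d_k - 1)*log(1+g) - (n-1)*log(1 + g*(1 - R2_k))

where d_k = |M_k| and R2_k is the intercept-adjusted coefficient of
determination of M_k.  Adding the model prior
Pr(M_k) ~ prod_{h in M_k} pi_hi * prod_{h not in M_k} (1 - pi_hi) contributes
2*sum_{h in M_k} log(pi_hi/(1-pi_hi)) to the 2*log posterior odds against
the null (the shared prod(1-pi) factor cancels).  Larger scores mean more
probable models; the orientation is validated against a numerically
integrated marginal likelihood in the test suite.

A BIC-based score, -n*log(1-R2) - d*log(n) + prior term, is available as an
alternative backend; with g = n (the unit information prior) the two agree
closely.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import ExpressionTimeSeries

__all__ = [
    "RegressionData",
    "ModelKey",
    "model_key",
    "ScoredModel",
    "build_lagged_design",
    "r_squared",
    "g_prior_two_log_odds",
    "bic_two_log_odds",
    "model_weights",
    "inclusion_probabilities",
    "ModelScorer",
]

#: A model is a canonical (sorted, duplicate-free) tuple of candidate indices.
ModelKey = tuple[int, ...]

R2_CLAMP = 1e-12  # keep log(1 + g*(1-R2)) finite on collinear toys


def model_key(indices) -> ModelKey:
    """Canonicalise a collection of candidate indices into a ModelKey."""
    key = tuple(sorted(set(int(i) for i in indices)))
    if key and key[0] < 0:
        raise ValueError("candidate indices must be non-negative")
    return key


@dataclass
class RegressionData:
    """Stacked lagged regression problem for one target gene.

    ``y`` holds the target's values at t = 2..T for every replicate;
    column h of ``X`` holds candidate h's values at t-1, aligned row-wise.
    """

    y: np.ndarray
    X: np.ndarray
    candidate_ids: list[str]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.y.ndim != 1:
            raise ValueError("X must be 2-D and y 1-D")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if self.X.shape[1] != len(self.candidate_ids):
            raise ValueError("X column count != number of candidate ids")
        self._yc = self.y - self.y.mean()
        self._Xc = self.X - self.X.mean(axis=0, keepdims=True)
        self._tss = float(self._yc @ self._yc)

    @property
    def n(self) -> int:
        return int(self.y.shape[0])

    @property
    def p(self) -> int:
        return int(self.X.shape[1])

    @property
    def tss(self) -> float:
        return self._tss

    def subset(self, indices: list[int]) -> "RegressionData":
        """Restrict the candidate set to ``indices`` (e.g. after prescreening)."""
        return RegressionData(
            self.y, self.X[:, indices], [self.candidate_ids[i] for i in indices]
        )


@dataclass(frozen=True)
class ScoredModel:
    """A candidate-regulator subset with its fit and posterior score."""

    key: ModelKey
    r2: float
    d: int
    two_log_odds: float


def build_lagged_design(
    ts: ExpressionTimeSeries,
    target: str,
    candidates: list[str] | None = None,
    include_self: bool = False,
) -> RegressionData:
    """Stack the lag-1 design for one target over all replicates.

    ``y`` gets X[target, t, s] for t = 2..T and every s; column h gets
    X[h, t-1, s] in the same row order, giving n = S*(T-1) observations.
    By default the target itself is excluded from the candidates (its own
    lagged effect is handled by the self-detrending transform).
    """
    if candidates is None:
        candidates = [g for g in ts.gene_ids if include_self or g != target]
    elif not include_self and target in candidates:
        raise ValueError(f"target {target!r} in candidate list but self-edges are disabled")
    t_idx = ts.gene_index(target)
    c_idx = [ts.gene_index(g) for g in candidates]
    # replicate-major stacking; downstream scores are invariant to row order
    y = ts.values[t_idx, 1:, :].T.reshape(-1)
    X = np.stack([ts.values[i, :-1, :].T.reshape(-1) for i in c_idx], axis=1)
    return RegressionData(y, X, list(candidates))


def r_squared(data: RegressionData, key: ModelKey) -> float:
    """Intercept-adjusted R^2 of the OLS fit on the selected columns.

    The null model returns 0.  Rank-deficient selections are handled by the
    minimum-norm least-squares solution; a zero-variance response returns 0
    with a warning.  Values are clamped to [0, 1 - 1e-12].
    """
    d = len(key)
    if d > data.n - 2:
        raise ValueError(f"model size {d} exceeds n - 2 = {data.n - 2}")
    if d == 0:
        return 0.0
    if data.tss == 0.0:
        warnings.warn("zero-variance response: R^2 defined as 0", stacklevel=2)
        return 0.0
    Xk = data._Xc[:, list(key)]
    coef, *_ = np.linalg.lstsq(Xk, data._yc, rcond=None)
    resid = data._yc - Xk @ coef
    r2 = 1.0 - float(resid @ resid) / data.tss
    return float(min(max(r2, 0.0), 1.0 - R2_CLAMP))


def g_prior_two_log_odds(
    r2: float, d: int, n: int, g: float, prior_log_odds_sum: float = 0.0
) -> float:
    """2*log posterior odds of a model against the null under the g-prior.

    ``prior_log_odds_sum`` is 2*sum_{h in M} log(pi_hi/(1-pi_hi)).
    """
    if g <= 0:
        raise ValueError("g must be positive")
    if not 0.0 <= r2 < 1.0:
        raise ValueError("R^2 must lie in [0, 1)")
    if n < d + 2:
        raise ValueError(f"need n >= d + 2 (n={n}, d={d})")
    return (
        (n - d - 1) * math.log1p(g)
        - (n - 1) * math.log1p(g * (1.0 - r2))
        + prior_log_odds_sum
    )


def bic_two_log_odds(r2: float, d: int, n: int, prior_log_odds_sum: float = 0.0) -> float:
    """BIC approximation to the 2*log posterior odds against the null."""
    if not 0.0 <= r2 < 1.0:
        raise ValueError("R^2 must lie in [0, 1)")
    if n < d + 2:
        raise ValueError(f"need n >= d + 2 (n={n}, d={d})")
    return -n * math.log1p(-r2) - d * math.log(n) + prior_log_odds_sum


def model_weights(models: list[ScoredModel]) -> np.ndarray:
    """Posterior model probabilities, proportional to exp(score/2)."""
    if not models:
        raise ValueError("empty model list")
    half = np.array([m.two_log_odds for m in models]) / 2.0
    half -= half.max()  # max-shift for numerical stability
    w = np.exp(half)
    return w / w.sum()


def inclusion_probabilities(models: list[ScoredModel], weights: np.ndarray, p: int) -> np.ndarray:
    """Posterior inclusion probability of each candidate: the summed weight
    of the models that contain it."""
    probs = np.zeros(p)
    for m, w in zip(models, weights):
        for h in m.key:
            probs[h] += w
    return np.clip(probs, 0.0, 1.0)


class ModelScorer:
    """Caches R^2 by model and produces scores for a given g.

    R^2 is the expensive, g-independent part; it is computed once per model
    and reused across Occam's-window sweeps and EM iterations.  The prior
    term uses per-candidate log-odds log(pi/(1-pi)) aligned with the columns
    of ``data``.
    """

    def __init__(
        self,
        data: RegressionData,
        prior_log_odds: np.ndarray | None = None,
        backend: str = "gprior",
    ) -> None:
        if backend not in ("gprior", "bic"):
            raise ValueError(f"unknown score backend {backend!r}")
        self.data = data
        self.backend = backend
        if prior_log_odds is None:
            prior_log_odds = np.zeros(data.p)
        self.prior_log_odds = np.asarray(prior_log_odds, dtype=float)
        if self.prior_log_odds.shape != (data.p,):
            raise ValueError("prior_log_odds length must match the candidate count")
        self._r2: dict[ModelKey, float] = {}

    @property
    def n(self) -> int:
        return self.data.n

    @property
    def p(self) -> int:
        return self.data.p

    def r2(self, key: ModelKey) -> float:
        val = self._r2.get(key)
        if val is None:
            val = r_squared(self.data, key)
            self._r2[key] = val
        return val

    def prior_sum(self, key: ModelKey) -> float:
        return 2.0 * float(self.prior_log_odds[list(key)].sum()) if key else 0.0

    def score(self, key: ModelKey, g: float) -> ScoredModel:
        key = model_key(key)
        r2 = self.r2(key)
        ps = self.prior_sum(key)
        if self.backend == "gprior":
            s = g_prior_two_log_odds(r2, len(key), self.n, g, ps)
        else:
            s = bic_two_log_odds(r2, len(key), self.n, ps)
        return ScoredModel(key=key, r2=r2, d=len(key), two_log_odds=s)
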