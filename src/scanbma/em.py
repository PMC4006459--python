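"""EM estimation of the g-prior scale by maximum marginal likelihood.

g controls the prior spread of the regression coefficients; g = n is the
unit information prior and the recommended range is 1 <= g <= n.  The
marginal likelihood summed over the model space is maximised by an EM
algorithm in which the missing data are the model-membership indicators:
the E-step runs the Occam's-window scan at the current g and computes
posterior model weights, and the M-step maximises

    Q(g) = sum_k w_k * [ (n - d_k - 1)*log(1+g) - (n-1)*log(1 + g*(1 - R2_k)) ]

over g in [1, n] — the weighted g-dependent part of the 2*log Bayes
factors.  Iterate until g stabilises.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .bma_core import ModelScorer, ScoredModel, model_weights

__all__ = ["EMState", "q_function", "maximize_q", "em_loop"]

EM_MAX_ITER = 100
EM_REL_TOL = 1e-6


@dataclass
class EMState:
    g: float
    iteration: int
    converged: bool
    history: list[tuple[float, float]] = field(default_factory=list)


def q_function(g: float, models: list[ScoredModel], weights: np.ndarray, n: int) -> float:
    """Expected complete-data objective at g, given model weights."""
    if g <= 0:
        raise ValueError("g must be positive")
    d = np.array([m.d for m in models])
    r2 = np.array([m.r2 for m in models])
    w = np.asarray(weights, dtype=float)
    return float(np.sum(w * ((n - d - 1) * np.log1p(g) - (n - 1) * np.log1p(g * (1.0 - r2)))))


def maximize_q(
    models: list[ScoredModel],
    weights: np.ndarray,
    n: int,
    current_g: float | None = None,
) -> float:
    """Argmax of Q over [1, n] by bounded scalar optimisation.

    The endpoints are checked explicitly so boundary maximisers (e.g. g = 1
    when no model fits better than the null) are exact.  A flat Q — all
    weight on null-equivalent models — returns ``current_g`` unchanged.
    """
    if not models:
        raise ValueError("empty model list")
    lo, hi = 1.0, float(max(n, 1))
    probe = np.linspace(lo, hi, 7)
    q_probe = [q_function(g, models, weights, n) for g in probe]
    if max(q_probe) - min(q_probe) < 1e-12:
        return float(current_g) if current_g is not None else hi
    res = minimize_scalar(
        lambda g: -q_function(g, models, weights, n),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    candidates = [(q_function(lo, models, weights, n), lo),
                  (q_function(hi, models, weights, n), hi),
                  (-res.fun, float(res.x))]
    return max(candidates)[1]


def em_loop(scorer: ModelScorer, opts) -> tuple[EMState, list[ScoredModel], np.ndarray]:
    """Alternate Occam's-window scans and Q maximisation until g stabilises.

    Starts from g = n (unit information prior).  Each iteration re-runs the
    scan at the current g (R^2 values are cached in the scorer, so only the
    g-dependent score terms are recomputed), reweights the window models and
    maximises Q.  g is clamped to [1, n] throughout.  Returns the final
    state together with the window models and weights at the converged g.
    """
    from .search import scan  # local import to avoid a cycle

    n = scorer.n
    g = float(n)
    state = EMState(g=g, iteration=0, converged=False)
    models = scan(scorer, g, opts)
    weights = model_weights(models)
    for it in range(1, EM_MAX_ITER + 1):
        g_new = float(np.clip(maximize_q(models, weights, n, current_g=g), 1.0, n))
        state.history.append((g_new, q_function(g_new, models, weights, n)))
        state.iteration = it
        if abs(g_new - g) <= EM_REL_TOL * max(1.0, abs(g)):
            g = g_new
            state.converged = True
            break
        g = g_new
        models = scan(scorer, g, opts)
        weights = model_weights(models)
    else:
        warnings.warn(
            f"EM for g did not converge within {EM_MAX_ITER} iterations "
            f"(last g = {g:.6g})", stacklevel=2,
        )
    # final scan at the converged g so scores, weights and g are consistent
    models = scan(scorer, g, opts)
    weights = model_weights(models)
    state.g = g
    return state, models, weights
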