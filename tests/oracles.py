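"""Independent oracles used by the test suite.

These deliberately avoid the closed-form expressions implemented in the
package: the marginal-likelihood oracle integrates the g-prior numerically,
the search oracle enumerates the full model space, and the metric oracles
count pairs by brute force.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy.integrate import dblquad, nquad


def _log_integrand_factory(y: np.ndarray, X: np.ndarray | None, g: float):
    """log p(y | b0, sigma) with the Gaussian coefficient prior marginalised.

    Under beta | sigma^2 ~ N(0, g sigma^2 (X'X)^-1), the linear-Gaussian
    identity gives y | b0, sigma ~ N(b0*1, sigma^2 (I + g*X(X'X)^-1 X')).
    For the null model the covariance is sigma^2 I.  The flat priors on b0
    and log sigma contribute constant densities that cancel in the ratio.
    """
    n = len(y)
    if X is None or X.shape[1] == 0:
        sigma0 = np.eye(n)
    else:
        sigma0 = np.eye(n) + g * X @ np.linalg.inv(X.T @ X) @ X.T
    inv = np.linalg.inv(sigma0)
    _, logdet = np.linalg.slogdet(sigma0)
    const = -0.5 * n * math.log(2 * math.pi) - 0.5 * logdet
    ones = np.ones(n)

    def log_f(b0: float, t: float) -> float:
        # t = log sigma; flat prior in t (equivalent to p(sigma^2) ~ 1/sigma^2)
        r = y - b0 * ones
        return const - n * t - 0.5 * math.exp(-2.0 * t) * float(r @ inv @ r)

    return log_f


def _log_integral(y: np.ndarray, X: np.ndarray | None, g: float, shift: float) -> float:
    log_f = _log_integrand_factory(y, X, g)
    b0_lim = (float(y.mean() - 15 * (y.std() + 1)), float(y.mean() + 15 * (y.std() + 1)))
    t_lim = (-8.0, 6.0)
    val, _ = dblquad(
        lambda t, b0: math.exp(log_f(b0, t) - shift),
        b0_lim[0], b0_lim[1], t_lim[0], t_lim[1],
        epsabs=1e-10, epsrel=1e-8,
    )
    return math.log(val) + shift


def two_log_bayes_factor_quadrature(y: np.ndarray, X: np.ndarray, g: float) -> float:
    """2*log of the marginal-likelihood ratio model-vs-null by 2-D quadrature.

    The g-prior sits on the slopes of the centered design (the intercept
    carries the flat prior and is orthogonal to the slope prior), so X is
    column-centered here; the model itself is unchanged by the
    reparameterisation b0' = b0 + mean(X) @ beta.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    # common shift keeps both integrals O(1)
    log_f0 = _log_integrand_factory(y, None, g)
    shift = log_f0(float(y.mean()), math.log(y.std() + 0.1))
    log_mk = _log_integral(y, X, g, shift)
    log_m0 = _log_integral(y, None, g, shift)
    return 2.0 * (log_mk - log_m0)


def two_log_bayes_factor_full_quadrature(y: np.ndarray, x: np.ndarray, g: float) -> float:
    """Fully numerical 3-D version for a single predictor: integrates over
    (beta, b0, log sigma) with the g-prior density written out explicitly.
    Used to validate the 2-D oracle itself."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float).reshape(-1)
    x = x - x.mean()  # slope prior on the centered predictor, as in the 2-D oracle
    n = len(y)
    xtx = float(x @ x)

    def log_fk(beta, b0, t):
        sigma2 = math.exp(2.0 * t)
        resid = y - b0 - beta * x
        log_lik = -0.5 * n * math.log(2 * math.pi * sigma2) - 0.5 * float(resid @ resid) / sigma2
        prior_var = g * sigma2 / xtx
        log_prior = -0.5 * math.log(2 * math.pi * prior_var) - 0.5 * beta**2 / prior_var
        return log_lik + log_prior  # flat in b0 and t

    def log_f0(b0, t):
        sigma2 = math.exp(2.0 * t)
        resid = y - b0
        return -0.5 * n * math.log(2 * math.pi * sigma2) - 0.5 * float(resid @ resid) / sigma2

    shift = log_f0(float(y.mean()), math.log(y.std() + 0.1))
    span = 10 * (float(y.std()) + 1.0)
    opts = {"epsabs": 1e-9, "epsrel": 1e-7}
    mk, _ = nquad(
        lambda beta, b0, t: math.exp(log_fk(beta, b0, t) - shift),
        [(-span, span), (y.mean() - span, y.mean() + span), (-8, 6)], opts=opts,
    )
    m0, _ = nquad(
        lambda b0, t: math.exp(log_f0(b0, t) - shift),
        [(y.mean() - span, y.mean() + span), (-8, 6)], opts=opts,
    )
    return 2.0 * (math.log(mk) - math.log(m0))


# ---------------------------------------------------------------------------
# exhaustive model-space enumeration

def enumerate_window(scorer, g: float, occam_c: float, max_d: int | None = None):
    """All models within Occam's window of the global best, by enumerating
    every subset of the candidate set."""
    p = scorer.p
    if max_d is None:
        max_d = min(p, scorer.n - 2)
    scored = []
    for d in range(0, max_d + 1):
        for key in combinations(range(p), d):
            scored.append(scorer.score(tuple(key), g))
    best = max(m.two_log_odds for m in scored)
    width = 2.0 * math.log(occam_c)
    return {m.key for m in scored if m.two_log_odds >= best - width}


# ---------------------------------------------------------------------------
# metric oracles

def auroc_bruteforce(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney by explicit pair counting over all true x false pairs."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        return float("nan")
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def bic_difference_oracle(y: np.ndarray, X: np.ndarray, key) -> float:
    """BIC_0 - BIC_k from residual sums of squares, by the direct definition
    BIC = n*log(RSS/n) + k*log(n) with k counting regression coefficients."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    ones = np.ones((n, 1))
    rss0 = float(np.sum((y - y.mean()) ** 2))
    Xk = np.hstack([ones, np.asarray(X, dtype=float)[:, list(key)]])
    beta, *_ = np.linalg.lstsq(Xk, y, rcond=None)
    rssk = float(np.sum((y - Xk @ beta) ** 2))
    bic0 = n * math.log(rss0 / n) + 1 * math.log(n)
    bick = n * math.log(rssk / n) + (1 + len(key)) * math.log(n)
    return bic0 - bick
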