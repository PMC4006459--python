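"""Active-set Occam's-window model search and the per-target fit orchestrator.

The search keeps an active set of models around which to look.  Starting
from the null model, every model reachable by adding or removing a single
candidate regulator from an active model is scored; models within Occam's
window — within a factor C (default 100) of the best model's posterior
probability, i.e. within 2*log(C) on the 2-log-odds scale — join the active
set and are expanded in turn.  Because the best score only improves, a model
once judged outside the window can never re-enter, so the final window is
simply every evaluated model within 2*log(C) of the final best.

Because the window omits most of the model space, raw inclusion
probabilities saturate at 0 or 1 for many regulators.  They are refined by
comparing the best model with the best model with the regulator removed
(for saturated-high) or added (for saturated-low): with O the posterior odds
of the best model to the modified one, the refined probabilities are
O/(1+O) and 1/(1+O) respectively, giving a strict ordering among regulators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .bma_core import (
    ModelKey,
    ModelScorer,
    RegressionData,
    ScoredModel,
    build_lagged_design,
    inclusion_probabilities,
    model_key,
    model_weights,
)
from .data_io import ExpressionTimeSeries, PriorEdgeMatrix

__all__ = ["ScanOptions", "BMAResult", "prescreen", "scan", "refine_inclusion", "fit_target"]

#: raw inclusion probabilities within this distance of 0/1 are refined
SATURATION_TOL = 1e-9
REFINE_CLAMP = 1e-12


@dataclass
class ScanOptions:
    """Tuning knobs of the model search.

    occam_c
        Occam's-window factor C > 1; models whose posterior probability is
        more than C times below the best are discarded.  Default 100,
        a conventional "strong evidence" cutoff.
    nvar
        Number of top-prescreened candidate regulators per target, or "all".
        Default 20: yeast target genes rarely have more than 13 regulators,
        so 20 leaves margin.
    g
        Either the string "em" (estimate g by maximum marginal likelihood
        via EM, the default) or a fixed positive float.
    score
        "gprior" (default) or "bic".
    max_model_size
        Largest model considered; defaults to n - 2, the scoring guard.
    seed
        Only consumed by the simulator; the search itself is deterministic.
    """

    occam_c: float = 100.0
    nvar: int | str = 20
    g: float | str = "em"
    score: str = "gprior"
    max_model_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.occam_c <= 1:
            raise ValueError("occam_c must be > 1")
        if self.nvar != "all":
            self.nvar = int(self.nvar)
            if self.nvar < 1:
                raise ValueError("nvar must be >= 1 (or 'all')")
        if isinstance(self.g, str):
            if self.g != "em":
                raise ValueError("g must be 'em' or a positive number")
        elif self.g <= 0:
            raise ValueError("g must be 'em' or a positive number")
        if self.score not in ("gprior", "bic"):
            raise ValueError("score backend must be 'gprior' or 'bic'")

    @property
    def window_width(self) -> float:
        """Window width on the 2*log-odds scale: 2*ln(C)."""
        return 2.0 * math.log(self.occam_c)


@dataclass
class BMAResult:
    """Per-target output of the model search and averaging."""

    target: str
    candidates: list[str]
    window_models: list[ScoredModel]
    weights: np.ndarray
    g: float
    inclusion: np.ndarray
    refined_inclusion: np.ndarray
    em_converged: bool | None = None
    em_iterations: int = 0

    def edge_probabilities(self) -> dict[str, float]:
        """Refined posterior inclusion probability per candidate regulator."""
        return {c: float(p) for c, p in zip(self.candidates, self.refined_inclusion)}


def _best_sort_key(m: ScoredModel):
    # higher score first; ties by smaller d, then lexicographic key
    return (-m.two_log_odds, m.d, m.key)


def prescreen(
    data: RegressionData,
    priors: PriorEdgeMatrix,
    target: str,
    nvar: int | str,
    g: float,
    backend: str = "gprior",
) -> list[str]:
    """Rank candidates by their single-predictor model score and keep the top nvar.

    Each candidate h is scored as the one-variable model {h} (its univariate
    R^2 plus its prior log-odds); ties are broken by higher prior probability,
    then lexicographic gene id.
    """
    plo = priors.log_odds_for_target(target, data.candidate_ids)
    scorer = ModelScorer(data, plo, backend=backend)
    pi = priors.probs_for_target(target, data.candidate_ids)
    scored = []
    for h, gene in enumerate(data.candidate_ids):
        s = scorer.score((h,), g).two_log_odds
        scored.append((-s, -pi[h], gene))
    order = sorted(range(data.p), key=lambda h: scored[h])
    if nvar == "all":
        keep = order
    else:
        keep = order[: int(nvar)]
    return [data.candidate_ids[h] for h in keep]


def scan(scorer: ModelScorer, g: float, opts: ScanOptions) -> list[ScoredModel]:
    """Find all models in Occam's window by active-set search.

    Returns every evaluated model whose 2*log odds is within 2*log(C) of the
    best model found, sorted best-first (ties by smaller size, then
    lexicographic key).  Deterministic: neighbours are generated in ascending
    candidate-index order and the frontier is processed in sorted order.
    """
    width = opts.window_width
    max_d = opts.max_model_size if opts.max_model_size is not None else scorer.n - 2
    max_d = min(max_d, scorer.p, scorer.n - 2)

    evaluated: dict[ModelKey, ScoredModel] = {}
    null = scorer.score((), g)
    evaluated[()] = null
    best = null
    expanded: set[ModelKey] = set()

    def neighbours(key: ModelKey):
        members = set(key)
        for h in range(scorer.p):  # ascending index order: deterministic
            if h in members:
                yield tuple(i for i in key if i != h)
            elif len(key) < max_d:
                yield model_key(key + (h,))

    while True:
        frontier = sorted(
            k
            for k, m in evaluated.items()
            if k not in expanded and m.two_log_odds >= best.two_log_odds - width
        )
        if not frontier:
            break
        for key in frontier:
            expanded.add(key)
            for nb in neighbours(key):
                if nb in evaluated:
                    continue
                sm = scorer.score(nb, g)
                evaluated[nb] = sm
                if _best_sort_key(sm) < _best_sort_key(best):
                    best = sm

    window = [m for m in evaluated.values() if m.two_log_odds >= best.two_log_odds - width]
    window.sort(key=_best_sort_key)
    return window


def refine_inclusion(
    result: "BMAResult", scorer: ModelScorer, g: float | None = None
) -> np.ndarray:
    """Refine saturated (0 or 1) inclusion probabilities via best-model odds.

    For a regulator h with raw probability ~1, O = odds of the best model to
    the best model with h removed; refined = O/(1+O) < 1.  For raw ~0, O =
    odds of the best model to the best model with h added; refined =
    1/(1+O) > 0.  Intermediate probabilities are left as they are.  All
    outputs are clamped strictly inside (0, 1).
    """
    if g is None:
        g = result.g
    best = min(result.window_models, key=_best_sort_key)
    raw = np.asarray(result.inclusion, dtype=float)
    refined = raw.copy()
    max_d = scorer.n - 2
    for h in range(len(raw)):
        if raw[h] >= 1.0 - SATURATION_TOL:
            if h not in best.key:  # numerically saturated but absent from best: keep raw
                continue
            reduced = tuple(i for i in best.key if i != h)
            delta = best.two_log_odds - scorer.score(reduced, g).two_log_odds
            refined[h] = float(expit(delta / 2.0))  # O/(1+O) with O = exp(delta/2)
        elif raw[h] <= SATURATION_TOL:
            if h in best.key:
                continue
            if best.d + 1 > max_d:
                continue  # cannot score the enlarged model; keep (clamped) raw
            enlarged = model_key(best.key + (h,))
            delta = best.two_log_odds - scorer.score(enlarged, g).two_log_odds
            refined[h] = float(expit(-delta / 2.0))  # 1/(1+O)
    return np.clip(refined, REFINE_CLAMP, 1.0 - REFINE_CLAMP)


def fit_target(
    ts: ExpressionTimeSeries,
    target: str,
    priors: PriorEdgeMatrix,
    opts: ScanOptions | None = None,
    candidates: list[str] | None = None,
) -> BMAResult:
    """Full per-target fit: design, prescreen, (EM-)g, scan, averaging, refinement.

    ``ts`` must already be transformed as desired (see
    :func:`scanbma.transform.apply_transform`); this function does not
    transform.  Deterministic for fixed inputs.
    """
    from .em import em_loop  # local import to avoid a cycle

    if opts is None:
        opts = ScanOptions()
    data = build_lagged_design(ts, target, candidates=candidates)

    g0 = float(data.n) if opts.g == "em" else float(opts.g)
    kept = prescreen(data, priors, target, opts.nvar, g0, backend=opts.score)
    data = data.subset([data.candidate_ids.index(c) for c in kept])
    plo = priors.log_odds_for_target(target, data.candidate_ids)
    scorer = ModelScorer(data, plo, backend=opts.score)

    em_converged: bool | None = None
    em_iterations = 0
    if opts.g == "em" and opts.score == "gprior":
        state, models, weights = em_loop(scorer, opts)
        g = state.g
        em_converged = state.converged
        em_iterations = state.iteration
    else:
        g = g0
        models = scan(scorer, g, opts)
        weights = model_weights(models)

    inclusion = inclusion_probabilities(models, weights, data.p)
    result = BMAResult(
        target=target,
        candidates=list(data.candidate_ids),
        window_models=models,
        weights=weights,
        g=g,
        inclusion=inclusion,
        refined_inclusion=inclusion,  # placeholder, replaced below
        em_converged=em_converged,
        em_iterations=em_iterations,
    )
    result.refined_inclusion = refine_inclusion(result, scorer, g)
    return result
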