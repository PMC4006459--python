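"""Synthetic sparse networks and autoregressive time-series for end-to-end testing.

The generator mirrors the statistical structure the inference model assumes:
a sparse directed network whose per-gene in-degree follows a geometric law
with mean 2.76 (the empirical mean number of transcription factors per yeast
gene, truncated at 13, the largest observed), linear-Gaussian lag-1 dynamics
with a per-gene autoregressive self term, and a common exponentially
decaying trajectory shared by all genes and replicates that emulates the
transcriptome-wide transient after a drug perturbation.  The default shape
(10 genes, 21 time points, 5 replicates) matches the DREAM4 10-gene
challenge data.

All draws come from one seeded generator stream in a documented order
(in-degrees, then parents and coefficients gene by gene, then self
coefficients, then initial values and noise), so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import (
    ExpressionTimeSeries,
    GoldStandard,
    write_gold_standard_edges,
)

__all__ = [
    "SimulationConfig",
    "TrueNetwork",
    "sample_network",
    "simulate_timeseries",
    "simulate_dataset",
    "gold_standard_from_network",
    "write_gold_standard",
]

MAX_IN_DEGREE = 13  # largest regulator count observed per yeast target gene
OVERFLOW_LIMIT = 1e8


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults: DREAM4 10-gene shape (10 genes x 21 times x 5 replicates),
    mean in-degree 2.76, regulatory coefficients +/-0.8, self-autoregression
    0.5, noise sd 0.25 and a unit-amplitude common perturbation trajectory.
    """

    genes: int = 10
    times: int = 21
    replicates: int = 5
    mean_in_degree: float = 2.76
    coefficient_scale: float = 0.8
    self_ar: float = 0.5
    noise_sd: float = 0.25
    amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.genes, self.times, self.replicates) < 1:
            raise ValueError("genes, times and replicates must all be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be positive")
        if self.mean_in_degree < 0:
            raise ValueError("mean in-degree must be non-negative")
        if not -1.0 < self.self_ar < 1.0:
            raise ValueError("self_ar must lie in (-1, 1)")

    def gene_ids(self) -> list[str]:
        width = len(str(self.genes))
        return [f"G{i + 1:0{width}d}" for i in range(self.genes)]

    def replicate_ids(self) -> list[str]:
        return [f"R{s + 1}" for s in range(self.replicates)]


@dataclass
class TrueNetwork:
    """Ground-truth directed network with generative coefficients."""

    gene_ids: list[str]
    edges: dict[tuple[str, str], float]  # (regulator, target) -> beta
    alphas: dict[str, float]

    def __post_init__(self) -> None:
        for (r, t) in self.edges:
            if r == t:
                raise ValueError("self-edges belong in the alpha terms, not the edge set")
        indeg: dict[str, int] = {}
        for (_, t) in self.edges:
            indeg[t] = indeg.get(t, 0) + 1
        too_many = {t: k for t, k in indeg.items() if k > MAX_IN_DEGREE}
        if too_many:
            raise ValueError(f"in-degree above {MAX_IN_DEGREE}: {too_many}")

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.edges)

    def parents(self, target: str) -> list[str]:
        return [r for (r, t) in self.edges if t == target]


#: stabilisation target for the lag-1 coefficient matrix (self + regulatory)
STABILITY_MARGIN = 0.95


def _spectral_radius(ids, edges, alphas) -> float:
    """Spectral radius of the combined lag-1 coefficient matrix."""
    n = len(ids)
    idx = {g: i for i, g in enumerate(ids)}
    if n > 2000:  # sparse path for genome-scale networks
        from scipy.sparse import coo_matrix
        from scipy.sparse.linalg import eigs

        rows = [idx[t] for (_, t) in edges] + list(range(n))
        cols = [idx[r] for (r, _) in edges] + list(range(n))
        vals = [b for b in edges.values()] + [alphas[g] for g in ids]
        A = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        try:
            return float(np.max(np.abs(eigs(A, k=1, which="LM",
                                            return_eigenvectors=False, tol=1e-6))))
        except Exception:  # rare non-convergence: fall through to row-sum bound
            return float(np.max(np.abs(A).sum(axis=1)))
    A = np.diag([alphas[g] for g in ids]).astype(float)
    for (r, t), b in edges.items():
        A[idx[t], idx[r]] = b
    return float(np.max(np.abs(np.linalg.eigvals(A))))


def sample_network(cfg: SimulationConfig) -> TrueNetwork:
    """Draw a sparse directed network with stationary lag-1 dynamics.

    Per-gene in-degrees are geometric on {0, 1, 2, ...} with the configured
    mean, truncated at min(13, genes - 1); parents are sampled uniformly
    without replacement; coefficients are +/- coefficient_scale with random
    sign; self coefficients are the configured self_ar.  If the combined
    lag-1 coefficient matrix is explosive (spectral radius >= 1, the matrix
    analogue of |alpha_i| + sum_h |beta_hi| >= 1), all coefficients are
    rescaled uniformly to spectral radius ``STABILITY_MARGIN`` so that the
    simulated trajectories are stationary — the standard stabilisation used
    for vector-autoregressive benchmark generators.
    """
    if cfg.genes < 2:
        raise ValueError("need at least 2 genes to sample a network")
    rng = np.random.default_rng(cfg.seed)
    ids = cfg.gene_ids()
    cap = min(MAX_IN_DEGREE, cfg.genes - 1)
    if cfg.mean_in_degree == 0:
        degrees = np.zeros(cfg.genes, dtype=int)
    else:
        p = 1.0 / (1.0 + cfg.mean_in_degree)
        degrees = np.minimum(rng.geometric(p, size=cfg.genes) - 1, cap)
    edges: dict[tuple[str, str], float] = {}
    for i, target in enumerate(ids):
        # draw from genes-1 slots and skip the target's own index
        parents = rng.choice(cfg.genes - 1, size=int(degrees[i]), replace=False)
        for j in sorted(parents):
            h = j if j < i else j + 1
            sign = 1.0 if rng.random() < 0.5 else -1.0
            edges[(ids[h], target)] = sign * cfg.coefficient_scale
    alphas = {g: cfg.self_ar for g in ids}

    rho = _spectral_radius(ids, edges, alphas)
    if rho >= 1.0:
        c = STABILITY_MARGIN / rho
        edges = {e: b * c for e, b in edges.items()}
        alphas = {g: a * c for g, a in alphas.items()}
    return TrueNetwork(gene_ids=ids, edges=edges, alphas=alphas)


def simulate_timeseries(net: TrueNetwork, cfg: SimulationConfig) -> ExpressionTimeSeries:
    """Simulate lag-1 linear-Gaussian dynamics on the network.

    X[i,1,s] ~ N(0,1); for t >= 2,
    X[i,t,s] = m(t) + alpha_i X[i,t-1,s] + sum_parents beta_hi X[h,t-1,s] + eps,
    eps ~ N(0, noise_sd^2), with the common trajectory
    m(t) = amplitude * exp(-(t-1)) shared by all genes and replicates.
    Raises if the dynamics diverge (values overflow); that indicates the
    combined coefficient magnitudes |alpha_i| + sum |beta_hi| are too large.
    """
    rng = np.random.default_rng(cfg.seed + 1)  # distinct stream from sample_network
    ids = net.gene_ids
    n_g, n_t, n_s = len(ids), cfg.times, cfg.replicates
    idx = {g: i for i, g in enumerate(ids)}
    A = np.zeros((n_g, n_g))
    for (r, t), beta in net.edges.items():
        A[idx[t], idx[r]] = beta
    alphas = np.array([net.alphas[g] for g in ids])

    values = np.empty((n_g, n_t, n_s))
    values[:, 0, :] = rng.standard_normal((n_g, n_s))
    for t in range(1, n_t):
        m_t = cfg.amplitude * np.exp(-float(t - 1))  # 1-based t: exp(-(t-1)) with t = step+1
        noise = rng.normal(0.0, cfg.noise_sd, size=(n_g, n_s))
        prev = values[:, t - 1, :]
        values[:, t, :] = m_t + alphas[:, None] * prev + A @ prev + noise
        if not np.all(np.isfinite(values[:, t, :])) or np.max(np.abs(values[:, t, :])) > OVERFLOW_LIMIT:
            raise ValueError(
                "simulated dynamics diverged; reduce coefficient magnitudes "
                "(|alpha_i| + sum_h |beta_hi| is too large)"
            )
    times = np.arange(n_t, dtype=float)
    return ExpressionTimeSeries(ids, times, cfg.replicate_ids(), values)


def simulate_dataset(cfg: SimulationConfig) -> tuple[TrueNetwork, ExpressionTimeSeries]:
    """Convenience: sample a network and simulate one dataset from it."""
    net = sample_network(cfg)
    return net, simulate_timeseries(net, cfg)


def gold_standard_from_network(net: TrueNetwork, evaluable_only: bool = False) -> GoldStandard:
    """Gold standard from the true edge set.

    With ``evaluable_only`` the partial-assessment regulator set is attached:
    genes with out-degree > 0 (the simulated analogue of transcription
    factors with documented targets).  Since the simulated truth is complete,
    the default evaluates over all pairs.
    """
    regulators = frozenset(r for (r, _) in net.edges) if evaluable_only else None
    return GoldStandard(edges=frozenset(net.edges), regulators=regulators or None)


def write_gold_standard(net: TrueNetwork, path, regulators_path=None) -> None:
    """Write the true edges as TSV triples (regulator, target, 1); optionally
    also write the evaluable-regulator list (genes with out-degree > 0)."""
    write_gold_standard_edges(net.edge_set, path)
    if regulators_path is not None:
        regulators = sorted({r for (r, _) in net.edges})
        with open(regulators_path, "w") as fh:
            for r in regulators:
                fh.write(f"{r}\n")
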