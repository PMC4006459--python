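# Methods

## Model

For each target gene *i*, regulators are selected in the lag-1 linear model

    X[i,t,s] = b0 + sum_{h in M} b_h X[h,t-1,s] + eps[i,t,s],
    eps ~ iid N(0, s^2),

over t = 2..T and replicates/strains s = 1..S, giving n = S·(T−1) stacked
observations per regression. A model M is a subset of candidate regulators;
the quantity reported per edge is the posterior inclusion probability
Pr(b_h ≠ 0 | D) = Σ_k 1(h ∈ M_k) Pr(M_k | D), i.e. the summed posterior
weight of the models containing the regulator.

### Priors and scores

Coefficients carry Zellner's g-prior b | s² ~ N(0, g·s²·(XᵀX)⁻¹) on the
centered design, with a flat prior on the intercept and p(s²) ∝ 1/s².
This yields a closed-form Bayes factor against the intercept-only null:

    2 log BF_k = (n − d_k − 1) log(1+g) − (n − 1) log(1 + g (1 − R²_k)),

with d_k = |M_k| and R²_k the intercept-adjusted coefficient of
determination. Model-space priors enter through per-edge probabilities
π_hi: Pr(M) ∝ Π_{h∈M} π_hi Π_{h∉M} (1 − π_hi), contributing
2 Σ_{h∈M} log(π_hi/(1−π_hi)) to the 2·log posterior odds. The orientation
(larger score = more probable model) is verified in the test suite against
a numerically integrated marginal-likelihood ratio: the coefficient prior
is marginalised by the linear-Gaussian identity and the remaining
(intercept, log sigma) integral evaluated by adaptive 2-D quadrature, with
a fully numerical 3-D integral validating that oracle in turn. A BIC-based
score, −n log(1−R²) − d log n + prior term, is available as an alternative
backend and agrees in ranking with the g-prior at g = n (the unit
information prior) on well-separated models.

Prior probabilities of exactly 0 or 1 would make the log-odds infinite;
they are clipped to [1e-8, 1−1e-8] with a warning. R² is clamped below
1 by 1e-12 so the score stays finite on collinear toys; models with
d > n − 2 are outside the model space (the (n−d−1) factor degenerates).

### Occam's window search

The averaging set is Occam's window: models whose posterior probability is
within a factor C of the best model found, i.e. within 2·ln C on the
2·log-odds scale. C defaults to 100, a conventional strong-evidence cutoff.
The search keeps an active set initialised at the null model — the natural
anchor of the odds scale — and repeatedly expands every window model that
has not yet been expanded, scoring all single-add and single-drop
neighbours (generated in ascending candidate-index order, for determinism).
Because the best score only improves, the window threshold only rises, so a
model once outside the window can never re-enter; the returned window is
exactly the set of evaluated models within 2·ln C of the final best.
Expansion continues until every window member has been expanded, which is
the strongest termination rule consistent with the active-set idea and, on
random instances up to p = 12, reproduces the exhaustively enumerated
window exactly (test suite). R² values are memoised per model and shared
across sweeps and EM iterations; only the g-dependent score terms are
recomputed when g changes. Ties in "best model" break toward smaller d,
then lexicographic candidate indices. Only the symmetric factor-C window is
applied; the stricter variant that also discards models with better-scoring
nested submodels is not.

### Candidate prescreening (nvar)

Before the search, candidates are ranked by their single-predictor model
score (univariate R² plus the edge's prior log-odds) and the top nvar are
kept; ties break by higher prior probability, then gene id. nvar defaults
to 20: yeast target genes are regulated by ~2.76 factors on average and at
most 13 in curated data, so 20 leaves margin. nvar = "all" disables the
prescreen.

### Estimating g

g controls the prior spread of the coefficients; g = n is the unit
information prior, and g is constrained to [1, n] (a prior more diffuse
than the unit-information one is not recommended, and g < 1 would bury
even ideal coefficients in prior noise). g is estimated by maximum
marginal likelihood over the model space with an EM algorithm whose
missing data are the model-membership indicators: the E-step runs the
window search at the current g and computes posterior model weights w_k;
the M-step maximises

    Q(g) = Σ_k w_k [ (n − d_k − 1) log(1+g) − (n − 1) log(1 + g (1 − R²_k)) ]

over [1, n] by bounded scalar optimisation with explicit endpoint checks
(the no-signal case has its maximiser exactly at g = 1; a flat Q leaves g
unchanged). Iteration starts at g = n and stops when |Δg| ≤ 1e-6·max(1, g)
or after 100 iterations (a warning flags non-convergence; conventional
choices, as the stopping rule is not otherwise dictated). After
convergence one final scan at the converged g makes scores, weights and g
mutually consistent.

### Refined inclusion probabilities

Because the window omits most of the model space, raw inclusion
probabilities saturate at 0 or 1 for many regulators. For a regulator at
~1, the odds O of the best model against the best model with that
regulator removed give the refined probability O/(1+O); for a regulator at
~0, the odds O against the best model with it added give 1/(1+O). The
modified models are scored fresh (through the memoising scorer) rather
than looked up in the window, so the refinement is defined even when the
modified model was never visited. Intermediate probabilities are left
unchanged; all outputs are clamped strictly inside (0, 1). Refinement
yields a strict ordering within each saturated group, which is what the
rank-based evaluation metrics consume.

## Data transformations

Two transformations precede inference, in this order:

1. **Time adjustment** subtracts the per-(gene, time) mean across
   replicates, removing any trajectory shared by all replicates — e.g. the
   transcriptome-wide transient after a drug perturbation, which otherwise
   induces correlations between every gene pair.
2. **Self-detrending** replaces each gene by the residuals of its
   no-intercept lag-1 self-regression X[i,t] = a_i X[i,t-1] + delta, with
   a_i estimated by least squares over all S(T−1) pairs; the output loses
   the first time point. A gene whose lagged values are identically zero
   gets a_i := 0 (residuals then equal the input, avoiding 0/0).

The self-regression is estimated on time-adjusted values (the two steps are
sequential; `--transform` exposes `none`, `time` and `time+self` for
comparison). The design choice of no intercept follows the regression form
of the self-trend model; step 1 has already centered the data across
replicates.

## The simulator

The generator mirrors the structure the inference model assumes, which is
what makes clean parameter-recovery testing possible — it is deliberately
not a realistic kinetic simulator.

- **Network**: per-gene in-degree geometric with mean 2.76 (the empirical
  mean number of transcription factors per yeast gene), truncated at
  min(13, genes−1) (13 is the largest curated in-degree); parents uniform
  without replacement; regulatory coefficients ±0.8 with random sign; a
  self-coefficient of 0.5 per gene.
- **Stabilisation**: if the combined lag-1 coefficient matrix (self +
  regulatory) has spectral radius ≥ 1 — the matrix analogue of
  |a_i| + Σ|b_hi| ≥ 1 — all coefficients are rescaled uniformly to
  spectral radius 0.95. This is the standard stationarity guarantee for
  vector-autoregressive benchmark generators; without it, dense draws
  explode within the 21-step horizon and all genes collapse onto one
  dominant mode, which tests nothing about sparse recovery. A uniform
  rescale preserves the relative coefficient structure (per-gene row-sum
  normalisation was rejected: it crushes hub-gene coefficients and with
  them the signal the recovery study measures). `simulate_timeseries`
  still raises on hand-built networks whose trajectories actually diverge.
- **Dynamics**: X[i,1,s] ~ N(0,1); for t ≥ 2, X[i,t,s] = m(t) +
  a_i X[i,t-1,s] + Σ_parents b_hi X[h,t-1,s] + N(0, 0.25²), with the
  shared trajectory m(t) = amplitude·exp(−(t−1)) emulating a post-drug
  transient (default amplitude 1; 5 in the transform-stress study).
- **Shape**: defaults of 10 genes × 21 time points × 5 replicates match
  the DREAM4 10-gene challenge data.
- **Seeding**: one generator stream for the network, one (offset) for the
  time series, draws in documented order; identical seeds give bit-identical
  data.

What passing recovery tests show — and what they do not: the simulated data
are linear, Gaussian, stationary and complete, with the generative model
inside the fitted model class. Success here demonstrates the correctness of
the search, scoring, EM and refinement machinery, not performance on real
expression data, where dynamics are nonlinear and saturating, noise is
heavy-tailed, measurements are sparse in time and the true model class is
unknown.

## Evaluation conventions

The universe is every ordered (regulator, target) pair among the genes
under evaluation, self-pairs excluded (the regression never proposes them;
the self-effect is handled by detrending). Pairs without an emitted edge
score 0 and rank below every emitted edge. Absent gold-standard edges count
as negatives even when the gold standard is known to be incomplete. The
partial assessment drops edges whose regulator is outside the evaluable
set (e.g. transcription factors with documented targets) before any metric.
AUROC is the Mann-Whitney statistic (average ranks; ties count half).
AUPRC accumulates precision·Δrecall over descending unique thresholds with
tied scores grouped into one step — the same convention as standard
average-precision implementations, cross-checked against one in the tests.
Precision at a cutoff counts thresholded edges (≥ cutoff) present/absent in
the gold standard; an empty prediction reports NaN. A caveat established
while testing: the average precision of a *random* ranking exceeds the
prevalence in finite universes (e.g. 0.041 at prevalence 0.038 with 2000
pairs); the tests compare Monte-Carlo means against the exact finite-sample
expectation rather than prevalence itself.

## Problem sizes in the test suite

The search is validated against exhaustive enumeration up to p = 12
candidates (4096 models) at n = 30; the score formula against quadrature at
n ≤ 8, d ≤ 2 over 50 instances; EM against 100,000-point grid searches; and
the recovery study runs 10 seeds of the 10-gene DREAM4 shape under four
configurations. These sizes exercise every code path while keeping the full
suite under a minute of compute apart from the quadrature tests.

## Known limitations

- Lag-1 linear dynamics only; no higher-order autoregression, smoothing or
  interpolation of irregular time grids.
- Missing observations are rejected at load time rather than imputed.
- The EM objective is maximised over a window set that itself changes with
  g; monotone ascent is guaranteed only on a fixed window (asserted as
  such in the tests), and convergence is to a fixed point, not a certified
  global maximum.
- The greedy window search can in principle miss window members not
  connected to the null model through within-window neighbours; this was
  never observed against enumeration at p ≤ 12.
- Constructing informative priors from external evidence is out of scope;
  the prior matrix is consumed as an input.
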