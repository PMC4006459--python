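"""Domain types and text-format I/O for expression data, edge priors and networks.

The canonical expression format is a long TSV with columns
``gene``, ``replicate``, ``time``, ``value`` on a complete
(gene x time x replicate) grid.  A DREAM4-style wide dialect
(``Time`` column plus one column per gene, replicates as consecutive
blocks) is supported as a convenience reader.

Prior edge probabilities are a regulator x target matrix of
probabilities pi_hi; the flat "Guelzim" prior sets every entry to
2.76/6000, the empirical mean number of transcription factors per
yeast gene over a ~6000-gene genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionTimeSeries",
    "PriorEdgeMatrix",
    "EdgeList",
    "GoldStandard",
    "GUELZIM_MEAN_REGULATORS",
    "GUELZIM_GENOME_SIZE",
    "PROB_CLIP",
    "read_expression_long",
    "write_expression_long",
    "read_expression_dream4",
    "read_prior_matrix",
    "guelzim_prior",
    "read_edge_list",
    "write_edge_list",
    "read_gold_standard",
    "read_regulator_list",
]

#: Empirical mean number of transcription factors regulating a yeast gene.
GUELZIM_MEAN_REGULATORS = 2.76
#: Approximate yeast genome size used to turn the mean in-degree into a
#: per-pair prior probability.
GUELZIM_GENOME_SIZE = 6000
#: Probabilities are clipped to [PROB_CLIP, 1 - PROB_CLIP] so that prior
#: log-odds stay finite.
PROB_CLIP = 1e-8


@dataclass
class ExpressionTimeSeries:
    """Expression values on a (gene, time, replicate) grid.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per row of ``values``.
    times
        Strictly increasing time stamps (arbitrary units).
    replicate_ids
        Strain/replicate identifiers, one per slab of ``values``.
    values
        Real array of shape ``(n_genes, n_times, n_replicates)``; must be
        finite (missing observations are rejected at load time).
    """

    gene_ids: list[str]
    times: np.ndarray
    replicate_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.replicate_ids = [str(r) for r in self.replicate_ids]
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene identifiers must be unique")
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("need at least 2 time points (lagged regression requires T >= 2)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time stamps must be strictly increasing")
        expected = (len(self.gene_ids), len(self.times), len(self.replicate_ids))
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"(genes, times, replicates) = {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (no missing values)")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_ids)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene identifier: {gene!r}") from None


@dataclass
class PriorEdgeMatrix:
    """Prior probability pi_hi that regulator h regulates target i.

    Entries are kept strictly inside (0, 1) by clipping to
    ``[PROB_CLIP, 1 - PROB_CLIP]`` so that the prior log-odds term of the
    model score is always finite.
    """

    regulator_ids: list[str]
    target_ids: list[str]
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.regulator_ids = [str(g) for g in self.regulator_ids]
        self.target_ids = [str(g) for g in self.target_ids]
        self.probs = np.asarray(self.probs, dtype=float)
        expected = (len(self.regulator_ids), len(self.target_ids))
        if self.probs.shape != expected:
            raise ValueError(f"prior matrix shape {self.probs.shape} != {expected}")
        if np.any(self.probs < 0) or np.any(self.probs > 1):
            raise ValueError("prior probabilities must lie in [0, 1]")
        if np.any(self.probs <= 0) or np.any(self.probs >= 1):
            warnings.warn(
                f"prior probabilities of exactly 0 or 1 clipped to "
                f"[{PROB_CLIP}, {1 - PROB_CLIP}] to keep log-odds finite",
                stacklevel=2,
            )
        self.probs = np.clip(self.probs, PROB_CLIP, 1 - PROB_CLIP)
        self._reg_index = {g: i for i, g in enumerate(self.regulator_ids)}
        self._tgt_index = {g: i for i, g in enumerate(self.target_ids)}

    def prob(self, regulator: str, target: str) -> float:
        return float(self.probs[self._reg_index[regulator], self._tgt_index[target]])

    def probs_for_target(self, target: str, regulators: list[str]) -> np.ndarray:
        """Prior probabilities for ``regulators`` -> ``target`` in that order."""
        j = self._tgt_index[target]
        rows = [self._reg_index[r] for r in regulators]
        return self.probs[rows, j]

    def log_odds_for_target(self, target: str, regulators: list[str]) -> np.ndarray:
        p = self.probs_for_target(target, regulators)
        return np.log(p / (1.0 - p))


@dataclass
class EdgeList:
    """Directed weighted edges (regulator, target, score in [0, 1])."""

    records: list[tuple[str, str, float]]
    allow_self_edges: bool = False

    def __post_init__(self) -> None:
        self.records = [(str(r), str(t), float(s)) for r, t, s in self.records]
        pairs = [(r, t) for r, t, _ in self.records]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (regulator, target) pairs in edge list")
        for r, t, s in self.records:
            if r == t and not self.allow_self_edges:
                raise ValueError(f"self-edge {r}->{t} not allowed")
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"edge score {s} outside [0, 1] for {r}->{t}")

    def __len__(self) -> int:
        return len(self.records)

    def sorted_records(self) -> list[tuple[str, str, float]]:
        """Deterministic order: probability descending, ties by (regulator, target)."""
        return sorted(self.records, key=lambda rec: (-rec[2], rec[0], rec[1]))

    def scores(self) -> dict[tuple[str, str], float]:
        return {(r, t): s for r, t, s in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.sorted_records(), columns=["regulator", "target", "probability"])


@dataclass
class GoldStandard:
    """Reference truth network: set of true directed edges, plus the optional
    set of regulators that are evaluable (e.g. known transcription factors)."""

    edges: frozenset[tuple[str, str]]
    regulators: frozenset[str] | None = None

    def __post_init__(self) -> None:
        self.edges = frozenset((str(r), str(t)) for r, t in self.edges)
        if self.regulators is not None:
            self.regulators = frozenset(str(r) for r in self.regulators)

    def is_true(self, regulator: str, target: str) -> bool:
        return (regulator, target) in self.edges


# ---------------------------------------------------------------------------
# expression readers / writers

_LONG_COLUMNS = ["gene", "replicate", "time", "value"]


def read_expression_long(path) -> ExpressionTimeSeries:
    """Read the canonical long TSV (gene, replicate, time, value).

    The grid must be complete: every (gene, time, replicate) combination
    present exactly once.  Gene and replicate order follow first appearance
    in the file; times are sorted ascending.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "replicate": str})
    missing_cols = [c for c in _LONG_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"expression file missing columns: {missing_cols}")
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = values.isna() & df["value"].notna()
    if bad.any() or df["value"].isna().any():
        line = int(df.index[values.isna()][0]) + 2  # +1 header, +1 one-based
        raise ValueError(f"non-numeric or missing expression value at line {line}")
    times_arr = pd.to_numeric(df["time"], errors="coerce")
    if times_arr.isna().any():
        line = int(df.index[times_arr.isna()][0]) + 2
        raise ValueError(f"non-numeric time stamp at line {line}")

    genes = list(dict.fromkeys(df["gene"]))
    reps = list(dict.fromkeys(df["replicate"]))
    times = np.array(sorted(set(times_arr)))

    gi = {g: i for i, g in enumerate(genes)}
    ti = {t: i for i, t in enumerate(times)}
    ri = {r: i for i, r in enumerate(reps)}

    block = np.full((len(genes), len(times), len(reps)), np.nan)
    seen = np.zeros(block.shape, dtype=bool)
    for g, r, t, v in zip(df["gene"], df["replicate"], times_arr, values):
        idx = (gi[g], ti[t], ri[r])
        if seen[idx]:
            raise ValueError(f"duplicate grid cell (gene={g}, time={t}, replicate={r})")
        seen[idx] = True
        block[idx] = v
    if not seen.all():
        g_, t_, r_ = (int(a[0]) for a in np.nonzero(~seen))
        raise ValueError(
            f"incomplete grid: missing cell (gene={genes[g_]}, "
            f"time={times[t_]}, replicate={reps[r_]})"
        )
    return ExpressionTimeSeries(genes, times, reps, block)


def write_expression_long(ts: ExpressionTimeSeries, path) -> None:
    """Write the canonical long TSV at full float precision (round-trip safe)."""
    rows = []
    for i, g in enumerate(ts.gene_ids):
        for s, rep in enumerate(ts.replicate_ids):
            for t, time in enumerate(ts.times):
                rows.append((g, rep, time, repr(float(ts.values[i, t, s]))))
    df = pd.DataFrame(rows, columns=_LONG_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_expression_dream4(path) -> ExpressionTimeSeries:
    """Read the DREAM4 time-series dialect.

    Format: a header line starting with ``Time`` followed by one column per
    gene; replicates appear as consecutive blocks, separated either by blank
    lines or by the time stamp resetting to the first value.  All blocks must
    share the same time grid.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    lines = text.splitlines()
    if not lines:
        raise ValueError("empty DREAM4 file")
    header = lines[0].rstrip("\n").split("\t")
    if not header or header[0].strip().strip('"').lower() != "time":
        raise ValueError("DREAM4 file must start with a 'Time' column header")
    genes = [h.strip().strip('"') for h in header[1:]]
    if not genes:
        raise ValueError("DREAM4 file has no gene columns")

    blocks: list[list[list[float]]] = []
    current: list[list[float]] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        line = raw.strip()
        if not line:
            if current:
                blocks.append(current)
                current = []
            continue
        fields = line.split("\t")
        if len(fields) != len(genes) + 1:
            raise ValueError(f"line {lineno}: expected {len(genes) + 1} columns, got {len(fields)}")
        try:
            row = [float(f) for f in fields]
        except ValueError:
            raise ValueError(f"line {lineno}: non-numeric value") from None
        if current and row[0] == current[0][0]:
            # time reset to the block's first stamp -> new replicate block
            blocks.append(current)
            current = []
        current.append(row)
    if current:
        blocks.append(current)
    if not blocks:
        raise ValueError("DREAM4 file contains no data rows")

    ref_times = [r[0] for r in blocks[0]]
    for b, block in enumerate(blocks):
        times_b = [r[0] for r in block]
        if len(times_b) != len(ref_times):
            raise ValueError(f"replicate block {b + 1} has {len(times_b)} rows, expected {len(ref_times)}")
        for j, (ta, tb) in enumerate(zip(ref_times, times_b)):
            if ta != tb:
                raise ValueError(f"replicate block {b + 1}, row {j + 1}: time {tb} differs from {ta}")

    n_g, n_t, n_s = len(genes), len(ref_times), len(blocks)
    values = np.empty((n_g, n_t, n_s))
    for s, block in enumerate(blocks):
        arr = np.asarray(block)  # (n_t, 1 + n_g)
        values[:, :, s] = arr[:, 1:].T
    reps = [f"R{s + 1}" for s in range(n_s)]
    return ExpressionTimeSeries(genes, np.asarray(ref_times, dtype=float), reps, values)


# ---------------------------------------------------------------------------
# priors

def read_prior_matrix(path, regulators: list[str], targets: list[str]) -> PriorEdgeMatrix:
    """Read a regulator x target prior TSV (first column regulator ids,
    header row target ids), reordered to the supplied id lists."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    unknown = [g for g in regulators if g not in df.index]
    unknown += [g for g in targets if g not in df.columns]
    if unknown:
        raise ValueError(f"prior matrix missing identifiers: {unknown}")
    probs = df.loc[regulators, targets].to_numpy(dtype=float)
    if np.any(~np.isfinite(probs)):
        raise ValueError("prior matrix contains non-finite entries")
    if np.any(probs < 0):
        raise ValueError("prior matrix contains negative entries")
    if np.any(probs > 1):
        raise ValueError("prior matrix contains entries greater than 1")
    return PriorEdgeMatrix(list(regulators), list(targets), probs)


def write_prior_matrix(prior: PriorEdgeMatrix, path) -> None:
    df = pd.DataFrame(prior.probs, index=prior.regulator_ids, columns=prior.target_ids)
    df.to_csv(path, sep="\t")


def guelzim_prior(regulators: list[str], targets: list[str]) -> PriorEdgeMatrix:
    """Flat prior pi_hi = 2.76/6000 for all pairs (expected in-degree 2.76
    over a 6000-gene candidate pool)."""
    if not regulators or not targets:
        raise ValueError("regulator and target id lists must be non-empty")
    p = GUELZIM_MEAN_REGULATORS / GUELZIM_GENOME_SIZE
    probs = np.full((len(regulators), len(targets)), p)
    return PriorEdgeMatrix(list(regulators), list(targets), probs)


# ---------------------------------------------------------------------------
# edge lists and gold standards

def write_edge_list(edges: EdgeList, path) -> None:
    """Write edges as TSV (regulator, target, probability to 6 decimals),
    sorted by descending probability, ties broken lexicographically."""
    with open(path, "w") as fh:
        fh.write("regulator\ttarget\tprobability\n")
        for r, t, s in edges.sorted_records():
            fh.write(f"{r}\t{t}\t{s:.6f}\n")


def read_edge_list(path, allow_self_edges: bool = False) -> EdgeList:
    df = pd.read_csv(path, sep="\t", dtype={"regulator": str, "target": str})
    records = list(zip(df["regulator"], df["target"], df["probability"].astype(float)))
    return EdgeList(records, allow_self_edges=allow_self_edges)


def read_gold_standard(path, regulators_path=None) -> GoldStandard:
    """Read gold-standard TSV triples ``regulator\\ttarget\\t{0|1}``
    (DREAM4 convention; absent pairs are treated as 0)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["regulator", "target", "flag"],
        dtype={"regulator": str, "target": str}, comment="#", skip_blank_lines=True,
    )
    # tolerate an optional header row
    if len(df) and str(df.iloc[0]["flag"]).strip().lower() in {"flag", "truth", "label"}:
        df = df.iloc[1:]
    edges = frozenset(
        (r, t) for r, t, f in zip(df["regulator"], df["target"], df["flag"]) if int(f) == 1
    )
    regulators = None
    if regulators_path is not None:
        regulators = frozenset(read_regulator_list(regulators_path))
    return GoldStandard(edges, regulators)


def write_gold_standard_edges(edges: set[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("regulator\ttarget\ttruth\n")
        for r, t in sorted(edges):
            fh.write(f"{r}\t{t}\t1\n")


def read_regulator_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
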