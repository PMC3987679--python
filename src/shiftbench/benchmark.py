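"""Similarity matrices, retrieval ranks, MRR and accuracy statistics.

The central object is the experimental x simulated similarity matrix: row i
holds the similarities of experimental spectrum i to every simulated
spectrum, and the correct match of row i is column i.  Each row is treated
as a retrieval query; predictors are scored by the Mean Reciprocal Rank

    MRR = (1/n) * sum_i 1 / rank_i,

by the cumulative fraction of correct matches within the n best hits, and by
the decomposition of each query's (best-match, correct-match) similarity
point into an absolute accuracy component along the identity direction and a
relative accuracy component orthogonal to it.  The traditional assigned
shift-error histogram is provided for validation against assigned data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .spectra_io import AssignmentTable, Spectrum
from .treesim import TreeParams, prepare_tree, tree_similarity

SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square similarity matrix; rows = experimental, columns = simulated.

    Row and column order share one molecule ordering, so entry (i, i) is the
    similarity of molecule i's experimental spectrum to its own simulation.
    """

    molecule_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "molecule_ids", tuple(self.molecule_ids))
        n = len(self.molecule_ids)
        if vals.shape != (n, n):
            raise ValueError(f"expected a {n}x{n} matrix, got {vals.shape}")
        if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
            raise ValueError("similarity values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.molecule_ids)

    def transposed(self) -> "SimilarityMatrix":
        """Swap query direction: simulated spectra query the experimental set."""
        return SimilarityMatrix(self.molecule_ids, self.values.T.copy())

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.molecule_ids, columns=self.molecule_ids)
        df.to_csv(path, index_label="molecule_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError(f"{path}: row and column molecule ids differ")
        return cls(tuple(str(m) for m in df.index), df.to_numpy(dtype=float))


@dataclass(frozen=True)
class QueryOutcome:
    """Outcome of one retrieval query: rank of and similarity to the match."""

    molecule_id: str
    rank: int
    s_correct: float
    s_best: float

    def __post_init__(self) -> None:
        if self.s_best < self.s_correct - 1e-12:
            raise ValueError(
                f"'{self.molecule_id}': s_best ({self.s_best}) < s_correct "
                f"({self.s_correct})"
            )


def similarity_matrix(
    experimental: Sequence[Spectrum],
    simulated: Sequence[Spectrum],
    p: TreeParams = TreeParams(),
) -> SimilarityMatrix:
    """Tree similarity of every experimental vs every simulated spectrum.

    The molecule_id lists must align element-wise; each spectrum's tree is
    built once and reused across the n^2 comparisons.
    """
    if len(experimental) != len(simulated):
        raise ValueError(
            f"{len(experimental)} experimental vs {len(simulated)} simulated spectra"
        )
    mismatches = [
        (e.molecule_id, s.molecule_id)
        for e, s in zip(experimental, simulated)
        if e.molecule_id != s.molecule_id
    ]
    if mismatches:
        raise ValueError(f"molecule id mismatches (experimental, simulated): {mismatches}")
    exp_trees = [prepare_tree(s, p) for s in experimental]
    sim_trees = [prepare_tree(s, p) for s in simulated]
    n = len(exp_trees)
    values = np.empty((n, n))
    for i, te in enumerate(exp_trees):
        for j, ts in enumerate(sim_trees):
            values[i, j] = tree_similarity(te, ts, p)
    return SimilarityMatrix(tuple(s.molecule_id for s in experimental), values)


def query_outcomes(m: SimilarityMatrix) -> list[QueryOutcome]:
    """Rank every row's correct match with the pessimistic tie rule.

    The rank is the worst position among entries tied with the correct
    match, i.e. the count of entries >= the diagonal entry.
    """
    out = []
    for i, mol in enumerate(m.molecule_ids):
        row = m.values[i]
        s_correct = float(row[i])
        rank = int(np.count_nonzero(row >= s_correct))
        out.append(QueryOutcome(mol, rank, s_correct, float(row.max())))
    return out


def mrr(outcomes: Sequence[QueryOutcome]) -> float:
    """Mean reciprocal rank of the correct matches; 1 iff every rank is 1."""
    if not outcomes:
        raise ValueError("mrr of an empty outcome list")
    return float(np.mean([1.0 / o.rank for o in outcomes]))


def cumulative_match_curve(
    outcomes: Sequence[QueryOutcome], n_max: int = 20
) -> np.ndarray:
    """Fraction of correct matches within the n best hits, for n = 1..n_max."""
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if not outcomes:
        raise ValueError("cumulative curve of an empty outcome list")
    ranks = np.array([o.rank for o in outcomes])
    return np.array([np.count_nonzero(ranks <= n) / len(ranks) for n in range(1, n_max + 1)])


def accuracy_components(o: QueryOutcome) -> tuple[float, float]:
    """Decompose a query point into absolute and relative accuracy.

    The point (s_best, s_correct) is projected onto the identity direction
    (absolute accuracy, growing toward the ideal at (1,1)) and onto the
    orthogonal direction (relative accuracy, zero exactly when the correct
    match is the best match; lower is better).
    """
    if o.s_correct > o.s_best + 1e-12:
        raise ValueError(f"'{o.molecule_id}': s_correct exceeds s_best")
    absolute = (o.s_best + o.s_correct) / SQRT2
    relative = max(0.0, (o.s_best - o.s_correct)) / SQRT2
    return absolute, relative


def accuracy_plane_summary(
    outcomes: Sequence[QueryOutcome],
) -> tuple[float, float, list[tuple[float, float]]]:
    """Mean absolute/relative accuracy plus the per-query (s_best, s_correct) points."""
    if not outcomes:
        raise ValueError("accuracy summary of an empty outcome list")
    comps = [accuracy_components(o) for o in outcomes]
    mean_abs = float(np.mean([c[0] for c in comps]))
    mean_rel = float(np.mean([c[1] for c in comps]))
    points = [(o.s_best, o.s_correct) for o in outcomes]
    return mean_abs, mean_rel, points


@dataclass(frozen=True)
class ShiftErrorHistogram:
    """Histogram of |observed - predicted| shift errors.

    ``fractions[k]`` is the fraction of assigned shifts in
    [edges[k], edges[k+1]); the final bin collects everything at or beyond
    the cutoff.  ``cumulative`` is the fraction of predictions within each
    successive deviation threshold.
    """

    edges: tuple[float, ...]  # inner bin edges, ending at the cutoff
    fractions: tuple[float, ...]
    cumulative: tuple[float, ...]
    n_pairs: int


def shift_error_histogram(
    tables: Sequence[AssignmentTable],
    bin_width: float = 0.1,
    cutoff: float = 0.35,
) -> ShiftErrorHistogram:
    """Pool assigned shift errors and bin them on ``bin_width`` ppm intervals
    up to ``cutoff`` ppm, plus an overflow bin."""
    errors = np.concatenate([t.errors() for t in tables]) if tables else np.empty(0)
    if errors.size == 0:
        raise ValueError("no assigned shift pairs supplied")
    inner = list(np.arange(0.0, cutoff - 1e-12, bin_width))
    inner.append(cutoff)
    edges = np.array(inner + [np.inf])
    counts, _ = np.histogram(errors, bins=edges)
    fractions = counts / errors.size
    cumulative = np.cumsum(fractions)
    return ShiftErrorHistogram(
        tuple(float(e) for e in inner),
        tuple(float(f) for f in fractions),
        tuple(float(c) for c in cumulative),
        int(errors.size),
    )


@dataclass
class BenchmarkReport:
    """All evaluation statistics for one predictor on one dataset."""

    predictor: str
    outcomes: list[QueryOutcome]
    mrr: float
    cumulative: list[float]
    mean_absolute_accuracy: float
    mean_relative_accuracy: float
    shift_errors: Optional[ShiftErrorHistogram] = None

    def to_dict(self) -> dict:
        d = {
            "predictor": self.predictor,
            "mrr": self.mrr,
            "cumulative": list(self.cumulative),
            "mean_absolute_accuracy": self.mean_absolute_accuracy,
            "mean_relative_accuracy": self.mean_relative_accuracy,
            "outcomes": [
                {
                    "molecule_id": o.molecule_id,
                    "rank": o.rank,
                    "s_correct": o.s_correct,
                    "s_best": o.s_best,
                }
                for o in self.outcomes
            ],
        }
        if self.shift_errors is not None:
            d["shift_errors"] = {
                "edges": list(self.shift_errors.edges),
                "fractions": list(self.shift_errors.fractions),
                "cumulative": list(self.shift_errors.cumulative),
                "n_pairs": self.shift_errors.n_pairs,
            }
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "BenchmarkReport":
        d = json.loads(Path(path).read_text())
        outcomes = [
            QueryOutcome(o["molecule_id"], o["rank"], o["s_correct"], o["s_best"])
            for o in d["outcomes"]
        ]
        sh = None
        if "shift_errors" in d:
            e = d["shift_errors"]
            sh = ShiftErrorHistogram(
                tuple(e["edges"]), tuple(e["fractions"]),
                tuple(e["cumulative"]), e["n_pairs"],
            )
        return cls(
            d["predictor"], outcomes, d["mrr"], d["cumulative"],
            d["mean_absolute_accuracy"], d["mean_relative_accuracy"], sh,
        )


def run_benchmark(
    experimental: Sequence[Spectrum],
    simulated: Sequence[Spectrum],
    p: TreeParams = TreeParams(),
    *,
    predictor: str = "predictor",
    n_max: int = 20,
    assignments: Optional[Sequence[AssignmentTable]] = None,
    query_direction: str = "experimental",
) -> BenchmarkReport:
    """Full evaluation of one predictor: matrix, ranks, MRR, curve, accuracy.

    ``query_direction='experimental'`` (default) queries each experimental
    spectrum against the simulated database; ``'simulated'`` reverses the
    direction.
    """
    if query_direction not in ("experimental", "simulated"):
        raise ValueError("query_direction must be 'experimental' or 'simulated'")
    m = similarity_matrix(experimental, simulated, p)
    if query_direction == "simulated":
        m = m.transposed()
    return report_from_matrix(m, predictor=predictor, n_max=n_max, assignments=assignments)


def report_from_matrix(
    m: SimilarityMatrix,
    *,
    predictor: str = "predictor",
    n_max: int = 20,
    assignments: Optional[Sequence[AssignmentTable]] = None,
) -> BenchmarkReport:
    """Assemble a :class:`BenchmarkReport` from a precomputed matrix."""
    outcomes = query_outcomes(m)
    n_max = min(n_max, m.n) if m.n else n_max
    mean_abs, mean_rel, _ = accuracy_plane_summary(outcomes)
    sh = shift_error_histogram(assignments) if assignments else None
    return BenchmarkReport(
        predictor,
        outcomes,
        mrr(outcomes),
        list(cumulative_match_curve(outcomes, n_max)),
        mean_abs,
        mean_rel,
        sh,
    )
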