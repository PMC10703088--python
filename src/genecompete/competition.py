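"""Win/loss/games matrices from multi-dataset pairwise logFC competitions.

Within each dataset every pair of candidate genes plays one match on the
competing score.  In up-regulation mode the higher score wins; in
down-regulation the lower score wins; in absolute mode the larger |score|
wins.  An exact score tie credits BOTH genes a win and neither a loss — the
sign-based pairwise construction is followed literally, so under ties
``w_ij + l_ij = n_ij`` still holds per player but ``l_ij = w_ji`` does not.

Two aggregation strategies are provided:

* intersection — candidates are the genes present in every dataset; every
  pair plays exactly ``k`` games (one per dataset).
* union — candidates are the genes whose score passes the regulation filter
  (``> thres`` up, ``< -thres`` down, ``|score| > thres`` absolute) in at
  least one dataset; pair (i, j) plays one game per dataset containing both,
  each candidate competing with its original, unfiltered score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from genecompete.errors import DegenerateCompetitionError, EmptyCompetitionError
from genecompete.gene_tables import GeneTable

logger = logging.getLogger(__name__)

Regulation = Literal["up", "down", "absolute"]
Strategy = Literal["intersection", "union"]

REGULATIONS = ("up", "down", "absolute")
STRATEGIES = ("intersection", "union")

DEFAULT_CANDIDATE_CAP = 10_000


@dataclass(frozen=True)
class CompetitionConfig:
    """Settings for one competition run.

    ``thres`` is the logFC filter used by the union strategy only; the
    intersection strategy ignores it.
    """

    regulation: Regulation = "up"
    strategy: Strategy = "intersection"
    thres: float = 0.0
    score_col: str = "logFC"
    candidate_cap: int = DEFAULT_CANDIDATE_CAP

    def __post_init__(self) -> None:
        if self.regulation not in REGULATIONS:
            raise ValueError(
                f"regulation must be one of {REGULATIONS}, got {self.regulation!r}"
            )
        if self.strategy not in STRATEGIES:
            raise ValueError(
                f"strategy must be one of {STRATEGIES}, got {self.strategy!r}"
            )
        if self.thres < 0:
            raise ValueError(f"thres must be non-negative, got {self.thres}")


@dataclass
class CompetitionMatrices:
    """Aggregated tournament state over a fixed candidate list.

    Attributes
    ----------
    genes
        Candidate gene list (lexicographic); all matrices are indexed by it.
    W, L
        N x N integer win / loss count matrices (``W[i, j]`` = matches gene i
        beat gene j).
    n
        N x N symmetric games matrix; ``n[i, j]`` = matches played between
        i and j.
    per_dataset
        One gene -> score mapping per input dataset, restricted to the
        candidates present in it (needed by sequential raters and oracles).
    k
        Number of input datasets.
    regulation
        Comparison mode the matrices were built under.
    """

    genes: list[str]
    W: np.ndarray
    L: np.ndarray
    n: np.ndarray
    per_dataset: list[dict[str, float]] = field(default_factory=list)
    k: int = 0
    regulation: Regulation = "up"

    @property
    def N(self) -> int:
        return len(self.genes)

    @property
    def Ni(self) -> np.ndarray:
        """Games played per gene: row sums of the games matrix."""
        return self.n.sum(axis=1)

    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def validate(self) -> None:
        """Assert the structural invariants; raises AssertionError on violation."""
        N = self.N
        for M in (self.W, self.L, self.n):
            assert M.shape == (N, N)
            assert np.all(M >= 0)
            assert np.all(np.diag(M) == 0)
        assert np.array_equal(self.n, self.n.T), "games matrix must be symmetric"
        assert np.array_equal(self.W + self.L, self.n), "w_ij + l_ij must equal n_ij"


def _effective_scores(scores: np.ndarray, regulation: Regulation) -> np.ndarray:
    """Transform scores so that 'larger is better' for every regulation mode."""
    if regulation == "up":
        return scores
    if regulation == "down":
        return -scores
    return np.abs(scores)


def compare_within_dataset(
    scores: Mapping[str, float], regulation: Regulation = "up"
) -> tuple[np.ndarray, np.ndarray]:
    """Play all pairwise matches within one dataset.

    Returns ``(W, L)`` over the genes of ``scores`` in their mapping order.
    Gene i beats gene j when its effective score is >= gene j's, so an exact
    tie yields a win for both and a loss for neither; ``L = 1 - W``
    off-diagonal otherwise.
    """
    genes = list(scores)
    if len(genes) < 2:
        raise DegenerateCompetitionError(
            f"need at least 2 genes to compete, got {len(genes)}"
        )
    s = _effective_scores(
        np.asarray([scores[g] for g in genes], dtype=float), regulation
    )
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    # sign(sign(s_i - s_j) + 1): 1 when s_i >= s_j, 0 otherwise
    diff = s[:, None] - s[None, :]
    W = np.sign(np.sign(diff) + 1).astype(np.int64)
    np.fill_diagonal(W, 0)
    L = np.abs(np.sign(W - 1)).astype(np.int64)
    np.fill_diagonal(L, 0)
    return W, L


def build_intersection(
    tables: Sequence[GeneTable], config: CompetitionConfig
) -> CompetitionMatrices:
    """Aggregate matches over the genes common to every dataset.

    Every pair plays exactly ``k`` games, so ``n[i, j] = k`` off-diagonal and
    each gene plays ``k * (N - 1)`` games in total.
    """
    if not tables:
        raise EmptyCompetitionError("no input tables")
    if len(tables) == 1:
        logger.warning("single input table: running a k=1 competition")

    common: set[str] = set(tables[0].records)
    for t in tables[1:]:
        common &= set(t.records)
    if not common:
        raise EmptyCompetitionError(
            "intersection of gene sets is empty; no candidates to rank"
        )
    genes = sorted(common)
    N = len(genes)
    if N < 2:
        raise DegenerateCompetitionError(
            f"only {N} gene(s) in the intersection; nothing to compare"
        )

    k = len(tables)
    W = np.zeros((N, N), dtype=np.int64)
    L = np.zeros((N, N), dtype=np.int64)
    per_dataset = []
    for t in tables:
        scores = {g: t.records[g].logFC for g in genes}
        w, l = compare_within_dataset(scores, config.regulation)
        W += w
        L += l
        per_dataset.append(scores)

    n = np.full((N, N), k, dtype=np.int64)
    np.fill_diagonal(n, 0)
    cm = CompetitionMatrices(
        genes=genes, W=W, L=L, n=n, per_dataset=per_dataset, k=k,
        regulation=config.regulation,
    )
    cm.validate()
    return cm


def _passes_filter(logfc: float, regulation: Regulation, thres: float) -> bool:
    if regulation == "up":
        return logfc > thres
    if regulation == "down":
        return logfc < -thres
    return abs(logfc) > thres


def build_union(
    tables: Sequence[GeneTable], config: CompetitionConfig
) -> CompetitionMatrices:
    """Aggregate matches over the union of filter-passing genes.

    A candidate present in a dataset competes there with its original score
    even if it failed the filter in that particular dataset; genes absent
    from a dataset simply contribute zero rows/columns for it, and
    ``n[i, j]`` counts the datasets containing both i and j.
    """
    if not tables:
        raise EmptyCompetitionError("no input tables")
    if len(tables) == 1:
        logger.warning("single input table: running a k=1 competition")

    candidates: set[str] = set()
    for t in tables:
        candidates.update(
            g for g, rec in t.records.items()
            if _passes_filter(rec.logFC, config.regulation, config.thres)
        )
    if not candidates:
        raise EmptyCompetitionError(
            f"no gene passes the {config.regulation} filter at thres={config.thres}"
        )
    genes = sorted(candidates)
    N = len(genes)
    if N < 2:
        raise DegenerateCompetitionError(
            f"only {N} candidate gene(s) after filtering; nothing to compare"
        )
    if N > config.candidate_cap:
        logger.warning(
            "%d candidate genes exceed the recommended cap of %d; "
            "consider raising the logFC threshold",
            N, config.candidate_cap,
        )

    k = len(tables)
    idx = {g: i for i, g in enumerate(genes)}
    W = np.zeros((N, N), dtype=np.int64)
    L = np.zeros((N, N), dtype=np.int64)
    n = np.zeros((N, N), dtype=np.int64)
    per_dataset = []
    for t in tables:
        present = [g for g in genes if g in t.records]
        scores = {g: t.records[g].logFC for g in present}
        per_dataset.append(scores)
        if len(present) < 2:
            continue
        w, l = compare_within_dataset(scores, config.regulation)
        rows = np.asarray([idx[g] for g in present])
        W[np.ix_(rows, rows)] += w
        L[np.ix_(rows, rows)] += l
        ones = np.ones((len(rows), len(rows)), dtype=np.int64)
        np.fill_diagonal(ones, 0)
        n[np.ix_(rows, rows)] += ones

    cm = CompetitionMatrices(
        genes=genes, W=W, L=L, n=n, per_dataset=per_dataset, k=k,
        regulation=config.regulation,
    )
    cm.validate()
    return cm


def build_competition(
    tables: Sequence[GeneTable], config: CompetitionConfig
) -> CompetitionMatrices:
    """Dispatch to :func:`build_intersection` or :func:`build_union`."""
    if config.strategy == "intersection":
        return build_intersection(tables, config)
    return build_union(tables, config)


def export_matrices(cm: CompetitionMatrices, prefix: str, sep: str = ",") -> None:
    """Dump W/L/n as labelled delimited text for debugging."""
    import pandas as pd

    for label, M in (("W", cm.W), ("L", cm.L), ("n", cm.n)):
        pd.DataFrame(M, index=cm.genes, columns=cm.genes).to_csv(
            f"{prefix}.{label}.csv", sep=sep
        )
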