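"""Eight rating algorithms over a pairwise competition.

All methods consume a :class:`~genecompete.competition.CompetitionMatrices`
and return a :class:`RatingResult`; none of them uses randomness, so results
are fully deterministic.  Iterative solvers (Keener, Markov, PageRank) start
from the uniform vector and stop when the max-abs change drops below
``params.tol``.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import rankdata

from genecompete.competition import CompetitionMatrices
from genecompete.errors import ConvergenceError, DegenerateCompetitionError
from genecompete.errors import GeneCompeteError

logger = logging.getLogger(__name__)

#: canonical method identifiers, in reporting order
METHODS = (
    "winloss",
    "massey",
    "colley",
    "keener",
    "elo",
    "markov",
    "pagerank",
    "bipagerank",
)


@dataclass(frozen=True)
class RankerParams:
    """Tunable constants shared by the rating algorithms."""

    elo_f: float = 10.0
    elo_init: float = 1500.0
    elo_logistic_scale: float = 400.0
    alpha: float = 0.85
    tol: float = 1e-10
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.tol <= 0:
            raise ValueError(f"tol must be positive, got {self.tol}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")


@dataclass
class RatingResult:
    """Scores and 1-based ranks (average on ties) for one method."""

    method: str
    scores: dict[str, float]
    ranks: dict[str, float] = field(default_factory=dict)
    wall_time: float = 0.0

    def __post_init__(self) -> None:
        if not self.ranks:
            self.ranks = _ranks_from_scores(self.scores)

    def top(self, n: int) -> list[str]:
        """The n best genes by rank (ties broken lexicographically)."""
        return sorted(self.scores, key=lambda g: (self.ranks[g], g))[:n]


def _ranks_from_scores(scores: dict[str, float]) -> dict[str, float]:
    genes = list(scores)
    vals = np.asarray([scores[g] for g in genes], dtype=float)
    ranks = rankdata(-vals, method="average")
    return {g: float(r) for g, r in zip(genes, ranks)}


def _result(method: str, cm: CompetitionMatrices, vec: np.ndarray) -> RatingResult:
    return RatingResult(method=method, scores={g: float(v) for g, v in zip(cm.genes, vec)})


def _require_pairs(cm: CompetitionMatrices) -> None:
    if cm.N < 2:
        raise DegenerateCompetitionError(f"need >= 2 genes, got {cm.N}")


def rank_winloss(cm: CompetitionMatrices) -> RatingResult:
    """Sum over opponents of the win fraction w_ij / n_ij.

    Pairs that never played contribute nothing.  Under the intersection
    strategy (constant n_ij = k) the ordering coincides with ordering by
    total wins.
    """
    _require_pairs(cm)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(cm.n > 0, cm.W / np.where(cm.n > 0, cm.n, 1), 0.0)
    return _result("winloss", cm, frac.sum(axis=1))


def _massey_matrix(cm: CompetitionMatrices) -> np.ndarray:
    M = -cm.n.astype(float)
    np.fill_diagonal(M, cm.Ni)
    return M


def rank_massey(cm: CompetitionMatrices) -> RatingResult:
    """Least-squares rating from the games-count linear system.

    Solves ``M r = p`` with ``M_ii = N_i``, ``M_ij = -n_ij`` and
    ``p_i = W_i - L_i``, after replacing the last row of M with ones and the
    last entry of p with zero to pin the (otherwise singular) system; ratings
    then sum to zero.  A still-singular replaced system (disconnected
    competition graph) falls back to the minimum-norm least-squares solution.
    """
    _require_pairs(cm)
    M = _massey_matrix(cm)
    p = (cm.W.sum(axis=1) - cm.L.sum(axis=1)).astype(float)
    M[-1, :] = 1.0
    p[-1] = 0.0
    try:
        r = np.linalg.solve(M, p)
    except np.linalg.LinAlgError:
        logger.warning("Massey system singular; using minimum-norm least squares")
        r = np.linalg.lstsq(M, p, rcond=None)[0]
    if not np.all(np.isfinite(r)) or np.linalg.cond(M) > 1e12:
        logger.warning("Massey system ill-conditioned; using minimum-norm least squares")
        r = np.linalg.lstsq(M, p, rcond=None)[0]
    return _result("massey", cm, r)


def rank_colley(cm: CompetitionMatrices) -> RatingResult:
    """Solve the regularized system ``C r = b``, ``C = M + 2I``.

    ``b_i = 1 + (W_i - L_i) / 2``; C is symmetric positive definite, so the
    solve always succeeds and with no games every rating is exactly 0.5.
    Ratings sum to N/2.
    """
    _require_pairs(cm)
    C = _massey_matrix(cm) + 2.0 * np.eye(cm.N)
    b = 1.0 + (cm.W.sum(axis=1) - cm.L.sum(axis=1)) / 2.0
    return _result("colley", cm, np.linalg.solve(C, b))


def keener_skew(x):
    """Non-linear skew h(x) = 0.5 + 0.5 sgn(x - 0.5) sqrt(|2x - 1|) on [0, 1]."""
    arr = np.asarray(x, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("keener_skew is defined on [0, 1]")
    out = 0.5 + 0.5 * np.sign(arr - 0.5) * np.sqrt(np.abs(2.0 * arr - 1.0))
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def rank_keener(
    cm: CompetitionMatrices, params: RankerParams = RankerParams()
) -> RatingResult:
    """Perron eigenvector of the skewed, Laplace-smoothed win-proportion matrix.

    ``a_ij = (w_ij + 1) / (w_ij + w_ji + 2)`` is defined for every pair
    (never-played pairs get 0.5, keeping the matrix positive off-diagonal
    hence irreducible); the dominant eigenpair is found by power iteration on
    ``K + I``, which shares the Perron vector while suppressing period-2
    oscillation.  Returned vector is positive and sums to 1.
    """
    _require_pairs(cm)
    W = cm.W.astype(float)
    a = (W + 1.0) / (W + W.T + 2.0)
    K = keener_skew(a)
    np.fill_diagonal(K, 0.0)

    B = K + np.eye(cm.N)
    r = np.full(cm.N, 1.0 / cm.N)
    for _ in range(params.max_iter):
        nxt = B @ r
        nxt /= nxt.sum()
        if np.max(np.abs(nxt - r)) < params.tol:
            return _result("keener", cm, nxt)
        r = nxt
    residual = float(np.max(np.abs(B @ r / (B @ r).sum() - r)))
    raise ConvergenceError(
        f"Keener power iteration did not converge in {params.max_iter} "
        f"iterations (residual {residual:.3e})"
    )


def _elo_outcome(si: float, sj: float) -> float:
    """Actual match outcome for player i: 1 win, 0 loss, 0.5 tie."""
    if si > sj:
        return 1.0
    if si < sj:
        return 0.0
    return 0.5


def rank_elo(
    cm: CompetitionMatrices, params: RankerParams = RankerParams()
) -> RatingResult:
    """Sequential logistic rating updates, one match per pair per dataset.

    Ratings start at ``elo_init``.  Datasets are processed in input order;
    within a dataset the unordered pairs present there are processed in
    lexicographic order.  Both players are updated simultaneously from their
    pre-match ratings:  ``r_i += f * (outcome - expected)`` with
    ``expected = 1 / (1 + 10^((r_j - r_i)/400))``.  Outcomes use the
    competition's regulation mode; exact ties score 0.5 for both.
    """
    _require_pairs(cm)
    if not cm.per_dataset and cm.k > 0:
        raise GeneCompeteError(
            "Elo requires the per-dataset outcome record; none available"
        )
    sign = {"up": 1.0, "down": -1.0}.get(cm.regulation)
    ratings = {g: params.elo_init for g in cm.genes}
    f, scale = params.elo_f, params.elo_logistic_scale
    for scores in cm.per_dataset:
        present = sorted(g for g in scores if g in ratings)
        for gi, gj in combinations(present, 2):
            si, sj = scores[gi], scores[gj]
            if sign is None:  # absolute mode
                si, sj = abs(si), abs(sj)
            else:
                si, sj = sign * si, sign * sj
            kappa = _elo_outcome(si, sj)
            ri, rj = ratings[gi], ratings[gj]
            mu_ij = 1.0 / (1.0 + 10.0 ** ((rj - ri) / scale))
            mu_ji = 1.0 - mu_ij
            ratings[gi] = ri + f * (kappa - mu_ij)
            ratings[gj] = rj + f * ((1.0 - kappa) - mu_ji)
    return RatingResult(method="elo", scores=ratings)


def _stationary(P: np.ndarray, tol: float, max_iter: int) -> np.ndarray | None:
    """Left fixed point of a row-stochastic matrix by power iteration."""
    N = P.shape[0]
    r = np.full(N, 1.0 / N)
    for _ in range(max_iter):
        nxt = r @ P
        nxt /= nxt.sum()
        if np.max(np.abs(nxt - r)) < tol:
            return nxt
        r = nxt
    return None


def _row_normalize(A: np.ndarray) -> np.ndarray:
    """Row-stochastic normalization; zero rows (dangling) become uniform."""
    N = A.shape[0]
    out = A.astype(float)
    rowsum = out.sum(axis=1)
    dangling = rowsum == 0
    out[dangling] = 1.0 / N
    out[~dangling] /= rowsum[~dangling, None]
    return out


def rank_markov(
    cm: CompetitionMatrices, params: RankerParams = RankerParams()
) -> RatingResult:
    """Stationary distribution of the losers-vote-for-winners chain.

    The binary voting matrix has ``V_ij = 1`` when gene i lost at least once
    to gene j; rows are normalized to a transition matrix (undefeated genes
    become uniform dangling rows) and the stationary distribution is found by
    power iteration.  If the chain is reducible/periodic and iteration fails,
    the matrix is mixed with uniform at weight 0.15 and retried.
    """
    _require_pairs(cm)
    V = (cm.L > 0).astype(float)
    P = _row_normalize(V)
    pi = _stationary(P, params.tol, params.max_iter)
    if pi is None:
        logger.warning("Markov chain did not converge; mixing with uniform (0.15)")
        N = cm.N
        P = 0.85 * P + 0.15 / N
        pi = _stationary(P, params.tol, params.max_iter)
        if pi is None:
            raise ConvergenceError(
                f"Markov stationary distribution did not converge in "
                f"{params.max_iter} iterations even after uniform mixing"
            )
    return _result("markov", cm, pi)


def _pagerank_vector(
    A: np.ndarray, params: RankerParams
) -> np.ndarray:
    """Damped PageRank of a weighted adjacency matrix (rows = sources)."""
    N = A.shape[0]
    Z = _row_normalize(A)
    G = params.alpha * Z + (1.0 - params.alpha) / N
    r = _stationary(G, params.tol, params.max_iter)
    if r is None:
        raise ConvergenceError(
            f"PageRank did not converge in {params.max_iter} iterations"
        )
    return r


def rank_pagerank(
    cm: CompetitionMatrices, params: RankerParams = RankerParams()
) -> RatingResult:
    """Damped PageRank on the loser -> winner graph.

    Edge weight from u to v is the number of matches u lost to v; dangling
    (undefeated) genes get uniform rows.  The Google matrix
    ``alpha * Z + (1 - alpha) * E`` is iterated from the uniform vector.
    """
    _require_pairs(cm)
    return _result("pagerank", cm, _pagerank_vector(cm.L, params))


def rank_bipagerank(
    cm: CompetitionMatrices, params: RankerParams = RankerParams()
) -> RatingResult:
    """PageRank minus reversed-graph PageRank.

    The backward component runs the same damped iteration on the
    winner -> loser graph (edge weight = matches won), propagating scores
    toward frequent losers; the difference sums to zero and may be negative.
    """
    _require_pairs(cm)
    r_p = _pagerank_vector(cm.L, params)
    r_q = _pagerank_vector(cm.W, params)
    return _result("bipagerank", cm, r_p - r_q)


_DISPATCH = {
    "winloss": lambda cm, params: rank_winloss(cm),
    "massey": lambda cm, params: rank_massey(cm),
    "colley": lambda cm, params: rank_colley(cm),
    "keener": rank_keener,
    "elo": rank_elo,
    "markov": rank_markov,
    "pagerank": rank_pagerank,
    "bipagerank": rank_bipagerank,
}


def rank_all(
    cm: CompetitionMatrices,
    methods: list[str] | None = None,
    params: RankerParams = RankerParams(),
) -> list[RatingResult]:
    """Run the requested methods (default: all eight) and time each.

    Duplicate method names are dropped with a warning; unknown names raise.
    """
    if methods is None:
        methods = list(METHODS)
    unknown = [m for m in methods if m not in _DISPATCH]
    if unknown:
        raise ValueError(
            f"unknown method(s) {unknown}; valid names: {list(METHODS)}"
        )
    seen: list[str] = []
    for m in methods:
        if m in seen:
            logger.warning("duplicate method %r dropped", m)
        else:
            seen.append(m)
    results = []
    for m in seen:
        t0 = time.perf_counter()
        res = _DISPATCH[m](cm, params)
        res.wall_time = time.perf_counter() - t0
        results.append(res)
    return results
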