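"""Leave-one-out cross-validation of rankings against held-out DEG calls.

Each fold holds out one dataset: the competition is built on the remaining
datasets, every requested rating method (plus three baselines) scores the
candidates, and the held-out table defines the positive set — genes with
logFC beyond the cut and adjusted p-value below the cut.  Performance is
measured by ROC-AUC and by AUPR normalized by the positive prevalence
(AUPRN = AUPR / prevalence), which corrects for class imbalance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from genecompete.competition import CompetitionConfig, build_competition
from genecompete.errors import SchemaError, UndefinedMetricError
from genecompete.gene_tables import GeneTable
from genecompete.rankers import RankerParams, RatingResult, rank_all

logger = logging.getLogger(__name__)

BASELINES = ("classical", "count", "avg_logfc")


@dataclass(frozen=True)
class PositiveSetRule:
    """Definition of a held-out DEG call.

    up: logFC > logfc_cut and adj_pval < adj_cut; down: logFC < -logfc_cut
    and adj_pval < adj_cut; absolute: either side.  All inequalities strict.
    """

    regulation: str = "up"
    logfc_cut: float = 1.0
    adj_cut: float = 0.05

    def __post_init__(self) -> None:
        if self.logfc_cut <= 0:
            raise ValueError(f"logfc_cut must be positive, got {self.logfc_cut}")
        if not 0 < self.adj_cut < 1:
            raise ValueError(f"adj_cut must be in (0, 1), got {self.adj_cut}")

    def matches(self, logfc: float, adj_pval: float) -> bool:
        if adj_pval >= self.adj_cut:
            return False
        if self.regulation == "up":
            return logfc > self.logfc_cut
        if self.regulation == "down":
            return logfc < -self.logfc_cut
        return abs(logfc) > self.logfc_cut


@dataclass
class EvaluationReport:
    """Metrics for one (held-out dataset, method) pair."""

    held_out: str
    method: str
    auc: float
    aupr: float
    auprn: float
    n_pos: int
    n_neg: int

    @property
    def universe(self) -> int:
        return self.n_pos + self.n_neg

    @property
    def prevalence(self) -> float:
        return self.n_pos / self.universe


def define_positives(test_table: GeneTable, rule: PositiveSetRule) -> set[str]:
    """Genes in ``test_table`` meeting the DEG rule (requires adj. p-values)."""
    if not test_table.has_adj_pvalues:
        raise SchemaError(
            f"dataset {test_table.name!r} lacks adjusted p-values; "
            "cannot define a positive set"
        )
    return {
        g
        for g, rec in test_table.records.items()
        if rule.matches(rec.logFC, rec.adj_pval)
    }


def score_curve_areas(
    scores: Mapping[str, float], positives: set[str], universe: Iterable[str]
) -> tuple[float, float, float]:
    """(AUC, AUPR, AUPRN) of a score over a labelled gene universe.

    AUC uses the rank-statistic (Mann-Whitney) formulation with midrank tie
    correction.  AUPR integrates the precision-recall curve step-wise with
    tied scores grouped into single thresholds; AUPRN divides by the positive
    prevalence.
    """
    genes = sorted(universe)
    labels = np.asarray([g in positives for g in genes])
    n_pos = int(labels.sum())
    n_neg = len(genes) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            f"curve metrics undefined: {n_pos} positives, {n_neg} negatives"
        )
    y = np.asarray([scores[g] for g in genes], dtype=float)

    ranks = rankdata(y, method="average")
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    # stepwise PR: descending score, tied blocks collapse to one threshold
    order = np.argsort(-y, kind="stable")
    y_sorted, lab_sorted = y[order], labels[order]
    block_end = np.nonzero(np.diff(y_sorted))[0]  # last index of each tied block
    cuts = np.append(block_end, len(y_sorted) - 1)
    tp = np.cumsum(lab_sorted)[cuts].astype(float)
    n_at = (cuts + 1).astype(float)
    precision = tp / n_at
    recall = tp / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    aupr = float(np.sum((recall - prev_recall) * precision))

    prevalence = n_pos / (n_pos + n_neg)
    return float(auc), aupr, aupr / prevalence


def baseline_scores(
    train_tables: Sequence[GeneTable],
    rule: PositiveSetRule,
    universe: Iterable[str],
) -> dict[str, dict[str, float]]:
    """The three reference scorers: classical, count and average logFC.

    classical(g) — 1 iff g meets the DEG rule in every training dataset where
    it is present (the intersection-of-DEG-lists convention), else 0.
    count(g) — number of training datasets in which g meets the rule.
    avg_logfc(g) — mean logFC across the training datasets containing g,
    sign-flipped in down mode and absolute in absolute mode so that larger
    is always better.  Genes absent from every training dataset score 0.
    """
    genes = sorted(universe)
    if not genes:
        raise ValueError("empty evaluation universe")
    for t in train_tables:
        if not t.has_adj_pvalues:
            raise SchemaError(
                f"training dataset {t.name!r} lacks adjusted p-values"
            )

    classical: dict[str, float] = {}
    count: dict[str, float] = {}
    avg: dict[str, float] = {}
    n_orphans = 0
    for g in genes:
        hits, present, fcs = 0, 0, []
        for t in train_tables:
            rec = t.records.get(g)
            if rec is None:
                continue
            present += 1
            fcs.append(rec.logFC)
            if rule.matches(rec.logFC, rec.adj_pval):
                hits += 1
        count[g] = float(hits)
        classical[g] = 1.0 if present > 0 and hits == present else 0.0
        if present == 0:
            n_orphans += 1
            avg[g] = 0.0
        else:
            m = float(np.mean(fcs))
            if rule.regulation == "down":
                avg[g] = -m
            elif rule.regulation == "absolute":
                avg[g] = float(np.mean(np.abs(fcs)))
            else:
                avg[g] = m
    if n_orphans:
        logger.warning(
            "%d universe genes absent from all training datasets scored 0",
            n_orphans,
        )
    return {"classical": classical, "count": count, "avg_logfc": avg}


def loocv(
    tables: Sequence[GeneTable],
    config: CompetitionConfig,
    methods: Sequence[str] | None = None,
    params: RankerParams = RankerParams(),
    rule: PositiveSetRule | None = None,
    absent_as_negative: bool = False,
    include_baselines: bool = True,
) -> tuple[list[EvaluationReport], dict[str, dict[str, float]]]:
    """Leave-one-dataset-out evaluation of rankings and baselines.

    Returns the per-(fold, method) reports and per-method means over the
    folds where the metric was defined.  By default the evaluation universe
    of a fold is the set of ranked candidates also present in the held-out
    table; with ``absent_as_negative`` every ranked candidate is evaluated
    and absentees count as negatives.
    """
    if len(tables) < 3:
        raise ValueError(
            f"LOOCV needs at least 3 datasets (>= 2 training per fold), "
            f"got {len(tables)}"
        )
    if rule is None:
        rule = PositiveSetRule(regulation=config.regulation)

    reports: list[EvaluationReport] = []
    for held in range(len(tables)):
        test = tables[held]
        train = [t for i, t in enumerate(tables) if i != held]
        cm = build_competition(train, config)
        results = rank_all(cm, list(methods) if methods is not None else None, params)

        if absent_as_negative:
            universe = set(cm.genes)
        else:
            universe = {g for g in cm.genes if g in test}
        if not universe:
            logger.warning("fold %r: empty evaluation universe; skipped", test.name)
            continue
        positives = define_positives(test, rule) & universe

        scorers: dict[str, Mapping[str, float]] = {
            res.method: res.scores for res in results
        }
        if include_baselines:
            scorers.update(baseline_scores(train, rule, universe))

        for method, scores in scorers.items():
            restricted = {g: scores[g] for g in universe}
            try:
                auc, aupr, auprn = score_curve_areas(restricted, positives, universe)
            except UndefinedMetricError:
                logger.warning(
                    "fold %r method %r: metric undefined "
                    "(%d positives in universe of %d); excluded from means",
                    test.name, method, len(positives), len(universe),
                )
                continue
            reports.append(
                EvaluationReport(
                    held_out=test.name,
                    method=method,
                    auc=auc,
                    aupr=aupr,
                    auprn=auprn,
                    n_pos=len(positives),
                    n_neg=len(universe) - len(positives),
                )
            )

    means: dict[str, dict[str, float]] = {}
    by_method: dict[str, list[EvaluationReport]] = {}
    for rep in reports:
        by_method.setdefault(rep.method, []).append(rep)
    for method, reps in by_method.items():
        means[method] = {
            "auc": float(np.mean([r.auc for r in reps])),
            "aupr": float(np.mean([r.aupr for r in reps])),
            "auprn": float(np.mean([r.auprn for r in reps])),
            "n_folds": float(len(reps)),
        }
    return reports, means


def write_report(
    reports: list[EvaluationReport],
    means: dict[str, dict[str, float]],
    path,
    sep: str = ",",
) -> None:
    """Write per-fold rows plus a summary block of per-method means."""
    import pandas as pd

    rows = [
        {
            "held_out": r.held_out,
            "method": r.method,
            "auc": r.auc,
            "aupr": r.aupr,
            "auprn": r.auprn,
            "n_pos": r.n_pos,
            "universe": r.universe,
        }
        for r in reports
    ]
    rows.extend(
        {
            "held_out": "MEAN",
            "method": method,
            "auc": m["auc"],
            "aupr": m["aupr"],
            "auprn": m["auprn"],
            "n_pos": "",
            "universe": "",
        }
        for method, m in means.items()
    )
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False, float_format="%.12g")
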