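"""Deterministic synthetic multi-dataset DE tables with planted signal.

Each synthetic gene universe holds mostly null genes (logFC centred on zero)
plus a handful of planted up/down-regulated genes with a strong mean effect.
Every gene appears in each dataset with a fixed probability, giving the
heterogeneous, partially overlapping per-dataset universes the union
strategy is designed for.  Adjusted p-values are a monotone-decreasing
transform of |logFC| with a small seeded jitter — plausible joint structure,
not calibrated tests — so planted genes satisfy the usual DEG rule
(|logFC| > 1, adj.p < 0.05) with high probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np

from genecompete.gene_tables import GeneRecord, GeneTable

LABEL_UP = "up"
LABEL_DOWN = "down"
LABEL_NULL = "null"


def _default_pval_model(abs_logfc: np.ndarray) -> np.ndarray:
    """Monotone-decreasing map |logFC| -> adjusted-p-like value in (0, 1]."""
    return np.exp(-4.0 * abs_logfc)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic multi-dataset scenario."""

    n_genes: int = 200
    k_datasets: int = 4
    presence_prob: float = 0.8
    n_planted_up: int = 10
    n_planted_down: int = 0
    effect_mu: float = 2.5
    noise_sd: float = 0.5
    pval_model: Callable[[np.ndarray], np.ndarray] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.k_datasets < 1:
            raise ValueError("n_genes and k_datasets must be positive")
        if not 0 < self.presence_prob <= 1:
            raise ValueError(
                f"presence_prob must be in (0, 1], got {self.presence_prob}"
            )
        if self.n_planted_up + self.n_planted_down > self.n_genes:
            raise ValueError("more planted genes than genes in the universe")
        if self.noise_sd <= 0 or self.effect_mu < 0:
            raise ValueError("noise_sd must be > 0 and effect_mu >= 0")


class FixtureResult(NamedTuple):
    tables: list[GeneTable]
    labels: dict[str, str]  # gene -> up / down / null


def gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_tables(spec: FixtureSpec) -> FixtureResult:
    """Draw ``spec.k_datasets`` GeneTables plus the planted/null truth labels.

    Fully reproducible from ``spec.seed``.  Planted genes are forced present
    in at least two datasets (when k >= 2) so they remain rankable under the
    union strategy.
    """
    rng = np.random.default_rng(spec.seed)
    genes = gene_names(spec.n_genes)
    n, k = spec.n_genes, spec.k_datasets
    pmodel = spec.pval_model or _default_pval_model

    labels = {g: LABEL_NULL for g in genes}
    planted = rng.choice(n, size=spec.n_planted_up + spec.n_planted_down, replace=False)
    up_idx = planted[: spec.n_planted_up]
    down_idx = planted[spec.n_planted_up:]
    for i in up_idx:
        labels[genes[i]] = LABEL_UP
    for i in down_idx:
        labels[genes[i]] = LABEL_DOWN

    mu = np.zeros(n)
    mu[up_idx] = spec.effect_mu
    mu[down_idx] = -spec.effect_mu

    presence = rng.random((k, n)) < spec.presence_prob
    if k >= 2:
        min_present = min(2, k)
        for i in planted:
            have = int(presence[:, i].sum())
            if have < min_present:
                absent = np.nonzero(~presence[:, i])[0]
                add = rng.choice(absent, size=min_present - have, replace=False)
                presence[add, i] = True

    tables = []
    for d in range(k):
        logfc = rng.normal(mu, spec.noise_sd)
        jitter = rng.normal(0.0, 0.2, size=n)
        adj = np.clip(pmodel(np.abs(logfc)) * np.exp(jitter), 1e-300, 1.0)
        pval = np.clip(adj * rng.uniform(0.1, 1.0, size=n), 1e-300, 1.0)
        records = {
            genes[i]: GeneRecord(
                logFC=float(logfc[i]),
                pval=float(pval[i]),
                adj_pval=float(adj[i]),
            )
            for i in range(n)
            if presence[d, i]
        }
        tables.append(GeneTable(name=f"sim{d + 1}", records=records))
    return FixtureResult(tables=tables, labels=labels)


def write_fixture(result: FixtureResult, outdir, sep: str = ",") -> list[str]:
    """Write each table as ``<name>.csv`` plus ``truth.csv`` (gene, label)."""
    import os

    import pandas as pd

    from genecompete.gene_tables import write_gene_table

    os.makedirs(outdir, exist_ok=True)
    paths = []
    for table in result.tables:
        path = os.path.join(outdir, f"{table.name}.csv")
        write_gene_table(table, path, sep=sep)
        paths.append(path)
    truth = os.path.join(outdir, "truth.csv")
    pd.DataFrame(
        {"Gene": list(result.labels), "label": list(result.labels.values())}
    ).to_csv(truth, sep=sep, index=False)
    paths.append(truth)
    return paths
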