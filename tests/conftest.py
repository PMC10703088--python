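import numpy as np
import pytest

from genecompete.competition import (
    CompetitionConfig,
    CompetitionMatrices,
    build_competition,
)
from genecompete.gene_tables import GeneRecord, GeneTable


def make_table(name, scores, pvals=None, adj=None):
    """GeneTable from a gene->logFC dict (optional p-value dicts)."""
    records = {}
    for g, v in scores.items():
        records[g] = GeneRecord(
            logFC=float(v),
            pval=None if pvals is None else pvals.get(g),
            adj_pval=None if adj is None else adj.get(g),
        )
    return GeneTable(name=name, records=records)


def random_tables(rng, n_genes, k, presence=1.0, integer_scores=False):
    """k random gene->logFC tables over a shared universe (possibly sparse)."""
    genes = [f"g{i:03d}" for i in range(n_genes)]
    tables = []
    for d in range(k):
        if integer_scores:
            vals = rng.integers(-3, 4, size=n_genes).astype(float)
        else:
            vals = rng.normal(0, 1.5, size=n_genes)
        mask = rng.random(n_genes) < presence
        if mask.sum() < 2:
            mask[:2] = True
        tables.append(
            make_table(
                f"t{d}", {g: v for g, v, m in zip(genes, vals, mask) if m}
            )
        )
    return tables


def random_competition(rng, n_genes=10, k=3, strategy="intersection",
                       regulation="up", presence=1.0, thres=0.0,
                       integer_scores=False):
    tables = random_tables(rng, n_genes, k, presence, integer_scores)
    cfg = CompetitionConfig(regulation=regulation, strategy=strategy, thres=thres)
    return build_competition(tables, cfg)


def zero_competition(n=5):
    """A competition in which no games have been played."""
    genes = [f"g{i}" for i in range(n)]
    Z = np.zeros((n, n), dtype=np.int64)
    return CompetitionMatrices(
        genes=genes, W=Z.copy(), L=Z.copy(), n=Z.copy(), per_dataset=[], k=0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def two_gene_cm():
    """Single dataset, A beats B once."""
    t = make_table("d", {"A": 2.0, "B": 1.0})
    return build_competition([t], CompetitionConfig())
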