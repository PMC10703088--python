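# genecompete

Gene prioritization across multiple differential-expression (DE) datasets by
pairwise competition. Each input table (gene symbol + `logFC`, optionally
`P.Value` / `adj.P.Val`) contributes one round of matches: within a dataset
every pair of candidate genes plays on log-fold change — higher wins in the
up-regulation case, lower in the down-regulation case, larger |logFC| in the
two-sided (absolute) case; an exact tie credits both genes a win. Outcomes
are aggregated into win/loss/games matrices under one of two strategies:

* **intersection** — candidates are the genes present in every dataset; all
  pairs play `k` games;
* **union** — candidates are the genes passing the logFC filter
  (`> thres` up, `< -thres` down, `|logFC| > thres` absolute) in at least
  one dataset; each pair plays one game per dataset containing both, and a
  candidate competes with its original score even where it failed the
  filter.

Eight rating methods score the tournament: `winloss`, `massey`, `colley`,
`keener`, `elo`, `markov`, `pagerank`, `bipagerank`. Rankings can be
validated by leave-one-dataset-out cross-validation against held-out DEG
calls (logFC and adjusted-p cuts), with ROC-AUC and prevalence-normalized
AUPR (AUPRN), alongside three baselines (classical intersection-of-DEG-lists
indicator, dataset count, mean logFC).

Ranking is fully deterministic; randomness exists only in the synthetic
fixture generator and is seed-controlled.

## CLI

```sh
# rank genes across datasets
genecompete rank --input a.csv --input b.csv --input c.csv \
    --regulation up --strategy union --thres 0 \
    --methods winloss,pagerank,keener --output scores.csv

# leave-one-out cross-validation (inputs need adj.P.Val)
genecompete evaluate --input a.csv --input b.csv --input c.csv \
    --strategy union --methods all --logfc-cut 1 --adj-cut 0.05 \
    --output report.csv

# synthetic fixtures with planted signal + truth labels
genecompete simulate --n-genes 200 --k 4 --planted-up 10 --seed 1 \
    --outdir fixtures/

# per-method runtime vs candidate count
genecompete benchmark --sizes 50,100,200 --output bench.csv
```

Inputs are delimited text (comma/tab/semicolon auto-detected) with a header;
the first column holds gene symbols. Duplicate symbols keep the row with
the smallest p-value, or the largest |score| when no p-value column exists
(the latter rule is our convention; see module docs). Ranking only needs
the score column — p-values are required only by `evaluate`.

Notable CLI knobs: `--alpha` (PageRank damping, 0.85), `--elo-init` (1500),
`--elo-f` (10), `--tol` / `--max-iter` (iterative solvers),
`--candidate-cap` (union-size guard, 10,000), `--absent-as-negative`
(evaluate ranked genes missing from the held-out table as negatives instead
of excluding them).

## Library

```python
from genecompete import (
    read_gene_table, CompetitionConfig, build_competition, rank_all, loocv,
)

tables = [read_gene_table(p) for p in ("a.csv", "b.csv", "c.csv")]
cm = build_competition(tables, CompetitionConfig(strategy="union"))
results = rank_all(cm, ["pagerank", "winloss"])
reports, means = loocv(tables, CompetitionConfig(strategy="union"))
```

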