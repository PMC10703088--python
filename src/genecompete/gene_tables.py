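"""Reading, validating and writing differential-expression gene tables.

Input files are delimited text with a header row; the first column holds
gene symbols and the remaining columns are numeric DE statistics.  The
default score column is ``logFC``; ``P.Value`` and ``adj.P.Val`` (limma
``topTable`` dialect) are recognized when present, as are the common
aliases ``pval``, ``adj.pval`` and ``padj``.
"""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from genecompete.errors import EmptyTableError, InputError, SchemaError

logger = logging.getLogger(__name__)

PVAL_COL = "P.Value"
ADJ_PVAL_COL = "adj.P.Val"

#: accepted spellings for the p-value columns, mapped to canonical names
COLUMN_ALIASES = {
    "pval": PVAL_COL,
    "p.value": PVAL_COL,
    "pvalue": PVAL_COL,
    "adj.pval": ADJ_PVAL_COL,
    "adj.p.val": ADJ_PVAL_COL,
    "padj": ADJ_PVAL_COL,
    "adj.pvalue": ADJ_PVAL_COL,
}


@dataclass(frozen=True)
class GeneRecord:
    """One gene's DE statistics within a single dataset."""

    logFC: float
    pval: float | None = None
    adj_pval: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.logFC):
            raise ValueError(f"logFC must be finite, got {self.logFC!r}")
        for label, value in (("pval", self.pval), ("adj_pval", self.adj_pval)):
            if value is not None and not (0.0 <= value <= 1.0):
                raise ValueError(f"{label} must lie in [0, 1], got {value!r}")


@dataclass
class GeneTable:
    """Ordered mapping gene symbol -> :class:`GeneRecord` for one dataset."""

    name: str
    records: dict[str, GeneRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene: str) -> bool:
        return gene in self.records

    @property
    def genes(self) -> list[str]:
        return list(self.records)

    def scores(self) -> dict[str, float]:
        """Gene -> logFC mapping in table order."""
        return {g: r.logFC for g, r in self.records.items()}

    @property
    def has_pvalues(self) -> bool:
        return all(r.pval is not None for r in self.records.values())

    @property
    def has_adj_pvalues(self) -> bool:
        return all(r.adj_pval is not None for r in self.records.values())


def _sniff_delimiter(path: str) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(65536)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def _canonical_columns(columns: Iterable[str]) -> dict[str, str]:
    mapping = {}
    for col in columns:
        canon = COLUMN_ALIASES.get(col.strip().lower())
        if canon is not None and canon not in mapping.values():
            mapping[col] = canon
    return mapping


def read_gene_table(
    path: str | os.PathLike,
    score_col: str = "logFC",
    dataset_name: str | None = None,
) -> GeneTable:
    """Load one DE table from delimited text.

    Duplicate gene symbols are resolved by keeping the row with the smallest
    p-value when a p-value column exists, otherwise the row with the largest
    absolute score.  Rows with empty symbols or a missing/non-finite score
    are dropped (count logged).

    Parameters
    ----------
    path
        Delimited text file; delimiter auto-detected among comma, tab and
        semicolon.  First column must hold gene symbols.
    score_col
        Name of the numeric column used as the competing score.
    dataset_name
        Label for the dataset; defaults to the file stem.

    Raises
    ------
    InputError
        If the file does not exist.
    SchemaError
        If ``score_col`` is not among the columns.
    EmptyTableError
        If no parsable rows remain.
    """
    path = os.fspath(path)
    if not os.path.isfile(path):
        raise InputError(f"no such file: {path}")
    name = dataset_name or os.path.splitext(os.path.basename(path))[0]

    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    if df.shape[1] < 2:
        raise SchemaError(
            f"{path}: expected gene-symbol column plus numeric columns, "
            f"found only {list(df.columns)}"
        )
    df = df.rename(columns=_canonical_columns(df.columns[1:]))
    if score_col not in df.columns[1:]:
        raise SchemaError(
            f"{path}: score column {score_col!r} not found; "
            f"available columns: {list(df.columns[1:])}"
        )
    return _table_from_frame(df, score_col, name, origin=path)


def table_from_frame(
    df: pd.DataFrame, score_col: str = "logFC", dataset_name: str = "dataset"
) -> GeneTable:
    """Build a :class:`GeneTable` from an in-memory frame (first column = symbols)."""
    if score_col not in df.columns[1:]:
        raise SchemaError(
            f"score column {score_col!r} not found; available: {list(df.columns[1:])}"
        )
    return _table_from_frame(df.copy(), score_col, dataset_name, origin="<frame>")


def _table_from_frame(
    df: pd.DataFrame, score_col: str, name: str, origin: str
) -> GeneTable:
    symbol_col = df.columns[0]
    df[symbol_col] = df[symbol_col].astype(str).str.strip()
    n_raw = len(df)

    score = pd.to_numeric(df[score_col], errors="coerce")
    keep = np.isfinite(score.to_numpy(dtype=float)) & (df[symbol_col] != "")
    keep &= df[symbol_col].str.lower() != "nan"
    dropped = n_raw - int(keep.sum())
    if dropped:
        logger.info("%s: dropped %d rows with missing symbol/score", origin, dropped)
    df = df.loc[keep]
    if df.empty:
        raise EmptyTableError(f"{origin}: zero parsable rows")

    has_pval = PVAL_COL in df.columns
    if has_pval:
        pv = pd.to_numeric(df[PVAL_COL], errors="coerce")
        # smallest p-value wins; NaN p-values sort last
        order = pv.fillna(np.inf).to_numpy()
    else:
        order = -pd.to_numeric(df[score_col], errors="coerce").abs().to_numpy()
    df = df.iloc[np.argsort(order, kind="stable")]
    df = df.drop_duplicates(subset=symbol_col, keep="first")
    # restore original row order for determinism of table iteration
    df = df.sort_index()

    def _opt(row, col):
        if col not in df.columns:
            return None
        v = row[col]
        try:
            v = float(v)
        except (TypeError, ValueError):
            return None
        return v if np.isfinite(v) else None

    records: dict[str, GeneRecord] = {}
    for _, row in df.iterrows():
        records[row[symbol_col]] = GeneRecord(
            logFC=float(row[score_col]),
            pval=_opt(row, PVAL_COL),
            adj_pval=_opt(row, ADJ_PVAL_COL),
        )
    return GeneTable(name=name, records=records)


def write_gene_table(table: GeneTable, path: str | os.PathLike, sep: str = ",") -> None:
    """Write a table back to delimited text (inverse of :func:`read_gene_table`)."""
    rows = []
    for gene, rec in table.records.items():
        row = {"Gene": gene, "logFC": rec.logFC}
        if rec.pval is not None:
            row[PVAL_COL] = rec.pval
        if rec.adj_pval is not None:
            row[ADJ_PVAL_COL] = rec.adj_pval
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False, float_format="%.12g")


def write_ratings(results: list, path: str | os.PathLike, sep: str = ",") -> None:
    """Write rating results as one delimited table.

    Column 1 is the gene symbol, followed by ``<method>_score`` and
    ``<method>_rank`` per method.  Rows are sorted by the first method's rank
    ascending, ties broken lexicographically by symbol.  Values round-trip at
    12 significant digits.
    """
    if not results:
        logger.warning("write_ratings called with no results; writing header only")
        pd.DataFrame(columns=["Gene"]).to_csv(path, sep=sep, index=False)
        return

    universe = list(results[0].scores)
    for res in results[1:]:
        if set(res.scores) != set(universe):
            raise ValueError(
                f"method {res.method!r} has a different gene universe"
            )
    data: dict[str, list] = {"Gene": sorted(universe)}
    for res in results:
        data[f"{res.method}_score"] = [res.scores[g] for g in data["Gene"]]
        data[f"{res.method}_rank"] = [res.ranks[g] for g in data["Gene"]]
    df = pd.DataFrame(data)
    first_rank = f"{results[0].method}_rank"
    df = df.sort_values([first_rank, "Gene"], kind="stable")
    df.to_csv(path, sep=sep, index=False, float_format="%.12g")


def read_ratings(path: str | os.PathLike, sep: str = ",") -> pd.DataFrame:
    """Read a ratings table written by :func:`write_ratings`."""
    return pd.read_csv(path, sep=sep, dtype={"Gene": str})
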