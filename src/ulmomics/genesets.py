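"""Crossing differential / co-alteration tables with curated gene lists.

Used for the antioxidant-response-element (ARE / NRF2-target) crossing and
for synthetic-lethality candidate lists: restrict a result table to set
members and tabulate direction concordance.  Deliberately count-based — no
enrichment statistic is attached to these crossings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .crossome import CoAlterationTable
from .differential import DifferentialResult
from .io import GeneSet, read_gene_sets

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCrossing:
    """Result rows restricted to a gene set, with direction counts.

    ``table`` keeps whatever logFC columns the input carried; counts are
    taken on the protein-layer logFC when present, else the single logFC.
    """

    gene_set_name: str
    table: pd.DataFrame
    n_elevated: int
    n_decreased: int
    n_zero: int


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, CoAlterationTable):
        return table.table.copy()
    if isinstance(table, DifferentialResult):
        return table.table.copy()
    return pd.DataFrame(table).copy()


def _direction_column(df: pd.DataFrame) -> str:
    for col in ("protein_log2FC", "log2FC"):
        if col in df.columns:
            return col
    raise KeyError("table has no protein_log2FC or log2FC column")


def cross_with_gene_set(table, gene_set: GeneSet) -> GeneSetCrossing:
    """Restrict a result table to gene-set members and count directions.

    Matching is on uppercased row symbols; an empty overlap yields an empty
    crossing with a warning, never an error.
    """
    df = _as_frame(table)
    df.index = df.index.str.upper()
    members = df.index.intersection(sorted(gene_set.symbols))
    subset = df.loc[members]
    if subset.empty:
        logger.warning("gene set %r has no overlap with the result table", gene_set.name)
    col = _direction_column(df)
    return GeneSetCrossing(
        gene_set_name=gene_set.name,
        table=subset,
        n_elevated=int((subset[col] > 0).sum()),
        n_decreased=int((subset[col] < 0).sum()),
        n_zero=int((subset[col] == 0).sum()),
    )


def direction_table(crossing: GeneSetCrossing) -> pd.DataFrame:
    """Per-gene protein/transcript logFC with concordance, sorted for display.

    Rows are ordered by protein logFC descending; ties break alphabetically
    by symbol.  Requires both layers per row.
    """
    df = crossing.table
    for col in ("protein_log2FC", "transcript_log2FC"):
        if col not in df.columns:
            raise KeyError(f"direction_table needs column {col!r}")
    out = df[["protein_log2FC", "transcript_log2FC"]].copy()
    out["concordant"] = (out["protein_log2FC"] * out["transcript_log2FC"]) > 0
    out = out.sort_index().sort_values("protein_log2FC", ascending=False, kind="mergesort")
    return out


def load_are_demo_table() -> pd.DataFrame:
    """Packaged 17-gene ARE/NRF2-target demo table of published cohort log2FCs.

    Columns protein_log2FC and transcript_log2FC, indexed by gene symbol —
    the worked-example input for the ARE crossing.
    """
    path = resources.files("ulmomics.data") / "are_nrf2_targets_log2fc.tsv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", index_col="symbol")


def load_are_gene_set() -> GeneSet:
    """Gene set of the packaged ARE/NRF2-target demo table."""
    path = resources.files("ulmomics.data") / "are_nrf2_targets.gmt"
    with resources.as_file(path) as p:
        return read_gene_sets(p)[0]
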