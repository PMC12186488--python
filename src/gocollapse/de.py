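"""Differential-expression tables and directional significance selection.

Consumes DESeq2-style result tables (``gene_id``, ``log2FoldChange``,
``pvalue``, ``padj``) and applies the volcano-plot thresholds — strict
``p < alpha`` and ``|l2fc| > lfc_min`` — to produce disjoint up/down gene
lists for enrichment testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import IO, Mapping

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: default DESeq2 result column names; a column map can rename other dialects
DESEQ2_COLUMNS = {"gene_id": "gene_id", "l2fc": "log2FoldChange",
                  "pvalue": "pvalue", "padj": "padj"}


@dataclass
class DEResultTable:
    """One species/contrast worth of per-gene DE results.

    ``frame`` is indexed by gene id with columns ``l2fc`` (finite float),
    ``pvalue`` and ``padj`` (floats in [0, 1] or NaN for missing).
    """

    species_label: str
    frame: pd.DataFrame

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.frame.index)

    def l2fc_of(self, genes) -> list[float]:
        """l2fc values for the given genes, skipping unmeasured ones.

        Values come back in sorted-gene-id order so downstream summaries
        are order-independent; the number of missing genes is logged.
        """
        wanted = sorted(genes)
        present = [g for g in wanted if g in self.frame.index]
        missing = len(wanted) - len(present)
        if missing:
            logger.warning(
                "%s: %d gene(s) absent from the DE table excluded from l2fc values",
                self.species_label, missing,
            )
        return [float(v) for v in self.frame.loc[present, "l2fc"]]


@dataclass(frozen=True)
class DirectionalGeneLists:
    """Disjoint up/down significant gene sets plus the thresholds used."""

    up: frozenset[str]
    down: frozenset[str]
    alpha: float
    lfc_min: float
    p_column: str

    @property
    def all_significant(self) -> frozenset[str]:
        return self.up | self.down


def read_de_table(
    source: IO[str] | str,
    species_label: str,
    column_map: Mapping[str, str] | None = None,
) -> DEResultTable:
    """Read a DESeq2-style TSV into a :class:`DEResultTable`.

    Requires a gene id column and a log2 fold change column plus at least
    one of pvalue/padj; "NA" marks missing values.  Rows with missing or
    non-finite l2fc are dropped (count logged).  Duplicate gene ids and
    p-values outside [0, 1] raise :class:`ValidationError`.
    """
    cols = dict(DESEQ2_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(source, sep="\t", na_values=["NA"], dtype={0: str})

    for key in ("gene_id", "l2fc"):
        if cols[key] not in df.columns:
            raise SchemaError(f"DE table is missing required column {cols[key]!r}")
    if cols["pvalue"] not in df.columns and cols["padj"] not in df.columns:
        raise SchemaError(
            f"DE table needs at least one of {cols['pvalue']!r} or {cols['padj']!r}"
        )

    rename = {cols["gene_id"]: "gene_id", cols["l2fc"]: "l2fc"}
    for key in ("pvalue", "padj"):
        if cols[key] in df.columns:
            rename[cols[key]] = key
    df = df.rename(columns=rename)
    for key in ("pvalue", "padj"):
        if key not in df.columns:
            df[key] = np.nan
    df = df[["gene_id", "l2fc", "pvalue", "padj"]]

    dupes = df["gene_id"][df["gene_id"].duplicated()]
    if len(dupes):
        raise ValidationError(f"duplicate gene id in DE table: {dupes.iloc[0]!r}")

    bad_l2fc = ~np.isfinite(df["l2fc"].astype(float))
    if bad_l2fc.any():
        logger.warning(
            "%s: dropped %d row(s) with missing/non-finite log2 fold change",
            species_label, int(bad_l2fc.sum()),
        )
        df = df[~bad_l2fc]

    for key in ("pvalue", "padj"):
        vals = df[key].astype(float)
        out_of_range = vals.notna() & ((vals < 0) | (vals > 1))
        if out_of_range.any():
            gene = df.loc[out_of_range, "gene_id"].iloc[0]
            raise ValidationError(f"{key} outside [0, 1] for gene {gene!r}")

    frame = df.set_index("gene_id").astype(float)
    return DEResultTable(species_label=species_label, frame=frame)


def select_directional(
    table: DEResultTable,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    p_column: str = "padj",
) -> DirectionalGeneLists:
    """Apply strict volcano thresholds ``p < alpha`` and ``|l2fc| > lfc_min``.

    Genes with a missing value in ``p_column`` are excluded from both
    lists (never treated as significant).
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if lfc_min < 0:
        raise ValidationError(f"lfc_min must be >= 0, got {lfc_min}")
    if p_column not in ("padj", "pvalue"):
        raise SchemaError(f"p_column must be 'padj' or 'pvalue', got {p_column!r}")
    p = table.frame[p_column]
    if p.isna().all() and len(table.frame):
        raise SchemaError(
            f"selection on {p_column!r} requested but the DE table has no "
            f"{p_column} values"
        )
    sig = p.notna() & (p < alpha)
    l2fc = table.frame["l2fc"]
    up = frozenset(table.frame.index[sig & (l2fc > lfc_min)])
    down = frozenset(table.frame.index[sig & (l2fc < -lfc_min)])
    return DirectionalGeneLists(
        up=up, down=down, alpha=alpha, lfc_min=lfc_min, p_column=p_column
    )


def volcano_counts(
    table: DEResultTable,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    p_column: str = "padj",
) -> int:
    """Total genes passing both thresholds (the volcano-plot headline count)."""
    lists = select_directional(table, alpha=alpha, lfc_min=lfc_min, p_column=p_column)
    return len(lists.up) + len(lists.down)


def list_intersections(
    lists_by_condition: Mapping[str, DirectionalGeneLists],
) -> dict[str, dict[tuple[str, ...], int]]:
    """Venn-cell sizes of the up and down gene sets across conditions.

    For each direction and each nonempty subset S of conditions, reports
    the number of genes present in every set of S and in no other
    condition's set (an exact Venn region).
    """
    if len(lists_by_condition) < 2:
        raise ValidationError("list_intersections needs at least 2 conditions")
    labels = sorted(lists_by_condition)
    out: dict[str, dict[tuple[str, ...], int]] = {}
    for direction in ("up", "down"):
        sets = {lab: getattr(lists_by_condition[lab], direction) for lab in labels}
        cells: dict[tuple[str, ...], int] = {}
        for r in range(1, len(labels) + 1):
            for inside in combinations(labels, r):
                region = frozenset.intersection(*(sets[lab] for lab in inside))
                for lab in labels:
                    if lab not in inside:
                        region = region - sets[lab]
                cells[inside] = len(region)
        out[direction] = cells
    return out
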