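"""Hypergeometric over-representation analysis with BH FDR control.

For a gene list of size n drawn from a universe of N genes, a term with K
annotated genes overlapping the list in k genes is scored by the
upper-tail probability P[X >= k], X ~ Hypergeometric(N, K, n).  Up and
down lists are tested and BH-corrected independently, and the BH family
is exactly the size-eligible terms tested for that direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .de import DirectionalGeneLists
from .errors import ValidationError
from .ontology import AnnotationMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentRecord:
    """One tested GO term in one direction."""

    term: str
    direction: str          # "up" or "down"
    k: int                  # list ∩ term
    K: int                  # term size in universe
    n: int                  # list size in universe
    N: int                  # universe size
    p: float                # hypergeometric upper tail P[X >= k]
    padj: float             # BH-adjusted within direction
    genes: frozenset[str]   # the k overlapping genes


@dataclass
class OraResult:
    """Per-direction significant records plus BH-family bookkeeping."""

    records: dict[str, list[EnrichmentRecord]]
    n_tested: dict[str, int]
    padj_cutoff: float

    @property
    def up(self) -> list[EnrichmentRecord]:
        return self.records["up"]

    @property
    def down(self) -> list[EnrichmentRecord]:
        return self.records["down"]

    def enriched_terms(self) -> set[str]:
        """Union of significant terms over both directions."""
        return {r.term for recs in self.records.values() for r in recs}

    def directions_of(self, term: str) -> set[str]:
        return {
            d for d, recs in self.records.items() if any(r.term == term for r in recs)
        }


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n), via the survival function.

    Raises :class:`ValidationError` for impossible counts.
    """
    for label, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValidationError(f"{label} must be a nonnegative integer, got {v!r}")
    if K > N or n > N:
        raise ValidationError(f"K={K} and n={n} must not exceed N={N}")
    if k > min(K, n):
        raise ValidationError(f"impossible overlap k={k} > min(K={K}, n={n})")
    if k == 0:
        return 1.0
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= i} ( m * p_(j) / j ) over the ascending order,
    capped at 1; ties share a value.
    """
    arr = np.asarray(list(pvalues), dtype=float)
    if arr.size == 0:
        return arr
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise ValidationError("p-values must be finite and within [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def run_ora(
    lists: DirectionalGeneLists,
    ann: AnnotationMap,
    min_term_size: int = 3,
    max_term_size: int = 500,
    padj_cutoff: float = 0.05,
) -> OraResult:
    """Test every size-eligible term against the up and the down list.

    Genes outside the annotation universe are dropped with a warning; an
    empty list yields an empty result for that direction.  Output records
    are those with ``padj < padj_cutoff``, sorted by (padj, p, term id).
    """
    if min_term_size < 1:
        raise ValidationError(f"min_term_size must be >= 1, got {min_term_size}")
    if max_term_size < min_term_size:
        raise ValidationError("max_term_size must be >= min_term_size")
    N = len(ann.universe)
    eligible = sorted(
        t for t, gs in ann.propagated.items()
        if min_term_size <= len(gs) <= max_term_size
    )

    records: dict[str, list[EnrichmentRecord]] = {}
    n_tested: dict[str, int] = {}
    for direction in ("up", "down"):
        gene_list = getattr(lists, direction)
        outside = gene_list - ann.universe
        if outside:
            logger.warning(
                "%s/%s: dropped %d gene(s) outside the annotation universe",
                ann.species_label, direction, len(outside),
            )
            gene_list = gene_list & ann.universe
        n = len(gene_list)
        if n == 0:
            logger.warning(
                "%s/%s: empty significant gene list, no enrichment performed",
                ann.species_label, direction,
            )
            records[direction] = []
            n_tested[direction] = 0
            continue
        raw: list[tuple[str, int, int, float, frozenset[str]]] = []
        for term in eligible:
            genes = ann.propagated[term]
            overlap = genes & gene_list
            p = hypergeom_upper_tail(len(overlap), len(genes), n, N)
            raw.append((term, len(overlap), len(genes), p, frozenset(overlap)))
        padj = bh_adjust([r[3] for r in raw])
        recs = [
            EnrichmentRecord(
                term=term, direction=direction, k=k, K=K, n=n, N=N,
                p=p, padj=float(q), genes=overlap,
            )
            for (term, k, K, p, overlap), q in zip(raw, padj)
            if q < padj_cutoff
        ]
        recs.sort(key=lambda r: (r.padj, r.p, r.term))
        records[direction] = recs
        n_tested[direction] = len(raw)
    return OraResult(records=records, n_tested=n_tested, padj_cutoff=padj_cutoff)
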