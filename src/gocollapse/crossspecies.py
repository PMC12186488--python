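"""Joint two-species term clustering and shared-cluster reporting.

The two species are annotated against the same ontology, so the same GO
term can appear in both dissimilarity matrices.  For such term pairs the
joint dissimilarity is the arithmetic mean of the two species' values;
pairs measurable in only one species keep that species' value; pairs of
terms that no single species annotates together are assigned 1 (never
merged).  Cutting the joint tree yields GO clusters spanning both
species; a cluster is *shared* when at least one member term is enriched
in each species (in either direction), which also captures opposite
responses — up in one species, down in the other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cluster import DissimilarityMatrix, GOCluster, cluster_stats
from .de import DEResultTable, DirectionalGeneLists
from .enrich import OraResult
from .errors import ValidationError
from .ontology import AnnotationMap

logger = logging.getLogger(__name__)


def joint_matrix(
    matrix_a: DissimilarityMatrix, matrix_b: DissimilarityMatrix
) -> DissimilarityMatrix:
    """Merge two species' dissimilarity matrices over the union term set."""
    if matrix_a.metric_tag != matrix_b.metric_tag:
        raise ValidationError(
            f"metric mismatch: {matrix_a.metric_tag!r} vs {matrix_b.metric_tag!r}"
        )
    terms = tuple(sorted(set(matrix_a.terms) | set(matrix_b.terms)))
    ia = {t: i for i, t in enumerate(matrix_a.terms)}
    ib = {t: i for i, t in enumerate(matrix_b.terms)}
    k = len(terms)
    d = np.zeros((k, k))
    n_unmeasured = 0
    for i in range(k):
        for j in range(i + 1, k):
            s, t = terms[i], terms[j]
            in_a = s in ia and t in ia
            in_b = s in ib and t in ib
            if in_a and in_b:
                val = 0.5 * (matrix_a.d[ia[s], ia[t]] + matrix_b.d[ib[s], ib[t]])
            elif in_a:
                val = float(matrix_a.d[ia[s], ia[t]])
            elif in_b:
                val = float(matrix_b.d[ib[s], ib[t]])
            else:
                val = 1.0  # no species annotates both terms; never merged
                n_unmeasured += 1
            d[i, j] = d[j, i] = val
    if n_unmeasured:
        logger.warning(
            "%d term pair(s) measurable in neither species assigned d=1",
            n_unmeasured,
        )
    return DissimilarityMatrix(terms=terms, d=d, metric_tag=matrix_a.metric_tag)


@dataclass(frozen=True)
class BoxSummary:
    """Tukey boxplot summary of an l2fc distribution.

    Quartiles use linear interpolation between order statistics; whiskers
    reach the most extreme values within 1.5·IQR of the box; everything
    beyond is listed individually as an outlier.
    """

    n: int
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: tuple[float, ...]


def l2fc_summary(values: Sequence[float]) -> BoxSummary:
    """Boxplot statistics of a fold-change multiset (>= 1 value required)."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValidationError("cannot summarise an empty l2fc multiset")
    q1, med, q3 = (float(q) for q in np.percentile(vals, [25, 50, 75]))
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
    outliers = tuple(sorted(float(v) for v in vals[(vals < lo_fence) | (vals > hi_fence)]))
    return BoxSummary(
        n=int(vals.size),
        median=med,
        q1=q1,
        q3=q3,
        whisker_lo=float(inside.min()),
        whisker_hi=float(inside.max()),
        outliers=outliers,
    )


@dataclass
class SpeciesClusterView:
    """One species' slice of a joint cluster."""

    species_label: str
    member_terms: tuple[str, ...]       # members annotated in this species
    enriched_directions: tuple[str, ...]
    n_genes: int
    ratio_n: float
    ratio_up: float
    ratio_down: float
    box: BoxSummary | None              # None when no member gene is measured


@dataclass
class JointClusterReport:
    """A joint GO cluster with per-species statistics and a shared flag."""

    cluster_id: str
    members: tuple[str, ...]
    representative: str
    shared: bool
    per_species: dict[str, SpeciesClusterView]


def _joint_representative(
    members: Sequence[str],
    anns: Sequence[AnnotationMap],
    sigs: Sequence[frozenset[str]],
) -> str:
    """Representative for a joint cluster.

    Scores each member by its best per-species proportion of significant
    genes (over the species that annotate it); ties go to the smaller
    minimum term size, then the lexicographically smaller id.
    """

    def key(term: str):
        props = []
        sizes = []
        for ann, sig in zip(anns, sigs):
            genes = ann.propagated.get(term)
            if genes:
                props.append(len(genes & sig) / len(genes))
                sizes.append(len(genes))
        best = max(props) if props else 0.0
        size = min(sizes) if sizes else 0
        return (-best, size, term)

    return min(members, key=key)


def shared_clusters(
    joint_clusters: Sequence[tuple[str, ...]],
    joint: DissimilarityMatrix,
    ora_a: OraResult,
    ora_b: OraResult,
    ann_a: AnnotationMap,
    ann_b: AnnotationMap,
    lists_a: DirectionalGeneLists,
    lists_b: DirectionalGeneLists,
    de_a: DEResultTable,
    de_b: DEResultTable,
    include_all: bool = False,
) -> list[JointClusterReport]:
    """Build per-cluster reports; shared clusters only unless ``include_all``.

    The output is invariant to which species is called A and which B,
    apart from the species labels themselves.
    """
    species = (
        (ann_a, ora_a, lists_a, de_a),
        (ann_b, ora_b, lists_b, de_b),
    )
    reports: list[JointClusterReport] = []
    for idx, members in enumerate(sorted(joint_clusters)):
        views: dict[str, SpeciesClusterView] = {}
        enriched_flags = []
        for ann, ora, lists, de in species:
            enriched = ora.enriched_terms() & set(members)
            directions = tuple(
                sorted({d for t in enriched for d in ora.directions_of(t)})
            )
            enriched_flags.append(bool(enriched))
            local = tuple(t for t in members if t in ann.propagated)
            if local:
                stats: GOCluster = cluster_stats(
                    local, ann, lists.up, lists.down, de
                )
                box = l2fc_summary(stats.l2fc_values) if stats.l2fc_values else None
                views[ann.species_label] = SpeciesClusterView(
                    species_label=ann.species_label,
                    member_terms=local,
                    enriched_directions=directions,
                    n_genes=len(stats.union_genes),
                    ratio_n=stats.ratio_n,
                    ratio_up=stats.ratio_up,
                    ratio_down=stats.ratio_down,
                    box=box,
                )
            else:
                views[ann.species_label] = SpeciesClusterView(
                    species_label=ann.species_label,
                    member_terms=(),
                    enriched_directions=(),
                    n_genes=0,
                    ratio_n=0.0,
                    ratio_up=0.0,
                    ratio_down=0.0,
                    box=None,
                )
        shared = all(enriched_flags)
        if not shared and not include_all:
            continue
        rep = _joint_representative(
            members,
            (ann_a, ann_b),
            (lists_a.all_significant, lists_b.all_significant),
        )
        reports.append(
            JointClusterReport(
                cluster_id=f"C{idx + 1:03d}",
                members=tuple(members),
                representative=rep,
                shared=shared,
                per_species=views,
            )
        )
    return reports
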