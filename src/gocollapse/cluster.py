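"""Collapse redundant GO terms by gene-membership overlap.

Enriched terms often describe near-identical gene sets.  This module
builds a term-by-term dissimilarity matrix from gene membership (0 =
identical gene sets, 1 = no shared genes), runs complete-linkage
agglomerative clustering, and cuts the tree at a height threshold so that
every pair of terms inside a cluster shares at least the required
fraction of genes.  The default cut height of 0.25 corresponds to
clusters whose members pairwise share >= 75% of their genes under the
Jaccard reading of overlap.

Each cluster is then labelled by a representative term — the member with
the highest proportion of significantly up/down-regulated genes — and
summarised by ``ratio n``: the number of differentially regulated genes
in the cluster divided by the total number of genes in the cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .de import DEResultTable
from .errors import ValidationError
from .ontology import AnnotationMap

logger = logging.getLogger(__name__)

Metric = Literal["jaccard", "overlap_coefficient"]

DEFAULT_CUT_HEIGHT = 0.25  # complement of "at least 75% shared genes"


def term_dissimilarity(
    genes_a: frozenset[str] | set[str],
    genes_b: frozenset[str] | set[str],
    metric: Metric = "jaccard",
) -> float:
    """Gene-membership dissimilarity between two term gene sets.

    ``jaccard``: 1 - |A∩B| / |A∪B|; ``overlap_coefficient``:
    1 - |A∩B| / min(|A|, |B|).  Both are 0 for identical sets and 1 for
    disjoint sets.
    """
    if not genes_a or not genes_b:
        raise ValidationError("term gene sets must be nonempty")
    inter = len(genes_a & genes_b)
    if metric == "jaccard":
        return 1.0 - inter / len(genes_a | genes_b)
    if metric == "overlap_coefficient":
        return 1.0 - inter / min(len(genes_a), len(genes_b))
    raise ValidationError(f"unknown metric {metric!r}")


@dataclass
class DissimilarityMatrix:
    """Symmetric term dissimilarities with a deterministic term order."""

    terms: tuple[str, ...]
    d: np.ndarray
    metric_tag: str

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        k = len(self.terms)
        if self.d.shape != (k, k):
            raise ValidationError(
                f"matrix shape {self.d.shape} does not match {k} terms"
            )
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValidationError("dissimilarity matrix is not symmetric")
        if np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise ValidationError("dissimilarity matrix diagonal must be zero")
        if np.any(self.d < -1e-12) or np.any(self.d > 1 + 1e-12):
            raise ValidationError("dissimilarities must lie in [0, 1]")

    def index_of(self, term: str) -> int:
        return self.terms.index(term)

    def value(self, term_a: str, term_b: str) -> float:
        return float(self.d[self.index_of(term_a), self.index_of(term_b)])


def build_matrix(
    terms: Iterable[str], ann: AnnotationMap, metric: Metric = "jaccard"
) -> DissimilarityMatrix:
    """All-pairs dissimilarity over ``terms``, ordered by term id."""
    ordered = tuple(sorted(set(terms)))
    if not ordered:
        raise ValidationError("build_matrix needs at least one term")
    sets = [ann.term_genes(t) for t in ordered]  # raises for unknown terms
    k = len(ordered)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = term_dissimilarity(sets[i], sets[j], metric)
    return DissimilarityMatrix(terms=ordered, d=d, metric_tag=metric)


@dataclass
class MergeNode:
    """One internal node of the agglomeration tree."""

    height: float
    members: tuple[str, ...]        # sorted term ids
    children: tuple[object, object] | None  # (MergeNode|str, MergeNode|str)


def _linkage_tree(matrix: DissimilarityMatrix) -> MergeNode | str:
    """Full complete-linkage agglomeration with a deterministic tie-break.

    When several pairs attain the minimal linkage value, the pair whose
    merged sorted term-id tuple is lexicographically smallest merges
    first.  Complete linkage has no inversions, so merge heights are
    nondecreasing and equal the maximum pairwise dissimilarity inside the
    merged cluster.
    """
    terms = matrix.terms
    if len(terms) == 1:
        return terms[0]
    nodes: dict[int, MergeNode | str] = {i: terms[i] for i in range(len(terms))}
    members: dict[int, tuple[str, ...]] = {i: (terms[i],) for i in range(len(terms))}
    dist: dict[frozenset[int], float] = {
        frozenset((i, j)): float(matrix.d[i, j])
        for i in range(len(terms))
        for j in range(i + 1, len(terms))
    }
    next_id = len(terms)
    while len(nodes) > 1:
        best_key = None
        best_pair = None
        for pair, dd in dist.items():
            i, j = sorted(pair)
            key = (dd, tuple(sorted(members[i] + members[j])))
            if best_key is None or key < best_key:
                best_key, best_pair = key, (i, j)
        i, j = best_pair
        height = dist[frozenset((i, j))]
        merged = tuple(sorted(members[i] + members[j]))
        node = MergeNode(height=height, members=merged, children=(nodes[i], nodes[j]))
        del dist[frozenset((i, j))]
        for k in list(nodes):
            if k in (i, j):
                continue
            dik = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            dist[frozenset((next_id, k))] = max(dik, djk)  # complete linkage
        del nodes[i], nodes[j], members[i], members[j]
        nodes[next_id] = node
        members[next_id] = merged
        next_id += 1
    return next(iter(nodes.values()))


def _cut(node: MergeNode | str, cut_height: float) -> list[tuple[str, ...]]:
    """Maximal subtrees whose merge height is <= cut_height (inclusive)."""
    if isinstance(node, str):
        return [(node,)]
    if node.height <= cut_height:
        return [node.members]
    out: list[tuple[str, ...]] = []
    for child in node.children:
        out.extend(_cut(child, cut_height))
    return out


def complete_linkage_cut(
    matrix: DissimilarityMatrix, cut_height: float = DEFAULT_CUT_HEIGHT
) -> list[tuple[str, ...]]:
    """Flat clusters from complete-linkage agglomeration cut at ``cut_height``.

    The cut is inclusive (pairs at exactly the threshold merge).  Every
    output cluster satisfies the complete-linkage guarantee: all pairwise
    dissimilarities among its members are <= ``cut_height``.  Clusters are
    returned as sorted term-id tuples, ordered by their first member.
    """
    if not 0 <= cut_height <= 1:
        raise ValidationError(f"cut_height must be in [0, 1], got {cut_height}")
    tree = _linkage_tree(matrix)
    clusters = sorted(_cut(tree, cut_height))
    for members in clusters:  # assert the guarantee on every run
        idx = [matrix.index_of(t) for t in members]
        sub = matrix.d[np.ix_(idx, idx)]
        if sub.max(initial=0.0) > cut_height + 1e-12:
            raise AssertionError(
                "complete-linkage guarantee violated for cluster "
                f"{members}: max within-cluster d={sub.max():.6f} > {cut_height}"
            )
    return clusters


def to_newick(matrix: DissimilarityMatrix) -> str:
    """Merge tree as a Newick string; branch lengths are height increments.

    Term ids contain ``:`` so every leaf label is single-quoted.
    """
    tree = _linkage_tree(matrix)

    def render(node: MergeNode | str, parent_height: float) -> str:
        if isinstance(node, str):
            return f"'{node}':{parent_height:.6g}"
        inner = ",".join(render(c, node.height) for c in node.children)
        return f"({inner}):{parent_height - node.height:.6g}"

    if isinstance(tree, str):
        return f"'{tree}':0;"
    inner = ",".join(render(c, tree.height) for c in tree.children)
    return f"({inner});"


def select_representative(
    members: Sequence[str], ann: AnnotationMap, sig_genes: frozenset[str] | set[str]
) -> str:
    """Member term with the highest proportion of significant genes.

    Ties go to the smaller term, then the lexicographically smaller id,
    so the choice is stable across runs.
    """
    if not members:
        raise ValidationError("cannot pick a representative from zero members")

    def key(term: str):
        genes = ann.term_genes(term)
        prop = len(genes & set(sig_genes)) / len(genes)
        return (-prop, len(genes), term)

    return min(members, key=key)


@dataclass
class GOCluster:
    """A collapsed group of GO terms with its summary statistics.

    ``ratio_n`` pools both directions (differentially regulated genes in
    the cluster over all genes in the cluster); ``ratio_up``/``ratio_down``
    are the per-direction variants.  ``l2fc_values`` holds the fold
    changes of every cluster gene measured in the DE table.
    """

    members: tuple[str, ...]
    representative: str
    union_genes: frozenset[str]
    sig_genes: frozenset[str]
    ratio_n: float
    ratio_up: float
    ratio_down: float
    height: float
    l2fc_values: tuple[float, ...]


def cluster_stats(
    members: Sequence[str],
    ann: AnnotationMap,
    up: frozenset[str] | set[str],
    down: frozenset[str] | set[str],
    de_table: DEResultTable,
    matrix: DissimilarityMatrix | None = None,
) -> GOCluster:
    """Complete a cluster: union set, significant overlap, ratios, l2fc."""
    if not members:
        raise ValidationError("cluster must have at least one member")
    members = tuple(sorted(members))
    union: frozenset[str] = frozenset().union(*(ann.term_genes(t) for t in members))
    up = frozenset(up)
    down = frozenset(down)
    sig = union & (up | down)
    representative = select_representative(members, ann, up | down)
    height = 0.0
    if matrix is not None and len(members) > 1:
        idx = [matrix.index_of(t) for t in members]
        height = float(matrix.d[np.ix_(idx, idx)].max())
    return GOCluster(
        members=members,
        representative=representative,
        union_genes=union,
        sig_genes=sig,
        ratio_n=len(sig) / len(union),
        ratio_up=len(union & up) / len(union),
        ratio_down=len(union & down) / len(union),
        height=height,
        l2fc_values=tuple(de_table.l2fc_of(union)),
    )
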