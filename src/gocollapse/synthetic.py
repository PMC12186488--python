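"""Deterministic synthetic ontologies, annotations and DE tables.

These generators emulate the inputs of a two-species co-culture
transcriptomics comparison — a GO DAG, per-species gene annotations, and
DESeq2-style result tables — with *planted* structure whose ground truth
is recorded, so every pipeline stage can be tested end to end without
any downloads:

* planted term groups: clusters of leaf terms built from a shared core
  gene set plus a few private genes per term, so within-group Jaccard
  similarity stays at or above a requested level while groups built from
  disjoint gene pools stay maximally dissimilar;
* planted differential expression: all genes of selected groups receive
  large fold changes and tiny adjusted p-values in a chosen direction,
  making those terms the enriched ones by construction.

Everything is driven by a single integer seed and regenerating with the
same seed reproduces byte-identical text artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .ontology import OntologyGraph, parse_obo

DEFAULT_NAMESPACE = "molecular_function"


def _term_id(i: int) -> str:
    return f"GO:{i:07d}"


def _gene_id(i: int) -> str:
    return f"g{i:04d}"


def make_ontology(
    n_terms: int = 60,
    max_depth: int = 4,
    branching: int = 3,
    seed: int = 0,
    namespace: str = DEFAULT_NAMESPACE,
) -> str:
    """Emit a rooted single-namespace tree ontology as OBO 1.2 text.

    Term i+1 attaches by ``is_a`` to a uniformly chosen existing term
    that still has spare child slots (< ``branching`` children) and depth
    < ``max_depth``.  Raises if ``n_terms`` exceeds the capacity of such
    a tree.
    """
    if n_terms < 1:
        raise ValidationError("n_terms must be >= 1")
    if max_depth < 0 or branching < 1:
        raise ValidationError("max_depth must be >= 0 and branching >= 1")
    capacity = sum(branching**d for d in range(max_depth + 1))
    if n_terms > capacity:
        raise ValidationError(
            f"a depth-{max_depth}, branching-{branching} tree holds at most "
            f"{capacity} terms; {n_terms} requested"
        )
    rng = np.random.default_rng(seed)
    depth = {1: 0}
    n_children = {1: 0}
    parent: dict[int, int] = {}
    for i in range(2, n_terms + 1):
        open_slots = sorted(
            t for t in depth if depth[t] < max_depth and n_children[t] < branching
        )
        p = int(open_slots[rng.integers(len(open_slots))])
        parent[i] = p
        depth[i] = depth[p] + 1
        n_children[p] += 1
        n_children[i] = 0

    lines = ["format-version: 1.2", ""]
    for i in range(1, n_terms + 1):
        lines.append("[Term]")
        lines.append(f"id: {_term_id(i)}")
        lines.append(f"name: synthetic term {i}")
        lines.append(f"namespace: {namespace}")
        if i in parent:
            lines.append(
                f"is_a: {_term_id(parent[i])} ! synthetic term {parent[i]}"
            )
        lines.append("")
    return "\n".join(lines)


@dataclass
class AnnotationTruth:
    """Ground truth recorded while generating one species' annotations."""

    seed: int
    planted_term_groups: list[list[str]]
    group_gene_pools: list[list[str]]
    term_genes: dict[str, list[str]]          # direct sets of planted terms
    min_within_similarity: float
    max_between_similarity: float
    universe: list[str]


def _jaccard_sim(a: set[str], b: set[str]) -> float:
    return len(a & b) / len(a | b)


def make_annotations(
    ontology: str | OntologyGraph,
    n_genes: int = 500,
    term_size_range: tuple[int, int] = (5, 15),
    planted_groups: tuple[int, int, float] = (5, 4, 0.8),
    core_size: int = 20,
    seed: int = 0,
    planted_terms: Sequence[Sequence[str]] | None = None,
) -> tuple[str, AnnotationTruth]:
    """Generate a two-column annotation TSV with planted term groups.

    ``planted_groups`` is (group count, terms per group, target within-
    group Jaccard similarity).  Each group draws a disjoint core gene
    pool; every member term gets the full core plus at most
    ``floor(core·(1-s)/(2s))`` private genes, which bounds every within-
    group pairwise Jaccard similarity at >= s.  Non-planted leaf terms
    are annotated from the leftover background pool, so between-group
    similarity among planted cores is 0 (distance 1).  Pass
    ``planted_terms`` to pin the groups to specific leaf terms (used to
    give two species identical planted structure).
    """
    graph = ontology if isinstance(ontology, OntologyGraph) else parse_obo(ontology)
    n_groups, group_size, within_sim = planted_groups
    if not 0 < within_sim <= 1:
        raise ValidationError("within-group similarity must be in (0, 1]")
    rng = np.random.default_rng(seed)

    with_children = {p for pars in graph.parents.values() for p in pars}
    leaves = sorted(graph.terms - with_children)
    if planted_terms is None:
        if n_groups * group_size > len(leaves):
            raise ValidationError(
                f"need {n_groups * group_size} leaf terms for planting, "
                f"ontology has {len(leaves)}"
            )
        chosen = rng.choice(len(leaves), size=n_groups * group_size, replace=False)
        planted = [
            sorted(leaves[j] for j in chosen[g * group_size:(g + 1) * group_size])
            for g in range(n_groups)
        ]
    else:
        planted = [sorted(group) for group in planted_terms]
        for group in planted:
            for t in group:
                if t not in graph.terms:
                    raise ValidationError(f"planted term {t} not in the ontology")

    n_private = int(core_size * (1 - within_sim) // (2 * within_sim))
    pool_size = core_size + group_size * n_private
    if len(planted) * pool_size > n_genes:
        raise ValidationError(
            f"planting {len(planted)} groups needs {len(planted) * pool_size} "
            f"genes, universe has {n_genes}"
        )

    universe = [_gene_id(i) for i in range(1, n_genes + 1)]
    order = [universe[j] for j in rng.permutation(n_genes)]
    cursor = 0
    pairs: list[tuple[str, str]] = []
    group_pools: list[list[str]] = []
    term_genes: dict[str, list[str]] = {}
    for group in planted:
        pool = order[cursor:cursor + pool_size]
        cursor += pool_size
        group_pools.append(sorted(pool))
        core = pool[:core_size]
        for m, term in enumerate(group):
            start = core_size + m * n_private
            private = pool[start:start + n_private]
            genes = sorted(core + private)
            term_genes[term] = genes
            pairs.extend((g, term) for g in genes)

    background = order[cursor:]
    planted_set = {t for group in planted for t in group}
    lo, hi = term_size_range
    for term in leaves:
        if term in planted_set:
            continue
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(background))
        picks = rng.choice(len(background), size=size, replace=False)
        pairs.extend((background[j], term) for j in sorted(picks))

    # realized similarity bookkeeping from the emitted sets
    within = [
        _jaccard_sim(set(term_genes[a]), set(term_genes[b]))
        for group in planted
        for a, b in combinations(group, 2)
    ]
    between = [
        _jaccard_sim(set(term_genes[a]), set(term_genes[b]))
        for ga, gb in combinations(range(len(planted)), 2)
        for a in planted[ga]
        for b in planted[gb]
    ]
    truth = AnnotationTruth(
        seed=seed,
        planted_term_groups=[list(g) for g in planted],
        group_gene_pools=group_pools,
        term_genes=term_genes,
        min_within_similarity=min(within) if within else 1.0,
        max_between_similarity=max(between) if between else 0.0,
        universe=universe,
    )
    rows = sorted(set(pairs))
    tsv = "".join(f"{g}\t{t}\n" for g, t in rows)
    return tsv, truth


@dataclass
class DETruth:
    """Ground truth recorded while generating one species' DE table."""

    seed: int
    planted_up_terms: list[str]
    planted_down_terms: list[str]
    planted_up_genes: list[str]
    planted_down_genes: list[str]
    n_up: int        # realized count passing padj < alpha and l2fc > lfc_min
    n_down: int      # realized count passing padj < alpha and l2fc < -lfc_min
    alpha: float = 0.05
    lfc_min: float = 1.0


def make_de_table(
    universe: Sequence[str],
    term_genes: Mapping[str, Sequence[str]],
    planted_up_terms: Sequence[str] = (),
    planted_down_terms: Sequence[str] = (),
    effect: tuple[float, float] = (3.0, 0.3),
    null_sd: float = 0.5,
    seed: int = 0,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
) -> tuple[str, DETruth]:
    """Emit a DESeq2-style TSV with planted directional effects.

    Genes of planted up/down terms draw l2fc ~ Normal(±mean, sd) with
    padj far below ``alpha``; all other genes draw l2fc ~ Normal(0,
    ``null_sd``) with uniform-ish p-values (padj >= pvalue).  The truth
    records the realized up/down counts passing the thresholds, found by
    re-filtering the emitted rows.
    """
    for t in (*planted_up_terms, *planted_down_terms):
        if t not in term_genes:
            raise ValidationError(f"planted term {t} has no annotated gene set")
    mean, sd = effect
    rng = np.random.default_rng(seed)
    up_genes = sorted({g for t in planted_up_terms for g in term_genes[t]})
    down_genes = sorted({g for t in planted_down_terms for g in term_genes[t]})
    clash = set(up_genes) & set(down_genes)
    if clash:
        raise ValidationError(
            f"{len(clash)} gene(s) planted in both directions, e.g. {sorted(clash)[0]}"
        )

    rows = []
    n_up = n_down = 0
    for gene in universe:
        if gene in set(up_genes):
            l2fc = float(rng.normal(mean, sd))
            padj = float(rng.uniform(1e-8, 1e-4))
            pvalue = padj / 2
        elif gene in set(down_genes):
            l2fc = float(rng.normal(-mean, sd))
            padj = float(rng.uniform(1e-8, 1e-4))
            pvalue = padj / 2
        else:
            l2fc = float(rng.normal(0.0, null_sd))
            pvalue = float(rng.uniform(0.0, 1.0))
            padj = min(1.0, pvalue * float(rng.uniform(1.0, 3.0)))
        if padj < alpha and l2fc > lfc_min:
            n_up += 1
        elif padj < alpha and l2fc < -lfc_min:
            n_down += 1
        rows.append((gene, l2fc, pvalue, padj))

    header = "gene_id\tlog2FoldChange\tpvalue\tpadj\n"
    body = "".join(
        f"{g}\t{l2fc:.6g}\t{p:.6g}\t{q:.6g}\n" for g, l2fc, p, q in rows
    )
    truth = DETruth(
        seed=seed,
        planted_up_terms=sorted(planted_up_terms),
        planted_down_terms=sorted(planted_down_terms),
        planted_up_genes=up_genes,
        planted_down_genes=down_genes,
        n_up=n_up,
        n_down=n_down,
        alpha=alpha,
        lfc_min=lfc_min,
    )
    return header + body, truth


@dataclass
class TwoSpeciesFixture:
    """A complete synthetic two-species study with recorded ground truth."""

    seed: int
    labels: tuple[str, str]
    obo_text: str
    annotation_text: dict[str, str]
    de_text: dict[str, str]
    annotation_truth: dict[str, AnnotationTruth]
    de_truth: dict[str, DETruth]
    planted_term_groups: list[list[str]] = field(default_factory=list)

    def truth_dict(self) -> dict:
        """JSON-serializable ground-truth summary."""
        out = {
            "seed": self.seed,
            "labels": list(self.labels),
            "planted_term_groups": self.planted_term_groups,
            "species": {},
        }
        for label in self.labels:
            at, dt = self.annotation_truth[label], self.de_truth[label]
            out["species"][label] = {
                "universe_size": len(at.universe),
                "min_within_similarity": at.min_within_similarity,
                "max_between_similarity": at.max_between_similarity,
                "planted_up_terms": dt.planted_up_terms,
                "planted_down_terms": dt.planted_down_terms,
                "n_up": dt.n_up,
                "n_down": dt.n_down,
            }
        return out


def make_two_species_fixture(
    seed: int = 0,
    labels: tuple[str, str] = ("species_A", "species_B"),
    n_terms: int = 60,
    n_genes: int = 500,
    planted_groups: tuple[int, int, float] = (5, 4, 0.8),
    core_size: int = 20,
    group_directions: Mapping[str, Mapping[int, str]] | None = None,
    effect: tuple[float, float] = (3.0, 0.3),
) -> TwoSpeciesFixture:
    """One ontology, two species' annotations and DE tables, shared truth.

    Both species plant the *same* leaf-term groups (so joint clustering
    has cross-species structure) but draw independent gene memberships
    and effects.  ``group_directions`` maps species label → {group index:
    "up"/"down"}; groups absent from a species' map are annotated but not
    differentially expressed there.  The default plants groups 0-2 up and
    3-4 down in both species.
    """
    ss = np.random.SeedSequence(seed)
    sub = ss.generate_state(5)
    obo = make_ontology(n_terms=n_terms, seed=int(sub[0]) % (2**31))
    graph = parse_obo(obo)

    if group_directions is None:
        default = {0: "up", 1: "up", 2: "up", 3: "down", 4: "down"}
        n_groups = planted_groups[0]
        default = {g: d for g, d in default.items() if g < n_groups}
        group_directions = {labels[0]: default, labels[1]: dict(default)}

    annotation_text: dict[str, str] = {}
    de_text: dict[str, str] = {}
    ann_truth: dict[str, AnnotationTruth] = {}
    de_truth: dict[str, DETruth] = {}
    planted: Sequence[Sequence[str]] | None = None
    for i, label in enumerate(labels):
        ann_tsv, a_truth = make_annotations(
            graph,
            n_genes=n_genes,
            planted_groups=planted_groups,
            core_size=core_size,
            seed=int(sub[1 + i]) % (2**31),
            planted_terms=planted,
        )
        planted = a_truth.planted_term_groups  # species B reuses A's groups
        dirs = group_directions.get(label, {})
        up_terms = [
            t for g, d in sorted(dirs.items()) if d == "up"
            for t in a_truth.planted_term_groups[g]
        ]
        down_terms = [
            t for g, d in sorted(dirs.items()) if d == "down"
            for t in a_truth.planted_term_groups[g]
        ]
        de_tsv, d_truth = make_de_table(
            a_truth.universe,
            a_truth.term_genes,
            planted_up_terms=up_terms,
            planted_down_terms=down_terms,
            effect=effect,
            seed=int(sub[3 + i]) % (2**31),
        )
        annotation_text[label] = ann_tsv
        de_text[label] = de_tsv
        ann_truth[label] = a_truth
        de_truth[label] = d_truth

    return TwoSpeciesFixture(
        seed=seed,
        labels=labels,
        obo_text=obo,
        annotation_text=annotation_text,
        de_text=de_text,
        annotation_truth=ann_truth,
        de_truth=de_truth,
        planted_term_groups=[list(g) for g in (planted or [])],
    )
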