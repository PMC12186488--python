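"""OBO ontology parsing, gene annotation reading, and is_a propagation.

The Gene Ontology is a DAG of terms connected by ``is_a`` edges.  A gene
directly annotated to a term is implicitly annotated to every ancestor of
that term, so before any term gene set is used (for enrichment or for
membership-overlap clustering) annotations are propagated upward through
the ``is_a`` closure within a single namespace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from io import StringIO
from typing import IO, Iterable, Literal

import networkx as nx

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")

AnnotationDialect = Literal["gaf", "two_column_tsv"]


def _as_stream(source: str | IO[str]) -> IO[str]:
    if isinstance(source, str):
        return StringIO(source)
    return source


@dataclass
class OntologyGraph:
    """An ontology restricted to term id, label, namespace and is_a edges.

    ``terms`` holds only non-obsolete terms; obsolete ids are kept in
    ``obsolete`` so annotations pointing at them can be reported.  The
    is_a relation is validated acyclic at construction time.
    """

    terms: set[str]
    name: dict[str, str]
    namespace: dict[str, str]
    parents: dict[str, set[str]]
    obsolete: set[str] = field(default_factory=set)
    _ancestor_cache: dict[str, frozenset[str]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        for term, pars in self.parents.items():
            missing = pars - self.terms
            if missing:
                raise ValidationError(
                    f"term {term} references unknown parent(s) {sorted(missing)}"
                )
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(
            (t, p) for t, pars in self.parents.items() for p in pars
        )
        if not nx.is_directed_acyclic_graph(g):
            cycle = [u for u, _ in nx.find_cycle(g)]
            raise ValidationError(
                "is_a relation contains a cycle: " + " -> ".join(sorted(set(cycle)))
            )

    def ancestors(self, term: str) -> frozenset[str]:
        """All is_a ancestors of ``term`` (transitive, excluding itself)."""
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        out: set[str] = set()
        for p in self.parents.get(term, ()):
            out.add(p)
            out |= self.ancestors(p)
        result = frozenset(out)
        self._ancestor_cache[term] = result
        return result

    def terms_in_namespace(self, namespace: str) -> set[str]:
        return {t for t in self.terms if self.namespace.get(t) == namespace}


def parse_obo(source: str | IO[str]) -> OntologyGraph:
    """Parse an OBO 1.2 document into an :class:`OntologyGraph`.

    Only ``[Term]`` stanzas are read; ``id``, ``name``, ``namespace``,
    ``is_a`` and ``is_obsolete`` lines are honoured and everything else is
    ignored.  Trailing ``! comment`` text on ``is_a`` targets is stripped.
    Obsolete terms are recorded separately and excluded from the graph;
    is_a edges into an obsolete or unknown term are dropped with a warning.

    Raises :class:`ParseError` for a ``[Term]`` stanza without an ``id``
    (naming the stanza's starting line) and :class:`ValidationError` for a
    cyclic is_a relation.
    """
    stream = _as_stream(source)
    stanzas: list[dict] = []
    current: dict | None = None
    in_term = False

    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if line.startswith("["):
            if in_term and current is not None:
                stanzas.append(current)
            in_term = line == "[Term]"
            current = {"line": lineno, "is_a": [], "obsolete": False} if in_term else None
            continue
        if not in_term or current is None or not line or line.startswith("!"):
            continue
        if ":" not in line:
            continue
        tag, _, value = line.partition(":")
        tag = tag.strip()
        value = value.strip()
        if tag == "id":
            current["id"] = value
        elif tag == "name":
            current["name"] = value
        elif tag == "namespace":
            current["namespace"] = value
        elif tag == "is_a":
            target = value.split("!", 1)[0].strip()
            current["is_a"].append(target)
        elif tag == "is_obsolete":
            current["obsolete"] = value.lower() == "true"
    if in_term and current is not None:
        stanzas.append(current)

    terms: set[str] = set()
    name: dict[str, str] = {}
    namespace: dict[str, str] = {}
    raw_parents: dict[str, list[str]] = {}
    obsolete: set[str] = set()

    for stanza in stanzas:
        term_id = stanza.get("id")
        if not term_id:
            raise ParseError(
                f"[Term] stanza starting at line {stanza['line']} has no id"
            )
        if stanza["obsolete"]:
            obsolete.add(term_id)
            continue
        terms.add(term_id)
        name[term_id] = stanza.get("name", term_id)
        namespace[term_id] = stanza.get("namespace", "")
        raw_parents[term_id] = stanza["is_a"]

    parents: dict[str, set[str]] = {}
    for term_id, targets in raw_parents.items():
        kept = set()
        for target in targets:
            if target in terms:
                kept.add(target)
            else:
                reason = "obsolete" if target in obsolete else "unknown"
                logger.warning(
                    "dropping is_a edge %s -> %s (%s target)", term_id, target, reason
                )
        if kept:
            parents[term_id] = kept

    return OntologyGraph(
        terms=terms, name=name, namespace=namespace, parents=parents, obsolete=obsolete
    )


def read_annotations(
    source: str | IO[str], dialect: AnnotationDialect = "two_column_tsv"
) -> list[tuple[str, str]]:
    """Read gene→term annotation pairs, deduplicated in input order.

    ``gaf``: GAF 2.x — tab-separated, ``!`` comment lines skipped, gene id
    from column 2, term from column 5; rows whose qualifier (column 4)
    contains ``NOT`` are dropped.  ``two_column_tsv``: headerless
    ``gene TAB term`` rows.
    """
    if dialect not in ("gaf", "two_column_tsv"):
        raise ValidationError(f"unknown annotation dialect: {dialect!r}")
    stream = _as_stream(source)
    pairs: dict[tuple[str, str], None] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if dialect == "gaf":
            if line.startswith("!"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ParseError(
                    f"line {lineno}: GAF row has {len(fields)} columns, expected >= 5"
                )
            if "NOT" in fields[3].split("|"):
                continue
            pairs[(fields[1], fields[4])] = None
        else:
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"line {lineno}: expected 2 tab-separated columns, got {len(fields)}"
                )
            pairs[(fields[0], fields[1])] = None
    return list(pairs)


@dataclass
class AnnotationMap:
    """Per-species propagated term → gene-set view over a gene universe."""

    species_label: str
    universe: frozenset[str]
    direct: dict[str, frozenset[str]]
    propagated: dict[str, frozenset[str]]
    namespace_filter: str

    def term_genes(self, term: str) -> frozenset[str]:
        try:
            return self.propagated[term]
        except KeyError:
            raise ValidationError(
                f"term {term} has no propagated gene set in species "
                f"{self.species_label!r}"
            ) from None

    @property
    def terms(self) -> set[str]:
        return set(self.propagated)


def propagate(
    graph: OntologyGraph,
    pairs: Iterable[tuple[str, str]],
    universe: Iterable[str],
    namespace: str,
    species_label: str = "",
) -> AnnotationMap:
    """Close direct annotations under is_a ancestry within one namespace.

    Pairs whose term is absent from the graph (or obsolete), and genes
    outside ``universe``, are dropped with a logged warning.  Terms whose
    propagated set comes out empty are omitted, so every retained term has
    at least one annotated gene.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValidationError("gene universe is empty")
    if namespace not in NAMESPACES:
        raise ValidationError(
            f"namespace must be one of {NAMESPACES}, got {namespace!r}"
        )

    direct: dict[str, set[str]] = {}
    propagated: dict[str, set[str]] = {}
    n_unknown_terms = 0
    n_outside_universe = 0
    for gene, term in pairs:
        if term not in graph.terms:
            n_unknown_terms += 1
            continue
        if gene not in universe:
            n_outside_universe += 1
            continue
        if graph.namespace.get(term) != namespace:
            continue
        direct.setdefault(gene, set()).add(term)
        for t in (term, *graph.ancestors(term)):
            if graph.namespace.get(t) == namespace:
                propagated.setdefault(t, set()).add(gene)
    if n_unknown_terms:
        logger.warning(
            "%s: dropped %d annotation pair(s) with unknown/obsolete terms",
            species_label or "annotations",
            n_unknown_terms,
        )
    if n_outside_universe:
        logger.warning(
            "%s: dropped %d annotation pair(s) for genes outside the universe",
            species_label or "annotations",
            n_outside_universe,
        )

    return AnnotationMap(
        species_label=species_label,
        universe=universe,
        direct={g: frozenset(ts) for g, ts in direct.items()},
        propagated={t: frozenset(gs) for t, gs in propagated.items()},
        namespace_filter=namespace,
    )


def write_propagated_tsv(ann: AnnotationMap, stream: IO[str]) -> None:
    """Dump the propagated map as ``term TAB gene`` rows (sorted, reproducible)."""
    for term in sorted(ann.propagated):
        for gene in sorted(ann.propagated[term]):
            stream.write(f"{term}\t{gene}\n")
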