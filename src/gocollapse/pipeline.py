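"""End-to-end orchestration: DE selection → ORA → term collapsing → reports.

Library-level entry points used by the CLI.  All outputs are plain text
(TSV/JSON/Newick) written with fixed formatting so reruns on identical
inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .cluster import (
    DEFAULT_CUT_HEIGHT,
    DissimilarityMatrix,
    GOCluster,
    build_matrix,
    cluster_stats,
    complete_linkage_cut,
    to_newick,
)
from .crossspecies import JointClusterReport, joint_matrix, shared_clusters
from .de import DEResultTable, DirectionalGeneLists, select_directional
from .enrich import OraResult, run_ora
from .errors import ConfigError
from .ontology import AnnotationMap, OntologyGraph

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds and knobs shared by the single- and two-species runs."""

    alpha: float = 0.05
    lfc_min: float = 1.0
    p_column: str = "padj"
    padj_cutoff: float = 0.05
    min_term_size: int = 3
    max_term_size: int = 500
    cut_height: float = DEFAULT_CUT_HEIGHT
    metric: str = "jaccard"
    namespace: str = "molecular_function"
    include_all_clusters: bool = False

    def validate(self) -> None:
        checks = [
            (0 < self.alpha < 1, "alpha must be in (0, 1)"),
            (self.lfc_min >= 0, "lfc_min must be >= 0"),
            (0 < self.padj_cutoff <= 1, "padj_cutoff must be in (0, 1]"),
            (self.min_term_size >= 1, "min_term_size must be >= 1"),
            (self.max_term_size >= self.min_term_size,
             "max_term_size must be >= min_term_size"),
            (0 <= self.cut_height <= 1, "cut_height must be in [0, 1]"),
            (self.metric in ("jaccard", "overlap_coefficient"),
             "metric must be jaccard or overlap_coefficient"),
            (self.p_column in ("padj", "pvalue"),
             "p_column must be padj or pvalue"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)


@dataclass
class SingleSpeciesResult:
    """Everything one species' pipeline run produced."""

    species_label: str
    lists: DirectionalGeneLists
    n_up: int
    n_down: int
    ora: OraResult
    matrix: DissimilarityMatrix | None
    clusters: list[GOCluster] = field(default_factory=list)
    newick: str | None = None

    @property
    def volcano_count(self) -> int:
        return self.n_up + self.n_down


def run_single_species(
    ann: AnnotationMap,
    de_table: DEResultTable,
    config: RunConfig | None = None,
) -> SingleSpeciesResult:
    """DE thresholds → per-direction ORA → complete-linkage collapse."""
    cfg = config or RunConfig()
    cfg.validate()
    lists = select_directional(
        de_table, alpha=cfg.alpha, lfc_min=cfg.lfc_min, p_column=cfg.p_column
    )
    ora = run_ora(
        lists,
        ann,
        min_term_size=cfg.min_term_size,
        max_term_size=cfg.max_term_size,
        padj_cutoff=cfg.padj_cutoff,
    )
    enriched = sorted(ora.enriched_terms())
    matrix = None
    clusters: list[GOCluster] = []
    newick = None
    if enriched:
        matrix = build_matrix(enriched, ann, metric=cfg.metric)
        flat = complete_linkage_cut(matrix, cut_height=cfg.cut_height)
        clusters = [
            cluster_stats(members, ann, lists.up, lists.down, de_table, matrix)
            for members in flat
        ]
        newick = to_newick(matrix)
    else:
        logger.warning(
            "%s: no enriched terms at padj < %g; skipping clustering",
            ann.species_label, cfg.padj_cutoff,
        )
    return SingleSpeciesResult(
        species_label=ann.species_label,
        lists=lists,
        n_up=len(lists.up),
        n_down=len(lists.down),
        ora=ora,
        matrix=matrix,
        clusters=clusters,
        newick=newick,
    )


@dataclass
class TwoSpeciesResult:
    """Both species' runs plus the joint clustering and shared reports."""

    single: dict[str, SingleSpeciesResult]
    joint: DissimilarityMatrix | None
    joint_clusters: list[tuple[str, ...]]
    reports: list[JointClusterReport]
    joint_newick: str | None = None


def run_two_species(
    ann_a: AnnotationMap,
    de_a: DEResultTable,
    ann_b: AnnotationMap,
    de_b: DEResultTable,
    config: RunConfig | None = None,
) -> TwoSpeciesResult:
    """Run both species, merge their matrices, and report joint clusters."""
    cfg = config or RunConfig()
    cfg.validate()
    res_a = run_single_species(ann_a, de_a, cfg)
    res_b = run_single_species(ann_b, de_b, cfg)

    if res_a.matrix is not None and res_b.matrix is not None:
        joint = joint_matrix(res_a.matrix, res_b.matrix)
    else:
        joint = res_a.matrix or res_b.matrix
    joint_clusters: list[tuple[str, ...]] = []
    reports: list[JointClusterReport] = []
    joint_newick = None
    if joint is not None:
        joint_clusters = complete_linkage_cut(joint, cut_height=cfg.cut_height)
        joint_newick = to_newick(joint)
        reports = shared_clusters(
            joint_clusters,
            joint,
            res_a.ora,
            res_b.ora,
            ann_a,
            ann_b,
            res_a.lists,
            res_b.lists,
            de_a,
            de_b,
            include_all=cfg.include_all_clusters,
        )
    return TwoSpeciesResult(
        single={res_a.species_label: res_a, res_b.species_label: res_b},
        joint=joint,
        joint_clusters=joint_clusters,
        reports=reports,
        joint_newick=joint_newick,
    )


# ---------------------------------------------------------------- writers

def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_enrichment_tsv(
    ora: OraResult, graph: OntologyGraph, path: Path
) -> None:
    cols = ["term", "name", "namespace", "direction", "k", "K", "n", "N",
            "p", "padj", "genes"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for direction in ("up", "down"):
            for r in ora.records[direction]:
                fh.write("\t".join([
                    r.term,
                    graph.name.get(r.term, r.term),
                    graph.namespace.get(r.term, ""),
                    r.direction,
                    str(r.k), str(r.K), str(r.n), str(r.N),
                    _fmt(r.p), _fmt(r.padj),
                    ",".join(sorted(r.genes)),
                ]) + "\n")


def write_clusters_tsv(
    clusters: list[GOCluster], graph: OntologyGraph, path: Path
) -> None:
    cols = ["cluster_id", "representative", "representative_name", "members",
            "union_size", "sig_count", "ratio_n", "ratio_up", "ratio_down",
            "height"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for i, c in enumerate(clusters, start=1):
            fh.write("\t".join([
                f"C{i:03d}",
                c.representative,
                graph.name.get(c.representative, c.representative),
                ";".join(c.members),
                str(len(c.union_genes)),
                str(len(c.sig_genes)),
                _fmt(c.ratio_n), _fmt(c.ratio_up), _fmt(c.ratio_down),
                _fmt(c.height),
            ]) + "\n")


def write_matrix_tsv(matrix: DissimilarityMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("term\t" + "\t".join(matrix.terms) + "\n")
        for i, t in enumerate(matrix.terms):
            fh.write(t + "\t" + "\t".join(_fmt(v) for v in matrix.d[i]) + "\n")


def write_shared_report(
    reports: list[JointClusterReport], graph: OntologyGraph,
    tsv_path: Path, json_path: Path,
) -> None:
    cols = ["cluster_id", "representative", "representative_name", "shared",
            "members", "species", "enriched_directions", "n_genes",
            "ratio_n", "ratio_up", "ratio_down",
            "median", "q1", "q3", "whisker_lo", "whisker_hi", "outliers"]
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for rep in reports:
            for label in sorted(rep.per_species):
                v = rep.per_species[label]
                box = v.box
                fh.write("\t".join([
                    rep.cluster_id,
                    rep.representative,
                    graph.name.get(rep.representative, rep.representative),
                    str(rep.shared).lower(),
                    ";".join(rep.members),
                    label,
                    ",".join(v.enriched_directions),
                    str(v.n_genes),
                    _fmt(v.ratio_n), _fmt(v.ratio_up), _fmt(v.ratio_down),
                    _fmt(box.median) if box else "NA",
                    _fmt(box.q1) if box else "NA",
                    _fmt(box.q3) if box else "NA",
                    _fmt(box.whisker_lo) if box else "NA",
                    _fmt(box.whisker_hi) if box else "NA",
                    ",".join(_fmt(o) for o in box.outliers) if box else "NA",
                ]) + "\n")
    payload = []
    for rep in reports:
        entry = {
            "cluster_id": rep.cluster_id,
            "representative": rep.representative,
            "representative_name": graph.name.get(
                rep.representative, rep.representative
            ),
            "shared": rep.shared,
            "members": list(rep.members),
            "per_species": {
                label: {
                    "member_terms": list(v.member_terms),
                    "enriched_directions": list(v.enriched_directions),
                    "n_genes": v.n_genes,
                    "ratio_n": v.ratio_n,
                    "ratio_up": v.ratio_up,
                    "ratio_down": v.ratio_down,
                    "box": asdict(v.box) if v.box else None,
                }
                for label, v in sorted(rep.per_species.items())
            },
        }
        payload.append(entry)
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_manifest(
    out_dir: Path, inputs: dict[str, Path], config: RunConfig,
    extra: dict | None = None,
) -> None:
    """Provenance manifest: input hashes + config + version (no timestamps,
    so identical reruns stay byte-identical)."""
    manifest = {
        "gocollapse_version": __version__,
        "config": asdict(config),
        "inputs": {
            name: {
                "path": str(p),
                "sha256": hashlib.sha256(Path(p).read_bytes()).hexdigest(),
            }
            for name, p in sorted(inputs.items())
        },
    }
    if extra:
        manifest.update(extra)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
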