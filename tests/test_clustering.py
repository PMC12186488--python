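"""Term dissimilarity, complete-linkage collapsing and cluster statistics."""

from io import StringIO
from itertools import combinations

import numpy as np
import pytest

from gocollapse.cluster import (
    DissimilarityMatrix,
    build_matrix,
    cluster_stats,
    complete_linkage_cut,
    select_representative,
    term_dissimilarity,
    to_newick,
)
from gocollapse.de import read_de_table
from gocollapse.errors import ValidationError
from gocollapse.ontology import AnnotationMap

from .oracles import complete_linkage_bruteforce


def ann_of(term_sets, universe=None, label="s"):
    genes = universe or {g for s in term_sets.values() for g in s}
    return AnnotationMap(
        species_label=label,
        universe=frozenset(genes),
        direct={},
        propagated={t: frozenset(s) for t, s in term_sets.items()},
        namespace_filter="molecular_function",
    )


def random_matrix(rng, k):
    d = np.zeros((k, k))
    iu = np.triu_indices(k, 1)
    d[iu] = rng.uniform(size=len(iu[0]))
    d = d + d.T
    return DissimilarityMatrix(
        terms=tuple(f"GO:{i:07d}" for i in range(k)), d=d, metric_tag="jaccard"
    )


class TestTermDissimilarity:
    def test_identical_sets_are_zero(self):
        s = frozenset({"a", "b", "c"})
        assert term_dissimilarity(s, s, "jaccard") == 0.0
        assert term_dissimilarity(s, s, "overlap_coefficient") == 0.0

    def test_disjoint_sets_are_one(self):
        a, b = frozenset({"a"}), frozenset({"b", "c"})
        assert term_dissimilarity(a, b, "jaccard") == 1.0
        assert term_dissimilarity(a, b, "overlap_coefficient") == 1.0

    def test_partial_overlap_by_hand(self):
        a = frozenset({"g1", "g2", "g3", "g4"})
        b = frozenset({"g1", "g2", "g3"})
        assert term_dissimilarity(a, b, "jaccard") == pytest.approx(0.25)
        assert term_dissimilarity(a, b, "overlap_coefficient") == pytest.approx(0.0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            term_dissimilarity(frozenset(), frozenset({"a"}))

    def test_endpoint_semantics_over_random_pairs(self):
        rng = np.random.default_rng(1)
        pool = [f"g{i}" for i in range(40)]
        for _ in range(500):
            a = frozenset(rng.choice(pool, size=int(rng.integers(1, 15)),
                                     replace=False))
            b = frozenset(rng.choice(pool, size=int(rng.integers(1, 15)),
                                     replace=False))
            for metric in ("jaccard", "overlap_coefficient"):
                d = term_dissimilarity(a, b, metric)
                assert 0.0 <= d <= 1.0
                assert (d == 1.0) == (not a & b)
                if metric == "jaccard":
                    assert (d == 0.0) == (a == b)
                else:
                    assert (d == 0.0) == (a <= b or b <= a)

    def test_jaccard_triangle_inequality_on_small_fixtures(self):
        rng = np.random.default_rng(8)
        pool = [f"g{i}" for i in range(12)]
        sets = [
            frozenset(rng.choice(pool, size=int(rng.integers(1, 8)),
                                 replace=False))
            for _ in range(6)
        ]
        for a, b, c in combinations(sets, 3):
            dab = term_dissimilarity(a, b)
            dbc = term_dissimilarity(b, c)
            dac = term_dissimilarity(a, c)
            assert dac <= dab + dbc + 1e-12


class TestBuildMatrix:
    def test_single_term_zero_matrix(self):
        m = build_matrix(["GO:A"], ann_of({"GO:A": {"g1"}}))
        assert m.terms == ("GO:A",)
        assert m.d.shape == (1, 1) and m.d[0, 0] == 0.0

    def test_cells_match_pairwise_calls(self):
        sets = {"GO:A": {"g1", "g2"}, "GO:B": {"g2", "g3"}, "GO:C": {"g9"}}
        m = build_matrix(sets, ann_of(sets))
        for s, t in combinations(m.terms, 2):
            assert m.value(s, t) == term_dissimilarity(
                frozenset(sets[s]), frozenset(sets[t])
            )

    def test_symmetry_and_range_on_random_fixture(self):
        rng = np.random.default_rng(4)
        pool = [f"g{i}" for i in range(30)]
        sets = {
            f"GO:{j:07d}": set(rng.choice(pool, size=int(rng.integers(1, 10)),
                                          replace=False))
            for j in range(10)
        }
        m = build_matrix(sets, ann_of(sets))
        assert np.allclose(m.d, m.d.T)
        assert np.all((m.d >= 0) & (m.d <= 1))
        assert np.all(np.diag(m.d) == 0)

    def test_unknown_term_named(self):
        with pytest.raises(ValidationError, match="GO:MISSING"):
            build_matrix(["GO:MISSING"], ann_of({"GO:A": {"g1"}}))


class TestCompleteLinkageCut:
    def test_hand_worked_three_terms(self):
        terms = ("GO:A", "GO:B", "GO:C")
        d = np.array([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]])
        m = DissimilarityMatrix(terms=terms, d=d, metric_tag="jaccard")
        assert complete_linkage_cut(m, 0.25) == [("GO:A", "GO:B"), ("GO:C",)]

    def test_all_distance_one_stays_singletons(self):
        k = 5
        d = 1 - np.eye(k)
        m = DissimilarityMatrix(
            terms=tuple(f"GO:{i}" for i in range(k)), d=d, metric_tag="jaccard"
        )
        assert complete_linkage_cut(m, 0.25) == [(f"GO:{i}",) for i in range(k)]

    def test_cut_is_inclusive_at_threshold(self):
        # exactly 75% shared genes (jaccard d = 0.25) must still merge
        d = np.array([[0, 0.25], [0.25, 0]])
        m = DissimilarityMatrix(terms=("GO:A", "GO:B"), d=d, metric_tag="jaccard")
        assert complete_linkage_cut(m, 0.25) == [("GO:A", "GO:B")]

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 9))
        m = random_matrix(rng, k)
        got = complete_linkage_cut(m, 0.25)
        expected = complete_linkage_bruteforce(m.d, 0.25)
        got_idx = sorted(tuple(m.terms.index(t) for t in c) for c in got)
        assert got_idx == expected

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy_on_tie_free_matrices(self, seed):
        """Cross-check against scipy's complete-linkage fcluster."""
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(1000 + seed)
        k = int(rng.integers(3, 12))
        m = random_matrix(rng, k)
        got = complete_linkage_cut(m, 0.25)
        labels = fcluster(linkage(squareform(m.d), method="complete"),
                          t=0.25, criterion="distance")
        scipy_clusters = sorted(
            tuple(sorted(m.terms[i] for i in np.flatnonzero(labels == lab)))
            for lab in set(labels)
        )
        assert got == scipy_clusters

    def test_within_cluster_guarantee(self):
        rng = np.random.default_rng(77)
        for _ in range(25):
            m = random_matrix(rng, int(rng.integers(2, 12)))
            cut = float(rng.uniform(0.1, 0.9))
            for members in complete_linkage_cut(m, cut):
                for s, t in combinations(members, 2):
                    assert m.value(s, t) <= cut + 1e-12

    def test_permutation_invariance(self):
        rng = np.random.default_rng(13)
        pool = [f"g{i}" for i in range(25)]
        sets = {
            f"GO:{j:07d}": set(rng.choice(pool, size=int(rng.integers(2, 8)),
                                          replace=False))
            for j in range(9)
        }
        ann = ann_of(sets)
        a = complete_linkage_cut(build_matrix(list(sets), ann), 0.4)
        b = complete_linkage_cut(build_matrix(list(reversed(list(sets))), ann), 0.4)
        assert a == b


class TestNewick:
    def test_tree_parses_and_keeps_leaves(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(21)
        m = random_matrix(rng, 7)
        tree = dendropy.Tree.get(data=to_newick(m), schema="newick")
        leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert leaves == set(m.terms)

    def test_singleton_tree(self):
        m = DissimilarityMatrix(terms=("GO:A",), d=np.zeros((1, 1)),
                                metric_tag="jaccard")
        assert to_newick(m) == "'GO:A':0;"


class TestRepresentativeAndStats:
    def test_highest_proportion_wins(self):
        sets = {"GO:T1": {f"g{i}" for i in range(10)},
                "GO:T2": {f"h{i}" for i in range(20)}}
        ann = ann_of(sets)
        sig = {f"g{i}" for i in range(5)} | {f"h{i}" for i in range(6)}
        # 5/10 = 0.5 beats 6/20 = 0.3
        assert select_representative(["GO:T1", "GO:T2"], ann, sig) == "GO:T1"

    def test_singleton_is_its_own_representative(self):
        ann = ann_of({"GO:T": {"g1"}})
        assert select_representative(["GO:T"], ann, set()) == "GO:T"

    def test_tie_breaks_are_stable(self):
        sets = {"GO:B": {"g1", "g2"}, "GO:A": {"g3", "g4"}}
        ann = ann_of(sets)
        # equal proportion (0.5) and equal size -> lexicographically smaller
        assert select_representative(["GO:B", "GO:A"], ann, {"g1", "g3"}) == "GO:A"
        assert select_representative(["GO:A", "GO:B"], ann, {"g1", "g3"}) == "GO:A"

    def _de_table(self, genes, l2fc=1.0):
        rows = "".join(f"{g}\t{l2fc}\t0.01\t0.01\n" for g in sorted(genes))
        return read_de_table(
            StringIO("gene_id\tlog2FoldChange\tpvalue\tpadj\n" + rows), "s"
        )

    def test_ratio_n_division(self):
        genes = [f"g{i}" for i in range(40)]
        ann = ann_of({"GO:T": set(genes)})
        up = set(genes[:8])
        c = cluster_stats(["GO:T"], ann, up, set(), self._de_table(genes))
        assert c.ratio_n == pytest.approx(0.2)
        assert c.ratio_up == pytest.approx(0.2)
        assert c.ratio_down == 0.0

    def test_no_significant_genes_ratio_zero(self):
        ann = ann_of({"GO:T": {"g1", "g2"}})
        c = cluster_stats(["GO:T"], ann, set(), set(),
                          self._de_table(["g1", "g2"]))
        assert c.ratio_n == 0.0

    def test_union_without_double_counting(self):
        sets = {"GO:A": {"g1", "g2", "g3"}, "GO:B": {"g2", "g3", "g4"}}
        ann = ann_of(sets)
        c = cluster_stats(["GO:A", "GO:B"], ann, {"g2"}, set(),
                          self._de_table(["g1", "g2", "g3", "g4"]))
        brute_union = set()
        for s in sets.values():
            brute_union |= s
        assert c.union_genes == brute_union
        assert c.ratio_n == pytest.approx(1 / 4)
        assert len(c.l2fc_values) == 4

    def test_genes_missing_from_de_table_excluded_from_l2fc(self):
        ann = ann_of({"GO:T": {"g1", "g2", "gX"}})
        c = cluster_stats(["GO:T"], ann, set(), set(),
                          self._de_table(["g1", "g2"]))
        assert len(c.l2fc_values) == 2
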