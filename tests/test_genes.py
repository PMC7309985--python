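"""Gene containment and GO elim enrichment against hypergeometric oracles."""

from math import comb

import numpy as np
import pytest

from cichlidsv.core import ConsensusSV, GenomicInterval, SVClass
from cichlidsv.genes import (GeneRecord, GoDag, genes_fully_inside,
                             go_enrichment_elim, read_gene_bed)


def gene(start, end, gid, contig="lg1"):
    return GeneRecord(GenomicInterval(contig, start, end), gid)


def sv(start, end, cid, contig="lg1"):
    return ConsensusSV(GenomicInterval(contig, start, end), SVClass.INV,
                       frozenset({"Mzebra"}),
                       {"Mzebra": frozenset({"delly", "pindel"})}, ("r",), cid)


def hypergeom_tail_oracle(k, K, n, N):
    """P(X >= k) by direct summation of the hypergeometric pmf."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += comb(K, x) * comb(N - K, n - x) / comb(N, n)
    return total


class TestGenesFullyInside:
    def test_contained_gene_included(self):
        assert genes_fully_inside([gene(10, 20, "g")], [sv(0, 100, "s")]) == \
            [("g", "s")]

    def test_straddling_gene_excluded(self):
        assert genes_fully_inside([gene(90, 110, "g")], [sv(0, 100, "s")]) == []

    def test_gene_may_pair_with_multiple_svs(self):
        pairs = genes_fully_inside([gene(10, 20, "g")],
                                   [sv(0, 100, "s1"), sv(5, 50, "s2")])
        assert set(pairs) == {("g", "s1"), ("g", "s2")}

    def test_matches_brute_force_containment(self, rng):
        genes = [gene(int(s), int(s) + int(l), f"g{i}")
                 for i, (s, l) in enumerate(zip(rng.integers(0, 5000, 80),
                                                rng.integers(50, 400, 80)))]
        svs = [sv(int(s), int(s) + int(l), f"s{i}")
               for i, (s, l) in enumerate(zip(rng.integers(0, 5000, 30),
                                              rng.integers(100, 2000, 30)))]
        got = set(genes_fully_inside(genes, svs))
        oracle = {(g.gene_id, s.consensus_id) for g in genes for s in svs
                  if s.interval.start <= g.interval.start
                  and g.interval.end <= s.interval.end}
        assert got == oracle


def flat_dag(n_leaves, genes_per_leaf):
    """Root plus independent leaves annotating disjoint gene sets."""
    edges = [(f"T{i}", "root") for i in range(n_leaves)]
    ann = {f"T{i}": {f"g{i}_{j}" for j in range(genes_per_leaf)}
           for i in range(n_leaves)}
    return GoDag(edges, ann)


class TestGoDag:
    def test_propagation_true_path_rule(self):
        dag = GoDag([("child", "mid"), ("mid", "root")],
                    {"child": {"a"}, "mid": {"b"}})
        assert dag.annotated["mid"] == {"a", "b"}
        assert dag.annotated["root"] == {"a", "b"}
        for term in dag.graph.nodes:
            for parent in dag.graph.successors(term):
                assert dag.annotated[term] <= dag.annotated[parent]

    def test_cycle_rejected(self):
        with pytest.raises(ValueError):
            GoDag([("a", "b"), ("b", "a")], {})

    def test_depth_longest_path(self):
        dag = GoDag([("deep", "mid"), ("mid", "root"), ("deep", "root")], {})
        assert dag.depth["root"] == 0
        assert dag.depth["mid"] == 1
        assert dag.depth["deep"] == 2

    def test_obo_subset_reader(self, tmp_path):
        obo = tmp_path / "mini.obo"
        obo.write_text(
            "format-version: 1.2\n\n[Term]\nid: GO:1\nname: a\n"
            "is_a: GO:2 ! parent\n\n[Term]\nid: GO:2\nname: b\n")
        g2g = tmp_path / "g.tsv"
        g2g.write_text("geneA\tGO:1\n")
        dag = GoDag.from_obo(obo, g2g)
        assert dag.annotated["GO:2"] == {"geneA"}


class TestGoEnrichmentElim:
    def test_worked_hypergeometric_example(self):
        """Universe 100, study 10, term annotating 20 with 6 in the study:
        expected 2.0 and p equals the direct tail summation."""
        universe = {f"u{i}" for i in range(100)}
        term_genes = {f"u{i}" for i in range(20)}
        study = {f"u{i}" for i in range(6)} | {f"u{i}" for i in range(50, 54)}
        assert len(study) == 10 and len(study & term_genes) == 6
        dag = GoDag([("T", "root")], {"T": term_genes})
        results = go_enrichment_elim(study, universe, dag, elim_cutoff=0.01)
        res = next(r for r in results if r.term == "T")
        assert res.expected == pytest.approx(2.0)
        assert res.significant == 6
        assert res.p_elim == pytest.approx(
            hypergeom_tail_oracle(6, 20, 10, 100), abs=1e-12)

    def test_flat_dag_equals_classic_fisher(self, rng):
        dag = flat_dag(6, 10)
        universe = {g for s in dag.direct.values() for g in s}
        study = set(rng.choice(sorted(universe), size=12, replace=False))
        results = go_enrichment_elim(study, universe, dag, elim_cutoff=0.01,
                                     node_size=5)
        for r in results:
            if r.term == "root":
                continue
            K = len(dag.annotated[r.term] & universe)
            k = len(dag.annotated[r.term] & study)
            assert r.p_elim == pytest.approx(
                hypergeom_tail_oracle(k, K, len(study), len(universe)),
                abs=1e-12)

    def test_cutoff_zero_equals_classic_fisher(self, rng):
        """elim with cutoff 0 never eliminates, reducing to classic Fisher
        even on a deep DAG."""
        edges = [("leaf0", "mid"), ("leaf1", "mid"), ("mid", "root")]
        ann = {"leaf0": {f"a{i}" for i in range(8)},
               "leaf1": {f"b{i}" for i in range(8)},
               "mid": {f"c{i}" for i in range(4)}}
        dag = GoDag(edges, ann)
        universe = {g for s in ann.values() for g in s} | \
            {f"z{i}" for i in range(30)}
        study = {f"a{i}" for i in range(6)} | {"c0", "z0", "z1"}
        results = go_enrichment_elim(study, universe, dag, elim_cutoff=0.0)
        for r in results:
            K = len(dag.annotated[r.term] & universe)
            k = len(dag.annotated[r.term] & study)
            assert r.p_elim == pytest.approx(
                hypergeom_tail_oracle(k, K, len(study), len(universe)),
                abs=1e-12)

    def test_elim_decorrelates_parent(self):
        """A significant child's genes are removed from the parent's table,
        raising the parent's p relative to classic Fisher."""
        child_genes = {f"c{i}" for i in range(10)}
        parent_extra = {f"p{i}" for i in range(10)}
        background = {f"z{i}" for i in range(180)}
        universe = child_genes | parent_extra | background
        dag = GoDag([("child", "parent"), ("parent", "root")],
                    {"child": child_genes, "parent": parent_extra})
        study = set(list(child_genes)[:8]) | {"z0", "z1"}
        results = {r.term: r for r in
                   go_enrichment_elim(study, universe, dag, elim_cutoff=0.01)}
        child_p = results["child"].p_elim
        assert child_p == pytest.approx(
            hypergeom_tail_oracle(8, 10, 10, 200), abs=1e-12)
        assert child_p < 0.01  # triggers elimination
        parent_classic = hypergeom_tail_oracle(
            len((child_genes | parent_extra) & study), 20, 10, 200)
        # after elimination the parent's current set excludes the child's
        # genes: 10 annotated, 0 in study
        parent_elim_oracle = hypergeom_tail_oracle(0, 10, 10, 200)
        assert results["parent"].p_elim == pytest.approx(parent_elim_oracle,
                                                         abs=1e-12)
        assert results["parent"].p_elim > parent_classic

    def test_node_size_skips_small_terms(self):
        dag = GoDag([("tiny", "root"), ("big", "root")],
                    {"tiny": {"a", "b"}, "big": {f"g{i}" for i in range(10)}})
        universe = dag.annotated["root"]
        results = go_enrichment_elim({"a"}, universe, dag, node_size=5)
        assert "tiny" not in {r.term for r in results}

    def test_study_outside_universe_rejected(self):
        dag = flat_dag(2, 6)
        universe = {g for s in dag.direct.values() for g in s}
        with pytest.raises(ValueError):
            go_enrichment_elim({"alien"}, universe, dag)


def test_read_gene_bed_rejects_duplicates(tmp_path):
    bed = tmp_path / "g.bed"
    bed.write_text("lg1\t0\t100\tg1\nlg1\t200\t300\tg1\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_gene_bed(bed)
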