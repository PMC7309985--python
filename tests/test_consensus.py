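"""Within-tool merging and two-tool consensus against brute-force oracles."""

import numpy as np
import pytest

from cichlidsv.core import GenomicInterval, SVClass, reciprocal_overlap
from cichlidsv.consensus import (MergePolicy, build_consensus_set,
                                 merge_within_tool, pairwise_consensus)
from conftest import make_record

POLICY = MergePolicy()


def brute_force_clusters(records, edge):
    """Independent O(n^2) single-linkage: all-pairs edges, then connected
    components by breadth-first search."""
    n = len(records)
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            if edge(records[i], records[j]):
                adj[i].add(j)
                adj[j].add(i)
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k] - comp)
        seen |= comp
        comps.append(frozenset(records[k].record_id for k in comp))
    return set(comps)


def span_edge_oracle(a, b):
    ia, ib = a.interval, b.interval
    if ia.contig != ib.contig:
        return False
    inter = max(0, min(ia.end, ib.end) - max(ia.start, ib.start))
    return inter / ia.length >= 0.9 and inter / ib.length >= 0.9


def random_span_records(rng, n, caller="delly", species="Mzebra",
                        contig_count=3, scale=30):
    records = []
    for i in range(n):
        contig = f"lg{int(rng.integers(1, contig_count + 1))}"
        start = int(rng.integers(0, 2000)) * scale
        length = int(rng.integers(200, 5000))
        records.append(make_record(start, start + length, caller=caller,
                                   species=species, contig=contig,
                                   rid=f"{caller}{i}",
                                   n_read_pairs=int(rng.integers(5, 50))))
    return records


class TestMergeWithinTool:
    def test_overlapping_pair_merges(self):
        a = make_record(100, 200, rid="a")
        b = make_record(105, 205, rid="b")
        merged = merge_within_tool([a, b], POLICY)
        assert len(merged) == 1
        assert set(merged[0].source_ids) == {"a", "b"}

    def test_disjoint_stay_separate(self):
        a = make_record(100, 200, rid="a")
        b = make_record(500, 600, rid="b")
        assert len(merge_within_tool([a, b], POLICY)) == 2

    def test_single_linkage_transitivity(self):
        """A~B and B~C link all three even though A~C alone would not."""
        a = make_record(0, 1000, rid="a")
        b = make_record(50, 1050, rid="b")     # 0.95 with a
        c = make_record(130, 1130, rid="c")    # 0.92 with b, 0.87 with a
        assert reciprocal_overlap(a.interval, b.interval) >= 0.9
        assert reciprocal_overlap(b.interval, c.interval) >= 0.9
        assert reciprocal_overlap(a.interval, c.interval) < 0.9
        merged = merge_within_tool([a, b, c], POLICY)
        assert len(merged) == 1
        assert set(merged[0].source_ids) == {"a", "b", "c"}

    def test_representative_is_highest_support(self):
        a = make_record(100, 200, rid="a", n_read_pairs=5)
        b = make_record(101, 201, rid="b", n_read_pairs=50)
        (rep,) = merge_within_tool([a, b], POLICY)
        assert rep.interval == b.interval

    def test_matches_brute_force_oracle(self, rng):
        records = random_span_records(rng, 300)
        merged = merge_within_tool(records, POLICY)
        got = {frozenset(r.source_ids) for r in merged}
        assert got == brute_force_clusters(records, span_edge_oracle)

    def test_order_invariant(self, rng):
        records = random_span_records(rng, 120)
        merged1 = merge_within_tool(records, POLICY)
        perm = [records[i] for i in rng.permutation(len(records))]
        merged2 = merge_within_tool(perm, POLICY)
        assert merged1 == merged2

    def test_mixed_input_rejected(self):
        a = make_record(0, 100, caller="delly")
        b = make_record(0, 100, caller="pindel")
        with pytest.raises(ValueError):
            merge_within_tool([a, b], POLICY)

    def test_translocations_pass_through(self):
        t = make_record(100, 101, SVClass.TRA, rid="t",
                        mate_interval=GenomicInterval("lg2", 5, 6))
        assert merge_within_tool([t], POLICY) == [t]


class TestPairwiseConsensus:
    def test_matching_pair(self):
        a = make_record(0, 1000, caller="delly", rid="a")
        b = make_record(50, 1050, caller="pindel", rid="b")
        (cons,) = pairwise_consensus([a], [b], POLICY)
        assert cons.callers == frozenset({"delly", "pindel"})
        assert set(cons.source_ids) == {"a", "b"}

    def test_identical_singletons(self):
        a = make_record(0, 1000, caller="delly", rid="a")
        b = make_record(0, 1000, caller="pindel", rid="b")
        assert len(pairwise_consensus([a], [b], POLICY)) == 1

    def test_unpartnered_absent(self):
        a = make_record(0, 1000, caller="delly", rid="a")
        b = make_record(5000, 6000, caller="pindel", rid="b")
        assert pairwise_consensus([a], [b], POLICY) == []

    def test_one_to_one_matching(self, rng):
        """Each record joins at most one consensus pair."""
        set_a = random_span_records(rng, 80, caller="delly")
        set_b = random_span_records(rng, 80, caller="pindel")
        out = pairwise_consensus(set_a, set_b, POLICY)
        used = [sid for r in out for sid in r.source_ids]
        assert len(used) == len(set(used))
        for r in out:
            assert r.callers == frozenset({"delly", "pindel"})

    def test_insertion_breakpoint_window(self):
        a = make_record(500, 501, SVClass.INS, caller="delly", rid="a",
                        insertion_length=200)
        near = make_record(580, 581, SVClass.INS, caller="pindel", rid="b",
                           insertion_length=210)
        far = make_record(700, 701, SVClass.INS, caller="pindel", rid="c",
                          insertion_length=210)
        assert len(pairwise_consensus([a], [near], POLICY)) == 1
        assert pairwise_consensus([a], [far], POLICY) == []


class TestBuildConsensusSet:
    def _three_callers(self, start=0, end=1000):
        return {
            "breakdancer": [make_record(start, end, caller="breakdancer",
                                        rid="bd", score=99.0)],
            "delly": [make_record(start + 20, end + 20, caller="delly",
                                  rid="dl")],
            "pindel": [make_record(start + 40, end + 40, caller="pindel",
                                   rid="pd")],
        }

    def test_triple_support_single_record(self):
        out = build_consensus_set(self._three_callers(), POLICY)
        assert len(out) == 1
        assert out[0].callers == frozenset({"breakdancer", "delly", "pindel"})

    def test_single_caller_absent(self):
        by_caller = self._three_callers()
        by_caller["delly"] = []
        by_caller["pindel"] = []
        by_caller["breakdancer"].append(
            make_record(50000, 51000, caller="breakdancer", rid="solo",
                        score=99.0))
        out = build_consensus_set(by_caller, POLICY)
        assert out == []

    def test_three_disjoint_two_caller_events(self):
        by_caller = {
            "breakdancer": [make_record(0, 1000, caller="breakdancer",
                                        rid="b1", score=99.0)],
            "delly": [make_record(10, 1010, caller="delly", rid="d1"),
                      make_record(20000, 21000, caller="delly", rid="d2")],
            "pindel": [make_record(20010, 21010, caller="pindel", rid="p2"),
                       make_record(40000, 41000, caller="pindel", rid="p3")],
        }
        by_caller["breakdancer"].append(
            make_record(40010, 41010, caller="breakdancer", rid="b3",
                        score=99.0))
        out = build_consensus_set(by_caller, POLICY)
        assert len(out) == 3

    def test_two_caller_support_invariant(self, rng):
        by_caller = {
            "breakdancer": random_span_records(rng, 60, "breakdancer"),
            "delly": random_span_records(rng, 60, "delly"),
            "pindel": random_span_records(rng, 60, "pindel"),
        }
        out = build_consensus_set(by_caller, POLICY)
        for rec in out:
            assert len(rec.callers) >= 2

    def test_fewer_than_two_callers_error(self):
        with pytest.raises(ValueError):
            build_consensus_set({"delly": []}, POLICY)
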