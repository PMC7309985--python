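"""Within-tool merging and two-tool consensus building.

Redundant calls made by one tool are collapsed by single-linkage clustering
on >=90% reciprocal overlap; the consensus call set of a species/class is
the union of the three two-tool intersections (Breakdancer+Delly,
Breakdancer+Pindel, Delly+Pindel), each requiring >=90% reciprocal overlap
between independently called events.

Reciprocal overlap is undefined for translocations and degenerate for
insertion breakpoints, so those classes are matched by breakpoint-distance
windows instead (configurable; defaults 1 kb for translocations, 100 nt for
insertions).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

from .core import GenomicInterval, SVClass, SVRecord, reciprocal_overlap

__all__ = [
    "MergePolicy",
    "merge_within_tool",
    "pairwise_consensus",
    "build_consensus_set",
]


@dataclass(frozen=True)
class MergePolicy:
    """Thresholds and tie-break rules for call merging."""

    within_tool_threshold: float = 0.90
    cross_tool_threshold: float = 0.90
    classes_excluded_from_merge: frozenset[SVClass] = frozenset({SVClass.TRA})
    representative_rule: str = "highest_support"  # or "leftmost"
    ins_breakpoint_window: int = 100
    tra_breakpoint_window: int = 1000

    def __post_init__(self) -> None:
        for name in ("within_tool_threshold", "cross_tool_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.representative_rule not in ("highest_support", "leftmost"):
            raise ValueError(f"unknown representative_rule {self.representative_rule}")


def _rep_key_support(r: SVRecord):
    # highest read-pair support wins; ties: leftmost start, then smallest end
    return (-r.n_read_pairs, r.interval.contig, r.interval.start,
            r.interval.end, r.record_id)


def _rep_key_leftmost(r: SVRecord):
    return (r.interval.contig, r.interval.start, r.interval.end, r.record_id)


def _representative(members: Sequence[SVRecord], policy: MergePolicy) -> SVRecord:
    key = (_rep_key_support if policy.representative_rule == "highest_support"
           else _rep_key_leftmost)
    rep = min(members, key=key)
    source = tuple(sorted({sid for m in members for sid in m.source_ids}))
    callers = frozenset().union(*(m.callers for m in members))
    return replace(rep, source_ids=source, callers=callers)


def span_edge(threshold: float) -> Callable[[SVRecord, SVRecord], bool]:
    def edge(a: SVRecord, b: SVRecord) -> bool:
        return reciprocal_overlap(a.interval, b.interval) >= threshold
    return edge


def breakpoint_edge(window: int) -> Callable[[SVRecord, SVRecord], bool]:
    def edge(a: SVRecord, b: SVRecord) -> bool:
        if a.interval.contig != b.interval.contig:
            return False
        if abs(a.interval.start - b.interval.start) > window:
            return False
        if (a.mate_interval is None) != (b.mate_interval is None):
            return False
        if a.mate_interval is not None:
            return (a.mate_interval.contig == b.mate_interval.contig
                    and abs(a.mate_interval.start - b.mate_interval.start)
                    <= window)
        return True
    return edge


def edge_predicate(sv_class: SVClass, threshold: float,
                   policy: MergePolicy) -> Callable[[SVRecord, SVRecord], bool]:
    if sv_class is SVClass.TRA:
        return breakpoint_edge(policy.tra_breakpoint_window)
    if sv_class is SVClass.INS:
        return breakpoint_edge(policy.ins_breakpoint_window)
    return span_edge(threshold)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _single_linkage(records: list[SVRecord],
                    edge: Callable[[SVRecord, SVRecord], bool],
                    scan_window: int | None,
                    policy: MergePolicy) -> list[SVRecord]:
    """Cluster sorted records under ``edge`` and emit one representative per
    cluster.  ``scan_window`` bounds the start-distance beyond which no edge
    is possible (interval length for spans, the breakpoint window for
    breakpoint classes); None disables the pruning."""
    recs = sorted(records, key=SVRecord.sort_key)
    uf = _UnionFind(len(recs))
    for i, a in enumerate(recs):
        for j in range(i + 1, len(recs)):
            b = recs[j]
            if b.interval.contig != a.interval.contig:
                break
            if scan_window is not None and \
                    b.interval.start - a.interval.start > scan_window:
                break
            if b.interval.start >= a.interval.end and scan_window is None:
                break
            if edge(a, b):
                uf.union(i, j)
    clusters: dict[int, list[SVRecord]] = {}
    for i, r in enumerate(recs):
        clusters.setdefault(uf.find(i), []).append(r)
    out = [_representative(members, policy) for members in clusters.values()]
    out.sort(key=SVRecord.sort_key)
    return out


def merge_within_tool(records: Sequence[SVRecord],
                      policy: MergePolicy = MergePolicy()) -> list[SVRecord]:
    """Collapse one tool's redundant calls by single-linkage clustering.

    All records must share species, caller and SV class.  Span classes link
    at ``within_tool_threshold`` reciprocal overlap; insertion breakpoints
    link within ``ins_breakpoint_window``.  Translocations (excluded from
    reciprocal merging) are returned unchanged.
    """
    if not records:
        return []
    keys = {(r.species, r.caller, r.sv_class) for r in records}
    if len(keys) > 1:
        raise ValueError(f"mixed species/caller/class input: {sorted(map(str, keys))}")
    sv_class = records[0].sv_class
    if sv_class in policy.classes_excluded_from_merge:
        return sorted(records, key=SVRecord.sort_key)
    edge = edge_predicate(sv_class, policy.within_tool_threshold, policy)
    window = policy.ins_breakpoint_window if sv_class is SVClass.INS else None
    return _single_linkage(list(records), edge, window, policy)


def pairwise_consensus(set_a: Sequence[SVRecord], set_b: Sequence[SVRecord],
                       policy: MergePolicy = MergePolicy()) -> list[SVRecord]:
    """Greedy one-to-one matching of two tools' call sets.

    Pairs meeting the cross-tool criterion are matched best-overlap-first
    (ties resolved leftmost); each input record joins at most one pair.
    Matched pairs emit the representative record annotated with both
    callers; unmatched records are dropped (no two-tool support).
    """
    if not set_a or not set_b:
        return []
    classes = {r.sv_class for r in set_a} | {r.sv_class for r in set_b}
    species = {r.species for r in set_a} | {r.species for r in set_b}
    if len(classes) > 1 or len(species) > 1:
        raise ValueError("pairwise_consensus requires one species and one class")
    sv_class = classes.pop()
    edge = edge_predicate(sv_class, policy.cross_tool_threshold, policy)

    def pair_score(a: SVRecord, b: SVRecord) -> float:
        if sv_class in (SVClass.TRA, SVClass.INS):
            return -abs(a.interval.start - b.interval.start)
        return reciprocal_overlap(a.interval, b.interval)

    candidates = []
    for i, a in enumerate(set_a):
        for j, b in enumerate(set_b):
            if edge(a, b):
                candidates.append((-pair_score(a, b), a.sort_key(), b.sort_key(),
                                   i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    out = []
    for _, _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        out.append(_representative([set_a[i], set_b[j]], policy))
    out.sort(key=SVRecord.sort_key)
    return out


def build_consensus_set(by_caller: dict[str, Sequence[SVRecord]],
                        policy: MergePolicy = MergePolicy()) -> list[SVRecord]:
    """Union of all two-tool consensus sets, deduplicated.

    ``by_caller`` maps each caller to its filtered, within-tool-merged call
    set for one species and one SV class.  Every unordered caller pair
    contributes its consensus; a final single-linkage pass at the cross-tool
    threshold removes events recovered by more than one pair.
    """
    callers = sorted(by_caller)
    if len(callers) < 2:
        raise ValueError("consensus requires at least two callers")
    union: list[SVRecord] = []
    for idx, ca in enumerate(callers):
        for cb in callers[idx + 1:]:
            union.extend(pairwise_consensus(by_caller[ca], by_caller[cb], policy))
    if not union:
        return []
    sv_class = union[0].sv_class
    edge = edge_predicate(sv_class, policy.cross_tool_threshold, policy)
    if sv_class is SVClass.INS:
        window = policy.ins_breakpoint_window
    elif sv_class is SVClass.TRA:
        window = policy.tra_breakpoint_window
    else:
        window = None
    return _single_linkage(union, edge, window, policy)
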