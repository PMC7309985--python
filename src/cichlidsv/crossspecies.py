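"""Cross-species merging with size-conditional thresholds, conservation
classification, and size-vs-conservation rank tests.

Small events tolerate proportionally larger breakpoint uncertainty, so the
reciprocal-overlap threshold required to merge calls across species rises
with event size: 50% below 500 nt, 80% for 500-1000 nt, 90% for 1-10 kb and
95% above 10 kb (bands include their lower bound and exclude the upper).
When two events fall in different bands the stricter threshold governs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .core import ConsensusSV, GenomicInterval, SVClass, SVRecord, reciprocal_overlap
from .consensus import MergePolicy, _UnionFind, breakpoint_edge

__all__ = [
    "SizeBandPolicy",
    "ConservationClass",
    "conditional_merge_across_species",
    "classify_conservation",
    "conservation_summary",
    "size_by_conservation_tests",
]

DEFAULT_BANDS: tuple[tuple[float, float, float], ...] = (
    (0, 500, 0.50),
    (500, 1000, 0.80),
    (1000, 10000, 0.90),
    (10000, math.inf, 0.95),
)


@dataclass(frozen=True)
class SizeBandPolicy:
    """Size-dependent reciprocal-overlap thresholds, lower bound inclusive."""

    bands: tuple[tuple[float, float, float], ...] = DEFAULT_BANDS
    ins_breakpoint_window: int = 200
    tra_breakpoint_window: int = 1000

    def __post_init__(self) -> None:
        prev_upper, prev_thr = 0.0, 0.0
        for lower, upper, thr in self.bands:
            if lower != prev_upper:
                raise ValueError("bands must partition [0, inf)")
            if thr < prev_thr:
                raise ValueError("thresholds must be non-decreasing")
            prev_upper, prev_thr = upper, thr
        if prev_upper != math.inf:
            raise ValueError("last band must extend to infinity")

    def threshold(self, length: int) -> float:
        for lower, upper, thr in self.bands:
            if lower <= length < upper:
                return thr
        raise ValueError(f"no band for length {length}")  # pragma: no cover


@dataclass(frozen=True)
class ConservationClass:
    """How widely shared a merged event is across the analyzed species."""

    n_species: int
    conserved: bool


def _span_edge(a: SVRecord, b: SVRecord, policy: SizeBandPolicy) -> bool:
    thr = max(policy.threshold(a.interval.length),
              policy.threshold(b.interval.length))
    return reciprocal_overlap(a.interval, b.interval) >= thr


def conditional_merge_across_species(
    per_species: Mapping[str, Sequence[SVRecord]],
    policy: SizeBandPolicy = SizeBandPolicy(),
    id_prefix: str = "sv",
) -> list[ConsensusSV]:
    """Single-linkage merge of per-species consensus sets into multi-species
    events.

    Two span calls link when their reciprocal overlap meets the stricter of
    their two size-band thresholds; insertion and translocation breakpoints
    link within a distance window.  Each cluster becomes one
    :class:`ConsensusSV` whose representative interval comes from the member
    with the highest caller support (number of supporting callers, then
    read pairs; ties leftmost).
    """
    records: list[SVRecord] = []
    for sp in sorted(per_species):
        records.extend(per_species[sp])
    if not records:
        return []
    classes = {r.sv_class for r in records}
    if len(classes) > 1:
        raise ValueError(f"mixed SV classes: {sorted(c.value for c in classes)}")
    sv_class = classes.pop()
    records.sort(key=SVRecord.sort_key)

    if sv_class is SVClass.INS:
        bp = breakpoint_edge(policy.ins_breakpoint_window)
        window = policy.ins_breakpoint_window

        def edge(a, b):
            return bp(a, b)
    elif sv_class is SVClass.TRA:
        bp = breakpoint_edge(policy.tra_breakpoint_window)
        window = policy.tra_breakpoint_window

        def edge(a, b):
            return bp(a, b)
    else:
        window = None

        def edge(a, b):
            return _span_edge(a, b, policy)

    uf = _UnionFind(len(records))
    for i, a in enumerate(records):
        for j in range(i + 1, len(records)):
            b = records[j]
            if b.interval.contig != a.interval.contig:
                break
            if window is not None:
                if b.interval.start - a.interval.start > window:
                    break
            elif b.interval.start >= a.interval.end:
                break
            if edge(a, b):
                uf.union(i, j)

    clusters: dict[int, list[SVRecord]] = {}
    for i, r in enumerate(records):
        clusters.setdefault(uf.find(i), []).append(r)

    out: list[ConsensusSV] = []
    for members in clusters.values():
        rep = min(members, key=lambda r: (-len(r.callers), -r.n_read_pairs,
                                          r.sort_key()))
        callers_by_species: dict[str, frozenset[str]] = {}
        for m in members:
            prev = callers_by_species.get(m.species, frozenset())
            callers_by_species[m.species] = prev | m.callers
        out.append(
            ConsensusSV(
                interval=rep.interval,
                sv_class=sv_class,
                species_present=frozenset(callers_by_species),
                callers_by_species=callers_by_species,
                source_records=tuple(sorted({s for m in members
                                             for s in m.source_ids})),
                consensus_id="pending",
            )
        )
    out.sort(key=lambda sv: (sv.interval.contig, sv.interval.start,
                             sv.interval.end, sv.source_records))
    final = []
    for k, sv in enumerate(out):
        final.append(ConsensusSV(
            interval=sv.interval, sv_class=sv.sv_class,
            species_present=sv.species_present,
            callers_by_species=sv.callers_by_species,
            source_records=sv.source_records,
            consensus_id=f"{id_prefix}_{sv_class.value}_{k:06d}",
        ))
    return final


def classify_conservation(svs: Sequence[ConsensusSV],
                          all_species: Sequence[str]) -> dict[str, ConservationClass]:
    """Map each consensus event to its sharing level; ``conserved`` means
    present in every analyzed species."""
    known = set(all_species)
    out = {}
    for sv in svs:
        unknown = sv.species_present - known
        if unknown:
            raise ValueError(f"{sv.consensus_id}: unknown species {sorted(unknown)}")
        n = len(sv.species_present)
        out[sv.consensus_id] = ConservationClass(n, n == len(known))
    return out


def conservation_summary(svs: Sequence[ConsensusSV],
                         all_species: Sequence[str]) -> pd.DataFrame:
    """Per-class counts in the three-column layout: Total, shared by more
    than one species, shared by all species."""
    cls = classify_conservation(svs, all_species)
    rows = []
    for sv_class in SVClass:
        members = [sv for sv in svs if sv.sv_class is sv_class]
        ns = [cls[sv.consensus_id].n_species for sv in members]
        rows.append({
            "sv_class": sv_class.value,
            "total": len(ns),
            "gt1_species": sum(1 for n in ns if n > 1),
            "all_species": sum(1 for n in ns if n == len(set(all_species))),
        })
    return pd.DataFrame(rows)


def _mannwhitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (U of the first sample).  Exact when the
    combined sample is small and tie-free, normal approximation with tie
    correction otherwise."""
    method = "exact" if (len(x) + len(y) <= 20
                         and len(set(x) | set(y)) == len(x) + len(y)) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def size_by_conservation_tests(svs: Sequence[ConsensusSV],
                               alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise rank tests of event size between conservation levels.

    For each SV class and each pair of sharing levels, a two-sided
    Mann-Whitney test of the event lengths; when significant at ``alpha``
    the direction column records which level has the smaller ranks
    (e.g. ``"1 < 2"``).
    """
    rows = []
    for sv_class in SVClass:
        members = [sv for sv in svs if sv.sv_class is sv_class]
        by_level: dict[int, list[int]] = {}
        for sv in members:
            by_level.setdefault(len(sv.species_present), []).append(sv.length)
        levels = sorted(by_level)
        for i, la in enumerate(levels):
            for lb in levels[i + 1:]:
                x, y = by_level[la], by_level[lb]
                if len(x) < 2 or len(y) < 2:
                    rows.append({"sv_class": sv_class.value, "level_a": la,
                                 "level_b": lb, "n_a": len(x), "n_b": len(y),
                                 "U": math.nan, "p": math.nan,
                                 "direction": "untestable"})
                    continue
                u, p = _mannwhitney(x, y)
                direction = ""
                if p < alpha:
                    # U below its null mean: first sample ranks lower
                    if u < len(x) * len(y) / 2:
                        direction = f"{la} < {lb}"
                    elif u > len(x) * len(y) / 2:
                        direction = f"{lb} < {la}"
                rows.append({"sv_class": sv_class.value, "level_a": la,
                             "level_b": lb, "n_a": len(x), "n_b": len(y),
                             "U": u, "p": p, "direction": direction})
    return pd.DataFrame(rows)
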