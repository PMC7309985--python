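"""Per-caller quality filters and the deletion size floor.

Breakdancer and Pindel calls must be supported by a minimum number of
sequencing libraries and discordantly mapping read pairs; Breakdancer calls
additionally require the tool's maximum confidence score; Delly calls must
carry both a passing FILTER and the PRECISE flag.  Small deletions (read-pair
evidence is unreliable below ~1 kb) are removed by a class-specific size
floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence, TypeVar

from .core import ConsensusSV, SVClass, SVRecord

log = logging.getLogger(__name__)

__all__ = [
    "FilterThresholds",
    "filter_breakdancer",
    "filter_pindel",
    "filter_delly",
    "filter_records",
    "filter_deletion_size",
]


@dataclass(frozen=True)
class FilterThresholds:
    """Caller-level quality thresholds.

    Defaults: >=2 libraries and >=5 discordant read pairs (Breakdancer,
    Pindel); Breakdancer score >=99 (the tool's maximum confidence value);
    Delly calls must be PASS and PRECISE; deletions shorter than 1000 nt are
    dropped.
    """

    min_libraries: int = 2
    min_read_pairs: int = 5
    breakdancer_min_score: float = 99.0
    require_delly_pass: bool = True
    require_delly_precise: bool = True
    min_deletion_size: int = 1000

    def __post_init__(self) -> None:
        for name in ("min_libraries", "min_read_pairs",
                     "breakdancer_min_score", "min_deletion_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _support_ok(r: SVRecord, t: FilterThresholds) -> bool:
    return r.n_libraries >= t.min_libraries and r.n_read_pairs >= t.min_read_pairs


def filter_breakdancer(records: Sequence[SVRecord],
                       t: FilterThresholds = FilterThresholds()) -> list[SVRecord]:
    """Keep Breakdancer calls with sufficient library/read-pair support and
    score >= the confidence threshold.  Records without a score are rejected."""
    kept, rejected = [], 0
    for r in records:
        if r.caller != "breakdancer":
            raise ValueError(f"record {r.record_id} is not a breakdancer call")
        if _support_ok(r, t) and r.score is not None \
                and r.score >= t.breakdancer_min_score:
            kept.append(r)
        else:
            rejected += 1
    if rejected:
        log.info("filter_breakdancer: rejected %d of %d", rejected, len(records))
    return kept


def filter_pindel(records: Sequence[SVRecord],
                  t: FilterThresholds = FilterThresholds()) -> list[SVRecord]:
    """Keep Pindel calls with sufficient library/read-pair support (Pindel
    exposes no comparable confidence score, so none is required)."""
    kept = []
    for r in records:
        if r.caller != "pindel":
            raise ValueError(f"record {r.record_id} is not a pindel call")
        if _support_ok(r, t):
            kept.append(r)
    return kept


def filter_delly(records: Sequence[SVRecord],
                 t: FilterThresholds = FilterThresholds()) -> list[SVRecord]:
    """Keep Delly calls flagged both PASS and PRECISE."""
    kept = []
    for r in records:
        if r.caller != "delly":
            raise ValueError(f"record {r.record_id} is not a delly call")
        if (r.filter_pass or not t.require_delly_pass) and \
                (r.precise or not t.require_delly_precise):
            kept.append(r)
    return kept


_DISPATCH = {"breakdancer": filter_breakdancer, "pindel": filter_pindel,
             "delly": filter_delly}


def filter_records(records: Sequence[SVRecord],
                   t: FilterThresholds = FilterThresholds()) -> list[SVRecord]:
    """Apply the appropriate caller filter; unknown callers pass unfiltered."""
    if not records:
        return []
    caller = records[0].caller
    fn = _DISPATCH.get(caller)
    if fn is None:
        return list(records)
    return fn(records, t)


_SV = TypeVar("_SV", SVRecord, ConsensusSV)


def filter_deletion_size(svs: Sequence[_SV],
                         t: FilterThresholds = FilterThresholds()) -> list[_SV]:
    """Drop DEL events shorter than ``min_deletion_size`` nt (boundary
    inclusive: a deletion of exactly the minimum size is kept).  Other
    classes are untouched."""
    return [
        sv for sv in svs
        if sv.sv_class is not SVClass.DEL
        or sv.interval.length >= t.min_deletion_size
    ]
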