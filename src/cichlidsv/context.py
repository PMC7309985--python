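"""Repeat-landscape comparison, deletion-alignment concordance, and a
minimal liftover through chained whole-genome alignment blocks.

Repeat landscapes contrast the repeat content (proportion of nucleotides
covered, per repeat class and per divergence-from-consensus bin) inside SV
space against the rest of the genome.  Deletion concordance flags a
predicted deletion as discordant when any whole-genome alignment block
spans at least half of the supposedly deleted region — sequence aligning
across a deletion argues against it.  The liftover maps reference
coordinates into another assembly when both endpoints fall inside blocks of
one alignment chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core import ConsensusSV, GenomicInterval
from .enrichment import Workspace, merge_intervals

log = logging.getLogger(__name__)

__all__ = [
    "RepeatElement",
    "AlignmentBlock",
    "parse_repeatmasker_out",
    "repeat_landscape",
    "deletion_concordance",
    "liftover_interval",
    "read_alignment_bed",
    "write_alignment_bed",
    "invert_blocks",
]

REPEAT_CLASSES = ("DNA", "LINE", "SINE", "LTR", "RC", "Simple_repeat",
                  "Low_complexity", "Satellite", "Unknown", "Other")


@dataclass(frozen=True)
class RepeatElement:
    interval: GenomicInterval
    repeat_class: str
    family: str
    divergence: float  # percent from the family consensus, [0, 100]

    def __post_init__(self) -> None:
        if not 0 <= self.divergence <= 100:
            raise ValueError(f"divergence {self.divergence} outside [0, 100]")
        if self.repeat_class not in REPEAT_CLASSES:
            raise ValueError(f"unknown repeat class {self.repeat_class}")


@dataclass(frozen=True)
class AlignmentBlock:
    """One gapless block of a chained whole-genome alignment."""

    ref_interval: GenomicInterval
    query_interval: GenomicInterval
    strand: str  # '+' or '-'
    chain_id: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand}")
        if self.ref_interval.length != self.query_interval.length:
            raise ValueError(
                f"chain {self.chain_id}: ref span {self.ref_interval.length} "
                f"!= query span {self.query_interval.length}")


def _classify(class_family: str) -> tuple[str, str]:
    cls = class_family.split("/", 1)[0]
    family = class_family.split("/", 1)[1] if "/" in class_family else class_family
    if cls not in REPEAT_CLASSES:
        cls = "Other"
    return cls, family


def parse_repeatmasker_out(path: str | Path) -> list[RepeatElement]:
    """Parse a RepeatMasker ``.out`` file (3 header lines, whitespace-
    separated).  Query coordinates are 1-based inclusive and converted;
    the repeat class is the class/family column up to the first ``/``.
    Malformed rows are skipped with a warning."""
    elements = []
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 11:
            log.warning("%s:%d: malformed row skipped", path, lineno)
            continue
        try:
            div = float(parts[1])
            contig = parts[4]
            start, end = int(parts[5]), int(parts[6])
            cls, family = _classify(parts[10])
            elements.append(RepeatElement(
                GenomicInterval(contig, start - 1, end), cls, family, div))
        except (ValueError, IndexError):
            log.warning("%s:%d: malformed row skipped", path, lineno)
    return elements


def write_repeatmasker_out(elements: Sequence[RepeatElement],
                           path: str | Path) -> None:
    """Write elements in the RepeatMasker ``.out`` layout (for fixtures)."""
    header = (
        "   SW  perc perc perc  query     position in query    matching"
        "  repeat        position in repeat\n"
        "score  div. del. ins.  sequence  begin end (left)     repeat"
        "  class/family  begin end (left) ID\n"
        "\n"
    )
    rows = []
    for i, el in enumerate(elements, 1):
        rows.append(
            f"  500 {el.divergence:5.1f}  0.0  0.0  {el.interval.contig} "
            f"{el.interval.start + 1} {el.interval.end} (0) + {el.family} "
            f"{el.repeat_class}/{el.family} 1 {el.interval.length} (0) {i}"
        )
    Path(path).write_text(header + "\n".join(rows) + ("\n" if rows else ""))


def _complement(regions: list[GenomicInterval],
                genome: Workspace) -> list[GenomicInterval]:
    out = []
    for w in genome.intervals:
        cursor = w.start
        for r in regions:
            if r.contig != w.contig or r.end <= w.start or r.start >= w.end:
                continue
            s = max(r.start, w.start)
            if s > cursor:
                out.append(GenomicInterval(w.contig, cursor, s))
            cursor = max(cursor, min(r.end, w.end))
        if cursor < w.end:
            out.append(GenomicInterval(w.contig, cursor, w.end))
    return out


def repeat_landscape(sv_space: Sequence[GenomicInterval],
                     repeats: Sequence[RepeatElement],
                     genome: Workspace,
                     bin_width: float = 5.0) -> pd.DataFrame:
    """Repeat content inside vs outside SV space, by divergence bin and class.

    For each region (``inside`` = union of SV intervals, ``outside`` = its
    complement within the genome workspace) the proportion is the summed
    length of repeats of a class and divergence bin *fully contained* in
    the region, divided by the region's total length.  Elements straddling
    a region boundary count in neither region, so proportions need not sum
    to the genome-wide repeat fraction.
    """
    if 100 % bin_width:
        log.warning("bin_width %s does not divide 100; last bin truncated",
                    bin_width)
    inside = merge_intervals(sv_space) if sv_space else []
    outside = _complement(inside, genome)
    region_nt = {"inside": sum(iv.length for iv in inside),
                 "outside": sum(iv.length for iv in outside)}

    def region_of(el: RepeatElement) -> str | None:
        for iv in inside:
            if iv.contains(el.interval):
                return "inside"
        for iv in outside:
            if iv.contains(el.interval):
                return "outside"
        return None  # straddles a boundary

    edges = []
    lo = 0.0
    while lo < 100:
        edges.append((lo, min(lo + bin_width, 100.0)))
        lo += bin_width

    counts: dict[tuple[str, float, float, str], int] = {}
    for el in repeats:
        region = region_of(el)
        if region is None:
            continue
        for blo, bhi in edges:
            if blo <= el.divergence < bhi or (el.divergence == 100 == bhi):
                counts[(region, blo, bhi, el.repeat_class)] = \
                    counts.get((region, blo, bhi, el.repeat_class), 0) \
                    + el.interval.length
                break
    rows = []
    for region in ("inside", "outside"):
        for blo, bhi in edges:
            for cls in REPEAT_CLASSES:
                nt = counts.get((region, blo, bhi, cls), 0)
                denom = region_nt[region]
                rows.append({
                    "region": region, "div_lo": blo, "div_hi": bhi,
                    "repeat_class": cls, "repeat_nt": nt,
                    "region_nt": denom,
                    "proportion": nt / denom if denom else 0.0,
                })
    return pd.DataFrame(rows)


def deletion_concordance(
    deletions: Sequence[ConsensusSV],
    blocks: Sequence[AlignmentBlock],
    span_fraction: float = 0.5,
) -> tuple[pd.DataFrame, int, float]:
    """Flag deletions contradicted by the whole-genome alignment.

    A deletion is *discordant* when at least one alignment block overlaps
    it by >= ``span_fraction`` of the deletion length (default 50%):
    alignable sequence covering most of the region argues the sequence is
    still present.  Returns (per-deletion verdicts, discordant count,
    discordant fraction).
    """
    verdicts = []
    n_disc = 0
    for d in deletions:
        if d.interval.length == 0:
            raise ValueError(f"zero-length deletion {d.consensus_id}")
        need = span_fraction * d.interval.length
        discordant = any(
            b.ref_interval.intersection_length(d.interval) >= need
            for b in blocks
        )
        n_disc += discordant
        verdicts.append({"consensus_id": d.consensus_id,
                         "contig": d.interval.contig,
                         "start": d.interval.start, "end": d.interval.end,
                         "discordant": bool(discordant)})
    frame = pd.DataFrame(verdicts)
    frac = n_disc / len(deletions) if deletions else 0.0
    return frame, n_disc, frac


def _validate_chain(blocks: list[AlignmentBlock], chain_id: str) -> None:
    ref_sorted = sorted(blocks, key=lambda b: (b.ref_interval.contig,
                                               b.ref_interval.start))
    for a, b in zip(ref_sorted, ref_sorted[1:]):
        if (a.ref_interval.contig == b.ref_interval.contig
                and b.ref_interval.start < a.ref_interval.end):
            raise ValueError(f"chain {chain_id}: overlapping ref blocks")
        if a.strand != b.strand:
            raise ValueError(f"chain {chain_id}: mixed strands")


def _map_point(pos: int, contig: str,
               blocks: list[AlignmentBlock]) -> tuple[str, int] | None:
    for b in blocks:
        ri = b.ref_interval
        if ri.contig == contig and ri.start <= pos < ri.end:
            offset = pos - ri.start
            if b.strand == "+":
                return b.query_interval.contig, b.query_interval.start + offset
            return b.query_interval.contig, b.query_interval.end - 1 - offset
    return None


def liftover_interval(iv: GenomicInterval,
                      blocks: Sequence[AlignmentBlock]) -> GenomicInterval | None:
    """Map a reference interval into query coordinates, or None if unmapped.

    Both endpoints (start and the last covered base) must fall inside
    blocks of the *same* chain; on minus-strand chains the output interval
    is mirrored in query coordinates.  Fractional mapping is deliberately
    not attempted: an interval whose endpoints leave the chain is reported
    unmapped.
    """
    if iv.length == 0:
        raise ValueError("cannot lift a zero-length interval")
    chains: dict[str, list[AlignmentBlock]] = {}
    for b in blocks:
        chains.setdefault(b.chain_id, []).append(b)
    for chain_id in sorted(chains):
        members = chains[chain_id]
        _validate_chain(members, chain_id)
        p1 = _map_point(iv.start, iv.contig, members)
        p2 = _map_point(iv.end - 1, iv.contig, members)
        if p1 is None or p2 is None or p1[0] != p2[0]:
            continue
        lo, hi = sorted((p1[1], p2[1]))
        return GenomicInterval(p1[0], lo, hi + 1)
    return None


def read_alignment_bed(path: str | Path) -> list[AlignmentBlock]:
    """Read 6-column alignment BED: ref contig, ref start, ref end,
    ``qcontig:qstart-qend``, chain id, strand."""
    blocks = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise ValueError(f"{path}:{lineno}: expected 6 columns")
        contig, start, end, query, chain_id, strand = parts
        qcontig, qrange = query.rsplit(":", 1)
        qs, qe = qrange.split("-")
        blocks.append(AlignmentBlock(
            GenomicInterval(contig, int(start), int(end)),
            GenomicInterval(qcontig, int(qs), int(qe)),
            strand, chain_id))
    return blocks


def write_alignment_bed(blocks: Sequence[AlignmentBlock],
                        path: str | Path) -> None:
    lines = [
        f"{b.ref_interval.contig}\t{b.ref_interval.start}\t{b.ref_interval.end}"
        f"\t{b.query_interval.contig}:{b.query_interval.start}-"
        f"{b.query_interval.end}\t{b.chain_id}\t{b.strand}"
        for b in blocks
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def invert_blocks(blocks: Sequence[AlignmentBlock]) -> list[AlignmentBlock]:
    """Swap reference and query, preserving strand; lifting through the
    inverted chain undoes lifting through the original."""
    return [AlignmentBlock(b.query_interval, b.ref_interval, b.strand,
                           b.chain_id) for b in blocks]
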