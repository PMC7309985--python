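"""Domain types, coordinate conventions, and file I/O for the SV pipeline.

All genomic coordinates are held internally as 0-based half-open intervals
(the BED convention).  VCF, Breakdancer and RepeatMasker inputs use 1-based
inclusive coordinates and are converted on read; writers convert back where
the external format requires it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import cyvcf2

log = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "SVClass",
    "SVRecord",
    "ConsensusSV",
    "reciprocal_overlap",
    "read_sv_vcf",
    "write_sv_vcf",
    "read_breakdancer_tsv",
    "write_breakdancer_tsv",
    "read_sv_bed",
    "write_sv_bed",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval [start, end) on one contig."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("contig must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )


class SVClass(str, Enum):
    """The five rearrangement classes considered by the pipeline."""

    DEL = "DEL"
    DUP = "DUP"
    INV = "INV"
    INS = "INS"
    TRA = "TRA"


# caller output vocabulary -> canonical class
_SVTYPE_ALIASES = {
    "DEL": SVClass.DEL,
    "DUP": SVClass.DUP,
    "DUP:TANDEM": SVClass.DUP,
    "INV": SVClass.INV,
    "INS": SVClass.INS,
    "TRA": SVClass.TRA,
    "BND": SVClass.TRA,
    "CTX": SVClass.TRA,
    "ITX": SVClass.TRA,
}


@dataclass(frozen=True)
class SVRecord:
    """One caller's (possibly merged) structural-variant call."""

    interval: GenomicInterval
    sv_class: SVClass
    species: str
    caller: str
    record_id: str
    n_libraries: int = 0
    n_read_pairs: int = 0
    score: float | None = None
    filter_pass: bool = True
    precise: bool = True
    insertion_length: int = 0
    mate_interval: GenomicInterval | None = None
    # provenance accumulated by merging steps
    source_ids: tuple[str, ...] = ()
    callers: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.sv_class is SVClass.INS:
            if self.insertion_length < 0:
                raise ValueError("insertion_length must be >= 0")
        elif self.interval.length < 1:
            raise ValueError(
                f"{self.sv_class.value} record {self.record_id} has empty interval"
            )
        if not self.source_ids:
            object.__setattr__(self, "source_ids", (self.record_id,))
        if not self.callers:
            object.__setattr__(self, "callers", frozenset({self.caller}))

    @property
    def length(self) -> int:
        if self.sv_class is SVClass.INS:
            return self.insertion_length
        return self.interval.length

    def sort_key(self):
        return (self.interval.contig, self.interval.start, self.interval.end,
                self.record_id)


@dataclass(frozen=True)
class ConsensusSV:
    """A merged multi-species event with representative coordinates."""

    interval: GenomicInterval
    sv_class: SVClass
    species_present: frozenset[str]
    callers_by_species: dict[str, frozenset[str]]
    source_records: tuple[str, ...]
    consensus_id: str

    def __post_init__(self) -> None:
        if not self.species_present:
            raise ValueError("species_present must be non-empty")
        if set(self.species_present) != set(self.callers_by_species):
            raise ValueError("species_present must equal callers_by_species keys")

    @property
    def length(self) -> int:
        return self.interval.length


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(|a∩b|/|a|, |a∩b|/|b|): the fraction both intervals share.

    Symmetric; 0 for intervals on different contigs.  Undefined (raises) for
    zero-length intervals.
    """
    if a.length == 0 or b.length == 0:
        raise ValueError("reciprocal overlap undefined for zero-length interval")
    inter = a.intersection_length(b)
    if inter == 0:
        return 0.0
    return min(inter / a.length, inter / b.length)


# ---------------------------------------------------------------------------
# VCF

def read_sv_vcf(path: str | Path, species: str, caller: str) -> list[SVRecord]:
    """Read SV records from a VCF 4.x file (Delly/Pindel-style output).

    POS/END are converted from 1-based inclusive to 0-based half-open.
    ``FILTER == PASS`` maps to ``filter_pass``; the PRECISE info flag maps to
    ``precise``.  Records whose SVTYPE falls outside the supported
    enumeration are skipped with a warning.  Returns records sorted by
    (contig, start, end).
    """
    records: list[SVRecord] = []
    vcf = cyvcf2.VCF(str(path))
    try:
        for i, var in enumerate(vcf):
            svtype = var.INFO.get("SVTYPE")
            if svtype is None or svtype not in _SVTYPE_ALIASES:
                log.warning("%s: skipping record %s with SVTYPE=%r",
                            path, var.ID or i, svtype)
                continue
            sv_class = _SVTYPE_ALIASES[svtype]
            start = var.POS - 1
            precise = var.INFO.get("PRECISE") is not None
            filter_pass = var.FILTER is None  # cyvcf2: None means PASS
            rid = var.ID or f"{caller}_{species}_{i}"
            mate = None
            ins_len = 0
            if sv_class is SVClass.INS:
                svlen = var.INFO.get("SVLEN")
                if svlen is None:
                    svlen = 0
                ins_len = abs(int(svlen))
                interval = GenomicInterval(var.CHROM, start, start + 1)
            elif sv_class is SVClass.TRA:
                end2 = int(var.INFO.get("POS2", var.INFO.get("END", var.POS)))
                chr2 = var.INFO.get("CHR2", var.CHROM)
                interval = GenomicInterval(var.CHROM, start, start + 1)
                mate = GenomicInterval(str(chr2), end2 - 1, end2)
            else:
                end = var.INFO.get("END")
                if end is None:
                    raise ValueError(
                        f"{path}: record {rid} ({svtype}) lacks INFO/END")
                interval = GenomicInterval(var.CHROM, start, int(end))
            records.append(
                SVRecord(
                    interval=interval,
                    sv_class=sv_class,
                    species=species,
                    caller=caller,
                    record_id=rid,
                    n_libraries=int(var.INFO.get("NLIBS", 0)),
                    n_read_pairs=int(var.INFO.get("PE", 0)),
                    score=None if var.QUAL is None else float(var.QUAL),
                    filter_pass=filter_pass,
                    precise=precise,
                    insertion_length=ins_len,
                    mate_interval=mate,
                )
            )
    finally:
        vcf.close()
    records.sort(key=SVRecord.sort_key)
    return records


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of inserted sequence">
##INFO=<ID=CHR2,Number=1,Type=String,Description="Mate contig for translocations">
##INFO=<ID=POS2,Number=1,Type=Integer,Description="Mate position for translocations">
##INFO=<ID=PRECISE,Number=0,Type=Flag,Description="Precise structural variant">
##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="Imprecise structural variant">
##INFO=<ID=PE,Number=1,Type=Integer,Description="Supporting discordant read pairs">
##INFO=<ID=NLIBS,Number=1,Type=Integer,Description="Number of supporting libraries">
##FILTER=<ID=LowQual,Description="Low quality call">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_sv_vcf(records: Sequence[SVRecord], path: str | Path,
                 contigs: Sequence[tuple[str, int]] | None = None) -> None:
    """Write records as a minimal plain-text VCF readable by :func:`read_sv_vcf`."""
    header = _VCF_HEADER.split("\n", 1)[1]
    text = "##fileformat=VCFv4.2\n"
    if contigs:
        text += "".join(
            f"##contig=<ID={n},length={ln}>\n" for n, ln in contigs)
    text += header
    body = []
    for r in sorted(records, key=SVRecord.sort_key):
        info = [f"SVTYPE={r.sv_class.value}"]
        if r.sv_class is SVClass.INS:
            info.append(f"SVLEN={r.insertion_length}")
        elif r.sv_class is SVClass.TRA:
            assert r.mate_interval is not None
            info.append(f"CHR2={r.mate_interval.contig}")
            info.append(f"POS2={r.mate_interval.end}")
        else:
            info.append(f"END={r.interval.end}")
        info.append("PRECISE" if r.precise else "IMPRECISE")
        info.append(f"PE={r.n_read_pairs}")
        info.append(f"NLIBS={r.n_libraries}")
        qual = "." if r.score is None else f"{r.score:g}"
        filt = "PASS" if r.filter_pass else "LowQual"
        body.append(
            f"{r.interval.contig}\t{r.interval.start + 1}\t{r.record_id}"
            f"\tN\t<{r.sv_class.value}>\t{qual}\t{filt}\t{';'.join(info)}"
        )
    Path(path).write_text(text + "\n".join(body) + ("\n" if body else ""))


# ---------------------------------------------------------------------------
# Breakdancer

_BD_TYPE = {"DEL": SVClass.DEL, "INS": SVClass.INS, "INV": SVClass.INV,
            "DUP": SVClass.DUP, "ITX": SVClass.TRA, "CTX": SVClass.TRA}


def read_breakdancer_tsv(path: str | Path, species: str) -> list[SVRecord]:
    """Read Breakdancer-style tab-separated SV output.

    Expected columns: chrom, pos1, chrom2, pos2, type, size, score,
    num_reads, libraries (``lib:count`` entries joined by ``|``).
    Positions are 1-based and converted on read; ``n_libraries`` counts the
    distinct libraries listed.
    """
    records: list[SVRecord] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 9:
            raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(parts)}")
        chrom, pos1, chrom2, pos2, typ, size, score, num_reads, libs = parts[:9]
        try:
            pos1_i, pos2_i = int(pos1), int(pos2)
            size_i = int(size)
            score_f = float(score)
            nreads = int(num_reads)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric field: {exc}") from None
        if typ not in _BD_TYPE:
            log.warning("%s:%d: skipping unknown type %r", path, lineno, typ)
            continue
        sv_class = _BD_TYPE[typ]
        nlibs = len({entry.split(":")[0] for entry in libs.split("|") if entry})
        mate = None
        ins_len = 0
        if sv_class is SVClass.TRA:
            interval = GenomicInterval(chrom, pos1_i - 1, pos1_i)
            mate = GenomicInterval(chrom2, pos2_i - 1, pos2_i)
        elif sv_class is SVClass.INS:
            interval = GenomicInterval(chrom, pos1_i - 1, pos1_i)
            ins_len = abs(size_i)
        else:
            interval = GenomicInterval(chrom, pos1_i - 1, pos2_i)
        records.append(
            SVRecord(
                interval=interval,
                sv_class=sv_class,
                species=species,
                caller="breakdancer",
                record_id=f"breakdancer_{species}_{lineno}",
                n_libraries=nlibs,
                n_read_pairs=nreads,
                score=score_f,
                insertion_length=ins_len,
                mate_interval=mate,
            )
        )
    records.sort(key=SVRecord.sort_key)
    return records


def write_breakdancer_tsv(records: Sequence[SVRecord], path: str | Path) -> None:
    """Write records in the Breakdancer-style layout read back by
    :func:`read_breakdancer_tsv`.  Library counts are emitted as a single
    pseudo-library per supporting library ("lib1:n|lib2:n|...")."""
    lines = []
    for r in sorted(records, key=SVRecord.sort_key):
        if r.sv_class is SVClass.TRA:
            assert r.mate_interval is not None
            chrom2, pos2 = r.mate_interval.contig, r.mate_interval.end
            typ, size = "CTX", 0
        elif r.sv_class is SVClass.INS:
            chrom2, pos2 = r.interval.contig, r.interval.end
            typ, size = "INS", r.insertion_length
        else:
            chrom2, pos2 = r.interval.contig, r.interval.end
            typ, size = r.sv_class.value, r.interval.length
        libs = "|".join(f"lib{i + 1}:1" for i in range(r.n_libraries))
        score = 0.0 if r.score is None else r.score
        lines.append(
            f"{r.interval.contig}\t{r.interval.start + 1}\t{chrom2}\t{pos2}"
            f"\t{typ}\t{size}\t{score:g}\t{r.n_read_pairs}\t{libs}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# BED

def write_sv_bed(svs: Sequence[ConsensusSV], path: str | Path) -> None:
    """Write consensus events as BED6: contig, start, end, id, n_species, class."""
    lines = [
        f"{sv.interval.contig}\t{sv.interval.start}\t{sv.interval.end}"
        f"\t{sv.consensus_id}\t{len(sv.species_present)}\t{sv.sv_class.value}"
        for sv in svs
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_sv_bed(path: str | Path) -> list[tuple[GenomicInterval, str, int, SVClass]]:
    """Read the BED6 written by :func:`write_sv_bed`.

    Returns (interval, consensus_id, n_species, sv_class) tuples.
    """
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise ValueError(f"{path}:{lineno}: expected 6 columns")
        contig, start, end, cid, nsp, cls = parts
        out.append((GenomicInterval(contig, int(start), int(end)), cid,
                    int(nsp), SVClass(cls)))
    return out


def sort_records(records: Iterable[SVRecord]) -> list[SVRecord]:
    return sorted(records, key=SVRecord.sort_key)


def with_id(record: SVRecord, record_id: str) -> SVRecord:
    return replace(record, record_id=record_id)
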