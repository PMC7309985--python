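"""Synthetic data generator with known ground truth.

Emulates the downstream outputs of a multi-caller SV study on a four-species
radiation: SV gains arise once along a dated tree (Poisson per branch,
events/MY), may be lost on descendant branches, and each caller observes
the per-species presence with a detection probability, breakpoint jitter
and false-positive calls.  Companion annotation fixtures (repeats with a
plantable density boost, genes with a plantable enriched GO term, and
per-species whole-genome alignment blocks that exclude each species' true
deletions) give every downstream stage a recoverable signal.

Simulated histories are recorded in their identifiable (Dollo-canonical)
form: when losses erase one flank of a gain entirely, the gain is re-rooted
to the most recent common ancestor of the surviving leaves, since no
observer of presence/absence data could distinguish the two histories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from intervaltree import IntervalTree

from .core import (GenomicInterval, SVClass, SVRecord, write_breakdancer_tsv,
                   write_sv_vcf)
from .context import AlignmentBlock, RepeatElement, write_alignment_bed, \
    write_repeatmasker_out
from .dollo import PhyloTree, dollo_reconstruct

__all__ = [
    "CallerProfile",
    "SimulationConfig",
    "TruthEvent",
    "simulate_sv_evolution",
    "simulate_caller_calls",
    "simulate_annotation",
    "simulate_dataset",
]

DEFAULT_TREE = ("(((Mzebra:1.0,Pnyererei:1.0):2.0,Hburtoni:3.0):3.0,"
                "Nbrichardi:6.0):4.0;")

DEFAULT_GENOME = tuple((f"lg{i + 1}", 4_000_000) for i in range(20))

# events per million years per branch, by class
DEFAULT_GAIN_RATES = {"DEL": 40.0, "DUP": 15.0, "INV": 15.0,
                      "INS": 25.0, "TRA": 5.0}

# log-normal (mean, sd) of event size in log-nucleotides, plus a floor
DEFAULT_SIZE_DISTS = {
    "DEL": (math.log(3000.0), 0.6, 1200),
    "DUP": (math.log(6000.0), 0.7, 500),
    "INV": (math.log(8000.0), 0.8, 500),
    "INS": (math.log(300.0), 0.7, 50),
    "TRA": (math.log(1.0), 0.0, 1),
}


@dataclass(frozen=True)
class CallerProfile:
    """Detection behaviour of one caller."""

    sensitivity: float = 0.95
    fp_per_mb: float = 0.5
    jitter_sd: float = 50.0
    imprecise_fraction: float = 0.0  # delly-style IMPRECISE flags on FPs

    def __post_init__(self) -> None:
        if not 0 <= self.sensitivity <= 1:
            raise ValueError("sensitivity must lie in [0, 1]")
        if self.fp_per_mb < 0 or self.jitter_sd < 0:
            raise ValueError("rates must be >= 0")


NOISE_FREE = CallerProfile(sensitivity=1.0, fp_per_mb=0.0, jitter_sd=0.0)


@dataclass(frozen=True)
class SimulationConfig:
    tree_newick: str = DEFAULT_TREE
    genome: tuple[tuple[str, int], ...] = DEFAULT_GENOME
    gain_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GAIN_RATES))
    loss_rate: float = 0.02  # per MY, state flip of an existing event
    size_dists: Mapping[str, tuple[float, float, int]] = field(
        default_factory=lambda: dict(DEFAULT_SIZE_DISTS))
    caller_profiles: Mapping[str, CallerProfile] = field(
        default_factory=lambda: {
            "breakdancer": CallerProfile(),
            "delly": CallerProfile(),
            "pindel": CallerProfile(),
        })
    # repeat landscape
    repeat_coverage: float = 0.08          # genome-wide base coverage
    repeat_boost: float = 3.0              # density multiplier inside boosts
    repeat_boost_class: str = "SINE"
    repeat_boost_sv_class: str = "INV"     # truth regions receiving the boost
    # genes + GO
    n_genes: int = 400
    planted_go_term: str = "GO:PLANT"
    seed: int = 0

    def tree(self) -> PhyloTree:
        return PhyloTree.from_newick(self.tree_newick)

    @property
    def genome_length(self) -> int:
        return sum(length for _, length in self.genome)


@dataclass(frozen=True)
class TruthEvent:
    """A simulated SV with its identifiable evolutionary history."""

    event_id: str
    interval: GenomicInterval
    sv_class: SVClass
    gain_branch: str
    loss_branches: frozenset[str]
    species_present: frozenset[str]
    insertion_length: int = 0
    mate_interval: GenomicInterval | None = None


# ---------------------------------------------------------------------------
# evolution


def _sample_interval(rng: np.random.Generator, genome, size: int,
                     occupied: dict[str, IntervalTree],
                     margin: int = 0,
                     max_tries: int = 200) -> GenomicInterval:
    """Place a non-overlapping interval; ``margin`` keeps breakpoint-class
    events farther apart than the merge windows so distinct truth events
    stay distinguishable downstream."""
    contigs = [c for c, ln in genome if ln >= size]
    if not contigs:
        raise ValueError(f"no contig can hold an event of size {size}")
    lengths = np.array([ln for c, ln in genome if ln >= size], dtype=float)
    probs = lengths / lengths.sum()
    for _ in range(max_tries):
        idx = rng.choice(len(contigs), p=probs)
        contig, clen = contigs[idx], int(lengths[idx])
        start = int(rng.integers(0, clen - size + 1))
        iv = GenomicInterval(contig, start, start + size)
        if not occupied[contig].overlaps(max(0, start - margin),
                                         start + size + margin):
            occupied[contig].addi(start, start + size)
            return iv
    raise ValueError("genome too small to place events without overlap")


def simulate_sv_evolution(cfg: SimulationConfig,
                          rng: np.random.Generator | None = None
                          ) -> list[TruthEvent]:
    """Simulate gains and losses of SVs along the tree.

    Per branch and class the gain count is Poisson(rate x branch MY); each
    gain gets a non-overlapping interval (within its class) and may be lost
    on descendant branches with per-branch probability 1 - exp(-loss_rate x
    MY).  Events losing every descendant leaf are unobservable and dropped.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    tree = cfg.tree()
    occupied: dict[str, dict[str, IntervalTree]] = {
        cls: {c: IntervalTree() for c, _ in cfg.genome} for cls in cfg.gain_rates
    }
    events: list[TruthEvent] = []
    counter = 0
    for branch in tree.branches():
        length = tree.branch_length(branch)
        if not length:
            continue
        node = tree.node_of[branch]
        # branches strictly below the gain, preorder, with parent links
        below = [n for n in node.preorder_iter() if n is not node]
        for cls_name in sorted(cfg.gain_rates):
            rate = cfg.gain_rates[cls_name]
            n_gain = int(rng.poisson(rate * length))
            mu, sd, floor = cfg.size_dists[cls_name]
            for _ in range(n_gain):
                sv_class = SVClass(cls_name)
                size = max(floor, int(round(float(rng.lognormal(mu, sd)))))
                ins_len = 0
                mate = None
                if sv_class is SVClass.INS:
                    ins_len = size
                    iv = _sample_interval(rng, cfg.genome, 1,
                                          occupied[cls_name], margin=500)
                elif sv_class is SVClass.TRA:
                    iv = _sample_interval(rng, cfg.genome, 1,
                                          occupied[cls_name], margin=2500)
                    mate = _sample_interval(rng, cfg.genome, 1,
                                            occupied[cls_name], margin=2500)
                else:
                    iv = _sample_interval(rng, cfg.genome, size,
                                          occupied[cls_name])
                # losses: Poisson thinning down the subtree
                lost_nodes: set = set()
                loss_branches: set[str] = set()
                for d in below:
                    if any(a in lost_nodes for a in d.ancestor_iter()):
                        continue
                    blen = d.edge.length or 0.0
                    if cfg.loss_rate > 0 and \
                            rng.random() < 1.0 - math.exp(-cfg.loss_rate * blen):
                        lost_nodes.add(d)
                        loss_branches.add(tree.branch_id[d])
                present = set(tree.leaves_below[node])
                for b in loss_branches:
                    present -= tree.leaves_below[tree.node_of[b]]
                if not present:
                    continue  # unobservable
                rec = dollo_reconstruct(present, tree)  # identifiable form
                events.append(TruthEvent(
                    event_id=f"truth_{cls_name}_{counter:05d}",
                    interval=iv, sv_class=sv_class,
                    gain_branch=rec.gain_branch,
                    loss_branches=rec.loss_branches,
                    species_present=frozenset(present),
                    insertion_length=ins_len, mate_interval=mate,
                ))
                counter += 1
    events.sort(key=lambda e: (e.interval.contig, e.interval.start,
                               e.event_id))
    return events


# ---------------------------------------------------------------------------
# caller noise


def _support(rng: np.random.Generator) -> tuple[int, int]:
    return 2 + int(rng.poisson(1.5)), 5 + int(rng.poisson(8.0))


def _jitter_interval(iv: GenomicInterval, sd: float, contig_len: int,
                     rng: np.random.Generator,
                     breakpoint_only: bool = False) -> GenomicInterval:
    if sd == 0:
        return iv
    ds = int(round(float(rng.normal(0, sd))))
    de = 0 if breakpoint_only else int(round(float(rng.normal(0, sd))))
    start = min(max(0, iv.start + ds), contig_len - 1)
    end = min(max(start + 1, iv.end + (ds if breakpoint_only else de)),
              contig_len)
    if end <= start:
        end = start + 1
    return GenomicInterval(iv.contig, start, end)


def simulate_caller_calls(truth: Sequence[TruthEvent], species: str,
                          cfg: SimulationConfig,
                          rng: np.random.Generator | None = None
                          ) -> dict[str, list[SVRecord]]:
    """Noisy per-caller call sets for one species.

    Each truth event present in the species is detected by each caller with
    probability ``sensitivity``; detected endpoints are perturbed by rounded
    normal jitter (clamped within the contig).  False positives are added
    as Poisson(fp_per_mb x genome Mb) random events per caller.  Support
    counts and flags are drawn so that true calls pass the default filters.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    contig_len = dict(cfg.genome)
    out: dict[str, list[SVRecord]] = {}
    for caller in sorted(cfg.caller_profiles):
        profile = cfg.caller_profiles[caller]
        records: list[SVRecord] = []
        k = 0
        for ev in truth:
            if species not in ev.species_present:
                continue
            if rng.random() >= profile.sensitivity:
                continue
            bp_only = ev.sv_class in (SVClass.INS, SVClass.TRA)
            iv = _jitter_interval(ev.interval, profile.jitter_sd,
                                  contig_len[ev.interval.contig], rng, bp_only)
            mate = ev.mate_interval
            if mate is not None and profile.jitter_sd:
                mate = _jitter_interval(mate, profile.jitter_sd,
                                        contig_len[mate.contig], rng, True)
            nlib, npairs = _support(rng)
            records.append(SVRecord(
                interval=iv, sv_class=ev.sv_class, species=species,
                caller=caller,
                record_id=f"{caller}_{species}_t{k:05d}",
                n_libraries=nlib, n_read_pairs=npairs,
                score=99.0 if caller == "breakdancer" else 60.0,
                filter_pass=True, precise=True,
                insertion_length=ev.insertion_length,
                mate_interval=mate,
            ))
            k += 1
        # false positives
        n_fp = int(rng.poisson(profile.fp_per_mb * cfg.genome_length / 1e6))
        class_names = sorted(cfg.gain_rates)
        rates = np.array([cfg.gain_rates[c] for c in class_names])
        probs = rates / rates.sum()
        contigs = [c for c, _ in cfg.genome]
        for j in range(n_fp):
            cls_name = class_names[int(rng.choice(len(class_names), p=probs))]
            sv_class = SVClass(cls_name)
            mu, sd, floor = cfg.size_dists[cls_name]
            size = max(floor, int(round(float(rng.lognormal(mu, sd)))))
            ci = int(rng.integers(0, len(contigs)))
            contig, clen = cfg.genome[ci]
            ins_len, mate = 0, None
            if sv_class is SVClass.INS:
                start = int(rng.integers(0, clen - 1))
                iv = GenomicInterval(contig, start, start + 1)
                ins_len = size
            elif sv_class is SVClass.TRA:
                start = int(rng.integers(0, clen - 1))
                iv = GenomicInterval(contig, start, start + 1)
                cj = int(rng.integers(0, len(contigs)))
                c2, c2len = cfg.genome[cj]
                m = int(rng.integers(0, c2len - 1))
                mate = GenomicInterval(c2, m, m + 1)
            else:
                size = min(size, clen - 1)
                start = int(rng.integers(0, clen - size))
                iv = GenomicInterval(contig, start, start + size)
            nlib, npairs = _support(rng)
            imprecise = rng.random() < profile.imprecise_fraction
            records.append(SVRecord(
                interval=iv, sv_class=sv_class, species=species,
                caller=caller, record_id=f"{caller}_{species}_fp{j:05d}",
                n_libraries=nlib, n_read_pairs=npairs,
                score=99.0 if caller == "breakdancer" else 60.0,
                filter_pass=True, precise=not imprecise,
                insertion_length=ins_len, mate_interval=mate,
            ))
        records.sort(key=SVRecord.sort_key)
        out[caller] = records
    return out


# ---------------------------------------------------------------------------
# annotation fixtures


def simulate_repeats(cfg: SimulationConfig, truth: Sequence[TruthEvent],
                     rng: np.random.Generator | None = None
                     ) -> list[RepeatElement]:
    """Repeats at uniform base coverage, with the configured class boosted
    to ``repeat_boost`` x density inside truth regions of the chosen SV
    class (creating a recoverable interval enrichment)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    classes = ["DNA", "LINE", "SINE", "LTR", "Simple_repeat", "Low_complexity"]
    weights = np.array([0.35, 0.15, 0.20, 0.15, 0.10, 0.05])
    mean_len = math.exp(math.log(300.0) + 0.5 ** 2 / 2)
    n_base = int(round(cfg.genome_length * cfg.repeat_coverage / mean_len))
    contigs = [c for c, _ in cfg.genome]
    lengths = np.array([ln for _, ln in cfg.genome], dtype=float)
    cprobs = lengths / lengths.sum()
    elements: list[RepeatElement] = []

    def add(contig: str, clen: int, cls: str) -> None:
        size = max(50, int(round(float(rng.lognormal(math.log(300.0), 0.5)))))
        size = min(size, clen - 1)
        start = int(rng.integers(0, clen - size))
        div = float(rng.uniform(0.0, 45.0))
        elements.append(RepeatElement(
            GenomicInterval(contig, start, start + size), cls,
            f"{cls}-fam1", round(div, 1)))

    for _ in range(n_base):
        ci = int(rng.choice(len(contigs), p=cprobs))
        cls = classes[int(rng.choice(len(classes), p=weights))]
        add(contigs[ci], int(lengths[ci]), cls)

    # extra density of the boosted class inside the chosen truth regions
    boost_regions = [ev.interval for ev in truth
                     if ev.sv_class.value == cfg.repeat_boost_sv_class]
    boost_nt = sum(iv.length for iv in boost_regions)
    # Solve for the added density so the *fold change* of the boosted class
    # inside the regions equals the nominal boost b: the genome-wide mean the
    # fold is measured against itself contains the boosted regions, so with
    # f = boosted fraction, x = c(b-1)/(1 - b f) rather than c(b-1).
    f = boost_nt / cfg.genome_length
    b = cfg.repeat_boost
    if b * f >= 0.9:
        raise ValueError("boosted regions occupy too much of the genome "
                         "for the requested boost")
    c = cfg.repeat_coverage * weights[classes.index(cfg.repeat_boost_class)]
    extra = int(round(boost_nt * c * (b - 1.0) / (1.0 - b * f) / mean_len))
    if boost_regions and extra:
        rlens = np.array([iv.length for iv in boost_regions], dtype=float)
        rprobs = rlens / rlens.sum()
        for _ in range(extra):
            ri = int(rng.choice(len(boost_regions), p=rprobs))
            region = boost_regions[ri]
            size = max(50, int(round(float(rng.lognormal(math.log(300.0), 0.5)))))
            size = min(size, max(50, region.length - 1))
            start = int(rng.integers(region.start,
                                     max(region.start + 1, region.end - size)))
            div = float(rng.uniform(0.0, 45.0))
            elements.append(RepeatElement(
                GenomicInterval(region.contig, start,
                                min(start + size, region.end)),
                cfg.repeat_boost_class,
                f"{cfg.repeat_boost_class}-fam1", round(div, 1)))
    elements.sort(key=lambda e: (e.interval.contig, e.interval.start,
                                 e.interval.end, e.family))
    return elements


def simulate_genes(cfg: SimulationConfig, truth: Sequence[TruthEvent],
                   rng: np.random.Generator | None = None
                   ) -> tuple[list, list[tuple[str, str]], dict[str, set[str]]]:
    """Genes placed uniformly, a small GO DAG, and annotations with one
    planted term preferentially annotating genes inside the boosted SV
    regions.  Returns (genes, dag_edges, term->genes)."""
    from .genes import GeneRecord

    if rng is None:
        rng = np.random.default_rng(cfg.seed + 3)
    contigs = [c for c, _ in cfg.genome]
    lengths = np.array([ln for _, ln in cfg.genome], dtype=float)
    cprobs = lengths / lengths.sum()
    genes: list[GeneRecord] = []
    for i in range(cfg.n_genes):
        ci = int(rng.choice(len(contigs), p=cprobs))
        clen = int(lengths[ci])
        size = max(200, int(round(float(rng.lognormal(math.log(2000.0), 0.5)))))
        size = min(size, clen - 1)
        start = int(rng.integers(0, clen - size))
        genes.append(GeneRecord(
            GenomicInterval(contigs[ci], start, start + size),
            f"gene{i:04d}"))

    root = "GO:ROOT"
    edges: list[tuple[str, str]] = []
    leaf_terms: list[str] = []
    for m in range(5):
        mid = f"GO:MID{m}"
        edges.append((mid, root))
        for l in range(4):
            leaf = f"GO:L{m}{l}"
            edges.append((leaf, mid))
            leaf_terms.append(leaf)
    edges.append((cfg.planted_go_term, "GO:MID0"))

    target = [ev.interval for ev in truth
              if ev.sv_class.value == cfg.repeat_boost_sv_class]
    ann: dict[str, set[str]] = {t: set() for t in leaf_terms}
    ann[cfg.planted_go_term] = set()
    for g in genes:
        n_terms = 1 + int(rng.integers(0, 3))
        for t in rng.choice(len(leaf_terms), size=n_terms, replace=False):
            ann[leaf_terms[int(t)]].add(g.gene_id)
        inside = any(iv.contains(g.interval) for iv in target)
        p_plant = 0.8 if inside else 0.02
        if rng.random() < p_plant:
            ann[cfg.planted_go_term].add(g.gene_id)
    return genes, edges, ann


def simulate_alignments(cfg: SimulationConfig, truth: Sequence[TruthEvent],
                        species: str) -> list[AlignmentBlock]:
    """Alignment blocks tiling the reference minus the species' true
    deletions, so no block spans a true deletion (0% discordance by
    construction) while every other region lies inside one block."""
    deleted: dict[str, list[tuple[int, int]]] = {c: [] for c, _ in cfg.genome}
    for ev in truth:
        if ev.sv_class is SVClass.DEL and species in ev.species_present:
            deleted[ev.interval.contig].append((ev.interval.start,
                                                ev.interval.end))
    blocks: list[AlignmentBlock] = []
    for contig, clen in cfg.genome:
        cursor = 0
        qcursor = 0
        qcontig = f"{species}_{contig}"
        chain = f"{species}_{contig}"
        for s, e in sorted(deleted[contig]):
            if s > cursor:
                size = s - cursor
                blocks.append(AlignmentBlock(
                    GenomicInterval(contig, cursor, s),
                    GenomicInterval(qcontig, qcursor, qcursor + size),
                    "+", chain))
                qcursor += size
            cursor = max(cursor, e)
        if cursor < clen:
            size = clen - cursor
            blocks.append(AlignmentBlock(
                GenomicInterval(contig, cursor, clen),
                GenomicInterval(qcontig, qcursor, qcursor + size),
                "+", chain))
    return blocks


def simulate_annotation(cfg: SimulationConfig, truth: Sequence[TruthEvent]):
    """All annotation fixtures: repeats, (genes, DAG edges, term->genes)
    and per-species alignment blocks."""
    ss = np.random.SeedSequence(cfg.seed)
    child = ss.spawn(3)
    repeats = simulate_repeats(cfg, truth, np.random.default_rng(child[0]))
    genes, edges, ann = simulate_genes(cfg, truth,
                                       np.random.default_rng(child[1]))
    tree = cfg.tree()
    alignments = {sp: simulate_alignments(cfg, truth, sp)
                  for sp in sorted(tree.leaves)}
    return repeats, (genes, edges, ann), alignments


# ---------------------------------------------------------------------------
# full dataset on disk


def write_truth_tsv(truth: Sequence[TruthEvent], path: str | Path) -> None:
    lines = ["event_id\tcontig\tstart\tend\tsv_class\tgain_branch"
             "\tloss_branches\tspecies_present\tinsertion_length"]
    for ev in truth:
        lines.append("\t".join([
            ev.event_id, ev.interval.contig, str(ev.interval.start),
            str(ev.interval.end), ev.sv_class.value, ev.gain_branch,
            ",".join(sorted(ev.loss_branches)) or "-",
            ",".join(sorted(ev.species_present)),
            str(ev.insertion_length),
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth_tsv(path: str | Path) -> list[TruthEvent]:
    events = []
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        (eid, contig, start, end, cls, gain, losses, present,
         ins_len) = line.split("\t")
        events.append(TruthEvent(
            event_id=eid,
            interval=GenomicInterval(contig, int(start), int(end)),
            sv_class=SVClass(cls), gain_branch=gain,
            loss_branches=frozenset(losses.split(",")) if losses != "-"
            else frozenset(),
            species_present=frozenset(present.split(",")),
            insertion_length=int(ins_len)))
    return events


def simulate_dataset(cfg: SimulationConfig, outdir: str | Path) -> Path:
    """Generate every input file the pipeline consumes, plus truth tables.

    Layout: ``tree.nwk``, ``genome.tsv``, ``truth_events.tsv``,
    ``calls/<species>.<caller>.{vcf,tsv}``, ``repeats.out``, ``genes.bed``,
    ``gene2go.tsv``, ``go_edges.tsv``, ``alignments/<species>.bed`` and
    ``config.yaml``.  A fixed seed yields byte-identical files.
    """
    out = Path(outdir)
    (out / "calls").mkdir(parents=True, exist_ok=True)
    (out / "alignments").mkdir(exist_ok=True)

    ss = np.random.SeedSequence(cfg.seed)
    evo_seed, call_seed = ss.spawn(2)
    truth = simulate_sv_evolution(cfg, np.random.default_rng(evo_seed))
    write_truth_tsv(truth, out / "truth_events.tsv")
    (out / "tree.nwk").write_text(cfg.tree_newick + "\n")
    (out / "genome.tsv").write_text(
        "".join(f"{c}\t{ln}\n" for c, ln in cfg.genome))

    tree = cfg.tree()
    call_children = call_seed.spawn(len(tree.leaves))
    for sp, sp_seed in zip(sorted(tree.leaves), call_children):
        calls = simulate_caller_calls(truth, sp, cfg,
                                      np.random.default_rng(sp_seed))
        for caller, records in calls.items():
            if caller == "breakdancer":
                write_breakdancer_tsv(records, out / "calls" / f"{sp}.{caller}.tsv")
            else:
                write_sv_vcf(records, out / "calls" / f"{sp}.{caller}.vcf",
                             contigs=cfg.genome)

    repeats, (genes, edges, ann), alignments = simulate_annotation(cfg, truth)
    write_repeatmasker_out(repeats, out / "repeats.out")
    (out / "genes.bed").write_text("".join(
        f"{g.interval.contig}\t{g.interval.start}\t{g.interval.end}"
        f"\t{g.gene_id}\n" for g in genes))
    (out / "go_edges.tsv").write_text("".join(
        f"{c}\t{p}\n" for c, p in edges))
    gene2go = []
    for term in sorted(ann):
        for gene in sorted(ann[term]):
            gene2go.append(f"{gene}\t{term}")
    (out / "gene2go.tsv").write_text("\n".join(gene2go) + "\n")
    for sp, blocks in alignments.items():
        write_alignment_bed(blocks, out / "alignments" / f"{sp}.bed")

    cfg_dict = {
        "tree_newick": cfg.tree_newick,
        "genome": [list(g) for g in cfg.genome],
        "gain_rates": dict(cfg.gain_rates),
        "loss_rate": cfg.loss_rate,
        "size_dists": {k: list(v) for k, v in cfg.size_dists.items()},
        "caller_profiles": {k: asdict(v)
                            for k, v in cfg.caller_profiles.items()},
        "repeat_coverage": cfg.repeat_coverage,
        "repeat_boost": cfg.repeat_boost,
        "repeat_boost_class": cfg.repeat_boost_class,
        "repeat_boost_sv_class": cfg.repeat_boost_sv_class,
        "n_genes": cfg.n_genes,
        "planted_go_term": cfg.planted_go_term,
        "seed": cfg.seed,
    }
    (out / "config.yaml").write_text(
        yaml.safe_dump(cfg_dict, sort_keys=True))
    return out


def config_from_yaml(path: str | Path) -> SimulationConfig:
    raw = yaml.safe_load(Path(path).read_text())
    raw["genome"] = tuple((c, int(ln)) for c, ln in raw["genome"])
    raw["size_dists"] = {k: (float(a), float(b), int(c))
                         for k, (a, b, c) in raw["size_dists"].items()}
    raw["caller_profiles"] = {k: CallerProfile(**v)
                              for k, v in raw["caller_profiles"].items()}
    return SimulationConfig(**raw)
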