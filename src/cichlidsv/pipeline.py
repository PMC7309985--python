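"""End-to-end orchestration: filter -> within-tool merge -> two-tool
consensus -> cross-species merge -> Dollo reconstruction -> enrichment,
GO, repeat-landscape, concordance and liftover reports.

All stages are deterministic given the seed recorded in the manifest;
running twice with the same inputs yields byte-identical output trees.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .core import (ConsensusSV, GenomicInterval, SVClass, SVRecord,
                   read_breakdancer_tsv, read_sv_vcf, write_sv_bed)
from .filters import FilterThresholds, filter_deletion_size, filter_records
from .consensus import MergePolicy, build_consensus_set, merge_within_tool
from .crossspecies import (SizeBandPolicy, conditional_merge_across_species,
                           conservation_summary, size_by_conservation_tests)
from .dollo import PhyloTree, branch_summary_frame, dollo_reconstruct, \
    per_branch_summary
from .enrichment import Workspace, enrichment_test
from .genes import GoDag, genes_fully_inside, go_enrichment_elim, read_gene_bed
from .context import (deletion_concordance, liftover_interval,
                      parse_repeatmasker_out, read_alignment_bed,
                      repeat_landscape)

log = logging.getLogger(__name__)

CALLERS = ("breakdancer", "delly", "pindel")


@dataclass(frozen=True)
class PipelineConfig:
    input_dir: str
    output_dir: str
    thresholds: FilterThresholds = FilterThresholds()
    merge_policy: MergePolicy = MergePolicy()
    band_policy: SizeBandPolicy = SizeBandPolicy()
    n_samples: int = 10000
    seed: int = 0
    enrichment_sv_classes: tuple[str, ...] = ("DEL", "DUP", "INV")
    enrichment_repeat_classes: tuple[str, ...] = ("SINE", "DNA", "LTR")
    elim_cutoff: float = 0.01
    node_size: int = 5
    inv_size_caps: tuple[int, int] = (5_000_000, 10_000_000)
    concordance_species: str | None = None  # default: first leaf

    def hash(self) -> str:
        payload = json.dumps({
            "thresholds": vars(self.thresholds),
            "n_samples": self.n_samples, "seed": self.seed,
            "elim_cutoff": self.elim_cutoff, "node_size": self.node_size,
            "caps": self.inv_size_caps,
        }, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_calls(input_dir: Path, species: str) -> dict[str, list[SVRecord]]:
    out: dict[str, list[SVRecord]] = {}
    for caller in CALLERS:
        tsv = input_dir / "calls" / f"{species}.{caller}.tsv"
        vcf = input_dir / "calls" / f"{species}.{caller}.vcf"
        if tsv.exists():
            out[caller] = read_breakdancer_tsv(tsv, species)
        elif vcf.exists():
            out[caller] = read_sv_vcf(vcf, species, caller)
    return out


def species_consensus(by_caller: Mapping[str, Sequence[SVRecord]],
                      thresholds: FilterThresholds,
                      policy: MergePolicy) -> dict[SVClass, list[SVRecord]]:
    """Filter, within-tool merge and two-tool consensus for one species,
    per SV class."""
    per_class: dict[SVClass, dict[str, list[SVRecord]]] = {}
    for caller, records in by_caller.items():
        kept = filter_records(list(records), thresholds)
        for cls in SVClass:
            subset = [r for r in kept if r.sv_class is cls]
            merged = merge_within_tool(subset, policy) if subset else []
            per_class.setdefault(cls, {})[caller] = merged
    out: dict[SVClass, list[SVRecord]] = {}
    for cls, callers in per_class.items():
        if len(callers) < 2:
            out[cls] = []
            continue
        out[cls] = build_consensus_set(callers, policy)
    return out


def _presence_matrix(svs: Sequence[ConsensusSV],
                     species: Sequence[str]) -> pd.DataFrame:
    rows = []
    for sv in svs:
        row = {"consensus_id": sv.consensus_id,
               "contig": sv.interval.contig,
               "start": sv.interval.start, "end": sv.interval.end}
        for sp in species:
            row[sp] = int(sp in sv.species_present)
        rows.append(row)
    return pd.DataFrame(rows, columns=["consensus_id", "contig", "start",
                                       "end", *species])


def _exact_subsets(tree: PhyloTree) -> dict[str, frozenset[str]]:
    """Named presence patterns mirroring the lineage comparisons: each
    species alone, each internal clade, and the full species set."""
    subsets: dict[str, frozenset[str]] = {}
    for sp in sorted(tree.leaves):
        subsets[f"specific_{sp}"] = frozenset({sp})
    for node in tree._tree.preorder_node_iter():
        leaves = tree.leaves_below[node]
        if 1 < len(leaves) < len(tree.leaves):
            subsets["clade_" + "+".join(sorted(leaves))] = leaves
    subsets["conserved"] = tree.leaves
    return subsets


def run_all(config: PipelineConfig) -> Path:
    """Run every stage and write the report tree; returns the output dir."""
    input_dir = Path(config.input_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    tree = PhyloTree.from_newick(input_dir / "tree.nwk")
    species = sorted(tree.leaves)
    genome = [(c, int(ln)) for c, ln in
              (line.split("\t") for line in
               (input_dir / "genome.tsv").read_text().splitlines() if line)]
    workspace = Workspace(tuple(GenomicInterval(c, 0, ln) for c, ln in genome))

    # --- per-species consensus ---------------------------------------
    per_species_class: dict[SVClass, dict[str, list[SVRecord]]] = {
        cls: {} for cls in SVClass}
    for sp in species:
        calls = load_calls(input_dir, sp)
        if not calls:
            for cls in SVClass:
                per_species_class[cls][sp] = []
            continue
        consensus = species_consensus(calls, config.thresholds,
                                      config.merge_policy)
        for cls in SVClass:
            recs = consensus.get(cls, [])
            if cls is SVClass.DEL:
                recs = filter_deletion_size(recs, config.thresholds)
            per_species_class[cls][sp] = recs

    # --- cross-species merge ------------------------------------------
    merged: dict[SVClass, list[ConsensusSV]] = {}
    for cls in SVClass:
        merged[cls] = conditional_merge_across_species(
            per_species_class[cls], config.band_policy,
            id_prefix="sv")
        write_sv_bed(merged[cls], out / f"consensus_{cls.value}.bed")
        _presence_matrix(merged[cls], species).to_csv(
            out / f"presence_{cls.value}.tsv", sep="\t", index=False)

    all_svs = [sv for cls in SVClass for sv in merged[cls]]
    conservation_summary(all_svs, species).to_csv(
        out / "table1.tsv", sep="\t", index=False)
    size_by_conservation_tests(all_svs).to_csv(
        out / "size_tests.tsv", sep="\t", index=False,
        float_format="%.6g")

    # --- Dollo gain/loss ----------------------------------------------
    recon_rows = []
    for sv in all_svs:
        rec = dollo_reconstruct(sv.species_present, tree)
        recon_rows.append({
            "consensus_id": sv.consensus_id, "sv_class": sv.sv_class.value,
            "gain_branch": rec.gain_branch,
            "loss_branches": ",".join(sorted(rec.loss_branches)) or "-",
            "retained": int(rec.retained),
        })
    pd.DataFrame(recon_rows, columns=["consensus_id", "sv_class",
                                      "gain_branch", "loss_branches",
                                      "retained"]).to_csv(
        out / "reconstructions.tsv", sep="\t", index=False)
    frames = []
    for cls in SVClass:
        frame = branch_summary_frame(per_branch_summary(merged[cls], tree))
        frame.insert(0, "sv_class", cls.value)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(
        out / "branch_summary.tsv", sep="\t", index=False,
        float_format="%.6g")

    # --- interval enrichment ------------------------------------------
    repeats_path = input_dir / "repeats.out"
    repeats = parse_repeatmasker_out(repeats_path) if repeats_path.exists() \
        else []
    enr_rows = []
    for cls_name in config.enrichment_sv_classes:
        segments = [sv.interval for sv in merged[SVClass(cls_name)]]
        if not segments:
            continue
        for rep_cls in config.enrichment_repeat_classes:
            annotation = [r.interval for r in repeats
                          if r.repeat_class == rep_cls]
            if not annotation:
                continue
            res = enrichment_test(segments, annotation, workspace,
                                  n_samples=config.n_samples,
                                  seed=config.seed)
            enr_rows.append({
                "sv_class": cls_name, "repeat_class": rep_cls,
                "observed": res.observed_overlap,
                "expected": res.expected_overlap,
                "fold_change": res.fold_change, "p": res.p_empirical,
                "direction": res.direction, "n_samples": res.n_samples,
            })
    pd.DataFrame(enr_rows, columns=["sv_class", "repeat_class", "observed",
                                    "expected", "fold_change", "p",
                                    "direction", "n_samples"]).to_csv(
        out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")

    # --- genes + GO ----------------------------------------------------
    genes_path = input_dir / "genes.bed"
    if genes_path.exists():
        genes = read_gene_bed(genes_path)
        dag = GoDag.from_tsv(input_dir / "go_edges.tsv",
                             input_dir / "gene2go.tsv")
        universe = {g.gene_id for g in genes if g.mappable}
        subsets = _exact_subsets(tree)
        go_dir = out / "go"
        go_dir.mkdir(exist_ok=True)
        cap = config.inv_size_caps[0]
        for cls in (SVClass.INV, SVClass.DUP):
            for name, pattern in sorted(subsets.items()):
                chosen = [sv for sv in merged[cls]
                          if sv.species_present == pattern
                          and sv.interval.length <= cap]
                study = {g for g, _ in genes_fully_inside(genes, chosen)}
                results = go_enrichment_elim(study & universe, universe, dag,
                                             config.elim_cutoff,
                                             config.node_size)
                pd.DataFrame(
                    [{"term": r.term, "annotated": r.annotated,
                      "significant": r.significant,
                      "expected": round(r.expected, 4),
                      "p_elim": r.p_elim} for r in results],
                    columns=["term", "annotated", "significant", "expected",
                             "p_elim"],
                ).to_csv(go_dir / f"{cls.value}_{name}.tsv", sep="\t",
                         index=False, float_format="%.6g")
            # shared-by-2-or-more, within the size cap
            chosen = [sv for sv in merged[cls]
                      if len(sv.species_present) >= 2
                      and sv.interval.length <= cap]
            study = {g for g, _ in genes_fully_inside(genes, chosen)}
            results = go_enrichment_elim(study & universe, universe, dag,
                                         config.elim_cutoff, config.node_size)
            pd.DataFrame(
                [{"term": r.term, "annotated": r.annotated,
                  "significant": r.significant,
                  "expected": round(r.expected, 4),
                  "p_elim": r.p_elim} for r in results],
                columns=["term", "annotated", "significant", "expected",
                         "p_elim"],
            ).to_csv(go_dir / f"{cls.value}_shared_2plus.tsv", sep="\t",
                     index=False, float_format="%.6g")

    # --- repeat landscape ----------------------------------------------
    if repeats:
        for cls in (SVClass.INV, SVClass.DUP):
            space = [sv.interval for sv in merged[cls]]
            repeat_landscape(space, repeats, workspace).to_csv(
                out / f"repeat_landscape_{cls.value}.tsv", sep="\t",
                index=False, float_format="%.6g")

    # --- deletion concordance ------------------------------------------
    conc_species = config.concordance_species or species[0]
    aln_path = input_dir / "alignments" / f"{conc_species}.bed"
    if aln_path.exists():
        blocks = read_alignment_bed(aln_path)
        dels = [sv for sv in merged[SVClass.DEL]
                if conc_species in sv.species_present]
        verdicts, n_disc, frac = deletion_concordance(dels, blocks)
        verdicts.to_csv(out / "concordance.tsv", sep="\t", index=False)
        (out / "concordance_summary.tsv").write_text(
            "species\tn_deletions\tn_discordant\tdiscordant_fraction\n"
            f"{conc_species}\t{len(dels)}\t{n_disc}\t{frac:.6g}\n")

        # liftover of all merged SV spans through this species' chains
        lift_rows = []
        for cls in SVClass:
            mapped = unmapped = 0
            for sv in merged[cls]:
                if sv.interval.length == 0:
                    continue
                if liftover_interval(sv.interval, blocks) is None:
                    unmapped += 1
                else:
                    mapped += 1
            lift_rows.append({"sv_class": cls.value, "species": conc_species,
                              "mapped": mapped, "unmapped": unmapped})
        pd.DataFrame(lift_rows).to_csv(out / "liftover_summary.tsv",
                                       sep="\t", index=False)

    manifest = {
        "package": "cichlidsv", "version": __version__,
        "seed": config.seed, "config_hash": config.hash(),
        "input_dir": str(input_dir), "species": species,
        "n_consensus": {cls.value: len(merged[cls]) for cls in SVClass},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return out
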