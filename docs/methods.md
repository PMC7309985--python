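# Methods

`cichlidsv` re-implements, as a reusable and tested library, the downstream
analysis of multi-caller structural-variant (SV) surveys across a small
species radiation: call filtering, consensus building, cross-species
merging, gain/loss reconstruction on a dated phylogeny, and the companion
annotation analyses (interval enrichment, GO enrichment, repeat
landscapes, alignment concordance and liftover). A synthetic-data
generator with known ground truth drives every stage end to end.

## Coordinates and domain model

All intervals are 0-based half-open internally (BED convention). VCF,
Breakdancer TSV and RepeatMasker `.out` inputs are 1-based inclusive and
converted on read; writers convert back. Five SV classes are modelled:
deletions (DEL), tandem duplications (DUP), inversions (INV), insertions
(INS) and translocations (TRA). Insertions are represented as 1-nt
breakpoint intervals with the inserted length as metadata; translocations
carry a mate breakpoint. Unknown caller SV types are skipped with a
warning so heterogeneous output remains loadable.

## Call filtering

Per-caller thresholds (`FilterThresholds`): Breakdancer and Pindel calls
need support from ≥2 sequencing libraries and ≥5 discordantly mapping
read pairs; Breakdancer calls additionally need a score of ≥99 (the
tool's maximum confidence value, so effectively an equality); Delly calls
must carry both a passing FILTER and the PRECISE flag, with no
library/read-pair requirement. Deletions shorter than 1 kb are removed —
read-pair evidence severely over-calls small deletions — with the
boundary read inclusively (a 1000-nt deletion survives). The floor is
applied after per-species consensus building and before cross-species
merging.

## Consensus building

Reciprocal overlap of two intervals is `min(|a∩b|/|a|, |a∩b|/|b|)`.
Within one tool, species and class, calls with ≥90% reciprocal overlap
are collapsed by single-linkage clustering; single linkage matches the
behaviour of iterated pairwise `bedtools`-style merging. The cluster
representative is the member with the highest read-pair support (ties:
leftmost start, then smallest end) — support-weighted choice favours the
best-evidenced breakpoints.

Two-tool consensus pairs calls made independently by two callers at ≥90%
reciprocal overlap, using greedy best-overlap one-to-one matching (ties
leftmost); the species/class consensus set is the union of the three
pairwise sets (Breakdancer+Delly, Breakdancer+Pindel, Delly+Pindel)
deduplicated by one further single-linkage pass at the same threshold.

Reciprocal overlap is undefined for translocation breakpoints and
degenerate for insertion breakpoints, so those classes match by
breakpoint distance instead: 1 kb windows for translocations (both
breakpoints must agree), 100 nt for insertions. These windows make
cross-tool insertion agreement observable rather than structurally
impossible.

## Cross-species merging

Breakpoint uncertainty is roughly constant in nucleotides, so small
events tolerate proportionally more of it. The reciprocal-overlap
threshold to merge calls across species is therefore size-conditional:
50% below 500 nt, 80% for 500–1000 nt, 90% for 1–10 kb, 95% above 10 kb
(each band includes its lower bound, excludes the upper). When the two
events fall in different bands the **stricter** threshold governs — the
conservative choice, since the merge should be defensible for both
events. Insertion breakpoints merge across species within 200 nt (each
species' representative breakpoint carries two independent caller
jitters, so the window is twice the within-species one); translocations
within 1 kb.

Conservation is the number of species carrying the merged event;
"conserved" means present in all analyzed species. Size-vs-conservation
comparisons use two-sided Mann–Whitney tests: exact when the combined
sample is ≤20 and tie-free (scipy's exact method refuses ties), normal
approximation with tie correction otherwise. Significant rows (p < 0.05)
carry a direction label such as `1 < 2`.

## Dollo gain/loss reconstruction

An SV is defined relative to the reference genome, so absence is the
ancestral state and presence the derived one; under Dollo parsimony the
derived state arises exactly once. The gain is placed on the branch
subtending the MRCA of the present leaves; one loss is charged to each
maximal clade below the MRCA containing no present leaf. This is the
loss-minimal single-gain scenario, and the only identifiable one: a gain
higher in the tree whose extra flank is entirely lost is observationally
indistinguishable and strictly costlier. Events present in all species
gain on the root stem; their polarity (radiation gain versus a change on
the reference lineage) cannot be resolved without an outgroup, a caveat
that applies to any root-branch gain.

Branch durations in million years come from the user-supplied newick tree
(none are baked in). The net gain rate of a branch is
`(gains − losses) / length_MY`; branches without a usable length report
the rate as undefined rather than aborting.

## Interval enrichment

Association between a segment set and an annotation track is measured as
nucleotide overlap and calibrated by randomly relocating every segment
within a workspace (the sampleable genome): a workspace interval is
chosen with probability proportional to the number of valid start
positions it offers, the start uniform among them. Fold change is
observed/expected (null mean); the empirical p counts null samples at
least as extreme in the observed direction, floored at `1/n_samples`
(default 10,000 samples, hence the 1e-4 floor).

Two numerical choices matter. First, segments are relocated
independently, so two placements can collide; the null statistic
therefore sums per-segment overlaps, which equals the union statistic
whenever placements do not collide — exactly the behaviour of a sampler
that forbids self-overlap. The observed statistic is the union overlap of
the actual (already merged, effectively disjoint) segments. This keeps
the self-consistency identity exact: the annotation tested against
itself, with the workspace equal to the annotation, has fold 1 and p 1.
Second, the directional p is reported two ways: `p_empirical` picks the
tail on the observed side (the quantity usually quoted), while
`p_enriched` is the fixed upper-tail p, which is the uniform-under-null
quantity appropriate for calibration checks — an adaptive-direction p is
uniform on [0, 0.5] by construction and would fail any naive uniformity
test.

No multiple-testing correction is applied by default (raw empirical p
values are reported); Benjamini–Hochberg can be layered on externally.

## Gene containment and GO enrichment

A gene counts as affected by an SV only when its span is fully contained
in the event. GO enrichment uses the one-sided Fisher exact test
(hypergeometric upper tail) with the *elim* traversal: terms are
processed deepest-first (depth = longest path to the root, ties
lexicographic for determinism); a term significant at the elim cutoff
(default 0.01) has its current genes removed from all ancestors before
those are tested, decorrelating the hierarchy. Terms annotating fewer
than `node_size` (default 5) universe genes are skipped. With cutoff 0,
or on a flat DAG, elim reduces exactly to classic Fisher. The DAG is read
from a child→parent edge TSV or a minimal OBO subset (`id:`/`is_a:`
lines only); annotations propagate to ancestors (true-path rule).
Identifier cross-mapping is a user-supplied table, not computed.

## Repeat landscapes, concordance, liftover

The repeat landscape compares, per repeat class and per
divergence-from-consensus bin (default 5% bins — divergence is a proxy
for insertion age), the proportion of nucleotides covered by repeats
*fully contained* inside SV space versus its complement. The same
containment rule applies to both regions, so boundary-straddling elements
count in neither and proportions need not sum to the genome-wide repeat
fraction.

A predicted deletion is *discordant* with a whole-genome alignment when
any single alignment block spans ≥50% of the supposedly deleted region:
alignable sequence across the region argues the sequence is still
present.

The liftover maps an interval into another assembly when both endpoints
fall inside blocks of one alignment chain, applying per-block offsets and
mirroring coordinates on minus-strand chains. Fraction-based rescue of
partially covered intervals is deliberately not attempted; intervals
whose endpoints leave the chain report as unmapped (which is why many
inverted/duplicated regions drop out of landscape comparisons on real
data).

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
with full ground-truth bookkeeping:

- **Evolution.** Per branch and class, gains are Poisson with rate
  events/MY (defaults: DEL 40, INS 25, DUP 15, INV 15, TRA 5 — roughly
  2,000 events on the default 20 MY of total branch length, dominated by
  deletions as in real surveys). Losses flip existing events on
  descendant branches at 0.02/MY. Sizes are log-normal per class
  (medians: DEL 3 kb with a 1.2 kb floor, DUP 6 kb, INV 8 kb, INS 300 nt
  inserted sequence). Events of one class never overlap in truth, and
  insertion/translocation breakpoints are kept farther apart than the
  merge windows, so distinct truth events remain distinguishable — a
  deliberate idealization relative to real genomes. Histories are
  recorded in their identifiable (Dollo-canonical) form.
- **Callers.** Each caller detects a present event with probability 0.95,
  jitters breakpoints with rounded normal noise (sd 50 nt), adds
  0.5 false positives per Mb, and draws support metadata that passes the
  default filters for true calls. Noise-free profiles reproduce truth
  intervals exactly.
- **Genome.** 20 contigs × 4 Mb. Real cichlid genomes are ~1 Gb; the
  synthetic genome is scaled down but kept large enough that SV space is
  a small fraction of it, which matters for enrichment calibration.
- **Repeats.** Uniform base coverage 8% across six classes; one class
  (SINE by default) is boosted inside inversion truth regions. The added
  density solves `x = c(b−1)/(1−bf)` (f = boosted fraction of the
  genome) so that the *recovered fold statistic* equals the nominal boost
  b — the naive `(b−1)c` under-recovers because the genome-wide mean the
  fold is measured against itself contains the boosted regions.
- **Genes/GO.** Uniformly placed genes, a small three-level DAG, and one
  planted term annotating genes inside inversion regions with high
  probability (0.8 vs 0.02 background).
- **Alignments.** Per species, blocks tile the reference excluding that
  species' true deletions: true deletions are 0% discordant by
  construction, while any ≥2 kb interval inside an alignment gap-free
  region is 100% discordant.

What passing tests on this generator do **not** show about real data:
overlapping/nested SVs, caller-specific breakpoint biases, partial
losses, segmental-duplication-driven false calls and mappability holes
are all absent. The generator validates the pipeline's logic, not the
biology.

## Determinism and problem sizes

Every random step derives from one integer seed through spawned
`numpy` generators; a fixed seed yields byte-identical dataset files and
report trees. The shipped test suite runs the full recovery at the
~2,000-event scale (noise-free recovery is exact; with default noise,
per-branch gains are recovered within 10% on branches with ≥200 true
events) and completes in well under a minute; `scripts/acceptance.py`
recomputes the headline quantities in a few seconds.
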