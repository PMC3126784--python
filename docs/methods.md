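# Methods

This note documents the models, conventions and numerical choices behind
`chlorosmall`, and what the synthetic-data validation does and does not
establish about real libraries.

## Read processing

Adapter trimming is exact-match: evidence is a full occurrence of the 3′
adapter anywhere in the read, or an adapter **prefix** of ≥ `min_overlap`
(default 5) bases sitting at the read's 3′ end. The leftmost evidence wins
and trimming is iterated to fixpoint, because a cut can expose a new
terminal adapter prefix; iterating guarantees a returned insert carries no
residual adapter evidence (re-trimming it removes nothing). Reads with no
adapter evidence are dropped by default (`keep_untrimmed` reverses this):
an untrimmed fixed-cycle read has an unknown 3′ boundary, and downstream
matching is exact. A rare side effect of exact trimming is over-trimming —
an insert that genuinely ends with ≥ 5 bases equal to the adapter prefix is
shortened; such reads appear as trace-abundance short sequences and are
ignored wherever per-length ratios are aggregated (bins carrying < 0.1% of
reference mass are excluded).

Collapsing keeps sequences of 9–36 nt over {A,C,G,T}; everything else
(too short/long, N-containing, untrimmed) still counts toward library
depth, so reads-per-million normalization uses the full sequencing depth
and count conservation holds exactly at every stage.

## Exact matching and membership

Genomes are uppercase A/C/G/T; chloroplast genomes are circular, handled by
indexing the genome extended with its first 35 bases so origin-spanning
reads are ordinary substrings (hits are reported modulo genome length).
Matching is perfect (0 mismatches) on both strands via a 9-mer seed table
with verification; an independent naive doubled-string scan serves as the
oracle in tests. Coordinates are 0-based half-open on the forward strand;
minus-strand hits carry a strand flag.

Membership flags per genome role define the two analysis sets. csRNAs are
reads matching the chloroplast genomes of both species; reads additionally
matching the nuclear or mitochondrial genome are **included** — organellar
DNA shared with the nucleus still produces chloroplast-related reads. The
chloroplast-specific subset removes them. When no second-species genome is
supplied the csRNA set degrades to primary-chloroplast matches
(single-species mode).

Multi-locus reads are counted once per read in genome-level summaries and
once per feature in origin summaries, never once per placement: abundance
tables count molecules, not alignments.

## Origin classification

The two inverted-repeat copies of each rRNA gene are merged into one
logical feature (same class and name, equal length), giving a single rRNA
coordinate system; a read hitting both copies classifies identically
through either placement. Overlap priority is tRNA > rRNA > mRNA, ties by
larger overlap then leftmost feature; any ≥ 1 nt overlap with a feature's
genomic body binds the read to that feature, and reads touching no feature
are igRNA. The priority and the antisense handling (classified by the
overlapped feature, antisense flag retained) are conventions — the
underlying biology does not dictate them — so both are explicit parameters
of the code rather than buried constants. Transcript-relative coordinates
are spliced (exon-concatenated) for multi-exon tRNAs; intronic positions
collapse onto the junction, upstream/downstream positions are negative or
≥ L.

## Positional profiles

Block profiles divide a transcript of length L into `n_blocks` (default
20, i.e. 5% blocks): a position p in [0, L) falls in block
`floor(p / (L / n_blocks))`, clamped to the body. Flanks are proportional:
positions in [−0.2 L, 0) and [L, 1.2 L) map to four pseudo-blocks per side
of the same 5%-of-L width; mass beyond ±20% clamps to the outermost
pseudo-block. Only read **end** positions are tallied (one nucleotide per
read per end), not whole-read coverage; both the 5′ and the 3′ tallies are
kept separately and each conserves total assigned abundance. Histograms
weight by read count, with a unique-sequence mode (weight 1) available.
Terminus offsets are signed distances from the mature boundary (offset 0 =
first nucleotide for 5′ anchors, last nucleotide for 3′ anchors), windowed
at ±10 by default with out-of-window mass pooled.

## Family clustering

Families are genomic, not string-based: same-strand placements connected
by pairwise interval overlap ≥ `min_core` (default 9 nt, configurable up
to 15) form components; a component whose full interval intersection is
still ≥ `min_core` is one family, otherwise it is split greedily — members
ordered by descending abundance (ties: leftmost interval, then sequence)
seed families, and each member joins the family whose running core it
preserves (ties: longest resulting core, then leftmost). The greedy split
is deterministic and order-invariant, and on small instances it is checked
against an exhaustive branch-and-bound oracle that minimizes the number of
families with a canonical tie-break. Members on opposite strands never
share a family. Dominant lengths are local maxima of the family's length
histogram, at most two, a secondary mode requiring ≥ 10% of the primary's
mass and not adjacent to it.

## Differential analysis

Counts normalize to reads per million of total library depth. Fold change
is treatment/reference RPM with a pseudocount of 0.5 raw reads substituted
for zero counts before normalization (finite ratios; increasing a
treatment count can only move a unit toward "up"). Categories: down
< 1/5-fold, up > 5-fold, unchanged otherwise — boundaries exclusive, so
the three categories partition exactly. Per-tRNA response typing compares
the shorter (16–25 nt) and longer (29–32 nt) size classes at a 1.2-fold
trend threshold (direction cutoffs are not dictated by the data and are
exposed as parameters): group I = shorter up & longer down, II = shorter
up & longer unchanged, III = longer down & shorter unchanged, IV =
anything else. tRNAs with no reads in either condition are excluded.
Replicates, when given, are summed per condition.

## Synthetic data generator

The generator emulates a scaled-down plastome: 40 kb circular genome, two
inverted repeats (IRb the exact reverse complement of IRa) each carrying a
16S/23S/4.5S/5S rRNA operon, twenty tRNAs named by amino acid including a
two-exon tRNA-Ala (intron 150 nt), four mRNAs, and random spacers. A
second-species chloroplast is identical except one designated spacer
replaced with random sequence (divergence concentrated in intergenic
regions, as between related crucifers); a 60 kb nuclear decoy carries one
200 nt block copied from a chloroplast spacer, creating genuinely shared
sequence. Reads of ≥ 16 nt are guaranteed unambiguous: after constructing
the read slots, every slot sequence is checked to occur only at its
designed loci (twice for IR features, once plus a nuclear copy for the
shared block, once otherwise), and the genome is redrawn on the rare
chance violation.

Reads are emitted from a finite slot set — (origin, genomic start, length,
strand):

* **anchored slots** place the rRNA 3′ end or tRNA 5′ end at the mature
  boundary plus an offset drawn from {−1, 0, +1} (default probabilities
  0.01/0.98/0.01 — termini are precise to the mature end with rare 1 nt
  wobble, matching the single-nucleotide peaks seen at 4.5S/5S
  boundaries). Default anchor probabilities: rRNA 3′ 0.9, tRNA 5′ 0.97.
* **background slots** emanate from a small fixed set of per-feature
  processing sites (8 per rRNA, 4 per tRNA) with the class's characteristic
  lengths — real libraries are deeply saturated over a limited universe of
  processing products, and a finite slot space reproduces that saturation
  at desk-scale depth.
* class length mixtures follow the observed shapes: rRNA 16–30 nt with
  peaks at 18–19, 21–22 and 25; tRNA 16–32 nt peaking at 29 with smaller
  23–24 and 32 peaks; mRNA 21–24 nt; igRNA ≈ Poisson around 22 nt.
  Within rRNA, 4.5S carries 70% of the mass.
* half of each library is organellar (class split rRNA 0.62 / tRNA 0.15 /
  mRNA 0.08 / igRNA 0.15, the igRNA budget including the shared-block and
  primary-only sources), half is nuclear decoy. The organellar share is
  higher than in real libraries so that 50,000-read libraries carry enough
  organellar mass for stable profiling; the decoy fraction still exercises
  every filter.

Reads are emitted as fixed-cycle sequences with the 3′ adapter appended
and a constant pad. The cycle length is 42: a 36-cycle read cannot carry a
36 nt insert *and* ≥ 5 adapter bases, so with a 36-cycle instrument the
longest inserts are unrecoverable by adapter-evidence trimming; 42 cycles
preserve the full 9–36 nt window. No sequencing errors are simulated by
default (the analysis keeps perfect matches only); an `error_rate` knob
exists and defaults to 0.

Condition effects are planted as expected RPM ratios per slot. The
treatment library's organellar read total is solved self-consistently so
that each slot's expected RPM ratio equals its multiplier exactly (decoy
counts stay fixed; depth adjusts). The scenario preset
(`paper_scenario()`) encodes the reported heat responses: rRNA abundance
×0.49 with the unique pool masked to 0.29 of its slots (mask size
deterministic via largest-remainder quotas per read length, membership
random; removed mass redistributed within the same length so per-length
ratios are untouched), igRNA ×1.3, mRNA ×0.5, per-tRNA group multipliers
(I: shorter ×2 / longer ×0.5; II: shorter ×2; III: longer ×0.5; IV:
18 nt ×0.5 only), and a global exemption holding every 24 nt read at ×1.
Because the exemption overlaps the class mixtures, the non-exempt
multiplier of each class is solved so the class-level ratio still lands on
its target. The preset uses 800,000 reads per condition so that per-tRNA
size-class trends are estimated with ≈ 5% sampling error — comfortably
inside the 1.2-fold trend threshold — while the full end-to-end run stays
in seconds.

## What the validation does and does not show

Passing tests demonstrate that the pipeline recovers known biogenesis
parameters (anchor probabilities, offsets, class fractions, family modes,
condition multipliers) from data whose generative process matches the
analysis assumptions: exact reads, finite processing-site universe, no
sequencing error, ideal adapters. They do not establish robustness to
mismatches, quality-dependent errors, ligation bias, or annotation error
in real libraries, and the generator makes no attempt at realistic base
composition or structure-driven biogenesis. The published-count
arithmetic checks only the summary percentages, not the upstream
sequencing analysis.

## Known discrepancies and limitations

* From the published per-library counts, the heat-treated chloroplast
  share of all reads is 1,278,752 / 14,622,224 = 8.7%, while the source
  text rounds the pair to "15% and 10%"; the package reproduces the
  arithmetic (8.7%), not the printed rounding.
* The reported "approximately 25% of unique sequences and 36% of the csRNA
  abundance" after heat cannot be derived from the published per-library
  table (whose ratios are 67% and 59%); it was likely computed on an
  undescribed filtered subset. No guess is implemented; the package
  reports the table-derived ratios.
* Families are same-strand by construction; cross-strand families, if they
  exist, would be split.
* No statistical test is attached to fold-change categories (none is
  defined for the thresholds); the categories are descriptive.
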