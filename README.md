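# chlorosmall

Discovery and characterization of **chloroplast-derived small RNAs
(csRNAs)** from small-RNA sequencing libraries.

Plant small-RNA libraries contain a sizeable organellar fraction: in
heat-stress experiments on *Brassica* seedlings, roughly 9–15% of all
sequenced small RNAs map perfectly to the chloroplast genome. These reads
are not uniform degradation noise — they concentrate at the 3′ termini of
rRNAs and the 5′ termini of tRNAs, fall into families sharing a common
genomic core sequence with variable 5′/3′ extensions, and respond to heat
stress in a class- and size-dependent way. `chlorosmall` implements the
full analysis chain needed to make those observations, plus a synthetic
data generator with per-read ground truth so that every stage can be
validated quantitatively.

## What the package computes

Given raw FASTQ libraries and reference genomes, the pipeline runs:

1. **sequence_io** — 3′-adapter trimming (exact, leftmost, iterated to
   fixpoint) and collapsing into unique 9–36 nt sequences with per-library
   counts. Library depth bookkeeping is exact: collapsed + filtered = raw.
2. **genome_index** — perfect-match placement on circular genomes (both
   strands, origin-spanning reads included) via a seeded substring index.
   Membership across genomes defines the two read sets:
   *csRNA* = perfect match to the chloroplast genomes of **both** species
   (reads shared with the nucleus stay in, by definition);
   *chloroplast-specific* = csRNA additionally absent from the nuclear and
   mitochondrial genomes.
3. **origin_annotation** — each csRNA resolves to exactly one origin class
   (tRNA > rRNA > mRNA priority, else igRNA = intergenic) with
   transcript-relative coordinates; the two inverted-repeat copies of each
   rRNA gene are one logical feature; multi-exon tRNAs use spliced
   coordinates.
4. **positional_profile** — 5%-block profiles of read 5′/3′ end positions
   (20 blocks per transcript with proportional ±20% flank pseudo-blocks)
   and terminus-offset histograms at single-nucleotide resolution.
5. **family_clustering** — same-strand reads whose genomic intervals share
   a core of ≥ 9 nt form a family (greedy abundance-seeded splitting when a
   component's interval intersection collapses; verified against an
   exhaustive oracle); each family reports its dominant read lengths.
6. **differential_analysis** — reads-per-million normalization, HT/MT fold
   changes (pseudocount 0.5 raw reads, down < 1/5, up > 5), per-class and
   per-length summaries, and per-tRNA size-class response typing
   (shorter 16–25 nt vs longer 29–32 nt, groups I–IV).
7. **simulate** — a 40 kb circular chloroplast-like genome (two inverted
   repeats carrying a 23S/16S/5S/4.5S operon, 20 tRNAs incl. one
   intron-containing, mRNAs, spacers), a diverged second-species
   chloroplast, a nuclear decoy with one designed shared block, and
   condition-paired adapter-bearing read libraries with known biogenesis
   parameters and slot-level ground truth.

## Worked example

```python
import chlorosmall as cs
from chlorosmall import positional_profile as pp

cfg = cs.default_config(seed=4)          # 50,000 reads per condition
res = cs.generate_libraries(cfg)         # genome + libraries + ground truth
g = res.genome
out = cs.run_analysis(
    res.reads, [g.chloroplast, g.other_chloroplast, g.nuclear], g.features,
    adapter=cfg.adapter,
)

frac_r, _ = pp.end_peak_test(out.profiles["rRNA"], "3", 19)
frac_t, _ = pp.end_peak_test(out.profiles["tRNA"], "5", 0)
print(f"rRNA last-block 3' fraction: {frac_r:.3f}")
print(f"tRNA first-block 5' fraction: {frac_t:.3f}")
```

prints

```
rRNA last-block 3' fraction: 0.896
tRNA first-block 5' fraction: 0.963
```

i.e. 89.6% of rRNA-derived read 3′ ends fall in the last 5% block of the
mature rRNA and 96.3% of tRNA-derived read 5′ ends in the first block —
recovering the planted anchor probabilities (0.9 and 0.97) and reproducing
the qualitative signature of 3′-anchored rRNA fragments and 5′-anchored
tRNA fragments. More narrative walkthroughs live in `examples/`
(published-table arithmetic, matching and membership filters, family
length modes, heat-response recovery); each prints the numbers it computes
with a note on what they mean.

The same analyses run from the shell:

```bash
chlorosmall simulate --seed 17 -o simdir/
chlorosmall run --config pipeline.yaml      # emits the TSV report bundle
```

Reports are plain TSV with fixed columns: `mapping_summary`,
`composition`, `size_distribution`, `block_profiles`, `terminus_offsets`,
`families`, `differential`, `class_fold_summary`,
`class_length_fold_summary`, `response_groups`, `stage_log`, plus a BED6
file of csRNA placements.

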