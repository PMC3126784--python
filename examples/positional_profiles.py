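"""Where along the mature RNA do small RNAs arise?

Runs the default simulation and shows the two positional views: 5%-block
profiles (rRNA 3'-end peak in the last block, tRNA 5'-end peak in the
first) and single-nucleotide terminus-offset histograms.
"""

import chlorosmall as cs
from chlorosmall import positional_profile as pp

cfg = cs.default_config(seed=4)
res = cs.generate_libraries(cfg)
g = res.genome
out = cs.run_analysis(
    res.reads, [g.chloroplast, g.other_chloroplast, g.nuclear], g.features,
    adapter=cfg.adapter,
)

frac_r, _ = pp.end_peak_test(out.profiles["rRNA"], "3", 19)
frac_t, _ = pp.end_peak_test(out.profiles["tRNA"], "5", 0)
print(f"rRNA: {frac_r:.1%} of 3' ends fall in the last 5% block "
      f"(3'-anchor probability planted at {cfg.rrna_anchor_prob})")
print(f"tRNA: {frac_t:.1%} of 5' ends fall in the first 5% block "
      f"(5'-anchor probability planted at {cfg.trna_anchor_prob})")

hist = pp.terminus_offsets(
    out.assignments, g.feature_by_name("rrn4.5"), "3-prime",
    collapsed=out.collapsed,
)
print("4.5S rRNA 3'-end offsets (0 = last nucleotide of the mature RNA):")
for off in range(-3, 4):
    print(f"  {off:+d}: {hist.offsets[off]:8.0f}")
print(f"modal offset: {hist.modal_offset()}")

# The block fractions recover the planted anchor probabilities; the offset
# histogram resolves the anchor to single-nucleotide precision at the
# mature 3' boundary.
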