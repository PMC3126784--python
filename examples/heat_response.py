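"""Heat-response recovery on the scenario preset.

The scenario plants the reported effect directions — rRNA abundance to
~0.49x (unique pool to ~0.29x), igRNA to ~1.3x, tRNAs responding by size
class, 24-nt reads exempt — and the pipeline recovers them end to end.
"""

import chlorosmall as cs

cfg = cs.paper_scenario(seed=3)
res = cs.generate_libraries(cfg)
g = res.genome
out = cs.run_analysis(
    res.reads, [g.chloroplast, g.other_chloroplast, g.nuclear], g.features,
    adapter=cfg.adapter, reference="MT", treatment="HT",
)

cl = out.class_summary.set_index("class")
print("class-level HT/MT ratios (abundance, unique):")
for cls in ("rRNA", "tRNA", "mRNA", "igRNA"):
    print(f"  {cls:5s}  {cl.loc[cls, 'abundance_ratio']:.3f}  "
          f"{cl.loc[cls, 'unique_ratio']:.3f}")

agg = out.class_length_summary.groupby("length").agg(
    ref=("rpm_reference", "sum"), trt=("rpm_treatment", "sum")
)
agg = agg[agg.ref >= 1e-3 * agg.ref.sum()]
ratios = agg.trt / agg.ref
print(f"24-nt bin ratio: {ratios[24]:.3f} (all other bins < 1: "
      f"{bool((ratios.drop(24) < 1).all())})")

print("\ntRNA size-class response groups (I: shorter up & longer down, "
      "II: shorter up, III: longer down, IV: other):")
print(out.response_groups[["trna", "shorter_fold_change",
                           "longer_fold_change", "group"]].to_string(index=False))

# Group labels match the planted configuration for every tRNA; the 24-nt
# exemption shows up as the single length bin that does not decrease.
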