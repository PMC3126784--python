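"""Core-sequence families and their characteristic read lengths.

Small RNAs sharing a genomic core (>= 9 nt) with variable 5'/3' extensions
form a family; each family typically shows one or two dominant lengths.
Here a tRNA-Ala 5'-anchored family is planted with a bimodal {17, 29}
length mixture and recovered by clustering.
"""

import chlorosmall as cs
from chlorosmall import family_clustering as fc

cfg = cs.default_config(seed=8, n_reads=20_000, trna_lengths={17: 1.0, 29: 1.2})
res = cs.generate_libraries(cfg)
g = res.genome
out = cs.run_analysis(
    res.reads, [g.chloroplast, g.other_chloroplast, g.nuclear], g.features,
    adapter=cfg.adapter,
)
print(f"{len(out.families)} families over {len(out.assignments)} unique csRNAs")

# locate the family anchored at the tRNA-Ala mature 5' end
pl = g.feature_by_name("trnAla").placements[0]
g5 = pl.blocks[0][0] if pl.strand == "+" else pl.blocks[-1][1] - 1
fam = next(f for f in out.families if any(m.start <= g5 < m.end for m in f.members))

hist, modes = fc.family_size_distribution(fam)
print(f"tRNA-Ala family: {len(fam.members)} member sequences, "
      f"core {fam.core_interval} ({fam.core_end - fam.core_start} nt)")
print("length histogram (abundance):")
print(hist.to_string())
print(f"dominant lengths: {modes}")

# The two modes match the planted 17/29 mixture: one family, one core, two
# characteristic fragment sizes differing only in extension length.
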