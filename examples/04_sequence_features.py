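"""Sequence composition and bendability: are remodeler-preferred sites
stiff, A+T-rich DNA?

Builds a position frequency matrix over 16 synthetic point centromeres
(designed ~90% A+T) and compares the bendability of A+T-rich versus
G+C-rich 100-bp region classes (29 regions each).
"""

import numpy as np

from mnasefrag import io as fio, seqfeat, simulate as sim

SEED = 4

feats = []
for i in range(16):
    feats.extend(sim.centromere_placements("c", 2000 + 4000 * i, name=f"CEN{i + 1}"))
genome = sim.build_genome(sim.GenomeSpec({"c": 70_000}, feats), SEED)
anchors = fio.to_anchors(genome.features_of_class("centromere"), "midpoint")
pfm = seqfeat.pfm_from_anchors(genome.sequences, anchors, flank=200)
central = np.nanmean(pfm.at_fraction[150:251])
print(f"mean A+T fraction over the central 100 bp of 16 centromeres: {central:.2f}")

rng = np.random.default_rng(SEED)
at_rich = ["".join(rng.choice(list("ACGT"), 100, p=[.45, .05, .05, .45]))
           for _ in range(29)]
gc_rich = ["".join(rng.choice(list("ACGT"), 100, p=[.05, .45, .45, .05]))
           for _ in range(29)]
scale = seqfeat.BendabilityScale.default()
diff, t, p = seqfeat.compare_region_bendability(at_rich, gc_rich, scale, window=39)
print(f"mean bendability difference (A+T-rich - G+C-rich): {diff:+.3f}, "
      f"Welch t = {t:.1f}, p = {p:.2e}")
# A negative difference says the A+T-rich class is stiffer under the
# packaged scale, the property that makes such sites poor nucleosome
# substrates and favored remodeler entry points.
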