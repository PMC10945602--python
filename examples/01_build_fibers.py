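"""Build the fiber systems: uniform, life-like, TF patterns, and the Eed locus.

Constructs each fiber family, annotates TF-bindable regions, linker
histones and acetylation islands, and prints the resulting bead accounting.
"""

import numpy as np

import fibermc as fm
from fibermc.fixtures import make_fixture

# A 50-nucleosome fiber with medium (44 bp) linkers: each linker is 5 beads
# of ~9 bp of DNA.
uniform = fm.build_uniform_fiber(50, 44)
print(f"uniform 44 bp fiber: {uniform.n_cores} cores, "
      f"{uniform.n_linker_beads} linker beads "
      f"({uniform.linker_runs[0]} per linker)")

# A "life-like" fiber draws each linker from the mESC linker-length
# distribution (30% 26 bp, 17% 35 bp, ... 9% 80 bp).
life = fm.build_lifelike_fiber(50, seed=1)
bp = np.array(life.linker_bp)
print(f"life-like fiber: mean linker {bp.mean():.1f} bp "
      f"(classes {sorted(set(bp.tolist()))})")

# The four canonical TF binding patterns; pattern 1 marks the linkers of
# five 5-nucleosome regions spread along the fiber.
for pid in (1, 2, 3, 4):
    marked = fm.apply_tf_topology(uniform, fm.TFTopologySpec.pattern(pid))
    print(f"pattern {pid}: {sum(marked.tf_bindable)} TF-bindable linker beads")

# Concentration-style marking: 25% of linker beads, chosen at random.
conc = fm.set_tf_concentration(uniform, 25, seed=2)
print(f"25% concentration: {sum(conc.tf_bindable)} of "
      f"{conc.n_linker_beads} beads bindable")

# Linker histones and acetylation islands.
with_lh = fm.place_linker_histones(uniform, 1.0)
acet = fm.mark_acetylation(uniform, [(6, 11), (17, 22), (28, 33), (39, 44)])
print(f"+LH: {sum(with_lh.lh_occupied)} occupied cores; "
      f"+Ac: {sum(acet.acetylated)} acetylated cores")

# The Eed gene locus (mm9 chr7), tiled from its NFR/LH/TF tracks: 129
# nucleosomes at NRL 189 around seven nucleosome-free regions, with two
# ChIP-derived Myc:Max binding regions (region 1 overlaps the promoter).
eed, tracks = make_fixture("eed_tf")
print(f"Eed locus: {eed.n_cores} cores, {len(eed.nfr_spans)} NFRs, "
      f"{sum(eed.lh_occupied)} LHs (density "
      f"{sum(eed.lh_occupied) / eed.n_cores:.2f}), "
      f"{sum(eed.tf_bindable)} TF-bindable beads in 2 regions")
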