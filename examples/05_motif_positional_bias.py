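"""Where do TF-binding motifs sit inside common vs specific sites?

The positional profile gives, for each offset within +-150 bp of site
midpoints, the fraction of sites carrying a motif occurrence at that
offset. The family table contrasts the percentage of common vs specific
sites containing each TF family.
"""

import numpy as np

from mhscan.motifs import percentage_change_table, positional_profile, smooth_profile
from mhscan.simulate import SimConfig, simulate_all

cfg = SimConfig(
    seed=5, genome=(("chr1", 1_500_000),),
    n_common_sites=75, n_specific_sites=75, n_fragments=0,
)
sim = simulate_all(cfg)
genome = cfg.chrom_sizes()
common = sim.truth.site_interval_set(genome, "common")
specific = sim.truth.site_interval_set(genome, "specific")

table = percentage_change_table(common, specific, sim.motif_occurrences)
print("TF families ranked by percentage change (common - specific):")
print(table.to_string(index=False))

for name, centers in (("common", common), ("specific", specific)):
    prof = positional_profile(sim.motif_occurrences, centers, halfwidth=150)
    sm = smooth_profile(prof, window=11)
    half_mass = np.abs(np.arange(-150, 151))[sm > sm.max() / 2]
    print(
        f"{name}: profile peak {sm.max():.3f} at offset "
        f"{int(np.argmax(sm)) - 150:+d} bp; half-max extends to "
        f"+-{half_mass.max()} bp"
    )
# positive changes mark families enriched in common sites; the specific
# profile is much narrower — narrow sites centre their single footprint
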