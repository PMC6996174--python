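"""Split sites into common/specific classes and place them on the genome.

A site covered by another open-chromatin assay (DNase-seq, ATAC-seq) is
"common" (cMHS); one seen only by the MNase assay is "specific" (sMHS).
Each site also gets a genomic-feature category and, where one lies
within 1 kb, a cognate gene.
"""

from collections import Counter

from mhscan.annotate import (
    assign_cognate_gene,
    categorize,
    classify_specific,
    overlap_matrix,
)
from mhscan.simulate import SimConfig, simulate_all

cfg = SimConfig(
    seed=2, genome=(("chr1", 1_000_000),),
    n_common_sites=50, n_specific_sites=50, n_fragments=0,
)
sim = simulate_all(cfg)
genome = cfg.chrom_sizes()
sites = sim.truth.site_interval_set(genome)

labels = classify_specific(sites, list(sim.other_assays.values()))
counts = Counter(labels)
print(f"{counts['sMHS']}/{len(sites)} sites are specific "
      f"({100 * counts['sMHS'] / len(sites):.0f}%)")

mat = overlap_matrix({"MHS": sites, **sim.other_assays})
print("overlap-rate matrix (% of row set overlapping column set):")
print(mat.round(1))

cats = categorize(sites, sim.genes, sim.tes)
print("feature categories:", dict(Counter(c.value for c in cats)))

n_cognate = sum(
    assign_cognate_gene(iv, sim.genes, mhs_index=i).gene_id is not None
    for i, iv in enumerate(sites)
)
print(f"{n_cognate}/{len(sites)} sites have a cognate gene within 1 kb")
# specific sites sit outside the other assays' peaks by construction, so
# the sMHS share tracks the planted specific fraction
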