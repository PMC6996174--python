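# mhscan

Detection and characterization of **MNase hypersensitive sites (MHSs)** —
open-chromatin regions revealed by the small (20–100 bp) DNA fragments
that micrococcal nuclease releases from protein-bound, nucleosome-depleted
DNA. The package is aimed at regulatory genomicists who have aligned
sub-nucleosomal fragment data (or want to prototype against simulated
data) and need to call sites, compare them with DNase-seq/ATAC-seq peaks,
class their chromatin states, and relate them to methylation, genes and
TF motifs.

## The model

Fragment midpoints are counted in sliding windows (20 bp, step 10 bp).
The genomic background is a **zero-inflated Poisson (ZIP)**,

    P(K = 0) = π + (1 − π) e^{−λ},   P(K = k) = (1 − π) e^{−λ} λ^k / k!  (k ≥ 1),

fitted by EM: π absorbs the excess of empty windows (unmappable or
fragment-free genome) that would otherwise bias λ downward. Enrichment is
tested per window with a **Bayes factor** against a Poisson alternative
whose mean carries a Gamma(α, β) prior — the marginal under H1 is then a
closed-form negative binomial:

    BF(k) = NB(k | α, β/(β+1)) / ZIP(k | π, λ),   with α = 2, β = α/(f·λ̂), f = 5.

Windows with BF above the cutoff (default 1000, "decisive" evidence —
appropriate when 10^5–10^6 windows are scanned) are merged into MHSs;
within each MHS a **locally refitted ZIP** on per-bp midpoint counts sets
the threshold that resolves narrow sub-peaks (protein footprints, tens of
bp). Downstream modules implement overlap-rate matrices, the
specific/common (sMHS/cMHS) split, genomic-feature categories,
cognate-gene assignment, k-means chromatin classing with TWSS model
selection, a sliding-window methylated-region caller (CG > 60%,
CHG > 20%, CHH > 5%; 5-cytosine windows, ≥ 4 methylated), motif
positional profiles (±150 bp) and tissue-specificity entropy.

A seeded simulator (`mhscan.simulate`) generates every input with planted
ground truth: two site classes (wide, two-summit "common" sites with
phased flanking nucleosomes vs narrow, single-summit "specific" sites),
fragments enriched `enrichment_fold`-fold inside sites, five-class
epigenetic mark tracks, a methylome with planted methylated blocks, plus
assay peaks, genes, TEs and motif occurrences.

## Worked example

```bash
mhscan simulate --seed 1 --outdir sim --genome-size 1000000 \
    --n-common 50 --n-specific 50 --n-fragments 200000
mhscan call --fragments sim/fragments.tsv --genome sim/genome.chrom.sizes --out out/run
```

prints

```
simulated 100 sites, 200000 fragments -> sim
100 MHSs, 150 sub-peaks; background pi=0.304 lam=1.802; FRiP=0.669
```

— the fitted background says 30% of windows are structurally empty
(matching the simulated unmappable fraction) with λ ≈ 1.8 fragments per
20-bp window elsewhere; all 100 planted sites are recovered with 150
sub-peaks (one per narrow site, two per wide site), and two thirds of
fragments fall inside called sites (FRiP), as expected for a strongly
enriched library. The same pipeline from Python, with evaluation against
the planted truth:

```python
python examples/01_simulate_and_call.py
# fragments: 200000 simulated, 186337 retained
# background ZIP: pi=0.304 (zero inflation), lambda=1.802 fragments per 20-bp window
# called 100 MHSs, FRiP=0.669
# recall=1.000 precision=1.000 vs the 100 planted sites
# sub-peaks: 150 total, mean length 44 bp
```

The other `examples/` scripts walk through classification and annotation
(`02`), chromatin-state clustering (`03`), methylated regions (`04`) and
motif positional bias (`05`).

## Layout

- `src/mhscan/` — `intervals` (coordinate types), `io` (BED/bedGraph/
  GFF3/CX readers and writers), `fragments` (filtering, coverage),
  `caller` (ZIP + Bayes-factor MHS caller), `annotate` (overlaps,
  classes, categories, quantification), `profiles` (binned profiles,
  k-means/TWSS), `methylation`, `motifs`, `simulate`, `cli`.
- `docs/methods.md` — models, parameter choices, numerical details and
  limitations.
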