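# Methods

## Problem setting

Light MNase digestion of crosslinked chromatin releases short (20–100 bp)
DNA fragments from accessible, protein-bound regions; sequencing them
gives a genome-wide readout of open chromatin at sub-nucleosomal
resolution, including a class of condensed, repressive-mark-associated
sites that nuclease/transposase assays (DNase-seq, ATAC-seq) miss. The
package detects these MNase hypersensitive sites (MHSs) and implements
the descriptive analyses used to characterise them.

All coordinates are 0-based half-open internally (BED convention); GFF3
is converted on read. Fragment retention requires mapping quality
strictly greater than 10 and a full-length alignment, operationalised as
no soft/hard clipping (`aligned_fraction == 1`). Fragments are reduced
to midpoints for counting, which avoids double counting across
overlapping windows and preserves footprint-scale resolution.

## Background model and fitting

Window counts (window 20 bp, step 10 bp) are modelled as zero-inflated
Poisson. The zero-inflation weight π captures structural zeros —
unmappable or biologically empty stretches — so that the Poisson rate λ
reflects the mappable background. The EM fit treats "this zero is
structural" as the latent variable and runs on the count histogram
(cost O(max count) per iteration); the observed-data log-likelihood is
non-decreasing by construction and iteration stops when the improvement
falls below `tol` (default 1e-6) or at `max_iter` (500). Moment
estimates initialise (π, λ); an all-zero input raises a degenerate-model
error rather than returning an arbitrary fit. The background is fitted
on all windows after discarding the top 0.1% of counts (which are
dominated by true sites), and refitted once with windows inside
provisional calls excluded — standard two-pass background refinement.

## Enrichment test

H0 is the fitted ZIP. H1 is a Poisson window count with a
Gamma(shape, rate) prior on its mean; conjugacy gives the closed-form
negative-binomial marginal, so BF(k) is evaluated exactly (in log space;
an underflowing H0 mass yields +inf with a flag, not an exception).
Defaults: shape 2, prior mean 5·λ̂.

The Bayes-factor cutoff defaults to 1000, "decisive" on the Jeffreys
scale. The choice is deliberate: a genome scan tests 10^5–10^6 windows,
and at a cutoff of 10 ("strong" for a single pre-specified region) the
count threshold lands where the null tail probability is still ~10^-2 —
at typical backgrounds (λ ≈ 1.8) this produces on the order of ten
spurious merged regions per megabase. At 1000 the implied per-window
null exceedance is ~10^-6 and the called set stays clean without
affecting recall, since genuine sites sit far above any reasonable
cutoff. The cutoff is exposed (`--bf-cutoff`) for single-locus use.

Significant windows merge across gaps ≤ 30 bp; merged regions shorter
than 40 bp are discarded, so an isolated significant window never
survives alone. Ties at the cutoff are inclusive (BF ≥ cutoff). The
caller is deterministic given its input.

## Sub-peaks

Within each MHS ± 200 bp of context, per-bp fragment-midpoint counts are
fitted with a local ZIP; the sub-peak threshold is the smallest t whose
upper-tail probability under that local model is below
`subpeak_tail_prob` (default 0.01). Contiguous runs at or above t inside
the MHS become sub-peaks, after bridging gaps ≤ 15 bp and dropping runs
shorter than 10 bp (single-bp noise dips and slivers are not footprints);
if nothing clears the threshold the maximal run is kept, so every MHS
retains at least one sub-peak. Midpoint counts, not full-fragment
coverage, drive this stage: 20–100 bp fragments smear coverage by up to
±50 bp, which would fuse the ~40–50 bp footprints the method is meant to
resolve. On simulated data sub-peak lengths average ~44 bp.

## Downstream analyses

- **Overlap rates** are one-directional: the percentage of row-set
  intervals overlapping ≥ 1 bp (BEDTools-default semantics; the minimum
  overlap is configurable) of the column set.
- **Specific vs common sites**: a site overlapping any other assay's
  peaks is common (cMHS), otherwise specific (sMHS). When signal tracks
  are supplied, a nominal cMHS whose mean coverage is below the
  genome-wide quantile (default median) in every track is demoted to
  sMHS; demotion is one-directional by design.
- **Feature categories** partition sites with explicit precedence: gene
  overlap → proximal TSS/TTS (≤ 1 kb, nearer end wins, TSS on ties) →
  near-gene (≤ 3 kb) → transposable element (hence ≥ 3 kb from genes) →
  intergenic.
- **Cognate genes**: nearest gene within 1 kb either side (distance 0
  when overlapping), ties to the smaller start; no strand requirement,
  as regulatory elements act in both orientations.
- **Quantification**: peak level = fragments overlapping the peak per
  million fragments; comparisons use Spearman's rank correlation.
  Tissue specificity is Shannon entropy of the normalised expression
  profile (bits); a single-tissue gene scores 0, uniform expression over
  T tissues scores log2 T.
- **Profiles and chromatin classes**: signal over ± 1 kb of site
  midpoints is averaged into bins (10 bp for aggregate profiles, 40 bins
  for heatmaps); sites whose window crosses a chromosome end are dropped
  with a count, avoiding edge bias. Each mark's site × bin matrix is
  min-max scaled as a whole (per dataset, preserving cross-site
  contrast), the marks' matrices are concatenated, and k-means
  (Lloyd's, k-means++, best of 10 restarts, seeded) clusters the rows.

### Choosing k

The TWSS curve is computed for k = 2..16. Each k is additionally warm
started from the previous solution's centroids plus the worst-fit point,
which guarantees a non-increasing curve. "The smallest k past which the
curve flattens" is formalised by default as the knee criterion — the k
whose point lies farthest below the chord joining the curve's endpoints
(parameter-free, robust to how low the within-class noise floor is). A
relative-drop rule (smallest k with (TWSS(k) − TWSS(k+1))/TWSS(k) below
a threshold) is available as `method="rel_drop"`; note its threshold
interacts with noise level — on low-noise data even the split past the
true k can shave more than 10% of TWSS, which is why it is not the
default.

## Methylated regions

Per-cytosine calls use strict thresholds (level > 0.60/0.20/0.05 for
CG/CHG/CHH; configurable to ≥) at a minimum depth of 4 reads (sites
below depth are no-calls and excluded before windowing; this default
guards against 1-read artefacts — the convention is common WGBS
practice). Windows of 5 consecutive same-context callable cytosines
slide one cytosine at a time; windows with fewer than 4 methylated
cytosines are discarded. A window's genomic extent is [first cytosine,
last cytosine + 1); its mean level is recorded as an annotation and
never used as a filter. Retained windows merge per context when
overlapping or touching, then the three contexts are unioned; union
regions are labelled by their contributing contexts and carry
cytosine-count-weighted mean levels. For CG symmetry a documented
pre-step can pool minus-strand counts onto the plus-strand partner.

## Motif positional bias

An occurrence maps to the offset of its midpoint from a site's midpoint;
the profile value at offset d is the fraction of sites with ≥ 1
occurrence at d within ± 150 bp. The denominator is all sites in the
set, so profiles are probabilities. An 11-bp moving average is applied
for display only. The TF-family table reports, per family, the
percentage of common and of specific sites containing the family and
their difference (positive = common-enriched); it is antisymmetric under
swapping the classes.

## The simulator

The generator emulates the study conditions end to end and writes every
input in the formats the pipeline reads, so tests exercise the parsers
too. Defaults: a 5-Mb single-chromosome genome; 250 wide "common" sites
(mean 262 bp, two fragment summits, phased flanking nucleosomes with a
180-bp period) and 250 narrow "specific" sites (mean 85 bp, one central
summit), all gaps ≥ 2 kb; 10^6 fragments of 20–100 bp whose midpoint
density inside sites is 80× the mappable background — chosen so that
roughly 60% of fragments fall in sites, the fraction-of-reads-in-peaks
of a good library; 30% of the genome unmappable in 1-kb blocks, the
source of window-level zero inflation. Within-site placement is
triangular around each summit, giving the caller a realistic
unimodal/bimodal surface. Mark tracks follow five chromatin-class
templates (repressive H3K27me3; methylated flanks; two asymmetric
active classes with H3K27ac/H2A.Z; quiescent) with class frequencies of
26/18/9/9/38% at specific and 6/5/30/29/30% at common sites, so specific
sites are biased toward the repressive classes. The methylome plants
blocks with per-context levels (0.90/0.60/0.30) above the calling
thresholds on a sub-threshold background (0.05/0.04/0.01), binomial
counts at depth 20. Auxiliary annotations (DHS/ATAC peaks visible only
at common sites, genes near sites, TEs in deserts, class-specific motif
occurrences, expression tables) make every downstream module exercisable
with known truth. All randomness flows from NumPy's seeded PCG64
generator in independent named streams, so outputs are reproducible
across platforms.

What the simulator does *not* emulate: sequence content (no FASTA/FASTQ,
no MNase sequence bias), alignment artefacts beyond a scalar
mapq/clipping flag, replicate structure, copy-number variation, or
overlapping/nested regulatory elements. Passing the planted-recovery
tests therefore demonstrates correctness of the statistical machinery
under the stated generative model, not performance on real libraries,
where background is autocorrelated and enrichment varies continuously.

## Problem sizes used in tests

The unit suite runs on a 1-Mb two-chromosome genome with 100 sites and
2×10^5 fragments; the acceptance checks rerun the caller at the full
default scale (5 Mb, 500 sites, 10^6 fragments), the null calibration at
10^6 windows, and the clustering benchmark on 300 sites × 160 features.

## Known limitations

- The caller assumes a globally homogeneous background (per-chromosome
  fitting is available by fitting per chromosome); locally varying
  accessibility backgrounds are only partially absorbed by π.
- Fragments are single-end extents; paired-end template reconstruction
  is supported only through the optional BAM reader.
- The motif module consumes occurrence calls from an external scanner;
  it does not scan PWMs or correct for sequence composition.
- FRiP is reported as a QC metric only; it plays no role in calling.
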