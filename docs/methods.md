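# Methods

This note documents the models, parameter choices and numerical decisions
behind `homeox`, and what the synthetic experiments do and do not
demonstrate about real data.

## Cohort model and coordinates

The unit of analysis is a cross between two homozygous parents with twelve
F1 sister plants.  The maternal parent is the reference genotype (all SV
loci homozygous reference), the paternal parent carries the alternate
allele at every retained SV locus, so F1s are expected to be uniformly
heterozygous; any other F1 allele class is a candidate non-Mendelian
signal.  All internal coordinates are 0-based half-open; the 1-based
conventions of VCF and GFF3 are converted exactly once, at the format
boundary in `homeox.io`.

## SV filter cascade

Nine per-record predicates (type, length bounds, support, precision,
resolved insertion length, paternal genotype, missingness, allele-support
fractions) applied in a fixed order.  Because every stage is a pure
per-record predicate, the surviving set is invariant to stage order; the
order only attributes exclusion reasons, and a `FilterReport` logs
in/out counts per stage.  Notable choices:

* **Support (stage 3).**  "Supported by ≥ 25 reads" is interpreted as the
  variant caller's *discovery* threshold: at least one sample must carry
  ≥ 25 reads on its called allele (`support_mode="any"`).  A per-sample
  requirement would be unsatisfiable for heterozygotes at ~40× coverage,
  where the ALT support of a true het is Binomial(≈40, 0.5) and falls below
  25 most of the time.  Since retained records require a paternal
  homozygous-alternate call (~39 ALT reads at 40×), the discovery sample in
  practice is the paternal parent.  `support_mode="all"` restores the
  strict reading.
* **Heterozygote allele support.**  The ≥ 90 % rule is ill-posed for hets;
  they are instead required to have an ALT fraction inside a symmetric
  window [0.25, 0.75], which rejects allele-imbalanced miscalls while
  keeping true heterozygotes.
* **Boundaries.**  "Longer than 30 bp" and "smaller than 50 kbp" are
  strict inequalities; both are configurable.
* **Miscalled alleles** are implemented as missing genotypes only.

`divergent_among_f1` then keeps records whose F1 allele-class multiset has
≥ 2 distinct values and flags the samples deviating from the F1 majority
(ties broken toward HET, the Mendelian expectation).

## Large rearrangement detection

A deletion of the paternal haplotype leaves a joint footprint: ~0.5× depth
and homozygous-reference divergent SVs in the carrier.  Detection runs per
F1 sample:

1. **Window scan.**  Fixed windows (1 Mbp at full scale, 0.25 Mbp in the
   1:4 desk-scale configuration) combine width-weighted mean depth with
   the sample's allele-class counts among divergent SVs.  A window
   qualifies when it has no heterozygous divergent SV, at least one
   informative homozygous-reference divergent SV (`min_informative=1`,
   preventing SV deserts from qualifying vacuously), and mean depth
   ≤ `half_factor` × chromosome mean.  `half_factor` is 0.6 rather than
   0.5 because observed segment/chromosome coverage ratios of real events
   scatter up to ~0.59.  Chromosome means exclude bins above a 150×
   outlier cap.  Maximal runs of qualifying windows (≥ 1 window) become
   candidates; the final length requirement is applied to the *refined*
   interval, because the window grid truncates events ending mid-window
   (a 1.2 Mbp event covers only one full 1 Mbp window).
2. **Boundary refinement.**  On the fine-binned track (bins ≤ 10 kb) a
   centred moving mean over `smooth_k = 5` bins is thresholded at
   `refine_factor = 0.75` × chromosome mean — the midpoint between the
   deleted (0.5×) and normal (1×) levels.  With overdispersed bin depths
   (variance ≈ 2 × mean) the midpoint sits > 2.5 smoothed-SDs from both
   levels, whereas reusing the 0.6 window threshold would sit ~1.4 SDs
   above the deleted level and fragment the qualifying run.  Qualifying
   runs shorter than `persist_k = 3` bins are noise; interior gaps of at
   most `gap_k` bins (default `smooth_k`, since one outlier raw bin
   contaminates up to `smooth_k` smoothed bins) are bridged.  The run
   overlapping the candidate most is selected, and its ends are shifted by
   the analytical smoothing offset at a 0.5× step,
   2k(1−t) − (k+1)/2 bins (zero at the default t = 0.75).  Refinement is
   idempotent; a candidate with no sub-threshold run raises a refinement
   error and is logged.  Refined intervals from split candidates that
   overlap are merged; final calls require refined length strictly above
   `min_event_len`.
3. **Location.**  The centromere is the densest satellite-repeat cluster
   (largest run of hits with inter-hit gaps < 500 kb), widened to the
   nearest flanking scaffold breakpoints.  A call is telomeric when it
   starts or ends within 10 % of the chromosome length of either end
   (telomeric wins ties), pericentromeric within `pericen_dist` (2 Mbp
   full scale) of the centromere interval, otherwise interstitial.

## Homoeologous exchange calling

* **Pair selection.**  Candidate homoeologous gene pairs below similarity
  70 are dropped; remaining rows are consumed in order of descending
  similarity with ties broken by input order (first reported pair wins),
  each gene joining at most one pair.
* **Depth segmentation.**  Per sample and chromosome, bins above 150× are
  discarded from the mean/SD; retained bins at ≤ μ − σ (DEL) or ≥ μ + σ
  (DUP) are labelled, adjacent same-label bins merge with zero gap
  tolerance, and merged segments ≥ 25 kb survive.  A constant track
  (σ = 0) yields nothing.  Statistics are always per chromosome per
  sample, never pooled.
* **Matching.**  For each same-sample (DEL, DUP) pair on homoeologous
  partner chromosomes, supporting evidence is the set of selected gene
  pairs with one gene inside the deletion and its partner inside the
  duplication (≥ 50 % of the gene body; strict containment would be
  fragile at refined boundaries).  Each DEL joins at most one DUP — most
  supporting pairs, ties by overlap mass — and one pair suffices
  (`min_pairs = 1`, exposed).
* **Duplication extent.**  Re-binned at 100 kbp with a 100× cap, the
  refined extent is the maximal run of bins satisfying *both* depth
  ≥ 1.25 × μ and depth ≥ μ + σ (the two conditions are conjunctive),
  choosing the run overlapping the matched segment; if nothing qualifies
  the raw segment is kept and flagged unverified.
* **Linkage.**  μ ± σ segmentation inevitably produces occasional ~30 kb
  noise segments, and a noise DUP can share a single gene pair with a
  genuine large deletion.  A large rearrangement call is therefore
  labelled NRHE only when a same-sample exchange whose duplication passed
  the 100 kbp verification overlaps it; otherwise it stays a segmental
  deletion.  Raw exchange matches that touch no large call are reported
  but not propagated.

## Methylation

Per-cytosine observations (reads supporting methylation / total reads,
per CpG/CHG/CHH context) are handled as DataFrames for throughput.
1 kbp bins accumulate covered-cytosine counts and summed reads; the bin
proportion is undefined (NaN) without reads.  A cytosine counts as
"methylated" when its frequency exceeds 0.5 at ≥ 4× site coverage (the
threshold is exposed; no canonical value exists).

Differential calls use the two-proportion score test with pooled
p̂ = (m₁+m₂)/(n₁+n₂); its square equals the Pearson χ² statistic of the
2×2 table without continuity correction (verified to 1e-9 in tests).  A
degenerate pooled proportion gives z = 0, p = 1.  Bins qualify with ≥ 4
cytosines on both sides, |Δ| ≥ 0.4 and raw p < 0.01 — no multiplicity
correction by default, matching the stated operating point; a
Benjamini–Hochberg mode exists but is off.  `min_gap = 0` merges only
directly abutting significant bins of the same direction.  Coverage is
required pairwise (tested sample and control), not cohort-wide.  DMR
annotation flags exon, intron (gene minus exons), repeat and promoter
overlaps — promoters are 1 kbp strand-aware upstream windows clipped to
the chromosome — plus the distance to the nearest gene body (0 when
overlapping).

## Synthetic data generator

The generator emulates the study conditions at a 1:4 desk scale: eight
chromosomes of 5.6–15 Mbp across both subgenomes, 40× mean depth (the
emulated study reports ≈ 42×), 3000 SV loci on a jittered grid, 97 %
allele purity for homozygous calls, balanced hets, colinear homoeologous
gene pairs every 20 kb with similarities uniform on [60, 100], a
centromeric satellite array per chromosome with flanking scaffold
breakpoints, and methylation levels CpG 0.6 / CHG 0.35 / CHH 0.10 with
CHH sites most numerous (site densities 3/2/6 per kb; genome-wide plant
cytosine densities are far higher, this is a deliberate desk-scale
reduction).

* **Depth** is negative binomial per bin with size = mean by default
  (variance = 2 × mean): long-read depth is overdispersed, and this makes
  SD-threshold segmentation non-trivial.  Deletions multiply the local
  mean by 0.5 (the deleted haplotype is always paternal, matching the
  observed pattern), duplications by 1.5; whole-chromosome copy factors
  can emulate aneuploid parents, though meiotic behaviour of aneuploid
  chromosomes is not modelled.
* **Genotypes** are assigned by construction (truth), with read supports
  drawn binomially around the class-expected fraction at the local
  depth; the generator does not model genotyping error beyond sampling
  noise, so the Mendelian-null experiments measure the pipeline's
  false-call behaviour under sampling noise only, not caller artefacts.
* **Methylation** draws one latent level per cytosine from a Beta around
  the context mean (concentration 20) *shared across samples* — the
  level is a property of the locus — with per-sample binomial read
  sampling.  This is what makes the score test's null calibration
  meaningful; independent per-sample levels would build biological
  overdispersion into the null and no raw-p test would be calibrated
  against it.  Planted DMRs shift the carrier's latent level by Δ,
  clipped to [0, 1].  Deletions halve per-site read totals but leave
  levels unchanged, reproducing the count-down/level-stable signature of
  real deleted segments.
* The default planted events are the five published rearrangements at
  1:4 coordinates, with NRHE duplications placed at the colinear position
  on the homoeologous partner chromosome (the published table does not
  print duplication coordinates).

No read-level data (FASTQ/BAM) and no sequence content are simulated;
mapping artefacts, repeat-driven coverage structure and breakpoint
micro-homology are therefore outside what the synthetic experiments can
validate.

## Problem sizes and determinism

Synthetic experiments use the scaled geometry throughout: a full cohort
simulation plus detection takes ~0.3 s, so the 20-seed sweeps (event
recovery, boundary recovery, Mendelian null, segmentation oracle with 500
random tracks, type-I calibration over ~14.5k testable CpG bins on three
chromosomes) complete in seconds.  All outputs are pure functions of
(config, events, seed); `run_all` writes byte-identical artefacts for a
fixed seed, and the JSON manifest (versions, seed, parameters, per-stage
counts, relative artefact paths) suffices to re-run any stage in
isolation.

## Known limitations

* The exchange caller distinguishes reciprocal from non-reciprocal
  exchanges only through depth asymmetry; a perfectly reciprocal exchange
  leaves depth flat and is invisible here.
* Breakpoints are resolved to bin resolution (10 kb fine bins, 100 kbp
  duplication bins), not to sequence level.
* The ortholog filter and gene tallies operate on supplied tables and
  annotations; alignment itself (BLAST/inparanoid) is out of scope, as
  are GO enrichment and TE family classification.
* With `support_mode="all"` and realistic coverage the cascade rejects
  essentially all heterozygous records (see above); the mode exists for
  strictness experiments, not as a recommended setting.
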