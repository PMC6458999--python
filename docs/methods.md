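# Methods

This note documents the models, defaults and numerical choices behind
`pasfactory`, and what the synthetic-data results do and do not demonstrate.

## Coordinates and annotation

All internal coordinates are 0-based, half-open (BED convention); GTF input
is converted on read. Multi-isoform annotations are collapsed to one union
span per `gene_id` — every analysis here is gene-level. "Same-strand
overlap" in the analysis-set filter is evaluated on gene spans, not exons:
span overlap is the conservative choice for assigning strand-specific 3′-end
signal, which is the purpose of the filter. The downstream-spacing statistic
measures, from a gene's 3′ end in its direction of transcription, the
distance to the nearest TSS *or* 3′ end of any other gene on either strand;
an overlapping end gives distance 0 and an empty downstream gives infinity.

## Internal-priming mask

Plus-strand rules: mask every maximal run of ≥ 6 consecutive `A`, and every
10-nt window containing strictly more than 6 `A`; minus strand uses `T`.
Whitelisted 3′ ends (annotated gene ends, optionally a validated-PAS BED)
carve 20-nt unmask holes, strand-specifically, centred on the end position.
Both rules are implemented with vectorized run/window scans and are checked
exactly against an independent regex-plus-window-count scanner in the tests.

## PAS calling

Per-sample 3′-end tracks are scaled to counts per 10⁶ retained reads and
summed per strand across all samples. The genome is tiled into
non-overlapping 30-nt windows phased at coordinate 0 (a tiling, rather than
a sliding window, is what makes "merging adjacent kept windows" well
defined). Windows with summed signal **strictly** above 30 are merged when
adjacent; within each merged interval all plateau-resolved local maxima
(plateau ties break to the 5′-most position in the direction of
transcription) seed 30-nt intervals centred on the maxima. One further
recentre-and-deduplicate pass follows; any residual overlap is resolved by
keeping the higher-total-signal interval. The threshold applies to the
depth-normalized summed signal, so calling is invariant to adding empty
samples and to common rescaling.

Quantification counts raw (non-normalized) reads per PAS per sample.
A PAS joins the gene whose span extended 6 kb downstream contains its
summit (ties → nearer annotated 3′ end); unassigned PAS are kept as
orphans. Alongside mask-removed counts the matrix carries a per-sample
*background* tally (retained reads outside every called PAS) so that

    in-PAS + background + mask-removed = total reduced reads

holds exactly — without the background term the identity could not hold,
since sub-threshold scattered reads belong to no PAS.

## Differential PAS usage

For gene *g* with PAS counts `y_ij` and totals `n_i`, each PAS is tested
with a beta-binomial likelihood-ratio test: a single usage proportion under
the null versus one proportion per condition under the alternative, the
statistic referred to χ²(1). The overdispersion ρ is shared within a gene
and estimated by the method of moments on within-condition Pearson
residuals. Two corrections matter at 4 + 4 replicates:

* summed residuals against an estimated proportion lose one degree of
  freedom per condition, so the residual sum is scaled by 1/(m−1), not 1/m —
  without this ρ is biased low and the test anticonservative;
* per-gene estimates rest on few degrees of freedom, so they are shrunk
  toward the across-gene median with a prior weight of 20 effective dof.

With both, the raw type-I error at 0.05 is ≈ 0.06 on null simulations and
the BH-adjusted rate is far below nominal. Genes with a zero total in
either condition are flagged untestable and excluded from BH, which runs
across all tested PAS.

## Shift classification

Genes with no PAS at padj < 0.05 are *no shift*; single-PAS genes are their
own category. Otherwise the two most significant PAS are taken (padj ties
break to the larger absolute usage change); if only one PAS is significant
it is paired with the most-used other PAS on pooled control counts. The
pair is ordered proximal/distal along transcription and the distal/proximal
pooled-count ratio is compared between conditions: higher in treated →
distal, otherwise proximal. A zero proximal pool takes a +0.5 continuity
correction and is flagged. Because only the selected pair's counts enter
the ratio, the call is invariant to perturbing other PAS, and permuting the
condition labels swaps distal ↔ proximal exactly.

## Differential expression

Gene counts are PAS sums over the extended span. Size factors are
median-of-ratios over genes with all-nonzero counts; dispersions are moment
estimates from within-condition variances, shrunk halfway toward a fitted
`a₀ + a₁/mean` trend and floored at 1e-8; the Wald test comes from a
log-link negative-binomial fit (statsmodels GLM) of the condition indicator
with log-size-factor offsets. All-zero genes are excluded; BH runs across
genes.

## Attenuation

The gene universe is the analysis set restricted to protein-coding genes
longer than 5 kb. Gates:

* **upregulated** — log2FC > 0 and DE padj < 0.05;
* **premature termination** — control/treated mean depth-normalized
  nascent signal over the first 20 of 25 equal gene-body bins (5′→3′,
  TSS to the maximum-signal PAS) exceeds 2; an exactly zero treated mean
  gives an infinite, flagged ratio;
* **premature CPA** — some PAS other than the gene's major PAS (strongest
  pooled-control PAS) has usage padj < 0.1 *and* a decreased usage
  fraction. The decrease is required on the usage fraction, not the raw
  count, so that overall upregulation cannot mask a genuine PAS collapse.

Attenuated = upregulated ∧ (termination ∨ CPA); the reported counts always
satisfy |termination| + |CPA| − |overlap| = |attenuated|. The fold-change
variant replaces the CPA significance gate with a ≥ 2-fold drop in mean
depth-normalized PAS signal (+0.5 continuity at zero treated means); note
that for a strongly upregulated gene a usage collapse may not translate
into a count drop, so the two gates are not ordered in general — the
variant is the more sensitive gate at equal planted *count* effects, which
is the regime it exists for.

## Major-PAS grouping and termination windows

Grouping uses pooled depth-normalized counts over all samples: the two
strongest PAS are kept when within 2-fold of each other and ≥ 2 kb apart
(summit distance); the more 5′ of the pair is PAS1, and PAS1 > PAS2 →
proximal-major, PAS1 ≤ PAS2 (ties included) → distal-major.

Termination profiles are 50-bp binned signal from the gene's effective 3′
end (maximum-signal PAS summit) to +10 kb, strand-aware; the argmax offset
is the peak bin's start offset, so a monotone-decreasing profile reports 0
and an all-zero window reports no peak. Windows truncated by a chromosome
edge are NaN-padded and flagged. Composite (across-gene mean) profiles are
the robust statistic: on the toy chromosome, individual 10-kb windows can
reach a neighbouring gene (gaps are 7–12 kb), and a peak planted on a bin
edge splits its mass between two bins, so peak-location checks use the
composite with a ±3-bin allowance.

## ChIP calibration and region calling

Spike-in calibration scales a track by 10⁶ / spike-in reads. With a fixed
exogenous chromatin admixture per unit of target chromatin, spike reads
measure sequencing depth per chromatin unit, so genuine global occupancy
shifts survive calibration while depth-only scaling (10⁶ / total reads)
cancels them; the simulation plants a 2-fold global IP loss at constant
spike fraction and recovers 2.0 ± a few % calibrated versus ≈ 1 depth-only.

The region caller works on 50-bp bins of raw IP counts: the input is scaled
to IP depth and each bin's Poisson rate is the maximum of the scaled input
in the bin, its 5-kb and 10-kb window means, and the genome-wide mean (the
local-maximum guard prevents rate underestimation); upper-tail p-values are
BH-adjusted over all bins, q < 0.01 bins merge across ≤ 1-kb gaps. It is a
broad-peak caller of the same model class as the standard tools, and an
adapter ingests externally produced narrowPeak/broadPeak files so an
external caller can substitute. Only the intersection of two antibodies'
region sets counts as enriched; intersection output is merged and therefore
commutative and idempotent. Gene classes: *three_prime* when a region
overlaps PAS −2 kb..+5 kb (strand-aware), regardless of any TSS signal;
otherwise *tss_gene_body* if the body (TSS→PAS) or PAS..+5 kb window
overlaps; otherwise *not_enriched*.

## Metagene

Composite rows concatenate 50-bp means over TSS −5 kb..+1.5 kb (130 bins),
gene-body bins 4–22 inclusive of 25 equal bins (19), and PAS −1.5 kb..+10 kb
(230): 379 columns, minus-strand genes reversed so columns always run 5′→3′.
Replicate tracks are averaged; windows beyond chromosome edges are NaN and
excluded from column means; heatmap rows sort by descending mean. Binned
tracks are expanded to per-base means first, which makes calibration and
metagene assembly commute to machine precision.

## Synthetic study conditions

Defaults (one toy chromosome, all stages sub-minute): 200 genes of 6–30 kb
on 6.5 Mb with 7–12-kb gaps (so every gene meets the 6-kb isolation
criterion by construction); 1–3 PAS per gene with ≥ 2.5-kb spacing (so
major-PAS grouping is exercisable); two conditions × 4 replicates; gene
expression lognormal around 500 reads/replicate (σ = 0.3); NB dispersion
0.05; library factors 0.8–1.25; ±5-nt 3′-end jitter; 2% uniform gene-body
background. Planted effects: 30 distal usage shifts of Δ = 0.3; 30
attenuated genes (mechanisms split termination / CPA / both) with 2.5-fold
upregulation, a control-only intragenic termination peak sized for an
expected body-signal ratio of 3, and a 4-fold usage collapse of a prominent
(35%) but non-major premature PAS; 10 + 10 plain DE genes at 4-fold.
Decoys: Poisson(0.5) 8-nt A-runs per gene body, ≥ 600 bp from any PAS,
fed with reads at 15% of gene expression; the background genome is scrubbed
so decoys are the only maskable loci, making mask efficacy exactly
scoreable. ChIP: Poisson background 10/bin, 10-fold enrichment over 2-kb
blocks, 12–30 shared plus 5–10 antibody-unique regions, 5% spike fraction.

The intragenic termination peak is centred midway between the TSS and the
gene's most 5′ PAS. That placement keeps it inside the measured gene body
whichever PAS ends up carrying the maximum signal — the analysis body ends
at the maximum-signal PAS, which is often proximal.

What the generator does **not** emulate: sequencing error, mappability and
GC structure, overlapping or nested genes, isoform-level complexity,
unannotated background transcription, and batch effects. Passing recovery
tests here therefore demonstrates the correctness of the pipeline logic and
the calibration of its statistics under the stated noise model, not
performance on real libraries.

## Problem sizes

The test suite and the acceptance script run the full 200-gene pipeline
once per seed (~40 s), matrix-level null simulations with 1000–2000 PAS for
error control, 50 × 100-kb sequences for mask equivalence, and 100-kb-bin
noise genomes for the region-caller FDR — sizes chosen so every property is
measured with useful Monte-Carlo precision in minutes on one core.
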