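# pasfactory

Tools for quantifying how transcription ends: polyadenylation-site (PAS)
calling from 3′ mRNA-seq read ends with internal-priming filtering,
alternative-polyadenylation (APA) shift classification, detection of genes
attenuated by premature cleavage/polyadenylation (CPA) or premature
termination, spike-in-calibrated ChIP enrichment with dual-antibody
intersection, and composite metagene profiling — all exercisable end-to-end
on synthetic data with a planted ground-truth ledger.

The package is aimed at people analysing 3′-end sequencing (QuantSeq-style),
nascent-transcription (mNET-seq-like) and calibrated ChIP-seq data around
the question of where genes terminate and how termination-factor depletion
shifts PAS choice.

## The analyses

**PAS calling.** Oligo(dT)-primed 3′-end protocols misprime on genomic
poly(A), so a strand-specific mask is built first: every run of ≥ 6
consecutive A and every 10-nt window with more than 6 A (T on the minus
strand), minus 20-nt unmask windows centred on annotated/validated 3′ ends.
Read 3′-terminal nucleotides falling in the mask are removed. Depth-scaled
end densities summed over all samples are tiled into 30-nt windows; windows
with summed signal strictly above 30 are merged, local maxima seed 30-nt
intervals centred on the maxima, and one recentre-and-deduplicate pass gives
a non-overlapping PAS set. Each PAS is assigned to the gene whose span,
extended 6 kb downstream, contains its summit.

**APA and DE statistics.** Per-PAS differential usage is a beta-binomial
likelihood-ratio test of PAS count against gene-total count with a
condition-dependent usage proportion and a per-gene moment-estimated,
shrinkage-moderated overdispersion (BH-adjusted across PAS). Genes with a
significantly changed PAS are classified by the distal/proximal usage ratio:
higher in treated → *distal* shift, lower → *proximal*. Gene-level DE uses
PAS-summed counts, median-of-ratios size factors and a negative-binomial
Wald test with trend-shrunk dispersion.

**Attenuation.** A gene is called attenuated when it is significantly
upregulated on depletion (padj < 0.05, log2FC > 0) *and* either its mean
intragenic nascent signal (first 20 of 25 gene-body bins) drops more than
2-fold, or a non-major PAS decreases significantly (padj < 0.1). A
fold-change variant replaces the per-PAS significance gate with a ≥ 2-fold
mean signal drop for high-variability datasets.

**Signal tracks.** ChIP tracks are calibrated by exogenous spike-in reads
(signal per million spike-in reads), which preserves global occupancy
changes that depth normalization cancels. Enriched regions come from a
Poisson local-background bin test (BH, q < 0.01, 1-kb gap merging); only the
base-pair intersection of two independent antibodies' region sets counts as
enriched, and genes are classed as 3′-enriched (region within PAS −2 kb..+5 kb)
or TSS/gene-body enriched. Metagene profiles concatenate 50-bp bins over
TSS −5 kb..+1.5 kb, gene-body bins 4–22 of 25, and PAS −1.5 kb..+10 kb
(379 columns), strand-reversed for minus-strand genes.

**Synthetic data.** `pasfactory.synthetic` builds a ~6.5-Mb toy chromosome
(200 genes, 1–3 PAS each) with planted A-rich decoys, negative-binomial
replicate counts, usage shifts, attenuated genes and dual-antibody enriched
regions, recording everything in a `TruthLedger` so recovery and error
control are scored exactly.

## Worked example

```python
from pasfactory.pipeline import RunConfig, run_pipeline
res = run_pipeline(RunConfig(seed=1))
print(res.summary())
```

prints (seed 1):

```
{'genes_annotated': 200, 'genes_analysis_set': 200, 'pas_called': 431,
 'apa': {'no_shift': 98, 'single_pas': 52, 'distal': 50},
 'de_significant': 54,
 'attenuation': {'attenuated': 30, 'premature_termination': 20,
                 'premature_cpa': 19, 'overlap': 9},
 'major_pas': {'excluded': 89, 'major_proximal': 65, 'major_distal': 46}}
```

All 200 genes pass the analysis-set criteria (≥ 1 active PAS, no same-strand
overlap, 3′ end isolated by ≥ 6 kb) because the generator places genes with
≥ 7-kb gaps. 431 PAS are called for 406 planted; the 50 distal-shift calls
comprise the 30 planted usage shifts plus attenuated genes whose premature
(proximal) PAS collapses — itself a distal shift. The attenuation table
satisfies |termination| + |CPA| − |overlap| = |attenuated| (20 + 19 − 9 = 30),
and all 30 planted attenuated genes are recovered with no false positives.

The numbered drivers under `analysis/` rerun each stage with a narrative and
write their tables to `results/`:

```
python analysis/01_simulate_and_mask.py
python analysis/02_pas_recovery.py     # 406/406 PAS recovered, conservation exact
python analysis/03_apa_and_de.py       # 30/30 shifts, mean |log2FC error| 0.18
python analysis/04_attenuation_and_spacing.py
python analysis/05_chip_and_metagene.py
```

A `pasfactory` CLI wraps the pipeline (`pasfactory run --seed 1 --outdir out`,
`pasfactory simulate`, `pasfactory mask genome.fa`).

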