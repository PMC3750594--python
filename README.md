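# tdmr

Calling and annotating **tissue-specific differentially methylated regions
(tDMRs)** from methylation-array beta values, for epigenomics analysts
working with multi-tissue, matched-individual designs (e.g. Illumina 450k
data across blood, liver, muscle, fat, ...).

## What it computes

**Per-CpG testing.** For each CpG *j* the methylation fraction is modelled
as

    y_j = β0 + β1·T + b1·I + ε

with a tissue effect *T* and an individual term *I*. The tissue effect is
tested by comparing this model against the reduced model without *T* via an
F test; the default engine is a fixed-effects two-way ANOVA blocking on the
individual, which coincides with the random-individual mixed model on
balanced complete data (a REML mixed-model engine is available for
unbalanced designs). Effect size is the mean sum of squares of the
per-tissue means ȳ_i,j around their overall mean ȳ_j:

    MSS_j = Σ_i (ȳ_i,j − ȳ_j)² / n

A CpG is a **tDMP** when *p* ≤ 10⁻⁷ (a Bonferroni-style genome-wide
threshold; `--bonferroni` derives it from the number of tested probes) and
MSS ≥ 0.01 (a 20% split between two tissues).

**Region calling.** tDMPs are chained into **tDMRs**: ≥ 3 tDMPs with
consecutive inter-tDMP distances ≤ 1 kb and at most 3 interrogated
non-tDMPs inside the region, grown greedily left to right and trimmed to
end on a tDMP.

**Annotation.** Each probe gets one of five gene-centric classes measured
from the nearest TSS (distal promoter −10 kb..−1.5 kb, proximal promoter
−1.5 kb..+500 bp, gene body, downstream TES..+5 kb, intergenic), one
CpG-density class (island / 2 kb shore / next-2 kb shelf / open sea), and
boolean flags for arbitrary BED tracks (DHS, TFBS, alternative-event
extracts, ...).

**Enrichment.** Odds ratios of region probes in an annotation are corrected
for array density by dividing by the odds ratio of *region-like* background
chunks (runs of ~5 probes with gaps < 1 kb); empirical two-sided p-values
come from redrawing 4,500 such chunks per permutation (200,001 permutations
by default, p-floor 1/200,002 < 10⁻⁵) with the add-one rule.

**Cross-tissue correlation.** For CpGs variable between individuals in an
internal tissue (inter-individual MSS > 0.025, after masking SNP-overlapping
probes), the Pearson correlation of all pairwise individual differences
against the same differences in a reference tissue (blood) identifies CpGs
whose internal-tissue methylation can be tracked in an accessible tissue
(r > 0.8).

A seeded synthetic-data generator (`tdmr.simulate`) emulates bimodal betas,
local co-methylation, per-individual offsets, planted regions and SNP-like
trimodal probes, so the full pipeline runs and is benchmarked without any
downloads.

## Worked example

```sh
python examples/01_call_dmrs.py
```

prints

```
dataset: 6000 probes x 20 samples
tDMPs called: 739 of 6000 probes tested
tDMRs called: 174, mean length 540 bp
planted regions recovered: 174/200
first region chr1:20912-21396 (4 tDMPs, 1 non-tDMPs), hypomethylated in liver
```

i.e. on a simulated 4-tissue × 5-individual dataset with 200 planted
5-probe regions (beta shift 0.25), the dual threshold calls 739 of the
1,000 planted probes, the chainer assembles 174 regions — all of them over
planted regions (no false positives) — and each region is summarised by the
tissue with the lowest methylation, the one in which a nearby gene would
typically be expressed. The other scripts in `examples/` walk through
annotation, background-corrected enrichment and cross-tissue correlation
the same way.

The same pipeline is available as a CLI for file-based workflows:

```sh
tdmr simulate --out data/ --seed 1
tdmr call-dmrs --beta data/beta.tsv --sheet data/samples.tsv \
               --manifest data/manifest.tsv --out results/
tdmr annotate ... ; tdmr enrich ... ; tdmr cross-tissue ...
```

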