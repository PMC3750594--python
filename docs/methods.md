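# Methods

## Per-CpG model and test

Each CpG is modelled on the beta scale as `y = β0 + β1·T + b1·I + ε`, where
`T` is the tissue factor and `I` the individual. Tissue specificity is a
nested-model comparison against `y = β0 + b1·I + ε` via

    F = ((RSS_reduced − RSS_full)/df_num) / (RSS_full/df_den)

with `df_num = rank(full) − rank(reduced)` and `df_den = n − rank(full)`.

The default engine treats the individual as a fixed blocking factor. On
balanced complete data this F statistic is identical to the tissue-effect F
of the random-intercept mixed model: the GLS estimate of within-individual
contrasts reduces to OLS, and REML's residual variance equals the two-way
ANOVA mean squared error. We exploit that equivalence because the blocked
ANOVA is closed form and can be vectorised over hundreds of thousands of
probes (probes are grouped by missingness pattern; each group shares one
pair of orthonormal design bases, so a group's RSS values are two matrix
products). An optional `engine="mixed"` (statsmodels `MixedLM`, REML, Wald
F on the joint tissue contrast with the same `df_den` convention) is
provided for unbalanced designs; the balanced-case agreement is tested to
~1e-3 relative, the residual being optimizer tolerance.

Numerical notes: rows are centred before projecting, so an all-constant
probe yields RSS 0/0 and is reported as F = 0, p = 1 exactly rather than
noise-amplified garbage; p-values are clamped to the smallest positive
normal double, never 0; probes with data in fewer than two tissues or with
no residual degrees of freedom are flagged `tested = False` (the
single-probe API raises instead, naming the failure mode).

## Effect size and thresholds

Effect size is the mean sum of squares `MSS = Σ_i (ȳ_i − ȳ)²/n` over
per-tissue means. The overall mean `ȳ` is the mean of the per-tissue means
(identical under balance, robust to unequal replication otherwise). A CpG
is a tDMP iff `p ≤ alpha` **and** `MSS ≥ mss_min`; defaults `alpha = 1e-7`,
`mss_min = 0.01` (the value produced by two tissues 0.20 apart).
`bonferroni_alpha(n)` constructs the threshold as 0.05/n truncated down to
a power of ten (471,000 tests → 1e-7); the untruncated quotient is
available with `truncate=False`.

## Region chaining

The chaining semantics are fixed as: regions grow greedily left-to-right
over tDMPs sorted by position; the ≤ `max_gap_bp` rule applies between
consecutive member tDMPs; interrogated non-tDMPs between the first and last
member count against `max_non_dmps` (untested probes count as non-tDMPs); a
region closes when the next tDMP is too far or would exceed the budget, is
trimmed to end on a tDMP, and must hold ≥ `min_dmps` tDMPs; the next region
may start at the next tDMP. Because every constraint is monotone in region
extension, this greedy rule provably equals "leftmost valid start, longest
valid window", which is what the exhaustive-enumeration oracle in the test
suite checks on every tDMP/non-tDMP string up to length 12. Region span is
first-to-last tDMP position and `length_bp = end − start`; duplicate
positions on a chromosome are an error rather than a silent merge.

## Annotation

The classification gene is the nearest-TSS gene (ties on |offset| broken by
lexical gene id and flagged). Classes are measured in that gene's
strand-oriented coordinates: distal promoter [−10000, −1500), proximal
promoter [−1500, +500], gene body (+500, TES], downstream (TES, TES+5000],
else intergenic — half-open at class joints, inclusive at +500 and TES; the
boundary choice only affects probes exactly on a joint. A probe beyond its
nearest gene's downstream band is intergenic even if it lies inside another
gene's body; this nearest-TSS convention is a deliberate simplification.

CpG-density classes are computed as distance to the nearest merged island:
0 → island, 1–2000 → shore, 2001–4000 → shelf, else open sea; taking the
minimum distance over islands automatically implements the precedence
island > shore > shelf where bands of neighbouring islands overlap.

Coordinates are 1-based internally (array-manifest convention); BED I/O
converts exactly at the boundary (position p ↔ interval (p−1, p]).

## Enrichment

Raw odds ratio: `(a/b)/(c/d)` over the 2×2 table of set membership ×
annotation flag, with Haldane's 0.5 added to every cell only when a cell is
zero. Background correction divides by the odds ratio of the pooled
"region-like" chunks: the manifest is chained into runs with consecutive
gaps strictly under 1 kb, each run split left-to-right into 5-probe pieces,
a terminal remainder of ≥ 3 probes standing alone, a smaller one appended to
the preceding piece, runs under 3 probes discarded.

The permutation null redraws `regions_per_draw` chunks without replacement
per permutation (one seeded `numpy` Generator stream; draws are vectorised
via smallest-k random keys), recomputes that draw's corrected odds ratio,
and reports the two-sided add-one p-value
`p = (1 + 2·min(#≥obs, #≤obs))/(n_perm + 1)`, capped at 1 — at the default
200,001 permutations the attainable floor is 1/200,002 < 1e-5. The
permutation statistic is the corrected odds ratio (self-consistent with the
observed statistic); this choice, and the exact two-sided rule, are
conventions where only "two-sided" is prescribed.

## Cross-tissue correlation

Probes overlapping SNPs are removed first: a probe falls if a SNP hits the
CpG dinucleotide (position or position+1) or lies within `snp_window_bp`
(default 50) of the CpG on the probe-body side — lower coordinates for +
probes, higher for −, both sides when the strand is unknown. Without probe
sequences the 50-mer body is approximated by this window; the side
convention is ours and configurable.

For a tissue, per-individual mean betas are reduced to all unordered
pairwise differences with fixed p < q orientation; `r_with_reference` is
the Pearson correlation of that difference vector against the reference
tissue's, over pairwise-complete pairs (≥ 3 required; zero variance in
either vector yields a missing r). Selection requires inter-individual
MSS > 0.025 and r > 0.8. Pearson on signed differences is our reading of an
unspecified estimator. Note the 15 pairs from 6 individuals are not
independent observations, so the null tail of r is wider than the textbook
Pearson null at n = 15; the tests therefore benchmark selection rates
against simulated nulls, not the analytic tail.

## Synthetic data

The generator emulates, per seeded run: a bimodal baseline (two-component
beta mixture with modes ~0.1/~0.9, concentration 30 — under 5% of probes in
[0.35, 0.65]); local co-methylation (probes within 1 kb share a baseline up
to N(0, 0.02) jitter, so adjacent-probe correlation decays with distance);
geometric inter-probe gaps with mean 700 bp, placing ~85% of probes inside
sub-kilobase runs — the array-density regime that makes background
correction necessary, matched to the ~8×10⁴ five-CpG background regions a
real 450k manifest yields; planted regions of consecutive probes (gaps
50–250 bp, so five probes span ~600 bp like typical called regions) whose
affected tissue is shifted by Δβ toward the free side of [0,1], isolated by
> 2 kb from background probes so ground truth is unambiguous; shared
per-individual offsets (the `b1·I` term; `correlated_fraction < 1` makes
the complement's offsets independent per tissue, the null case for
cross-tissue correlation); SNP-like probes with Hardy–Weinberg genotype
means {0.05, 0.5, 0.95} identical across an individual's tissues; and
N(0, residual_sd) noise clamped to [0, 1].

Defaults are the bench conditions used throughout the tests: 6,000 probes,
4 tissues × 5 matched individuals, residual sd 0.03, individual sd 0.02,
200 planted 5-probe regions with Δβ = 0.25, 2% SNP-like probes. Noise is
additive normal on the beta scale (clamped), which is adequate for testing
but lighter-tailed near 0/1 than real intensity-ratio noise; the generator
also does not emulate probe-type chemistry, batch effects or
cell-composition mixtures — passing tests demonstrate correctness of the
algorithms under the stated generative model, not robustness to those
artefacts.

## Known limitations

- Under the default bench conditions the planted-region recovery tops out
  near 0.92 sensitivity (precision 1.0): with one tissue of four shifted by
  0.25, per-probe power at alpha = 1e-7 is ~0.79 for the F cut (critical
  F(3,12) ≈ 66, noncentrality ≈ 260) and ~0.90 for the MSS cut, and a
  5-probe region needs 3 called probes. Larger designs or effects recover
  regions essentially always.
- The mixed-model engine is per-probe Python-loop slow; it is meant for
  follow-up of unbalanced probes, not genome-wide sweeps.
- Nearest-TSS gene assignment is a simplification of regulatory-domain
  rules; probes inside a gene body can be labelled intergenic when another
  gene's TSS is closer.
- Raw-intensity preprocessing (normalisation, detection p-values) is out of
  scope; the loader accepts a pre-masked beta matrix with missing values.
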