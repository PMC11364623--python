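# Methods

This note documents the models, parameters and numerical choices behind
the package, and what the synthetic benchmark does and does not show.

## The synthetic study design

The generator builds a miniature genome whose statistical structure
matches what the downstream stages assume, with every implanted effect
recorded as ground truth.

**Layout.** Default: 2 chromosomes × 10 Mb at 250 bp bin resolution.
Features (400 genes, 200/200/200 H3K9me3 regions of the Cluster1 /
Cluster2 / nonDA classes, 120 enhancers) are placed in disjoint slots
with a 2.5 kb interior margin, which guarantees two invariants by
construction: regions are ≥ 2 kb from every TSS (distal), and the
±1.5 kb H3K27me3 flank zones of bivalent promoters never collide with a
neighbouring feature. H3K9me3 regions are 6–12 kb wide — broad
heterochromatin domains, so that the summit ± 5 kb heatmap span samples
mostly in-domain signal, as in real H3K9me3 data. Genes are 2–3.5 kb
with 2–4 exons; one canonical TSS per gene.

**ERVs.** 8 subfamilies × 75 instances across the ERVK, ERV1, ERVL and
MaLR families. The configured overlap fractions (0.60 / 0.40 / 0.22 of
Cluster1 / Cluster2 / nonDA regions containing an ERV ≥ 500 bp) are
realized exactly up to rounding: a rounded count of regions per class
receives an implanted instance ≥ 500 bp (drawn from the ERVK/ERV1
subfamilies, the K9A-responsive families), and the remaining copies are
placed uniformly but away from the study regions. Consequence: the
overlap percentages are controlled parameters, not noisy estimates, and
background ERV density near study regions is zero — a simplification
real data does not share.

**Tracks.** Signal is emitted directly as binned values (bedGraph
equivalents), not reads: every in-scope statistic consumes binned,
normalized signal. A track is a deterministic mean surface (background
1.0, features at their class amplitude) times mean-one lognormal bin
noise, `exp(σZ − σ²/2)` with σ = 0.25 by default. Amplitudes: H3K9me3 8×
over all three classes in control; in K9A, Cluster1 drops to 1× (back to
background — "full loss", ratio 0.125) and Cluster2 to 4× (ratio 0.5).
H3K27me3 sits at 6× inside bivalent-promoter SUZ12 zones (TSS ± 1 kb)
and 3× in the ±1.5 kb flanks; K27A retains f_in = 0.7 of the in-peak and
f_flank = 0.4 of the flank signal (the spreading defect), K9A retains
0.7 everywhere (uniform loss). Each (mark, genotype, replicate) track
draws from a substream derived by stable hashing from the root seed, so
adding one track never perturbs another.

**Peak calls.** Replicate-level peak sets are the true feature intervals
with ±100 bp boundary jitter and 8% dropout, emulating per-replicate
caller variability; this is what makes the replicate-consensus step
meaningful.

**Counts.** Negative binomial with mean–dispersion parameterization
(variance = μ + αμ², α = 0.1 by default; α = 0 is an exact-mean mode for
testing). Per-sample depth factors are lognormal (σ = 0.15). 80 of the
400 genes are linked to Cluster1/Cluster2 regions; 82% of linked genes
carry a +2 log2FC in K9A. Each Cluster region also gets a per-sample
log2 "activity" (genotype shift plus N(0, activity_sd) within-group
variation); the linked gene inherits the within-group part scaled by
`link_coupling`. This per-sample co-variation — chromatin state
fluctuating between cultures and propagating to the target gene — is
what the correlation linker detects. TE-subfamily counts upregulate
(+2 log2FC in K9A) exactly those subfamilies with an instance inside a
de-repressed region.

## Analysis machinery and its parameters

**Consensus peaks.** A base is "supported" when ≥ min_support (default 2)
replicates cover it; the output is the union footprint of all replicate
peaks touching a supported run, i.e. consensus peaks extend to the outer
boundaries of their supporting evidence rather than the ≥k-coverage
core. The core-only alternative is one flag away
(`merge_within(gap=0)` of the support runs).

**Merging and annotation.** "Within 500 bp" merging is inclusive at the
boundary (gap ≤ 500 merges). Regions are annotated by their midpoint
with priority promoter (≤ 2 kb of a TSS) > 5′UTR > 3′UTR > exon >
intron > distal intergenic, so each region gets exactly one category and
percentages sum to 100. The promoter window (2 kb) and the bivalent
TSS flank (1 kb) are deliberately separate constants.

**Normalization.** RPGC multiplies coverage by G/(N·L) so the
genome-wide mean is 1× (exact when the raw track is extended-fragment
coverage). Spike-in factors are mean(fly)/fly_s, renormalized to mean 1.
Count matrices use median-of-ratios size factors (geometric-mean
normalized). Two places deliberately do **not** use median-of-ratios on
the matrix at hand: per-region H3K9me3 signal (tracks are already
coverage-normalized; a third of regions losing signal would mis-center
the factors) and the 8-row TE matrix (most rows are responsive; the
gene-derived factors are used instead).

**Differential testing.** The statistic is a moderated t on
log2(normalized + 1), with the prior variance s₀² set to the median
pooled variance across features. p-values come from the permutation
distribution of group labels when the design admits ≥ 100 distinct
assignments — enumerated exactly up to 2000 assignments (6v6: all 924;
the attainable floor is 2/924 because the complement labelling always
ties |t|), randomly sampled above that with the add-one convention —
and from a t reference with n₁+n₂−2 df for smaller designs (3v3 hits
this branch). Calls: padj < 0.05 and |log2FC| ≥ 1 (genes, regions at
0.8 — see below) or ≥ 1.5 (TE subfamilies). A known property worth
stating plainly: at 3 replicates the df=4 t reference plus BH is
conservative, and the default 3v3 gene contrast calls few or no DEGs at
these effect sizes; the caller's power properties (recall ≥ 0.9 of +2
log2FC implants at FDR ≤ 0.1) hold at the 6v6 validation scale, which
the analysis scripts run alongside. Region-level DA calling uses an
|log2FC| cut of 0.8 because the +1 pseudocount shrinks the Cluster2
half-loss (true log2 ratio −1) to about −0.95.

**k-means clustering.** Features are the row-wise concatenation of
control and mutant 40-window vectors (both conditions are needed to
separate degrees of loss; a control-only mode exists), log1p-transformed
by default. The log scale matters: on raw signal the Euclidean distances
are dominated by region-width variance rather than fold-level loss, and
recovery collapses. Labels are renamed so Cluster1 is always the cluster
with the lower mean mutant/control ratio. 10 restarts, seeded k-means++.

**Spreading analysis.** Per SUZ12 peak, mean replicate-averaged signal
in [start, end), [start−1500, start) and [end, end+1500); summary ratios
are means over peaks, mutant/control per zone. The estimator is exact on
noise-free tracks and unbiased under the multiplicative noise model.

**Shuffle enrichment.** Observed statistic: bp overlap of the signal
regions with a subfamily's instances. Background: length-preserving
uniform re-placement within each chromosome (copy-number-aware
backgrounds are out of scope). Empirical p uses the add-one convention,
so p ≥ 1/(1+iterations): with the conventional 20 iterations the floor
is 0.048 and a p < 0.01 call is unattainable — the analysis scripts use
199 iterations when applying the p < 0.01 & log2FC > 1 rule. ε = 1 bp
guards the fold change; zero-instance subfamilies report log2FC 0, p 1,
flagged.

**Linkage.** Candidate pairs within 250 kb of a TSS by default (the
drivers use 100 kb at miniature scale), Pearson r across shared samples,
p from the t-transform with n−2 df, BH across all pairs, retained iff
padj < 0.2 and r > 0 (activating elements; a flag admits negative
links). The recovery benchmark runs in a 12-sample design with genotype
effects off and strong per-sample co-variation: with genotype effects
on, every (DA peak, DE gene) pair co-varies through the shared genotype
pattern and no correlation method can separate implanted from confounded
pairs at n ≈ 12 — an inherent limitation of correlation-based network
inference with few samples, which the benchmark design isolates away.
The linked-gene up-fraction estimate carries a small downward bias
(~0.04) because weakly expressed linked genes escape detection.

**Printed percentages.** Truncation (floor) at the requested number of
decimals, computed in integer arithmetic; this is the convention that
reproduces printed overlap fractions exactly, and the printed value
never exceeds the true ratio.

## What passing tests show — and what they do not

The benchmark shows that each stage recovers exactly the structure it is
designed to detect, at realistic noise levels, and that the statistical
kernels are calibrated (null type-I error, p-value floors, FDR control).
It does not emulate: mappability and copy-number structure of real
repeats (background ERVs avoid study regions entirely), read-level
artifacts, dispersion trends across expression strata, batch effects
beyond a scalar depth factor, or TF-level regulatory logic (TF–CRE–gene
triples are out of scope). Absolute counts of significant features at
the default 3-replicate scale are conservative relative to NB-GLM
tools and should be read as such.

## Problem sizes

Defaults were chosen so the full test suite runs in well under a minute
and the acceptance script in seconds on one CPU: 2 × 10 Mb genome
(80,000 bins), 400–2000 genes, 600 regions, ≤ 999 permutations or exact
enumeration of 924 assignments, 199 shuffle iterations where the 0.01
cut is applied.
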