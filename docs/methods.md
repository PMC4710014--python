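# Methods

This note documents the models implemented in `sweepscan`, the choices
made where the design was genuinely open, and what the synthetic-data
validation does and does not demonstrate.

## Per-site F<sub>ST</sub>

`fst.wc_fst_site` implements the Weir & Cockerham (1984) estimator for two
populations of diploids. From genotype-class counts it computes the
allele frequencies p̂᾿ᵢ, observed heterozygote proportions h̃ᵢ and the
sample-size corrections n̄ and n꜀, then the three variance components:

- a — among populations,
- b — among individuals within populations,
- c — between gametes within individuals (h̄/2),

and θ̂ = a/(a+b+c). Properties relied on downstream:

- θ̂ = 1 exactly (to floating point) iff the populations are fixed for
  opposite alleles with no heterozygotes among called genotypes;
- θ̂ may be negative (no clamping anywhere — clamping would bias window
  means upward);
- θ̂ is undefined (NaN) when a+b+c = 0 (sites monomorphic across both
  populations), when either population has no called genotypes, or when
  n̄ ≤ 1; such sites are excluded from window means.

The test suite checks the implementation against an independent
evaluation route (the nested ANOVA on individual-level allele indicators,
mean squares → components) on 1,000 random genotype configurations at
1e-10. No installed package provides this estimator, so the cross-check
is a second, independently written derivation rather than a third-party
library.

## Windowed scan

Windows tile each chromosome as [(k−1)·W+1, k·W], 1-based inclusive
(default W = 500 kb, matching the classic scan; the synthetic toy genome
uses 100 kb — see below). Two window statistics are computed because the
field's tools differ and the choice is rarely stated:

- `mean_fst` — unweighted arithmetic mean of defined per-site θ̂
  (the default used for outlier calling);
- `weighted_fst` — ratio of sums Σa / Σ(a+b+c), which down-weights
  low-information sites.

Windows with fewer than `min_sites` defined sites (default 10; the
original analysis is silent here) carry no mean and are excluded from the
Z-transform. Z-scores use the genome-wide mean and n−1 standard deviation
over all windows with defined means, X chromosome included; the outlier
rule is one-sided and inclusive (Z ≥ 5). Flanking means use windows of
`span` bp centred on the focal site, truncated at chromosome ends.

F<sub>ST</sub> bins are half-open and left-inclusive — [0.85, 0.90),
[0.90, 0.95), [0.95, 1.0) — with exact fixation (|θ̂−1| ≤ 1e-12) as its
own bin, since fixed differences are a qualitatively distinct class.

## Variant effect classification

A deliberately compact re-implementation of predictor semantics for the
categories the scan needs. Per overlapping transcript: CDS positions are
translated in transcript orientation under the standard genetic code
(missense / synonymous / stop_gained / stop_lost; frameshift is defined
for completeness but unreachable with SNP input); UTR membership comes
from annotated UTR features or exon-minus-CDS subtraction; the
splice-region convention is 1–3 bp exonic or 1–8 bp intronic from an
exon–intron junction, with the canonical 1–2 bp donor/acceptor positions
reported under the same coarse `splice_region` label. A site may carry
several effects (one per transcript, and a coding/UTR call may co-occur
with splice_region); gene-level summaries use a fixed severity order
(stop_gained > stop_lost > frameshift > missense > splice_region > UTR >
synonymous > non_functional). "Putatively functional" means any
consequence except synonymous and non_functional.

Known limitations: single codon table (nuclear), no regulatory prediction
beyond UTR/splice proximity, no conservation scores, reference mismatches
between FASTA and VCF are warned about rather than fatal.

## Fixed and divergent sites

"High" divergence is θ̂ ≥ 0.75 (inclusive). "Fixed" requires both the
numerical condition (|θ̂−1| ≤ 1e-12) and the biological one — both
populations monomorphic for opposite alleles among called genotypes —
which guards against rounding artefacts. Each divergent site is labelled
with its containing scan window and whether that window or an immediate
neighbour is an outlier.

## Enrichment

The sampling unit is the gene. With background size M, pathway size K and
foreground size n, the expected count is nK/M and the default p-value is
the binomial upper tail P(X ≥ k), X ~ Bin(n, K/M) — the classic
behaviour of pathway over-representation tools; a hypergeometric
(one-sided Fisher) mode is provided because the underlying test of the
original software is not documented. Bonferroni multiplies by the number
of *tested* pathways; an "Unclassified" pseudo-pathway is reported with
counts only and does not count toward the correction. The binomial tail
applied to without-replacement sampling is slightly conservative; the
suite verifies type-I error ≤ 0.05 at α = 0.05 over 10,000 null draws.

## Category spectra and contrasts

Bin spectra count sites per consequence category per F<sub>ST</sub> bin.
Because a site can carry several consequences, two modes exist: `multi`
(default; a site counts once in each category it carries, so category
percentages are not forced to sum to 100) and `exclusive` (most severe
only). Bin totals count each site once in either mode.

The flanking contrast takes the six categories 5′-UTR, 3′-UTR, missense,
splice region, stop gained and synonymous (synonymous as the neutral
reference), computes each site's flanking mean F<sub>ST</sub>, and runs a
classic equal-variance one-way ANOVA (F = MS_between/MS_within,
df = (k−1, N−k)) followed by Tukey–Kramer all-pairs comparisons with
q = |Δ| / √((MS_within/2)(1/n₁+1/n₂)) and family-wise p from the
studentized range distribution with parameters (k, N−k) (quantiles via
`scipy.stats.studentized_range`). Categories with fewer than two values
are dropped from the contrast. Both are verified against the
corresponding SciPy implementations and against the q = √2·|t| identity
for two groups.

## Structured-coalescent null

The simulator runs the continuous-time structured coalescent backwards in
time: within deme i with k lineages, pairwise coalescence at total rate
k(k−1)/(4Nᵢ) per generation (Nᵢ diploid, piecewise-constant epochs);
migration moves single lineages between demes at per-lineage backwards
rates m_ij; at split times all lineages of the derived deme re-label into
the ancestral deme. Mutations fall as a Poisson process at rate
μ·L_block per generation on each branch under infinite sites. Lineages
left in mutually isolated demes with no future events raise an error
(model misspecification).

Recombination is approximated by B independent non-recombining blocks per
window (default B = 50 per 500 kb). This preserves the
variance-reduction that intra-window recombination exerts on window-mean
F<sub>ST</sub> at a tiny fraction of the cost of an ancestral
recombination graph; it does not reproduce linkage patterns *within*
blocks, so the null is suitable for window means, not for
haplotype-structure statistics. Larger B shrinks the null's variance
toward the B→∞ limit; B is configurable everywhere.

Calibration checks in the suite: pairwise TMRCA ≈ 2N; coalescence waiting
times exponential with rate k(k−1)/(4N) (KS test on 10,000 draws);
pairwise diversity within 3 Monte-Carlo SE of 4Nμ; the folded SFS ∝ 1/i;
two-deme equilibrium F<sub>ST</sub> near 1/(1+16Nm); mean F<sub>ST</sub>
strictly decreasing in migration; and agreement with msprime run under a
matched demography.

The shipped demography (`data/dog_wolf_demography.yaml`) is illustrative:
a domesticate with a sustained bottleneck in the low thousands (N = 2500
pastwards of generation 500, N = 25,000 today) splitting from a wild
progenitor (N = 20,000) 4,500 generations ago with weak symmetric
migration (10⁻⁴/generation), μ = 10⁻⁸/bp/generation. It produces
genome-wide window-mean F<sub>ST</sub> around 0.15 — plausible for a
recent domestication — but it is a placeholder, not a fitted model; any
real analysis should supply its own YAML.

## Synthetic data generator

The generator emulates the structure the analysis assumes: two
populations (default 67 + 7 diploids), background SNPs from the
coalescent engine (realistic frequency spectra; an i.i.d. Balding–Nichols
mode with F = 0.14 exists for fast unit tests), per-genotype missingness
(default 5%), injected sweep regions (sites redrawn with strongly
diverged frequencies, target θ̂ ≈ 0.85), planted fixed functional
variants, and a pathway table whose enriched pathway contains the planted
functional genes.

Toy genes share one architecture — 200 bp 5′-UTR, 200 + 1000 bp CDS split
by a 1 kb intron, 200 bp 3′-UTR — laid on alternating strands. Coding
plants use designed codons (GAA→AAA missense, GGA→GGG synonymous,
TGG→TGA stop gain, terminal TAA→CAA stop loss), so the expected
amino-acid change is known by construction, independent of the
classifier being tested. Planted sites are written with full call rate;
missingness applies to background sites only, so recovery measures the
pipeline, not sampling luck.

The toy genome is 2 × 5 Mb and is scanned in 100 kb windows rather than
500 kb. The reason is arithmetic, not tuning: a sample Z-score over n
windows cannot exceed (n−1)/√n, so a 20-window genome can never produce
Z ≥ 5; ~100 windows give the genome-wide Z-transform room to behave like
a real scan while tests stay at seconds-scale. Problem sizes throughout
the suite (replicate counts, sample sizes, window counts) were chosen as
the smallest that keep Monte-Carlo error well inside the asserted
tolerances.

What passing tests show: the estimator, classifier, enrichment and
contrast machinery are correct on data whose generating process is fully
known, and the end-to-end pipeline recovers strong planted signals
exactly. What they do not show: behaviour under realistic linkage within
windows, variant-calling artefacts, reference bias, or weak/soft sweeps —
none of which the generator emulates.

## Numerical conventions

- Positions are 1-based inclusive internally and in report TSVs; BED
  exports are 0-based half-open.
- Undefined values are NaN sentinels, never silently zero.
- Fixation tolerance 1e-12; Z and F<sub>ST</sub> thresholds inclusive.
- All randomness flows from explicit seeds (`numpy` Generators, spawned
  per replicate); identical inputs and seeds give byte-identical outputs.
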