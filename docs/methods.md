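# Methods

This note documents the models, numerical choices and limitations behind
each stage of `pdcscreen`, and what the synthetic-data generators do and do
not emulate.

## Somatic variant filtering

A candidate is a single tumor/normal variant call with tumor depth, alt
read count, tumor and normal variant allele fractions (VAF), strand bias
(majority-strand fraction of alt reads), a population allele frequency, an
effect-class annotation, and a tandem-repeat proximity flag. The filter
chain retains a candidate iff all of:

| criterion | rule | default |
|---|---|---|
| min_tumor_depth | tumor depth ≥ t | 30 |
| max_normal_vaf | normal VAF ≤ t | 0.03 |
| min_vaf_diff | tumor VAF − normal VAF ≥ t (signed) | 0.05 |
| max_strand_bias | strand bias ≤ t | 0.9 |
| min_alt_reads | alt reads ≥ t | 5 |
| max_population_freq | population frequency ≤ t | 0.015 |
| effect_class | class in retained set | all but `other` |
| near_repeat | flag unset | drop flagged |

Boundary semantics are deliberate: thresholds phrased as a minimum or
maximum are inclusive, while the population-frequency filter removes
strictly greater values — so a frequency of exactly 0.015 is retained.
The VAF difference is signed (tumor minus normal) because a somatic gain
of allele fraction is the target; a variant richer in the normal is not
somatic evidence. Synonymous variants are retained by default: they are
part of the reported mutation spectrum even though they are rarely
actionable. Strand bias is defined as max(alt-forward, alt-reverse)/alt
and treated as a precomputed input so alternative definitions can be
swapped upstream. Repeat proximity is likewise an input flag; a helper
marks variants within 5 bp (configurable) of intervals in a repeat BED.
No minimum normal-sample coverage is enforced.

Substitution classes collapse SNVs to the pyrimidine-reference convention
(G>A ≡ C>T), the standard six-class spectrum.

## Read-depth CNV calling

Input is a table of fixed-width bins (1 kb default) with GC fraction and
paired tumor/normal read counts. The chain:

1. ratio_i = tumor_i / normal_i, with normal-zero bins masked and
   reported, never divided;
2. median centering (absorbs global depth differences — a genome-wide
   doubling of tumor coverage is not a CNV signal);
3. GC correction: ratios are divided by the median ratio of their GC
   decile; deciles with < 20 bins borrow the global median (a monotone,
   robust alternative to spline fits, adequate because the correction is
   shared between tumor and normal and mostly cancels);
4. log2 transform. "Log ratio" is base 2 throughout — the convention of
   the read-depth CNV literature — so the ±0.7 call thresholds correspond
   to ratios of ≈ 1.62 and ≈ 0.62.

Segmentation is greedy bottom-up merging: every bin starts as a segment
and the cheapest adjacent merge (in residual-sum-of-squares increase
ΔRSS = n₁n₂/(n₁+n₂)·(m₁−m₂)²) is applied while ΔRSS < λ·σ̂²·log n, a
BIC-style penalty with λ = 2 by default. The per-bin noise σ̂² is estimated
robustly from first differences (median |Δ| scaled by the half-normal
constant 0.9539), with a 1e-12 floor so noise-free input still merges its
equal-mean runs and yields exactly one segment per constant chromosome.
Segment means equal the mean of member bins and segments partition the
bins. The greedy merge tends to leave short spurious segments around
strong outlier bins; these are almost always sub-threshold (neutral) and
planted breakpoints are recovered within ±2 bins at Poisson depth 100
(verified over 20 seeds in the test suite).

Segment calls are strict: gain iff log2 ratio > +0.7, loss iff < −0.7.
Gene-level calls use exon overlap: an exon overlaps a called segment if at
least 1 bp intersects; a gene is called in the direction whose
overlapping-exon fraction is strictly > 0.75 (so exactly 3 of 4 exons do
not trigger a call). If both directions qualify the larger fraction wins;
a tie is neutral with a warning. Genes with exons on several chromosomes
are rejected with a warning. Coordinates are 0-based half-open
internally; SEG output is 1-based inclusive.

Not modelled: allele-fraction (BAF) integration, tumor purity and ploidy.

## Dose–response and IC50

The four-parameter logistic on concentration c (µM) is

    v(c) = bottom + (top − bottom) / (1 + (c/EC50)^h).

Fitting is least squares on log concentration (Levenberg–Marquardt with an
analytic Jacobian), parameterizing EC50 on the log scale. Multi-start
initialization varies the hill slope (1, 0.5, 2, −1) and the midpoint
guess; a start whose RMS residual is below 10% of the data spread is
accepted immediately, so clean sigmoids cost one solver call. Fits are
canonicalized to top ≥ bottom by flipping the slope sign (the two
parameterizations are the same function). Flat data (spread < 1e-6) cannot
identify EC50 and are flagged non-converged. A fit needs ≥ 4 distinct
concentrations.

The reported IC50 is *absolute*: the concentration where the fitted curve
crosses half the untreated-control viability (0.5 on the normalized
fraction scale), solved in closed form. This differs from the curve
midpoint (relative EC50) whenever bottom > 0 or top ≠ 1; the two coincide
for the symmetric bottom = 0, top = control curve at any hill slope. A
crossing outside the tested concentration range — or absent because the
level does not lie between the asymptotes — is censored `above_max` or
`below_min` rather than extrapolated.

Replicates are fit separately and uncensored IC50s averaged (mean, sample
SD, censored count) — matching the convention of averaging independent
experiments; a pooled-fit mode is available by flag. Censored replicates
are excluded from means; an all-censored aggregate carries no numeric
mean. Treatment duration is metadata and plays no computational role.

## Association screen

The panel is a binary lines × events matrix (event = gene plus alteration
kind: snv_indel, gain or loss). Per (drug, event):

- both groups ≥ 2 lines → two-sided pooled-variance Student's t-test
  (Welch by flag) on raw IC50s (log10 by flag); the pair enters the
  Benjamini–Hochberg family;
- exactly one line in a group → the record is kept with p missing and FDR
  forced to 1, outside the BH family (forcing rather than letting
  underpowered singletons dilute the correction);
- an empty group → untested, absent from output.

Zero-pooled-variance degenerates: equal means give (t = 0, p = 1);
unequal means give an infinite-signed t and p at the 1e-300 floor,
flagged by magnitude. Censored IC50s entering a tested group are
substituted by their censoring bound (the nearest tested concentration)
and counted, preserving group sizes.

BH is the standard step-up with monotonicity enforcement (the test suite
checks it against the brute-force min-over-j definition for every family
size up to 20). Ranking sorts ascending by FDR, breaking ties by
|log10 effect ratio| descending then (drug, event) lexicographically. The
candidate cut maximizes the multiplicative gap FDR_{i+1}/FDR_i over the
first k_max = 10 ranks (zero FDRs are floored at 1e-300); all-equal FDRs
yield no candidates with a warning. Because the rule maximizes the
*ratio*, one extremely small top FDR can place the gap at rank 1 even when
several true effects follow — the full ranked table is always written so
the block structure remains visible.

## Cohort statistics

Co-occurrence of two alterations uses inclusion–exclusion:
union = A + B − both, with the union fraction and Jaccard = both/union.
Percentages are computed at full precision; integer-percent display
rounding is presentation only.

Kaplan–Meier estimation and the log-rank test are delegated to lifelines;
the log-rank statistic is the 1-df chi-square of summed hypergeometric
observed-minus-expected deviations, no continuity correction, and a
data set with no events returns (0, 1) as a vacuous test. The Wilcoxon
rank-sum test defaults to the exact permutation null (appropriate at
panel-scale n; ties fall back to midranks with the normal approximation
and a warning); the normal-approximation mode applies a continuity
correction. Z-score normalization is per gene with the sample SD (n−1);
constant genes yield zero rows and are flagged rather than dividing by
zero. The 0.05 significance threshold is applied only when labelling
reports, never inside computations.

## Synthetic data: what it emulates and what it does not

The generators exist so every stage has inputs with known truth; all take
explicit seeds (NumPy `default_rng`), no global state, and identical
spec + seed reproduces byte-identical tables.

**Cohort / variants.** 161 samples by default, with per-gene alteration
frequencies typical of recurrently altered ESCC genes (CCND1 gain 0.42
down to CDKN2B loss 0.13; TP53 mutation 0.83). Events are independent
Bernoulli draws — real co-occurrence structure (e.g. the strong
CDKN2A/CDKN2B linkage) is *not* emulated, which is why the co-occurrence
arithmetic is exercised on published counts instead. Candidate variants
average 13 per sample (Poisson) at mean tumor depth 394; true somatic
variants are constructed to clear every filter criterion, and artifacts
(at a configurable rate) violate exactly one named criterion each, so
filter attrition is fully labelled. The effect-class spectrum is
missense-dominant (57/30/7/3% for missense/synonymous/stop-gain/splice)
and the substitution spectrum has the C>T transition modal — both chosen
as the canonical squamous-carcinoma pattern.

**Coverage.** One simulated chromosome of fixed-width bins; normal counts
are Poisson around depth_mean × GC bias (a unimodal curve peaking at 45%
GC), tumor counts additionally scaled by 2^(planted log2 ratio); the same
GC bias multiplies both members of a pair, as in matched libraries
sequenced together. A noise-free mode emits expected counts for exact
tests. Not modelled: read-level artifacts, mappability, tumor purity and
subclonality — planted ratios are clonal and exact.

**Viability.** 10 concentrations in an exact 3.3-fold dilution from 10 µM,
quadruplicate wells, 4PL with bottom 0 / top 1 / hill 1 around the line's
true IC50 = base (5 µM) × the fold change of every planted effect the line
carries. Noise is multiplicative log-normal with relative SD `cv_noise`
(default 0.05), mean-one — the relative-error behaviour of luminescence
readouts; replicate wells are independent (no plate or edge effects). An
optional `line_spread_sd` adds per-(line, drug) log-normal IC50 scatter
for calibration studies; it is off by default so the generator matches the
stated effect model exactly. The default panel is 8 lines × 46 drugs with
a 5/3 carrier split for the headline CDKN2A/2B-loss event and four planted
effects mirroring a realistic top-of-screen layout (two CDK4/6 inhibitors
sensitized at fold 0.05, one resistance effect at fold 8 — which lands
above the tested range and exercises the censoring path — and one
sensitization at fold 0.1).

**Survival.** Exponential event times per group; with probability
`censor_rate` a record is censored at a uniform time before its event.
This gives an exact, seedable censoring fraction at the cost of making
censoring informative in the weak sense of being time-uniform per subject;
adequate for exercising KM/log-rank, not for studying censoring bias.

Passing tests on these generators demonstrate internal correctness and
statistical calibration of the chain, not performance on real sequencing
or assay data, which carries structure (alignment artifacts, plate
effects, co-occurring alterations, purity) the generators deliberately
omit.

## Problem sizes

The test suite and the acceptance script run the screen-recovery study at
50 seeds (8 lines × 46 drugs, pooled fits), null calibration at 100 seeds
on analytically generated IC50 tables (log10 scale, where the log-normal
noise makes the t-test exactly calibrated; the calibration check compares
the mean per-seed false-positive fraction against its empirical standard
error, since pairs within a seed share lines and are correlated), 4PL
recovery at 100 curves, and breakpoint recovery at 20 seeds of 1000 bins.
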