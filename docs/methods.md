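# Methods

This note records the statistical model behind `erscan`, the defaults and
why they were chosen, what the synthetic data do and do not emulate, and the
numerical conventions that affect results.

## Data model

Observed data are per-site, per-library nucleotide counts (`sync` format,
`A:T:C:G:N:del`).  Coverage is `A+T+C+G`; `N` and deletion reads never enter
frequency arithmetic.  Each site is polarized once, on the founder libraries
pooled: the major allele is the highest summed founder count, the minor the
second highest, ties broken by the fixed order A < C < G < T.  Third and
fourth alleles are dropped and the lost read mass recorded — the data give
no principled way to fold a third allele into a 2×2 test, and such sites are
rare after SNP calling.  All internal coordinates are 1-based inclusive;
BED input/output converts to 0-based half-open explicitly.

## SNP calling and filtering

A site is a SNP when at least one founder library individually shows at
least `min_minor_count` (default 1) reads of a second allele.  The default
of a single read assumes stringent base-quality screening upstream (the
count files are expected to be built from high-quality bases only); raise it
when feeding raw counts.  Coverage tails are removed with nearest-rank
quantiles (integer depths, deterministic): the upper bound is the (1−q)
quantile of the single library with the highest mean depth, the lower bound
the q quantile of the total depth over all libraries, q = 0.01 by default.
The two bounds deliberately live on different scales — a spike in the
deepest library flags collapsed repeats, while only the total carries enough
information to flag genuinely under-covered sites — so they are not mutually
ordered; a threshold pair is "degenerate" when it would remove every site
(e.g. constant coverage).  Sites are removed when the focal-library depth is
`>= upper` or the total depth is `<= lower`.  Downsampling to a common mean
coverage is per-library binomial thinning with probability
`target/library_mean`, the count-level analogue of read subsampling: it
preserves the expected allele frequency and the first two moments of the
count distribution.  Filters commute and every removed site is tallied per
rule.

## CMH test

Per SNP, replicate k contributes the 2×2 table (founder vs. evolved ×
major vs. minor reads).  The statistic is the classical Mantel–Haenszel
chi-square with 1 df (see README for the formula), continuity correction
0.5 by default — the convention of the R `mantelhaen.test` dialect this
field's pipelines historically used; it is exposed as a flag because the
choice is not material once the cutoff is calibrated empirically (both
observed and null scores shift together).  The corrected numerator is
floored at zero.  Strata with a zero row or column margin carry no
information and are skipped rather than failing the site, preserving SNPs
with one low-coverage replicate; a site where all strata are degenerate is
flagged undefined and excluded downstream, with counts reported.  p-values
are floored at the smallest positive double; −log10 p is computed from the
chi-square log survival function, so ordering is preserved past the floor.

The CMH test conditions on read counts and therefore ignores genetic drift
between the time points.  On drifting data its p-values are strongly
anticonservative; they are treated purely as a ranking statistic, with
significance delegated to the simulation-calibrated cutoff below.

## Windowed temporal Ne

Windows are consecutive runs of 1000 SNPs in genomic order per chromosome
(not fixed bp), trailing windows under 500 SNPs dropped.  For founder/
evolved read frequencies x, y the per-SNP standardized change is
`Fc = (x−y)² / (z − x·y)`, `z = (x+y)/2`; sites fixed for the same allele at
both ends are skipped and tallied.  The window-level F̄ is the pooled ratio
`Σ(x−y)² / Σ(z − x·y)`, not the mean of per-SNP ratios: with a
rare-variant-skewed spectrum the per-SNP ratio of a low-frequency allele
collapses toward zero whenever the allele is lost, and averaging those
ratios inflates Ne by tens of percent (measured +38% at true Ne 285 under
the default conditions).  The pooled ratio is the weighting used by
moment-based temporal estimators generally, and recovery tests show it
within ~2% across true Ne 100–1000.

Sampling noise is removed via the two-stage effective sample size: a pool
of S chromosomes sequenced to depth R yields frequency variance
`p(1−p)·(1/S + 1/R − 1/(S·R)) = p(1−p)/S̃`, so `1/S̃₀` and `1/S̃ₜ` are
subtracted from F̄ (window mean of per-SNP `1/S̃`, since depths vary).
Under sampling plan I — sequenced individuals are drawn from, and return
to, the breeding population — the census term `+1/(2·N_census)` (in
chromosomes) is added; plan II omits it.  The remaining drift signal D is
inverted through the exact relation `D = 1 − (1 − 1/(2Ne))^t`; the familiar
linearization `Ne = t/(2D)` overestimates by >10% once `t/(2Ne)` reaches
0.3 (e.g. true Ne 100 at t = 60).  Windows whose corrected D falls outside
(0, 1) return an undefined sentinel (drift signal below sampling noise ~
infinite Ne) and are excluded from aggregation, with tallies.  The final
estimate is the mean across replicates of the per-replicate median over
windows — medians defuse windows contaminated by selection, the cross-
replicate mean uses the independent drift realizations.

Defaults: pool sizes 2000 chromosomes (1000 diploids, the census of the
emulated design), census 1000 diploids, plan I, t = 60 generations.

## Neutral null and empirical cutoff

Wright–Fisher cohorts of independent loci are simulated at the estimated
(rounded) Ne: per generation `p' = p(1+s)/(1+s·p)` (s = 0 in null cohorts)
followed by `Binomial(2·Ne, p')/(2·Ne)`.  Gene-copy number is `2·Ne`
(diploid reading of the estimate, on the same scale as the census).
Starting frequencies are resampled with replacement from the observed
founder spectrum; observation draws a pool `Binomial(S, p)/S`, a depth from
the coverage model (empirical depths resampled jointly per time point by
default; Poisson around a mean otherwise, floored at one read), and reads
`Binomial(R, p_pool)`.  The founder is observed with its own noise at
generation 0, because the experimental contrast is between two sequenced
samples.  Everything is deterministic under a fixed seed.

The cutoff at nominal false-positive rate f (default 0.02) is the smallest
cohort −log10 p value with at most a fraction f of the cohort strictly
above it (nearest-rank from above); candidates are observed SNPs strictly
above the cutoff.  The −log10 scale is used throughout: published cutoffs
of order 30 are only interpretable there, and window averages of raw
p-values near 10⁻³⁰ could never exceed such a cutoff.  Cohorts smaller than
50/f trigger a warning.  Held-out calibration (cutoff from cohort A applied
to an independent cohort B) realizes the nominal rate within exact binomial
99% bounds in the acceptance suite.

## Regions and AFC summary

Windows of 200 kb advancing by 100 kb tile each chromosome from position 1;
the run stops once a window reaches the chromosome end, so the last window
may be shorter and no window is strictly nested in another.  A window's
score is the mean −log10 p of the candidate SNPs inside it; windows without
candidates are undefined and never qualify.  Qualifying windows
(mean > cutoff, strictly) that overlap or abut are unioned into regions.
One structural consequence, worth stating plainly: because only candidate
scores are averaged and every candidate exceeds the cutoff, any window
containing a candidate qualifies.  On dense, small test genomes the
calibrated false-positive load can therefore tile most windows; realistic
genome sizes and SNP densities give sparse candidate windows and distinct
peaks.  The summary reports region count, unique bp and fraction of the
genome.

The allele-frequency-change summary averages founder and evolved
frequencies across replicates, re-polarizes each candidate by its rising
allele, and reports start/end/change histogram tables plus the fixation
fraction: candidates whose final major-allele frequency reaches 0.9.

## Synthetic data

The generator emulates the target experimental design — 3 replicates, 60
non-overlapping generations, census 1000 diploids, founder coverage ~259×,
evolved ~100× (or 190×/83× for the smaller-genome configuration), pools of
2000 chromosomes — with a founder spectrum Beta(0.2, 0.2) truncated to
[1/(2N), 1−1/(2N)]: U-shaped, i.e. skewed toward rare variants as empirical
founder spectra are.  Planted loci get a selection coefficient, an optional
fixed starting frequency, and an optional linked block: each neighbor
within the block half-width receives `clip(neutral + ρ·(focal − focal_p0))`
as its trajectory.  This mixing-of-deviations is a deliberate stand-in for
hitchhiking, not a recombination model: it preserves each neighbor's own
starting frequency, reduces to independence at ρ = 0 and to perfect
tracking of the focal frequency change at ρ = 1, and produces the
peak-shaped signatures a scan must detect.  What the generator does *not*
emulate: linkage disequilibrium among background SNPs, recombination-rate
variation, inversions, spatially varying coverage, mapping artifacts.
Passing tests on these data demonstrate the statistical machinery
(calibration, recovery, region logic), not robustness to those real-data
features.

## Problem sizes and tolerances

Simulation-based tests use 100 windows × 1000 SNPs × 3 replicates for Ne
recovery (tolerance ±10% of truth, seeded) and paired 100,000-SNP cohorts
for cutoff calibration (held-out rate within exact binomial 99% bounds of
the nominal 2%); distributional laws (drift variance, two-stage sampling
variance) are checked at 10⁵ draws within 2–3%.  The CMH implementation is
compared to an independent reference implementation on 1000 random 2×2×K
tables at 10 significant digits; where the reference applies the continuity
correction without flooring the corrected numerator at zero, comparisons
are restricted to tables where both definitions coincide.  All stochastic
tests fix their seeds; the pipeline is bit-reproducible for a given seed.

## Known limitations

- Two time points only; no likelihood or time-series Ne estimators.
- Independent-locus null: the cutoff does not account for LD among neutral
  SNPs, matching the calibrated procedure it implements.
- X-chromosome data pass through the same estimators with no ploidy
  rescaling; interpret X/autosome differences descriptively.
- Triallelic handling (drop rarest, record mass) is a convention, not an
  inference.
- The region caller is a windowing approximation, not peak deconvolution;
  nearby sweeps merge.
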