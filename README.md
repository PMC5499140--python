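# erscan

Selection scans for **evolve-and-resequence (E&R)** experiments: replicate
populations adapt to a new environment for tens of generations, and pooled
whole-genome sequencing (Pool-Seq) of the founder and evolved populations
yields per-SNP allele counts.  `erscan` identifies the SNPs and genomic
regions whose allele-frequency changes are too consistent across replicates
to be explained by genetic drift and sampling noise.

The package is aimed at experimental-evolution groups working with
PoPoolation2-style `sync` count files (typically *Drosophila* cage
experiments: ~3 replicates, ~60 non-overlapping generations, census around
1000 diploids, founder/evolved coverages of order 250×/100×), and at anyone
who wants a tested, scriptable re-implementation of this analysis to run on
simulated data.

## The method

1. **SNP calling and filtering** (`snp_filter`).  Sites polymorphic in at
   least one founder replicate are kept; sites in the upper 1% coverage tail
   (judged on the single deepest library) and the lower 1% tail (judged on
   total coverage) are removed; BED masks and count-level binomial
   downsampling to a common mean coverage are supported.

2. **CMH test** (`cmh`).  Each SNP contributes one 2×2 table per replicate
   (allele × time point).  With stratum totals `T_k`, row margins `n_1k,
   n_2k` and column margins `m_1k, m_2k`, the Cochran–Mantel–Haenszel
   chi-square (1 df) is

   ```
   X² = ( |Σ_k (a_k − n_1k m_1k / T_k)| − c )² / Σ_k n_1k n_2k m_1k m_2k / (T_k² (T_k − 1))
   ```

   with continuity correction `c = 0.5` by default.  It rewards frequency
   shifts that agree in direction across replicates.

3. **Temporal Ne** (`ne`).  In windows of 1000 SNPs, the standardized
   frequency change `Fc = (x − y)² / (z − x·y)` (with `z = (x + y)/2`) is
   pooled across SNPs, corrected for two-stage Pool-Seq sampling noise
   (`1/S̃ = 1/S + 1/R − 1/(S·R)` for a pool of `S` chromosomes sequenced to
   depth `R`) and, under sampling plan I, for the census term, then inverted
   through the exact binomial-drift relation `D = 1 − (1 − 1/(2Ne))^t`.
   Per-replicate window medians are averaged into one autosomal estimate.

4. **Matched neutral null and empirical cutoff** (`wf_sim`, `calibrate`).
   Because the CMH test knows nothing about drift, its nominal p-values are
   anticonservative.  Neutral Wright–Fisher cohorts with independent loci
   are simulated at the estimated Ne, with founder frequencies resampled
   from the observed spectrum and depths resampled from the observed
   libraries, and the candidate cutoff is set at an empirical
   false-positive rate (2% by default) on the −log10 p scale.

5. **Selected regions** (`regions`).  Candidate −log10 p values are averaged
   in 200-kb windows sliding every 100 kb; windows above the cutoff are
   merged into regions ("peaks"), and the candidate allele-frequency-change
   summary reports how many candidates approach fixation (major-allele
   frequency ≥ 0.9).

A synthetic-data generator (`synth`) stands in for real sequencing data:
neutral background SNPs, optional planted selected loci with linked blocks,
and full ground truth, written as ordinary `sync`/BED/TSV files.

## Worked example

Save as `demo.yaml`:

```yaml
seed: 11
species: synthetic-demo
synth:
  chromosomes: {"2L": 5000000, "2R": 5000000}
  n_snps: {"2L": 1500, "2R": 1500}
  replicates: 3
  generations: 60
  ne: 285
  founder_coverage_mean: 259
  evolved_coverage_mean: 100
  planted_loci:
    - {chrom: "2L", pos: 2500000, s: 0.15, block_halfwidth: 100000, rho: 0.9, p0: 0.1}
ne: {window_snps: 1000, min_snps: 500}
null: {n_loci: 30000}
calibrate: {fpr: 0.02}
```

then run `erscan run --config demo.yaml --outdir demo_out`.  It prints:

```
erscan pipeline report (synthetic-demo, seed 11)
  sites simulated        : 3001
  SNPs after filters     : 2767
  aggregate Ne           : 201.7
  empirical cutoff       : 11.999 (-log10 p at 2% FPR, 27676 neutral SNPs)
  candidate SNPs         : 53
  selected regions       : 8 (3.30 Mb, 33.0% of genome)
  fixation fraction      : 62.3% (of 53 candidates)
```

Reading the numbers: 3000 background SNPs plus one planted sweep (s = 0.15
at 2L:2,500,000 with a 100-kb linked block) were simulated at Ne = 285;
after SNP calling and coverage filtering 2767 SNPs remain.  The aggregate
Ne of 201.7 is biased below the simulated 285 because the selected block
inflates apparent drift in one of the few windows — exactly the behavior
that makes the matched-null calibration conservative.  The cutoff of
−log10 p ≈ 12 is the 2% tail of 27,676 neutral simulated SNPs, and 53
observed SNPs exceed it.  The strongest merged region, 2L:2,300,001–
3,000,000 (40 candidates, peak window score 91), covers the planted block;
the remaining small regions are the calibrated false-positive load, which
at this SNP density tiles isolated windows.  `demo_out/` holds every
intermediate artifact (`observed_cmh.tsv`, `ne_windows.tsv`, `null_cmh.tsv`,
`candidates.tsv`, `window_scores.tsv`, `regions.bed`, truth tables,
`report.json`).

Each stage is also available standalone (`erscan synth`, `erscan cmh`,
`erscan calibrate`, `erscan candidates`, `erscan regions`,
`erscan sync validate`) and as plain library functions.

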