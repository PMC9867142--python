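# Methods

`fascimap` implements the inference chain used to map a recessive,
yield-relevant maize mutation — a fasciated-ear locus — from pooled
sequencing of phenotype-selected bulks, and to narrow the mapped interval
to candidate genes with expression and natural-variation evidence. This
note documents the models, the parameter choices that matter, and the
limits of what the simulation-based validation shows.

## The mapping model

An F2 population segregates a single fully penetrant recessive allele.
Two DNA pools are formed from phenotypic extremes — 50 mutant-phenotype
and 50 normal individuals by default — and sequenced as pools. At every
biallelic variant distinguishing the parents, the **SNP-index** of a pool
is the fraction of reads carrying the mutant-line (alternate) allele, and

    ΔSNP-index = index(mutant pool) − index(normal pool).

Under random segregation both pools have expected allele frequency 1/2
and Δ has expectation 0. At the causal locus, the mutant pool is fixed
for the mutant allele (index 1) while the normal pool, a 1 AA : 2 Aa
mixture, has expectation 1/3 — so E[Δ] = 2/3, decaying with recombination
distance on either side.

The **Euclidean-distance statistic** on the same data is

    ED = sqrt(Σ_alleles (f_mut − f_wt)²),    ED^k with k = 5 by default,

taken over the {ref, alt} frequency pair in each pool. On biallelic sites
ED = √2·|Δ| identically (asserted as a test oracle); the k-th power
suppresses sampling noise relative to true signal. k = 5 is the
conventional choice in ED scans and is configurable.

### Windows and thresholds

Per-site statistics are averaged in sliding windows (defaults: 1 Mb
window, 100 kb step, ≥10 sites per window — chosen to resolve an interval
of a few Mb on a ~100 kb marker grid; all configurable).

Two null-calibrated cutoffs decide significance:

* **Δ threshold** — simulated from the null of no linkage: each pool's
  allele frequency is the mean of `bulk_size` F2 dosages
  (Binomial(2, ½)), reads are binomial at the observed median depth, and
  the cutoff is the (1−α) quantile of the null |Δ̄| (α = 0.05 default).
  Because sites within a window are tightly linked, their
  bulk-composition noise is shared while read noise averages out; the
  null therefore draws one frequency pair per simulated window and `k`
  read draws (`n_sites_per_window`, set from the median window
  occupancy). Calibrated this way, the per-window false-positive rate on
  phenotype-blind bulks is close to nominal (checked in the tests at
  α = 0.05 over 100 null replicates).
* **ED^k threshold** — the genome-wide median + 3·SD of per-site ED^k,
  the conventional rule for ED scans. This rule presumes the linked
  region is a small fraction of the genome; on a genome where most sites
  are linked to the locus the SD is inflated by the signal itself.

Runs of consecutive significant windows (bridging single non-significant
windows, and merging runs whose spans overlap) become **candidate
regions**; ties at a threshold count as significant. Regions may be
called on Δ, ED, or their intersection (default), mirroring the practice
of requiring both statistics to agree.

## Expression stage

Gene abundance is FPKM: `count · 10⁹ / (library_size · length_bp)`. The
differential test is deliberately transparent: log2FC is taken on mean
CPM with a 0.5 pseudo-count, and the p-value is a pooled-variance
two-sample t-test on log2(CPM + 0.5) across replicates. With three
replicates per group, pooling keeps the residual df at 4; an
unequal-variance test would be nearly powerless at this design size.
Multiple testing uses the Benjamini–Hochberg step-up. A gene is a DEG
when max(FPKM) is strictly above 0.1, |log2FC| ≥ 1, and adjusted
p ≤ 0.05. Direction is reported relative to normal ears ("up" = higher
in normal). CPM normalization uses library size only (no TMM) — a known
limitation; composition effects from very asymmetric DE are not
corrected.

This test is not an empirical-Bayes negative-binomial model: it does not
share dispersion information across genes, so it is less powerful than
edgeR/DESeq2 at very low counts. At the effect sizes the filter chain
targets (|log2FC| ≥ 1 at moderate abundance) the calls coincide; the
test is isolated behind `de_test` and swappable.

## Integration and ranking

Genes overlapping a candidate region by ≥1 bp (any-overlap — boundary
genes matter at Mb scale) are intersected with the DEG list, preserving
genomic order. Candidates are ranked by focal-tissue abundance
(descending, gene-id tie-break); candidates below 1 FPKM are flagged as
low-expressed. Cross-tissue specificity atlases are out of scope; the
single focal-tissue column stands in for that evidence.

## Classical statistics

* Segregation: χ² goodness of fit against an expected ratio (3:1
  default), no continuity correction, compared to the upper-α critical
  value at df = 1.
* Trait contrasts: Welch t from mean/SD/n summaries
  (Welch–Satterthwaite df); a pooled-variance variant is available. With
  balanced n = 40/40 and near-equal SDs the two are indistinguishable.
* Percent change: 100·(alt − ref)/ref, 1 d.p.
* LD: squared Pearson correlation of inbred dosages.
* Haplotype association: Welch t between haplotype groups plus percent
  variance explained, PVE = 100·(between-group SS / total SS) — the R²
  of the one-way group model, equal to the squared point-biserial
  correlation (asserted in tests).

## The synthetic-data generator

The generator forward-simulates the whole study so that every stage can
be validated against known truth. What it emulates, and the defaults:

* **Cross**: F2 from mutant × reference line; every marker is
  informative with the mutant allele as ALT. Gametes are Markov walks
  over the marker grid with Haldane recombination
  (r = ½(1 − e^(−2d))) at a uniform 1 cM/Mb. Phenotype is recessive on
  the F2 individuals themselves. (The field design phenotyped
  F2-derived families; for a fully penetrant recessive the pool
  allele-frequency expectations are identical, so the simpler direct-F2
  model is used.)
* **Genome**: 10 chromosomes × 60 Mb, markers every 100 kb, causal locus
  on chr4 at 8 Mb, n_f2 = 400. This is scaled down from a real maize
  genome but keeps the feature the scan statistics rely on: the region
  linked to the locus is a small fraction of the genome. One replicate
  simulates in a fraction of a second.
* **Pools**: bulks of 50 + 50; pool depth Poisson with means 71× (mutant
  bulk) and 44× (normal bulk); alt reads Binomial(depth,
  f(1−e) + (1−f)e) with per-read miscall e = 0.001.
* **Counts**: negative binomial via gamma–Poisson, dispersion 0.02
  (biological CV ≈ 14%, the replicated-inbred-line regime), baseline
  means uniform on [20, 500], three replicates per condition; planted
  DEGs draw |log2FC| from a configurable range, two of them inside the
  causal interval by default.
* **Panel**: 350 inbred lines; three promoter SNPs copy one latent
  haplotype with flip probability 0.002 each (pairwise r² ≈ 0.95);
  trait = 14 + effect·(Hap1) + N(0, 2²) kernel rows, with the effect
  sized analytically for a requested PVE (7.9% default) via
  b = s·sqrt(PVE/(1−PVE)/q(1−q)). Lines whose three SNPs disagree get
  no haplotype label, mimicking panel attrition.

All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawning.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: non-uniform recombination and marker
density, segregation distortion, incomplete penetrance or phenotyping
error, mapping/alignment artifacts and reference bias in the depths,
library-composition effects in the counts, and population structure or
kinship in the panel. The validation demonstrates the statistical chain
is correct and calibrated under its own model, not that the model
captures every property of field data.

## Numerical choices and degenerate inputs

* Zero-total-depth sites are excluded from the scan, never silently 0.
* Frequency vectors must sum to 1 within 1e-6 for ED.
* Thresholds: ties count as significant; thresholds are reproducible
  given the seed (null quantile SD < 0.01 at n_sim = 10,000).
* BH is order-stable; p-values outside [0, 1] are fatal.
* Zero-variance t-tests: p = 1 for equal means, p = 0 (flagged
  degenerate) otherwise; all-zero genes give (log2FC, p) = (0, 1).
* Multiallelic VCF sites are skipped (the statistics are written for
  biallelic frequencies); indels flow through like SNPs.
* Coordinates are 1-based inclusive internally; BED converts at the
  boundary, and regions export as 0-based half-open BED.

## Problem sizes used in validation

The test suite and the acceptance script run the simulator at the study
scale for the parameters that matter (bulks of 50+50, depths 71×/44×,
panel of 350) and use 10–200 seeded replicates per property, with the
reduced genome above; these sizes give stable Monte-Carlo estimates for
the quantities asserted (e.g. SE of the mean Δ at the causal locus
< 0.005 at 200 replicates) while keeping a full run in minutes.

## Known limitations

* The Δ null ignores double reduction, segregation distortion, and
  mapping bias; it calibrates read + bulk sampling noise only.
* The ED threshold rule (median + 3 SD) is heuristic; its false-positive
  behaviour is checked empirically rather than derived.
* The DE test is per-gene; no dispersion shrinkage, no TMM.
* PVE is the unadjusted R² of the group model and carries the usual
  small upward finite-sample bias (~0.3 points at n = 350).
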