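# Methods

## Problem and pipeline

Given a multi-sample VCF for a regional cohort, a BED file of capture
targets, and per-population allele-frequency catalogues, the pipeline
identifies variants that are common in the region (folded minor allele
frequency, MAF > 1%) and rare (MAF ≤ 1%) in every reference population,
validates them in a second regional cohort, and quantifies how much a
regional catalogue sharpens per-patient frequency filtering. Stages run in
a fixed order: site selection → discovery QC → cohort catalogue →
cross-population classification → validation → population-structure
statistics → per-patient retention benchmark. Every removed site is
attributed to exactly one rule so the counts telescope.

## Site selection and quality control

Analysis is restricted to biallelic autosomal SNVs (single-base ref and alt
in {A,C,G,T}, exactly one ALT, chromosomes 1–22) whose 1-based position
falls inside the target-interval union. Multiallelic records are excluded
whole, not split: splitting would redistribute allele counts between the
split records and change MAF classifications. Sex chromosomes are excluded
to avoid sex-composition bias, the mitochondrial genome because its
heteroplasmy breaks the diploid dose model.

Two regimes share one implementation and differ only in thresholds
(`QcThresholds`):

| parameter      | discovery | validation | failing side |
|----------------|-----------|------------|--------------|
| min depth (reads)   | 10   | 10         | DP < 10 masks the call |
| min GQ (phred)      | 50   | 50         | GQ < 50 masks the call |
| min call rate       | 1.0  | 0.8        | rate < threshold drops the site |
| HWE alpha           | 1e-5 | 1e-5       | p < 1e-5 drops the site |

All comparisons are strict on the failing side: DP = 10 passes, HWE
p = 1e-5 exactly is retained. Call-level masks are applied *before* the
call rate is computed, so a masked call counts as missing. Genotypes with
any missing allele (including half-calls like `./1`) are missing; phased
and unphased separators are equivalent. When a merged VCF lacks DP or GQ
entirely the corresponding filter is skipped with a warning rather than
emptying the matrix.

## Hardy–Weinberg exact test

The test conditions on the observed allele counts: for genotype counts
(n₀, n₁, n₂) with n = n₀+n₁+n₂, the probability of h heterozygotes is
proportional to the multinomial coefficient times 2^h, and the p-value sums
P(h) over all attainable h (same parity as the rare-allele count) with
P(h) ≤ P(n₁). Probabilities are built by a ratio recurrence outward from
the modal heterozygote count, which is numerically stable for any n, then
normalised. Ties in P(h) are compared with a relative guard of 1e-10 so
that equal probabilities split by floating-point rounding still count as
ties. A monomorphic site has a single attainable configuration and p = 1.
The test is the standard exact test, not the mid-p variant, matching the
default behaviour of the common tooling for this statistic. The test is
applied to all cohort samples (the cohort is already reduced to unrelated
individuals before QC).

## Relatedness

Method-of-moments IBD: per pair, identity-by-state (IBS = 2 − |dose₁ −
dose₂|) is tallied over informative sites (both calls present, frequency
strictly inside (0,1)), and the observed IBS-class counts are equated with
their expectations given allele frequencies under IBD states 0, 1, 2 to
solve for (k0, k1, k2). The raw solution is clipped to [0,1] and
renormalised to the simplex; PI_HAT = k1/2 + k2. Frequencies default to
cohort estimates; no small-sample correction is applied — with the ≥ 200
informative sites the estimator requires, the bias is far below the 0.05
tolerance used for classifying duplicate (≈1), parent-offspring (≈0.5) and
unrelated (≈0) pairs. Unrelated-sample selection is greedy: repeatedly drop
the sample in the most pairs with PI_HAT ≥ 0.1875 (ties broken by sample-id
order), until no such pair remains. The 0.1875 default is the midpoint
between the second-degree (0.25) and third-degree (0.125) expectations, a
conventional cut when no threshold is prescribed.

## Frequencies, MAF and composite references

MAF is folded: min(f, 1−f) of the alternate-allele frequency. At the
frequencies where common/rare classification matters (≈1%) folded and raw
frequencies coincide. The common/rare boundary is strict — common ⇔
MAF > 0.01 — with a 1e-12 tie guard because folding computes 1−f in binary
floating point (1 − 0.99 is representably above 0.01; the guard keeps a
frequency exactly at the boundary classified as rare).

Two composite constructions:

* **allele pooling** (for cohorts of genotyped samples, e.g. an Iberian
  panel plus a national panel): summed alternate-allele counts over summed
  total counts. Inputs must carry counts; frequency-only catalogues are
  rejected. A variant absent from a fully genotyped panel (single
  per-site total) contributes that panel's total as reference alleles.
* **unweighted mean of population frequencies** (for a many-population
  project with near-equal cohort sizes): the arithmetic mean of
  per-population alternate frequencies, with absent variants contributing
  0. Unweighted, so no single population dominates.

A variant absent from any reference catalogue is assigned frequency 0
(rare). Absence from a large panel is evidence of rarity, and it is the
only convention under which exclusive-common discovery is well defined for
variants private to the target cohort.

## Discovery, saturation, validation, retention

Classification runs over the union of variant keys across the panel. Each
variant's category is the subset of populations in which it is common (the
upset-plot structure); exclusive ⇔ common in the target only. Output
ordering and the category table are invariant to reference order.

Saturation draws, for each cohort size n, random sample subsets without
replacement (default 25 replicates), recomputes subset MAFs (no re-QC — the
minimal recomputation that isolates the sampling effect), and counts common
variants. The plateau is the smallest n whose mean count is within
`rel_tol × full count` of the full-cohort count; `rel_tol` defaults to 0
(no new variants at all) with 1% used in the saturation analyses reported
here, since at finite replicate counts a mean equality test is
degenerate.

Validation restricts the second cohort's matrix to the candidate list
(absent candidates reported), applies the relaxed QC regime, and confirms
candidates whose validation MAF is again common. For unconfirmed
candidates, 2-fold concordance is max(MAF_d, MAF_v)/min(MAF_d, MAF_v) ≤ 2,
undefined (not concordant) when either MAF is 0. The summary's exact
binomial test of the confirmed proportion uses a configurable null
(default 0.5) — a labelled reporting convention, since no specific sampling
null is implied by the design.

The per-patient benchmark defines a patient's variant list as all sites
with alternate dose ≥ 1 (het or hom), filters it against each catalogue
(removing catalogue-common variants, retaining catalogue-absent ones), and
summarises the retained fraction per catalogue by median and quartiles,
ordered most-stringent first.

## Population structure

PCA standardises each polymorphic site by centring on the mean dose and
scaling by √(2p̂(1−p̂)); missing doses are mean-imputed before scaling,
monomorphic and all-missing sites are dropped with a warning. Scores come
from an SVD, with a deterministic sign convention (the largest-magnitude
loading of each component is positive). Explained-variance fractions are
eigenvalues over total variance of the standardised matrix; degenerate rank
returns fewer components with a warning.

F_ST uses the Weir–Cockerham (1984) variance components for a biallelic
locus — among-population (a), among-individual (b), within-individual
(c) — computed from per-population sample sizes, allele frequencies and
observed heterozygosities. The pairwise estimate is the ratio of sums
Σa/Σ(a+b+c) over usable sites (the "weighted" estimate), with the per-site
mean also reported. Sites monomorphic across the populations contribute
(0,0,0) and are excluded from the ratios. Negative estimates are reported
as computed and flagged, not clamped.

## Synthetic cohorts and ground truth

The generator emulates the study design end to end. Ancestral frequencies
are uniform on [0.005, 0.5]; each population's frequency is a
Balding–Nichols draw, Beta(p(1−F)/F, (1−p)(1−F)/F), so the divergence
parameter F is on the same scale as the Weir–Cockerham estimate the
pipeline produces. Genotypes are Hardy–Weinberg binomial draws. Default
cohort structure mirrors the study scale: a 358-diploid discovery cohort
and 239-diploid validation cohort from the same target population; a
107-diploid and a 267-diploid Spanish-like panel whose counts pool into
`spain`; 25 reference-project populations of 100 diploids each (4 European,
4 admixed-American, 5 South-Asian, 5 East-Asian, 7 African) averaged into
`KGP_noIBS`; and a 15,691-diploid aggregate (`gnomAD`). Reference
catalogues carry binomially sampled allele counts, so reference sampling
noise is part of the test conditions. Divergence defaults (target and
sister panel 0.0005–0.001; European 0.004–0.008; admixed-American 0.015;
South-Asian 0.025; East-Asian 0.03; African 0.045; aggregate 0.01) are
typical continental-scale fixation indices for a south-European target.

Forty sites are spiked exclusive-common by default: target frequency
uniform on [0.03, 0.10], every reference frequency uniform on [0, 0.002].
Per-call read depth is negative-binomial (mean 30, size 200 — near-Poisson,
emulating well-covered 30× data), GQ is 99 with a 1e-5 chance of a draw
below 50, and calls go missing at rate 1e-5; at these defaults a 358-sample
site survives the 100% call-rate rule with probability ≈0.98, so QC removes
a small, realistic fraction of sites. Optional planted low-depth sites and
injected duplicate / parent-offspring pairs give QC and relatedness checks
known casualties. Everything is a pure function of (config, seed).

What the generator does **not** emulate: linkage disequilibrium (sites are
independent), the rare-variant tail below ancestral frequency 0.005 (real
exomes are dominated by singletons, so absolute per-patient retention
percentages are not comparable to real data — only the ordering of
catalogues by stringency is meaningful), genotyping error correlated with
genotype, batch effects between the WGS-like and WES-like cohorts, and
demographic history beyond the single-parameter divergence model. Passing
tests therefore demonstrate correctness of the statistics and the relative
behaviour of the pipeline, not absolute counts expected on real cohorts.

## Ground truth for discovery error rates

Spiked sites are planted strong effects and define *sensitivity*. False
discoveries are measured against genuine exclusivity: a discovered variant
counts as false only if it is not truly exclusive-common under the
simulator's true per-population frequencies, with composites built by the
same pooling/mean rules the pipeline uses
(`SimulatedStudy.true_exclusive_keys`). Drift alone makes a handful of
unplanted boundary variants genuinely exclusive-common; counting their
discovery as error would misstate the method's accuracy. Residual false
discoveries are 1%-boundary flips caused by finite cohort and panel sizes —
an irreducible property of threshold classification on point estimates that
the validation stage is designed to catch.

## Problem sizes used in the shipped analyses

Unit tests run on scaled-down cohorts (60–80 diploids, 400 sites). The
acceptance analyses use the study-scale defaults: 50 replicate studies of
2,000 sites for spike-in recovery; 20 replicates of 2×100 diploids × 5,000
sites per divergence level for F_ST recovery; all ≈5,500 genotype-count
triples with n ≤ 30 for HWE exactness; 50 replicates each for relatedness
ranking and retention ordering. The full suite runs in about a minute on
one CPU.
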