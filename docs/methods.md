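# Methods

This note documents the statistical procedures implemented in `tapirkin`,
the defaults they ship with, and what the synthetic-data generator does
and does not emulate.

## Consensus genotyping (multiple-tube protocol)

Non-invasive fecal DNA suffers allelic dropout (a heterozygote's allele
failing to amplify), false alleles and whole-PCR failures. The
multiple-tube rule accepts a genotype only when the *same unordered
allele pair* is observed at least `min_consistent` (default 3) times
among the first `max_reps` (default 7) PCRs; partial (single-allele)
matches do not count. A run of `max_consecutive_failures` (default 5)
failed PCRs before any pair reaches the threshold discards the
sample-locus; the rule is evaluated sequentially in replicate order
because the protocol it models is sequential. If two distinct pairs both
reach the threshold the call is ambiguous: at the level of a single call
this is an error (it can signal contamination), while the panel-level
driver treats it as a discarded sample-locus, because heavy dropout can
legitimately push a false homozygote to the threshold alongside the true
heterozygote and discarding is the protocol response at the PCR cap.

Single-allele replicate rows are read as homozygote observations
(electropherogram convention), which keeps the dropout process
expressible in the input format.

Recaptures: samples whose genotypes agree exactly at every mutually typed
locus, with at least 3 such loci, are merged as one individual (union-find,
hence order-independent). Exact-match identity is defensible when the
multilocus P(ID)sib of the panel is below 0.01. Under genotyping error a
transitive merge can rarely expose a conflicting locus between indirect
members; that locus is demoted to missing with a warning rather than
aborting, since the conflicting calls are by construction unreliable.

## Per-locus summaries

Pairwise (locus-wise) deletion is used throughout, so N varies per locus.
Unbiased expected heterozygosity is Nei's He = 2n/(2n−1)·(1 − Σpᵢ²).
The Hardy–Weinberg exact test draws random re-pairings of the observed
allele multiset and compares Levene's conditional probability of the
resulting genotype table with that of the observed table (add-one
corrected p-value); Monte-Carlo resampling is used because full
enumeration explodes beyond ~6 alleles, and an enumeration oracle covers
small tables in the test suite. Bonferroni correction uses the plain
α/k threshold.

Probability of identity: with aₖ = Σᵢ pᵢᵏ,

* P(ID) = 2a₂² − a₄ (unrelated pair, HW proportions);
* P(ID)unbiased = [n³(2a₂² − a₄) − 2n²(a₃ + 2a₂) + n(9a₂ + 2) − 6] /
  [(n−1)(n−2)(n−3)], the Paetkau small-sample-corrected estimator with
  n the number of genotyped individuals (undefined for n < 4; converges
  to the uncorrected form as n → ∞);
* P(ID)sib = ¼ + ½a₂ + ½a₂² − ¼a₄ (full-sib pair, the hardest case).

Multilocus values are products over loci (independence across loci).

F-statistics between margins use the Weir–Cockerham (1984) variance
components summed over alleles and loci (θ̂ for F_ST, f̂ for F_IS).
Significance is by permutation: individuals across groups for F_ST,
re-pairing alleles among individuals within groups for F_IS. This
replaces an AMOVA implementation: for a two-group co-dominant design the
estimators are numerically equivalent and far simpler.

## Relatedness estimators

Both moment estimators are asymmetric in the reference individual and are
symmetrised by averaging the two orientations; locus numerators and
denominators are pooled across loci before the ratio (for LR99 the
pooling weights are the locus weights of the original estimator). Loci
with a zero denominator for an orientation are dropped for that
orientation — for QG89 this includes a heterozygous reference at a
two-allele locus; for LR99 only degenerate frequency configurations.
Allele frequencies are computed from the full panel *including* the focal
dyad (the default of the programs in common use); a leave-two-out variant
would change estimates by O(1/n) and is not implemented.

Bootstrap confidence intervals resample loci with replacement (1000
replicates, percentile method). The locus is the only defensible
resampling unit with a 5-locus panel; the resulting intervals are wide
and their lower bounds drive the conservative behavior of the CI-based
classifier. Resamples in which the estimator is undefined are redrawn up
to a 10× draw inflation and then dropped.

## Dyad likelihoods and pedigree LRTs

At one locus, P(G₁,G₂ | k) = k₀P(G₁)P(G₂) + k₁P(G₁)T₁(G₂|G₁) +
k₂P(G₁)1[G₁=G₂], where T₁ passes one uniformly chosen allele of G₁
identical by descent and draws the rest from the population. The
likelihood sums to 1 over ordered genotype pairs and is symmetric in the
two genotypes for the canonical categories (both enumerated in tests).
Canonical IBD coefficients: PO (0,1,0), FS (¼,½,¼), HS (½,½,0), first
cousins (¾,¼,0), UN (1,0,0).

Five primary-vs-null comparisons are tested per dyad: PO vs {FS,UN},
FS vs {HS,UN}, HS vs {cousin,UN}, cousin vs {UN}, UN vs {PO,FS,HS,cousin}.
The statistic is logL(primary) − max logL(null); its p-value is the
add-one-corrected proportion of dyads simulated under the equal-weight
null mixture with a statistic at least as large. Null distributions
depend only on the locus set, so they are cached and shared across dyads
(seeded independently of the data via a stable hash of the comparison).
The accepted hypothesis has the lowest p; because Monte-Carlo p-values
have a floor of 1/(n_sims+1), ties break first toward the
best-fitting (highest log-likelihood) hypothesis and only then toward the
less related one — a pure "less related wins" rule would label an
identical-genotype dyad a cousin whenever several comparisons saturate.

Likelihood evaluation, simulation and the LRTs run on precomputed
per-locus genotype-pair probability tables (G×G per category), which
keeps the per-dyad cost at array lookups.

## Classification cascade

1. Allele-sharing rule: ≥7 shared alleles (multiset intersection summed
   over loci) at ≥0.8 of the mutually typed loci ⇒ FO. Requires ≥4 loci.
2. CI bands on each estimator's bootstrap interval: lower ≥0.5 FO;
   [0.25,0.5) HS/FO1; [0.125,0.25) HS/FO2; upper ≤0 UN; otherwise IN
   (the wording "lower bound in (0,0.125) or interval spans zero and
   related values" is read as: any interval not falling in the previous
   bands). Agreement of the two estimators (or a single available CI)
   decides; a disagreement goes to the less related band unless the
   accepted LRT hypothesis (p < 0.05) is compatible with the more
   related band.
3. HS/FO1 and HS/FO2 collapse to "HS" in final counts, which report only
   FO/HS/UN/IN.

The precedence (sharing → CI consensus → LRT tie-break) is pinned here
because the source protocol combined the three evidence streams
case-by-case without a stated algorithm; every decision records which
rule fired (audit trail column).

## Calibration error accounting

Simulated truth categories PO, FS (jointly "FO"), HS and UN, 100 dyads
each by default. Rates per classifier:

* type I — true-UN dyads positively classified as related;
* type II — true-related dyads classified UN;
* misFO — true-FO dyads positively classified into a category that
  *excludes* first order (strict HS or UN);
* misHS/UN — true-HS/UN dyads classified strictly FO.

An inconclusive call is a refusal to classify, not a positive call: it
counts toward none of the four rates (a `mis_fo_incl_inconclusive`
column is reported for transparency). This accounting is what makes a
CI-with-inconclusive method dominate point-estimate thresholds — IN
absorbs exactly the dyads that point estimators are forced to call — and
it reproduces that dominance ordering on the reference-panel frequencies.
The HS/FO bands include first order, so they are neither misFO nor
strict-FO.

## Spatial statistics

Distances are planar Euclidean meters (projected coordinates); water is
ignored, matching the straight-line convention of the source protocol.
The Mann–Whitney statistic is W = (rank sum of the first sample, midranks
for ties) − n₁(n₁+1)/2, with full enumeration when n₁+n₂ ≤ 12 and a
tie-corrected, continuity-corrected normal approximation otherwise.
"Related" means final category FO ∪ HS; IN pairs are excluded.

The Mantel statistic is the Pearson correlation of upper-triangle
entries (missing entries masked pairwise) with row/column permutation of
one matrix; the default tail is one-sided negative because the biological
hypothesis is that relatedness falls with distance.

Moran's I of allele sharing: each individual scores dosage/2 (0, ½, 1)
per allele per locus; per-allele I values with binary distance-class
weights are combined with allele-variance weights (equivalent to pooling
numerators and denominators), giving one I per distance class —
individual scale (< 3 km, strictly; a pair at exactly the threshold is
landscape) and landscape scale (≥ 3 km). The permutation-null mean is
−1/(N−1), verified in tests. CIs are 95% percentile bootstrap over
individuals; self-pairs created by resampling the same individual twice
are excluded. This naive individual bootstrap is known to be biased
slightly downward for weakly autocorrelated data (resampled duplicates
inflate the variance denominator without contributing pairs), so the
bootstrap SD is reported alongside and the CI should be read as a
variability measure, not a strict coverage interval. Published "±" values
for this statistic are ambiguous between SE and CI half-width; both
outputs are labeled.

Distance summaries per category use midpoint interpolation for quartiles
(quartile conventions differ across software and must be pinned for
reproducibility) and are reported in km.

## Mating-system arithmetic and population size

Bayes factors are BF_m = 2·(logL_m − max logL) on natural-log
likelihoods, the only convention consistent with published tables of this
design; values below −2 flag a significantly worse model. Posteriors are
exp(BF)/Σexp(BF) under equal priors; `bf_precision` optionally rounds the
BFs first, matching tables whose posterior column was derived from the
printed (1-decimal) BF column. Sibship/pedigree likelihood computation
itself is out of scope — this module consumes log-likelihoods.

θ = 4Nₑμ conversions assume a per-locus per-generation microsatellite
mutation rate; defaults span 10⁻⁴–5·10⁻⁴ (the range used for mammals).
Census size uses an Nₑ:N ratio of 10 by default.

## Synthetic-data generator

The generator's defaults mirror the reference study's scale: 5 loci with
allele richness (7, 6, 10, 5, 5) and expected heterozygosities within
0.03 of (0.78, 0.77, 0.86, 0.81, 0.63) — frequencies are Dirichlet draws
interpolated toward the uniform vector until 1 − Σp² hits the target —
32 individuals (12 unrelated founders + 20 offspring) under polygamous
mating on a 30 × 20 km two-margin landscape, exponential dispersal with
a 5 km mean (consistent with observed first-order pair distances spanning
0.1–30 km), 7 replicate PCRs per sample-locus with dropout 0.10 per
allele, false alleles 0.02 and failures 0.20 per PCR (mid-range values
for fecal DNA), and 4 individuals sampled twice within 1 km.

By default the population is redrawn until all multilocus genotypes are
distinct, emulating a study system where the panel's P(ID) certifies that
genotype identity uniquely flags recaptures; without this, two sibs share
a full 5-locus genotype about once per hundred sib pairs and the
recapture count becomes ill-defined.

What the generator does **not** emulate: island raster geometry and
water-mediated movement (dispersal is isotropic), age structure and more
than two generations (so cousins never arise from the pedigree; they are
simulated directly from k-coefficients where needed), linkage and
inbreeding (loci are independent, founders unrelated), and null alleles
or stutter. Consequently, passing tests demonstrate correctness of the
statistical machinery under the stated error model, not robustness to
null alleles, population structure or pedigree depth beyond two
generations.

## Numerical and reproducibility choices

All randomness flows from explicit seeds; the pipeline derives per-stage
substreams from one root seed via stable hashes, so stage outputs are
pure functions of (inputs, config) and reruns are byte-identical. Add-one
correction is applied to every permutation/Monte-Carlo p-value.
Bootstrap percentile intervals may exclude the point estimate for skewed
resampling distributions; this is expected behavior, not an error.
Monomorphic loci have He = 0, HWE p = 1, and carry no relatedness
information (dropped from estimators). The problem sizes used by the
acceptance script — 100 dyads per category for calibration, 2000 per
category for estimator recovery, 4000 permutations for the Moran null —
are the study's own design sizes or modest multiples chosen for stable
Monte-Carlo error.

## Known limitations

* With 5 microsatellites, bootstrap CIs over loci are wide; most pairs in
  a real survey land in the inconclusive class (as in the reference
  study, where 186 of 231 pairs were IN). This is a property of the
  design, not a defect of the estimator.
* Relatedness estimators assume known allele frequencies; with ~30
  individuals the sampling error of the frequencies propagates into a
  small bias that the locus bootstrap does not capture.
* The likelihoods ignore genotyping error; they are applied to consensus
  genotypes that the multiple-tube protocol has already error-screened.
* The published per-pair supplementary table of the reference study is
  available only as a journal XLS attachment; the test that reproduces
  its final category counts and distance statistics runs only when a
  text export of that table is supplied.
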