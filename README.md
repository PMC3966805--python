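# tapirkin

Microsatellite kinship and spatial-genetic analysis for non-invasively
sampled wildlife populations.

`tapirkin` implements the full analysis chain used in fecal-DNA kinship
studies of elusive mammals, modelled on a survey of lowland tapirs
(*Tapirus terrestris*) in the Balbina reservoir landscape (central
Amazon): replicate PCRs of degraded samples are collapsed into consensus
genotypes, identical genotypes are merged as recaptures of one individual,
pairwise relatedness is estimated and classified against
simulation-calibrated expectations, and spatial statistics test whether
relatives live closer together than non-relatives.

## What it computes

* **Multiple-tube consensus genotyping** — a genotype is accepted when the
  same unordered allele pair is observed at least 3 times within 7 PCRs;
  5 consecutive amplification failures discard the sample-locus.
  Recaptures are identified by exact genotype identity at ≥3 mutually
  typed loci, justified by the panel's probability of identity
  (P(ID)sib < 0.01).
* **Per-locus summaries** — allele frequencies, observed and unbiased
  expected heterozygosity, Monte-Carlo exact tests of Hardy–Weinberg
  proportions with Bonferroni correction, P(ID) statistics
  (P(ID) = 2a₂² − a₄ with aₖ = Σᵢ pᵢᵏ, its small-sample-corrected
  estimator, and the full-sib variant
  P(ID)sib = ¼ + ½a₂ + ½a₂² − ¼a₄), gene diversity, and
  Weir–Cockerham F_ST/F_IS with permutation tests.
* **Pairwise relatedness** — the Queller–Goodnight (r_QG89) and
  Lynch–Ritland (r_LR99) estimators, symmetrised over reference
  individuals and pooled across loci; 95% percentile bootstrap confidence
  intervals over loci; allele-sharing statistics; IBD dyad likelihoods
  P(G₁,G₂ | k₀,k₁,k₂) and Monte-Carlo likelihood-ratio tests of the
  standard pedigree hypotheses (PO, FS, HS, first cousins, UN).
* **Relationship classification** — a deterministic, audited cascade:
  an allele-sharing rule (≥7 shared alleles at ≥0.8 of the loci ⇒
  first-order), CI bands on the bootstrap interval (lower bound ≥0.5 FO,
  ≥0.25 HS/FO1, ≥0.125 HS/FO2; upper ≤0 UN; otherwise inconclusive), and
  an LRT tie-break when the two estimators disagree.
* **Calibration** — dyads simulated in known categories from the panel's
  allele frequencies give each classifier's type I, type II, misFO and
  misHS/UN error rates, reproducing the finding that a CI method with an
  inconclusive class dominates point-estimate thresholds.
* **Spatial statistics** — Euclidean distances, Mann–Whitney comparison of
  related vs unrelated pair distances, Mantel tests of r against
  distance, and Moran's I of allele sharing at an individual (<3 km) vs
  landscape (≥3 km) scale with bootstrap CIs.
* **Demographic arithmetic** — mating-system Bayes factors
  (BF = 2·ΔlogL vs the best model) and posteriors from supplied
  log-likelihoods, and θ = 4Nₑμ conversions to effective and census
  population sizes.
* **Synthetic study generator** — loci matched to the reference panel
  (allele richness 7, 6, 10, 5, 5; He 0.78, 0.77, 0.86, 0.81, 0.63), a
  two-generation pedigree under monogamy/polygyny/polygamy on a
  two-margin landscape, and replicate PCRs with dropout, false-allele and
  failure errors — with complete truth tables, so the whole pipeline is
  testable without any external data.

## Worked example

Generate a synthetic study (32 individuals, 5 loci, polygamous mating,
noisy PCRs, 4 recaptured individuals) and run the full pipeline:

```sh
tapirkin simulate --seed 3 --out sim
tapirkin run --replicates sim/replicates.csv --meta sim/metadata.csv \
    --boot 300 --null-sims 300 --permutations 100 --seed 3 --out run
```

The run report printed at the end (also in `run/report.txt`):

```
n_samples: 36
n_unique_individuals: 32
p_id_unbiased: 3.4756296747442375e-06
p_id_sib: 0.010819403577903388
gene_diversity_mean: 0.7542
gene_diversity_sd: 0.0486
f_st: -0.0037 (p=0.554)
f_is: -0.0467 (p=0.337)
count_FO: 13
count_HS: 20
count_UN: 112
count_IN: 290
mann_whitney_W: 1431 (p=0.050)
mantel_r: -0.04041 (p=0.218)
mantel_r: -0.04867 (p=0.059)
moran_individual: -0.0764 ci=(-0.3069, 0.1086) n_pairs=22
moran_landscape: -0.0323 ci=(-0.0914, -0.0488) n_pairs=413
```

Reading this: the 36 fecal samples collapse to 32 unique individuals (the
4 planted recaptures were caught); the multilocus P(ID)sib ≈ 0.011 says
two full sibs share a genotype about once in a hundred pairs, so exact
genotype matches are safely treated as recaptures; F-statistics between
the two margins are indistinguishable from panmixia; the classifier calls
13 first-order, 20 half-sib, 112 unrelated and 290 inconclusive pairs;
and neither the Mann–Whitney distance comparison, the Mantel tests (one
per estimator) nor the two-scale Moran's I show relatives living closer
together — as expected for a dispersing, non-philopatric population
simulated with a 5 km dispersal kernel.

Mating-system arithmetic from a table of model log-likelihoods:

```sh
$ tapirkin models --loglik loglik.tsv
                model  log_likelihood  bayes_factor  significantly_worse    posterior
             polygamy         -796.38          0.00                False 1.000000e+00
polygyny_or_polyandry         -809.17        -25.58                 True 7.775837e-12
             monogamy         -815.89        -39.02                 True 1.131955e-17
$ tapirkin ne --theta 6.5 --mu 1e-4
Ne = 16250
census (ratio 10) = 162500
```

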