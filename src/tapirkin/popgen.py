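"""Per-locus summary statistics for a microsatellite panel.

Allele frequencies, observed/unbiased expected heterozygosity, Monte-Carlo
exact tests of Hardy-Weinberg proportions, Bonferroni correction,
probability-of-identity statistics (biased, sample-size-corrected and
sib-pair variants), gene diversity, and Weir-Cockerham F-statistics between
groups with permutation tests.

Missing genotypes are handled by pairwise (locus-wise) deletion throughout,
so the number of typed individuals N can differ between loci.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypePanel

logger = logging.getLogger("tapirkin")


@dataclass
class LocusFrequencies:
    """Allele relative frequencies at one locus plus the typed count."""

    locus: str
    freqs: dict[int, float]
    n_typed: int
    monomorphic: bool

    def power_sum(self, k: int) -> float:
        """a_k = sum_i p_i^k."""
        return float(sum(p**k for p in self.freqs.values()))


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele frequencies estimated from a panel."""

    loci: dict[str, LocusFrequencies]

    def __getitem__(self, locus: str) -> LocusFrequencies:
        return self.loci[locus]

    def __contains__(self, locus: str) -> bool:
        return locus in self.loci

    @property
    def locus_names(self) -> list[str]:
        return list(self.loci)


@dataclass
class FStatsResult:
    f_st: float
    f_is: float
    p_st: float
    p_is: float
    n_permutations: int


@dataclass
class GeneDiversity:
    mean: float
    sd: float


def allele_frequencies(panel: GenotypePanel) -> AlleleFrequencyTable:
    """Allele relative frequencies per locus (copies / typed copies)."""
    loci = {}
    for name in panel.locus_names:
        counts: dict[int, int] = {}
        n_typed = 0
        for ind in panel.individuals:
            g = ind.genotype.get(name)
            if g is None:
                continue
            n_typed += 1
            for allele in g:
                counts[allele] = counts.get(allele, 0) + 1
        if n_typed == 0:
            raise ValueError(f"locus {name}: no typed individuals")
        total = 2 * n_typed
        freqs = {a: c / total for a, c in sorted(counts.items())}
        mono = len(freqs) == 1
        if mono:
            logger.info("locus %s is monomorphic in this panel", name)
        loci[name] = LocusFrequencies(name, freqs, n_typed, mono)
    return AlleleFrequencyTable(loci)


def heterozygosities(panel: GenotypePanel) -> pd.DataFrame:
    """Observed and unbiased expected heterozygosity per locus.

    Ho is the fraction of typed individuals that are heterozygous; He uses
    Nei's small-sample correction He = 2n/(2n-1) * (1 - sum p_i^2) with n
    typed individuals.
    """
    freqs = allele_frequencies(panel)
    rows = []
    for name in panel.locus_names:
        lf = freqs[name]
        het = sum(
            1
            for ind in panel.individuals
            if (g := ind.genotype.get(name)) is not None and g[0] != g[1]
        )
        ho = het / lf.n_typed
        if lf.monomorphic:
            he = 0.0
        else:
            n = lf.n_typed
            he = (2 * n / (2 * n - 1)) * (1.0 - lf.power_sum(2))
        rows.append({"locus": name, "N": lf.n_typed, "Ho": ho, "He": he})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Monte-Carlo)
# ---------------------------------------------------------------------------

def _log_multiset_perm(counts: np.ndarray) -> float:
    return math.lgamma(counts.sum() + 1) - sum(math.lgamma(c + 1) for c in counts)


def _log_conditional_prob(genotype_counts: dict[tuple[int, int], int]) -> float:
    """log P(genotype table | allele counts) under HW (Levene's conditional
    distribution): n! * 2^h * prod(allele_count!) / ((2n)! * prod(genotype_count!)).
    """
    n = sum(genotype_counts.values())
    h = sum(c for (a, b), c in genotype_counts.items() if a != b)
    allele_counts: dict[int, int] = {}
    for (a, b), c in genotype_counts.items():
        allele_counts[a] = allele_counts.get(a, 0) + c
        allele_counts[b] = allele_counts.get(b, 0) + c
    lp = (
        math.lgamma(n + 1)
        + h * math.log(2.0)
        + sum(math.lgamma(c + 1) for c in allele_counts.values())
        - math.lgamma(2 * n + 1)
        - sum(math.lgamma(c + 1) for c in genotype_counts.values())
    )
    return lp


def hwe_exact_test(
    panel: GenotypePanel,
    locus: str,
    n_montecarlo: int = 100_000,
    seed: int | None = None,
) -> float:
    """Monte-Carlo exact test of Hardy-Weinberg proportions at one locus.

    Random re-pairings of the observed allele multiset are drawn and the
    p-value is the (add-one corrected) proportion whose conditional
    probability is <= that of the observed genotype table.  A monomorphic
    locus is defined to have p = 1.
    """
    genotypes = [
        ind.genotype[locus]
        for ind in panel.individuals
        if ind.genotype.get(locus) is not None
    ]
    alleles = np.array([a for g in genotypes for a in g])
    if len(np.unique(alleles)) <= 1:
        return 1.0
    observed: dict[tuple[int, int], int] = {}
    for g in genotypes:
        observed[g] = observed.get(g, 0) + 1
    lp_obs = _log_conditional_prob(observed)

    rng = np.random.default_rng(seed)
    hits = 0
    tol = 1e-9
    for _ in range(n_montecarlo):
        perm = rng.permutation(alleles)
        table: dict[tuple[int, int], int] = {}
        for a, b in zip(perm[0::2], perm[1::2]):
            key = (a, b) if a <= b else (b, a)
            table[key] = table.get(key, 0) + 1
        if _log_conditional_prob(table) <= lp_obs + tol:
            hits += 1
    return (hits + 1) / (n_montecarlo + 1)


def bonferroni_adjust(
    p_values: list[float], alpha: float = 0.05
) -> tuple[float, list[bool]]:
    """Sequentially-agnostic Bonferroni correction: adjusted alpha and
    per-test reject decisions (p < alpha/k)."""
    if not p_values:
        raise ValueError("no p-values supplied")
    if any(not 0 <= p <= 1 for p in p_values):
        raise ValueError("p-values must lie in [0, 1]")
    threshold = alpha / len(p_values)
    return threshold, [p < threshold for p in p_values]


# ---------------------------------------------------------------------------
# probability of identity
# ---------------------------------------------------------------------------

def p_id_locus(
    lf: LocusFrequencies, n_typed: int | None = None
) -> tuple[float, float | None, float]:
    """Per-locus probability-of-identity statistics.

    Returns (biased, unbiased, sib):

    * biased   = 2*a2^2 - a4, the probability two unrelated individuals
      drawn from HW proportions share a genotype (a_k = sum p_i^k);
    * unbiased = the Paetkau small-sample-corrected estimator,
      [n^3(2a2^2 - a4) - 2n^2(a3 + 2a2) + n(9a2 + 2) - 6]
      / [(n-1)(n-2)(n-3)], with n the number of genotyped individuals;
      converges to the biased form as n grows, undefined (None) for n < 4;
    * sib      = 0.25 + 0.5*a2 + 0.5*a2^2 - 0.25*a4, the same probability
      for a full-sib pair (the hardest case).
    """
    n = lf.n_typed if n_typed is None else n_typed
    a2 = lf.power_sum(2)
    a3 = lf.power_sum(3)
    a4 = lf.power_sum(4)
    biased = 2 * a2**2 - a4
    sib = 0.25 + 0.5 * a2 + 0.5 * a2**2 - 0.25 * a4
    if n < 4:
        logger.warning(
            "locus %s: n=%d < 4, unbiased P(ID) undefined", lf.locus, n
        )
        unbiased = None
    else:
        num = (
            n**3 * (2 * a2**2 - a4)
            - 2 * n**2 * (a3 + 2 * a2)
            + n * (9 * a2 + 2)
            - 6
        )
        unbiased = num / ((n - 1) * (n - 2) * (n - 3))
    return biased, unbiased, sib


def p_id_multilocus(per_locus: list[float]) -> float:
    """Multilocus P(ID): product of independent per-locus values."""
    if not per_locus:
        raise ValueError("no per-locus values")
    return float(np.prod(per_locus))


def locus_summary_table(panel: GenotypePanel) -> pd.DataFrame:
    """Per-locus N, A, Ho, He and P(ID) statistics plus a product row."""
    freqs = allele_frequencies(panel)
    het = heterozygosities(panel).set_index("locus")
    rows = []
    for name in panel.locus_names:
        lf = freqs[name]
        biased, unbiased, sib = p_id_locus(lf)
        rows.append(
            {
                "locus": name,
                "N": lf.n_typed,
                "A": len(lf.freqs),
                "Ho": het.loc[name, "Ho"],
                "He": het.loc[name, "He"],
                "p_id_unbiased": unbiased,
                "p_id_sib": sib,
            }
        )
    table = pd.DataFrame(rows)
    return table


def gene_diversity(panel: GenotypePanel) -> GeneDiversity:
    """Mean and SD across loci of unbiased expected heterozygosity."""
    he = heterozygosities(panel)["He"].to_numpy()
    sd = float(np.std(he, ddof=1)) if len(he) > 1 else 0.0
    return GeneDiversity(mean=float(np.mean(he)), sd=sd)


# ---------------------------------------------------------------------------
# Weir-Cockerham F-statistics
# ---------------------------------------------------------------------------

def _wc_components(
    genotype_sets: list[list[tuple[int, int]]]
) -> tuple[float, float, float]:
    """Sum of Weir-Cockerham (1984) variance components a, b, c over
    alleles at one locus, given per-group lists of genotypes."""
    groups = [g for g in genotype_sets if g]
    r = len(groups)
    if r < 2:
        return 0.0, 0.0, 0.0
    n_i = np.array([len(g) for g in groups], dtype=float)
    n_bar = n_i.mean()
    n_sum = n_i.sum()
    n_c = (n_sum - (n_i**2).sum() / n_sum) / (r - 1)
    alleles = sorted({a for g in groups for pair in g for a in pair})
    a_sum = b_sum = c_sum = 0.0
    for allele in alleles:
        p_i = np.array(
            [sum(pair.count(allele) for pair in g) / (2 * len(g)) for g in groups]
        )
        h_i = np.array(
            [
                sum(1 for pair in g if (pair[0] == allele) != (pair[1] == allele))
                / len(g)
                for g in groups
            ]
        )
        p_bar = (n_i * p_i).sum() / n_sum
        s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum() / n_sum
        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1))
            * (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - s2 * (r - 1) / r
            - h_bar * (2 * n_bar - 1) / (4 * n_bar)
        )
        c = h_bar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def _wc_theta_f(panel: GenotypePanel, labels: dict[str, str]) -> tuple[float, float]:
    groups = sorted({m for m in labels.values()})
    a_tot = b_tot = c_tot = 0.0
    for name in panel.locus_names:
        sets = []
        for grp in groups:
            sets.append(
                [
                    ind.genotype[name]
                    for ind in panel.individuals
                    if labels.get(ind.individual_id) == grp
                    and ind.genotype.get(name) is not None
                ]
            )
        if sum(1 for s in sets if s) < 2:
            logger.warning("F-statistics: locus %s missing in a group, skipped", name)
            continue
        a, b, c = _wc_components(sets)
        a_tot += a
        b_tot += b
        c_tot += c
    denom = a_tot + b_tot + c_tot
    theta = a_tot / denom if denom != 0 else 0.0
    f_is = 1.0 - c_tot / (b_tot + c_tot) if (b_tot + c_tot) != 0 else 0.0
    return theta, f_is


def wc_f_statistics(
    panel: GenotypePanel,
    grouping: dict[str, str] | None = None,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> FStatsResult:
    """Multi-locus Weir-Cockerham F_ST (theta-hat) and F_IS (f-hat) with
    permutation p-values.

    ``grouping`` maps individual id -> group label; by default the panel's
    margin labels are used (``unassigned`` individuals excluded).  F_ST
    significance permutes individuals across groups; F_IS significance
    permutes allele assignments within individuals (re-pairing alleles
    within each group).
    """
    if grouping is None:
        grouping = {
            ind.individual_id: ind.margin
            for ind in panel.individuals
            if ind.margin != "unassigned"
        }
    group_sizes: dict[str, int] = {}
    for g in grouping.values():
        group_sizes[g] = group_sizes.get(g, 0) + 1
    if len(group_sizes) < 2 or min(group_sizes.values()) < 2:
        raise ValueError("need >=2 groups with >=2 individuals each")

    theta, f_is = _wc_theta_f(panel, grouping)

    rng = np.random.default_rng(seed)
    ids = sorted(grouping)
    group_list = [grouping[i] for i in ids]
    hits_st = 0
    for _ in range(n_permutations):
        perm = rng.permutation(group_list)
        perm_map = dict(zip(ids, perm))
        t, _ = _wc_theta_f(panel, perm_map)
        if t >= theta:
            hits_st += 1
    p_st = (hits_st + 1) / (n_permutations + 1)

    # F_IS null: re-pair alleles at random within each group per locus
    hits_is = 0
    base = [
        (name, grp)
        for name in panel.locus_names
        for grp in sorted(set(grouping.values()))
    ]
    pools = {}
    for name, grp in base:
        pool = [
            ind.genotype[name]
            for ind in panel.individuals
            if grouping.get(ind.individual_id) == grp
            and ind.genotype.get(name) is not None
        ]
        pools[(name, grp)] = [a for pair in pool for a in pair]
    for _ in range(n_permutations):
        shuffled_panel = _repair_alleles(panel, grouping, pools, rng)
        _, f = _wc_theta_f(shuffled_panel, grouping)
        if abs(f) >= abs(f_is):
            hits_is += 1
    p_is = (hits_is + 1) / (n_permutations + 1)

    return FStatsResult(
        f_st=theta, f_is=f_is, p_st=p_st, p_is=p_is, n_permutations=n_permutations
    )


def _repair_alleles(panel, grouping, pools, rng) -> GenotypePanel:
    from .genotypes import GenotypePanel as _Panel, IndividualGenotype

    shuffled: dict[tuple[str, str], list[int]] = {
        key: list(rng.permutation(alleles)) for key, alleles in pools.items()
    }
    cursors = {key: 0 for key in shuffled}
    individuals = []
    for ind in panel.individuals:
        grp = grouping.get(ind.individual_id)
        genotype = {}
        for name, g in ind.genotype.items():
            if g is None or grp is None:
                genotype[name] = g
                continue
            key = (name, grp)
            i = cursors[key]
            a, b = shuffled[key][i], shuffled[key][i + 1]
            cursors[key] = i + 2
            genotype[name] = (a, b) if a <= b else (b, a)
        individuals.append(
            IndividualGenotype(
                individual_id=ind.individual_id,
                genotype=genotype,
                x=ind.x,
                y=ind.y,
                margin=ind.margin,
            )
        )
    return _Panel(loci=panel.loci, individuals=individuals)
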