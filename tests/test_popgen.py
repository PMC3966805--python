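"""Summary statistics: frequencies, heterozygosity, HWE, P(ID), F-stats."""

import itertools
import math

import numpy as np
import pytest

from tapirkin import (
    GenotypePanel,
    IndividualGenotype,
    Locus,
    LocusFrequencies,
    allele_frequencies,
    bonferroni_adjust,
    gene_diversity,
    heterozygosities,
    hwe_exact_test,
    p_id_locus,
    p_id_multilocus,
    wc_f_statistics,
)


def _panel(genotype_lists, n_loci=1, margins=None):
    loci = [
        Locus(f"L{i+1}", tuple(sorted({a for g in genotype_lists for a in g or ()} | {98})))
        for i in range(n_loci)
    ]
    inds = []
    for k, g in enumerate(genotype_lists):
        margin = margins[k] if margins else "unassigned"
        inds.append(
            IndividualGenotype(
                f"I{k}", {loci[0].name: g}, margin=margin
            )
        )
    return GenotypePanel(loci=loci, individuals=inds)


class TestFrequenciesAndHeterozygosity:
    def test_allele_counting(self):
        panel = _panel([(100, 100), (100, 102)])
        freqs = allele_frequencies(panel)["L1"]
        assert freqs.freqs == {100: 0.75, 102: 0.25}
        assert freqs.n_typed == 2

    def test_monomorphic_flagged(self):
        freqs = allele_frequencies(_panel([(100, 100), (100, 100)]))["L1"]
        assert freqs.monomorphic and freqs.freqs == {100: 1.0}

    def test_sampled_frequencies_near_truth(self, table1_loci_freqs, rng):
        # binomial sampling: observed frequency within 3 SE of the generator
        loci, freqs = table1_loci_freqs
        name = loci[0].name
        truth = freqs[name].freqs
        alleles = sorted(truth)
        p = np.array([truth[a] for a in alleles])
        n = 500
        draws = rng.choice(alleles, size=(n, 2), p=p)
        inds = [
            IndividualGenotype(f"I{i}", {name: tuple(sorted(map(int, d)))})
            for i, d in enumerate(draws)
        ]
        panel = GenotypePanel(loci=[loci[0]], individuals=inds)
        observed = allele_frequencies(panel)[name].freqs
        for allele, p_true in truth.items():
            se = math.sqrt(p_true * (1 - p_true) / (2 * n))
            assert abs(observed.get(allele, 0.0) - p_true) <= 3 * se + 1e-12

    def test_hand_computed_he(self):
        # two heterozygous individuals: Ho=1, unbiased He=(4/3)*0.5
        table = heterozygosities(_panel([(100, 102), (100, 102)]))
        assert table.loc[0, "Ho"] == 1.0
        assert table.loc[0, "He"] == pytest.approx(2 / 3)

    def test_monomorphic_he_zero(self):
        table = heterozygosities(_panel([(100, 100), (100, 100)]))
        assert table.loc[0, "Ho"] == 0.0 and table.loc[0, "He"] == 0.0

    def test_gene_diversity_mean_and_sd(self):
        loci = [Locus("L1", (1, 2)), Locus("L2", (3, 4))]
        inds = [
            IndividualGenotype("I1", {"L1": (1, 2), "L2": (3, 3)}),
            IndividualGenotype("I2", {"L1": (1, 2), "L2": (3, 4)}),
            IndividualGenotype("I3", {"L1": (1, 1), "L2": (3, 4)}),
        ]
        panel = GenotypePanel(loci=loci, individuals=inds)
        he = heterozygosities(panel)["He"]
        gd = gene_diversity(panel)
        assert gd.mean == pytest.approx(he.mean())
        assert gd.sd == pytest.approx(he.std(ddof=1))


def _exact_hwe_p_two_alleles(n_a: int, n_b: int) -> dict[int, float]:
    """Exact conditional distribution over heterozygote counts for a
    two-allele locus (independent enumeration oracle)."""
    n = (n_a + n_b) // 2
    probs = {}
    for n_ab in range(n_a % 2 if n_a % 2 == n_b % 2 else 1, min(n_a, n_b) + 1, 2):
        n_aa = (n_a - n_ab) // 2
        n_bb = (n_b - n_ab) // 2
        if n_aa < 0 or n_bb < 0 or n_aa + n_ab + n_bb != n:
            continue
        lp = (
            math.lgamma(n + 1)
            - math.lgamma(n_aa + 1)
            - math.lgamma(n_ab + 1)
            - math.lgamma(n_bb + 1)
            + n_ab * math.log(2)
            + math.lgamma(n_a + 1)
            + math.lgamma(n_b + 1)
            - math.lgamma(2 * n + 1)
        )
        probs[n_ab] = math.exp(lp)
    return probs


class TestHWE:
    def test_monte_carlo_matches_enumeration(self):
        # 10 individuals: 3 AA, 4 AB, 3 BB (close to HW)
        genotypes = [(1, 1)] * 3 + [(1, 2)] * 4 + [(2, 2)] * 3
        panel = _panel(genotypes)
        n_a = sum(g.count(1) for g in genotypes)
        n_b = sum(g.count(2) for g in genotypes)
        dist = _exact_hwe_p_two_alleles(n_a, n_b)
        p_obs = dist[4]
        exact_p = sum(p for p in dist.values() if p <= p_obs + 1e-12)
        mc_p = hwe_exact_test(panel, "L1", n_montecarlo=20_000, seed=3)
        assert mc_p == pytest.approx(exact_p, abs=0.02)

    def test_table_at_hw_proportions_not_rejected(self):
        genotypes = [(1, 1)] * 4 + [(1, 2)] * 8 + [(2, 2)] * 4
        p = hwe_exact_test(_panel(genotypes), "L1", n_montecarlo=20_000, seed=1)
        assert p >= 0.5

    def test_heterozygote_excess_rejected(self):
        p = hwe_exact_test(_panel([(1, 2)] * 20), "L1", n_montecarlo=20_000, seed=1)
        assert p < 0.05

    def test_monomorphic_defined_as_one(self):
        assert hwe_exact_test(_panel([(1, 1)] * 6), "L1") == 1.0


class TestBonferroni:
    @pytest.mark.parametrize(
        "pvals, alpha, threshold, decisions",
        [
            ([0.01, 0.2], 0.05, 0.025, [True, False]),
            ([0.03], 0.05, 0.05, [True]),
            ([0.02, 0.02, 0.02, 0.02, 0.02], 0.05, 0.01, [False] * 5),
        ],
    )
    def test_threshold_and_decisions(self, pvals, alpha, threshold, decisions):
        t, d = bonferroni_adjust(pvals, alpha)
        assert t == pytest.approx(threshold)
        assert d == decisions

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([])


def _pid_enumeration_oracle(freqs: dict[int, float]):
    """Enumerate genotype distributions to get P(ID) for unrelated and
    full-sib pairs (independent of the closed forms)."""
    alleles = list(freqs)
    genotypes = [
        tuple(sorted(p))
        for p in itertools.combinations_with_replacement(alleles, 2)
    ]

    def pg(g):
        a, b = g
        return freqs[a] ** 2 if a == b else 2 * freqs[a] * freqs[b]

    p_unrelated = sum(pg(g) ** 2 for g in genotypes)
    # sibs: enumerate both parents' ordered genotypes and transmissions
    p_sib = 0.0
    for g in genotypes:
        match = 0.0
        for ma, mb in itertools.product(alleles, repeat=2):
            for fa, fb in itertools.product(alleles, repeat=2):
                pp = freqs[ma] * freqs[mb] * freqs[fa] * freqs[fb]
                kids = [
                    tuple(sorted((m, f)))
                    for m in (ma, mb)
                    for f in (fa, fb)
                ]
                p_child = sum(k == g for k in kids) / 4
                match += pp * p_child**2
        p_sib += match
    return p_unrelated, p_sib


class TestProbabilityOfIdentity:
    def test_two_equifrequent_alleles_closed_forms(self):
        lf = LocusFrequencies("L", {1: 0.5, 2: 0.5}, 100, False)
        biased, unbiased, sib = p_id_locus(lf)
        assert biased == pytest.approx(0.375)
        assert sib == pytest.approx(0.59375)

    def test_matches_enumeration_oracle(self):
        freqs = {1: 0.5, 2: 0.3, 3: 0.2}
        lf = LocusFrequencies("L", freqs, 50, False)
        biased, _, sib = p_id_locus(lf)
        oracle_unrel, oracle_sib = _pid_enumeration_oracle(freqs)
        assert biased == pytest.approx(oracle_unrel, rel=1e-12)
        assert sib == pytest.approx(oracle_sib, rel=1e-9)

    def test_unbiased_converges_to_biased(self):
        lf = LocusFrequencies("L", {1: 0.6, 2: 0.4}, 10**6, False)
        biased, unbiased, _ = p_id_locus(lf)
        assert unbiased == pytest.approx(biased, abs=1e-6)

    def test_small_sample_undefined(self):
        lf = LocusFrequencies("L", {1: 0.6, 2: 0.4}, 3, False)
        assert p_id_locus(lf)[1] is None

    def test_sib_is_hardest_case(self, table1_freqs):
        for name in table1_freqs.locus_names:
            lf = table1_freqs[name]
            biased, unbiased, sib = p_id_locus(
                LocusFrequencies(name, lf.freqs, 30, False)
            )
            assert sib >= biased
            assert sib >= unbiased

    def test_multilocus_product_non_increasing(self):
        values = [0.39, 0.396, 0.339]
        assert p_id_multilocus(values[:1]) >= p_id_multilocus(values[:2])
        assert p_id_multilocus(values[:2]) >= p_id_multilocus(values)
        assert p_id_multilocus([0.5]) == 0.5


class TestFStatistics:
    def _two_group_panel(self, genotypes_a, genotypes_b):
        alleles = tuple(
            sorted({a for g in genotypes_a + genotypes_b for a in g})
        )
        loci = [Locus("L1", alleles)]
        inds = [
            IndividualGenotype(f"A{i}", {"L1": g}, margin="east")
            for i, g in enumerate(genotypes_a)
        ] + [
            IndividualGenotype(f"B{i}", {"L1": g}, margin="west")
            for i, g in enumerate(genotypes_b)
        ]
        return GenotypePanel(loci=loci, individuals=inds)

    def test_identical_groups_near_zero(self, rng):
        genotypes = [
            tuple(sorted(map(int, rng.choice([1, 2, 3], size=2))))
            for _ in range(50)
        ]
        panel = self._two_group_panel(genotypes, list(genotypes))
        result = wc_f_statistics(panel, n_permutations=50, seed=0)
        assert abs(result.f_st) < 0.02

    def test_fixed_groups_give_one(self):
        panel = self._two_group_panel([(1, 1)] * 10, [(2, 2)] * 10)
        result = wc_f_statistics(panel, n_permutations=50, seed=0)
        assert result.f_st == pytest.approx(1.0)
        assert result.p_st < 0.05

    def test_heterozygote_deficit_positive_fis(self):
        # an excess of homozygotes relative to HW in both groups
        genotypes = [(1, 1)] * 8 + [(2, 2)] * 8 + [(1, 2)] * 4
        panel = self._two_group_panel(genotypes, list(genotypes))
        result = wc_f_statistics(panel, n_permutations=100, seed=0)
        assert result.f_is > 0.3

    def test_random_split_of_panmixia_rarely_significant(self, table1_loci_freqs):
        # null calibration over seeds: a random split of one HWE pool
        from tapirkin.calibration import simulate_dyads
        from tapirkin.relatedness import CANONICAL_K

        loci, freqs = table1_loci_freqs
        significant = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            dyads = simulate_dyads(freqs, CANONICAL_K["UN"], 15, rng=rng).dyads
            inds = []
            for i, (gx, gy) in enumerate(dyads):
                inds.append(
                    IndividualGenotype(f"E{i}", gx, margin="east")
                )
                inds.append(
                    IndividualGenotype(f"W{i}", gy, margin="west")
                )
            panel = GenotypePanel(loci=loci, individuals=inds)
            result = wc_f_statistics(panel, n_permutations=99, seed=seed)
            significant += result.p_st < 0.05
        assert significant <= 0.10 * n_seeds + 1

    def test_requires_two_groups(self, small_panel):
        with pytest.raises(ValueError):
            wc_f_statistics(small_panel, grouping={"I1": "east", "I2": "east"})
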