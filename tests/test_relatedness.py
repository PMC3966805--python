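"""Relatedness estimators, bootstrap CIs, dyad likelihoods and LRTs."""

import itertools

import numpy as np
import pytest

from tapirkin import (
    CANONICAL_K,
    DyadLikelihoodModel,
    KCoefficients,
    LocusFrequencies,
    AlleleFrequencyTable,
    allele_sharing,
    bootstrap_ci,
    dyad_likelihood,
    lrt_pedigree,
    multilocus_dyad_likelihood,
    r_lr99,
    r_qg89,
)
from tapirkin.calibration import simulate_dyads


class TestKCoefficients:
    def test_canonical_values(self):
        assert CANONICAL_K["PO"].expected_r == 0.5
        assert CANONICAL_K["FS"].expected_r == 0.5
        assert CANONICAL_K["HS"].expected_r == 0.25
        assert CANONICAL_K["cousin"].expected_r == 0.125
        assert CANONICAL_K["UN"].expected_r == 0.0

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError):
            KCoefficients(0.5, 0.6, 0.1)
        with pytest.raises(ValueError):
            KCoefficients(1.2, -0.2, 0.0)


class TestEstimators:
    def test_identical_heterozygotes_give_one(self, three_allele_freqs):
        gx = {"L1": (100, 102)}
        assert r_qg89(gx, gx, three_allele_freqs) == pytest.approx(1.0)
        assert r_lr99(gx, gx, three_allele_freqs) == pytest.approx(1.0)

    def test_lr99_hand_computed_locus_value(self, three_allele_freqs):
        # reference (a,b)=(100,102), partner (100,104); p=(0.5,0.3)
        # num = pa*(b in {c,d}) + pb*(a in {c,d}) - 4 pa pb over
        # den = (1+0)(pa+pb) - 4 pa pb; symmetrized with the reverse
        gx = {"L1": (100, 102)}
        gy = {"L1": (100, 104)}
        fwd = (0.5 * 0 + 0.3 * 1 - 0.6) / (0.8 - 0.6)
        pa, pb = 0.5, 0.2  # reverse orientation: reference (100,104)
        rev = (pa * 0 + pb * 1 - 4 * pa * pb) / ((pa + pb) - 4 * pa * pb)
        expected = (fwd + rev) / 2
        assert r_lr99(gx, gy, three_allele_freqs) == pytest.approx(expected)

    def test_monomorphic_only_loci_undefined(self):
        freqs = AlleleFrequencyTable(
            {"L1": LocusFrequencies("L1", {100: 1.0}, 10, True)}
        )
        gx = {"L1": (100, 100)}
        assert r_lr99(gx, gx, freqs) is None
        assert r_qg89(gx, gx, freqs) is None

    @pytest.mark.parametrize("category", ["PO", "FS", "HS", "cousin", "UN"])
    def test_estimator_expectation_matches_kinship(
        self, table1_freqs, category
    ):
        # E[r] = k1/2 + k2 for both estimators (800 simulated dyads)
        expected = CANONICAL_K[category].expected_r
        dyads = simulate_dyads(
            table1_freqs, CANONICAL_K[category], 800, seed=99, category=category
        ).dyads
        for est in (r_qg89, r_lr99):
            vals = np.array([est(gx, gy, table1_freqs) for gx, gy in dyads])
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - expected) <= 2.5 * se


class TestBootstrapCI:
    def test_identical_dyad_interval_degenerate_at_one(self, table1_freqs):
        gx = {
            name: tuple(sorted(table1_freqs[name].freqs)[:2])
            for name in table1_freqs.locus_names
        }
        lo, hi = bootstrap_ci(gx, gx, table1_freqs, "qg89", seed=1)
        assert hi == pytest.approx(1.0)
        assert lo == pytest.approx(1.0)

    def test_fixed_seed_reproducible(self, table1_freqs):
        dyad = simulate_dyads(table1_freqs, CANONICAL_K["HS"], 1, seed=5).dyads[0]
        a = bootstrap_ci(*dyad, table1_freqs, "lr99", seed=11)
        b = bootstrap_ci(*dyad, table1_freqs, "lr99", seed=11)
        assert a == b

    def test_lower_not_above_upper(self, table1_freqs):
        for i, (gx, gy) in enumerate(
            simulate_dyads(table1_freqs, CANONICAL_K["FS"], 20, seed=6).dyads
        ):
            lo, hi = bootstrap_ci(gx, gy, table1_freqs, "lr99", seed=i)
            assert lo <= hi

    def test_doubling_loci_narrows_intervals_on_average(self, table1_freqs):
        widths_5 = []
        widths_10 = []
        dyads = simulate_dyads(table1_freqs, CANONICAL_K["HS"], 50, seed=21).dyads
        doubled = AlleleFrequencyTable(
            {
                **table1_freqs.loci,
                **{
                    f"{name}_b": LocusFrequencies(
                        f"{name}_b",
                        table1_freqs[name].freqs,
                        table1_freqs[name].n_typed,
                        table1_freqs[name].monomorphic,
                    )
                    for name in table1_freqs.locus_names
                },
            }
        )
        for i, (gx, gy) in enumerate(dyads):
            lo, hi = bootstrap_ci(gx, gy, table1_freqs, "lr99", seed=i)
            widths_5.append(hi - lo)
            gx2 = {**gx, **{f"{k}_b": v for k, v in gx.items()}}
            gy2 = {**gy, **{f"{k}_b": v for k, v in gy.items()}}
            lo2, hi2 = bootstrap_ci(gx2, gy2, doubled, "lr99", seed=i)
            widths_10.append(hi2 - lo2)
        assert np.mean(widths_10) < np.mean(widths_5)

    def test_single_locus_rejected(self, two_allele_freqs):
        with pytest.raises(ValueError):
            bootstrap_ci(
                {"L1": (100, 102)}, {"L1": (100, 102)}, two_allele_freqs
            )


class TestAlleleSharing:
    def test_full_sharing(self):
        gx = {f"L{i}": (1, 2) for i in range(5)}
        assert allele_sharing(gx, gx) == (1.0, 10, 5)

    def test_multiset_intersection_of_homozygote_and_heterozygote(self):
        assert allele_sharing({"L1": (1, 1)}, {"L1": (1, 2)}) == (1.0, 1, 1)
        assert allele_sharing({"L1": (1, 1)}, {"L1": (1, 1)}) == (1.0, 2, 1)
        assert allele_sharing({"L1": (1, 2)}, {"L1": (3, 4)}) == (0.0, 0, 1)

    def test_parent_offspring_always_share(self, table1_freqs):
        dyads = simulate_dyads(table1_freqs, CANONICAL_K["PO"], 200, seed=8).dyads
        for gx, gy in dyads:
            frac, _, _ = allele_sharing(gx, gy)
            assert frac == 1.0


class TestDyadLikelihood:
    @pytest.mark.parametrize(
        "category, expected",
        [("UN", 0.0625), ("PO", 0.125), ("FS", 0.140625)],
    )
    def test_homozygote_pair_examples(self, category, expected):
        lf = LocusFrequencies("L", {1: 0.5, 2: 0.5}, 10, False)
        value = dyad_likelihood((1, 1), (1, 1), lf, CANONICAL_K[category])
        assert value == pytest.approx(expected)

    def test_po_likelihood_matches_parental_enumeration(self):
        # oracle: enumerate transmission from parent to offspring
        freqs = {1: 0.5, 2: 0.3, 3: 0.2}
        lf = LocusFrequencies("L", freqs, 10, False)
        alleles = list(freqs)
        genotypes = [
            tuple(sorted(g))
            for g in itertools.combinations_with_replacement(alleles, 2)
        ]

        def pg(g):
            a, b = g
            return freqs[a] ** 2 if a == b else 2 * freqs[a] * freqs[b]

        for g1 in genotypes:
            for g2 in genotypes:
                # P(child g2 | parent g1): pass one uniformly chosen parental
                # allele, draw the other from the population
                total = 0.0
                for passed in g1:
                    for other in alleles:
                        child = tuple(sorted((passed, other)))
                        total += 0.5 * freqs[other] * (child == g2)
                oracle = pg(g1) * total
                value = dyad_likelihood(g1, g2, lf, CANONICAL_K["PO"])
                assert value == pytest.approx(oracle, abs=1e-12)

    @pytest.mark.parametrize("category", list(CANONICAL_K))
    @pytest.mark.parametrize(
        "freqs",
        [
            {1: 0.5, 2: 0.5},
            {1: 0.5, 2: 0.3, 3: 0.2},
            {1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1},
        ],
    )
    def test_normalization_over_ordered_pairs(self, category, freqs):
        lf = LocusFrequencies("L", freqs, 10, False)
        genotypes = [
            tuple(sorted(g))
            for g in itertools.combinations_with_replacement(freqs, 2)
        ]
        total = sum(
            dyad_likelihood(g1, g2, lf, CANONICAL_K[category])
            for g1 in genotypes
            for g2 in genotypes
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("category", list(CANONICAL_K))
    def test_symmetry_in_the_two_genotypes(self, category):
        freqs = {1: 0.5, 2: 0.3, 3: 0.2}
        lf = LocusFrequencies("L", freqs, 10, False)
        genotypes = [
            tuple(sorted(g))
            for g in itertools.combinations_with_replacement(freqs, 2)
        ]
        for g1 in genotypes:
            for g2 in genotypes:
                assert dyad_likelihood(
                    g1, g2, lf, CANONICAL_K[category]
                ) == pytest.approx(
                    dyad_likelihood(g2, g1, lf, CANONICAL_K[category]), abs=1e-12
                )

    def test_zero_frequency_allele_rejected(self):
        lf = LocusFrequencies("L", {1: 1.0}, 10, True)
        with pytest.raises(ValueError):
            dyad_likelihood((1, 1), (2, 2), lf, CANONICAL_K["UN"])

    def test_multilocus_product(self, three_allele_freqs):
        freqs = AlleleFrequencyTable(
            {
                "L1": three_allele_freqs["L1"],
                "L2": LocusFrequencies("L2", {1: 0.5, 2: 0.5}, 10, False),
            }
        )
        gx = {"L1": (100, 100), "L2": (1, 1)}
        k = CANONICAL_K["UN"]
        expected = dyad_likelihood(
            (100, 100), (100, 100), freqs["L1"], k
        ) * dyad_likelihood((1, 1), (1, 1), freqs["L2"], k)
        assert multilocus_dyad_likelihood(gx, gx, freqs, k) == pytest.approx(
            expected
        )


class TestPedigreeLRT:
    def test_identical_genotypes_accept_first_order(self, table1_freqs):
        gx = {
            name: tuple(sorted(table1_freqs[name].freqs)[:2])
            for name in table1_freqs.locus_names
        }
        result = lrt_pedigree(gx, gx, table1_freqs, n_null_sims=500, seed=3)
        assert result.accepted in ("PO", "FS")
        assert result.accepted_p < 0.05

    def test_disjoint_genotypes_accept_unrelated(self, table1_freqs):
        gx, gy = {}, {}
        for name in table1_freqs.locus_names:
            alleles = sorted(table1_freqs[name].freqs)
            gx[name] = (alleles[0], alleles[1])
            gy[name] = (alleles[2], alleles[3])
        result = lrt_pedigree(gx, gy, table1_freqs, n_null_sims=500, seed=3)
        assert result.accepted == "UN"

    def test_fixed_seed_reproduces_p_values(self, table1_freqs):
        dyad = simulate_dyads(table1_freqs, CANONICAL_K["HS"], 1, seed=17).dyads[0]
        a = lrt_pedigree(*dyad, table1_freqs, n_null_sims=300, seed=9)
        b = lrt_pedigree(*dyad, table1_freqs, n_null_sims=300, seed=9)
        assert a.tests == b.tests
        assert a.accepted == b.accepted

    def test_reports_all_five_comparisons(self, table1_freqs):
        dyad = simulate_dyads(table1_freqs, CANONICAL_K["FS"], 1, seed=2).dyads[0]
        result = lrt_pedigree(*dyad, table1_freqs, n_null_sims=200, seed=4)
        assert [t[0] for t in result.tests] == ["PO", "FS", "HS", "cousin", "UN"]
        assert all(0 < t[2] <= 1 for t in result.tests)

    def test_model_caches_null_distributions(self, table1_freqs):
        model = DyadLikelihoodModel(table1_freqs, seed=5)
        dyads = simulate_dyads(table1_freqs, CANONICAL_K["UN"], 3, seed=1).dyads
        for gx, gy in dyads:
            model.lrt(gx, gy, n_null_sims=200)
        # one cached null set per comparison for the shared locus set
        assert len(model._null_cache) == 5
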