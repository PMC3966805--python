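"""Published summary values from the Balbina reservoir lowland-tapir survey.

The Balbina study (central Amazon, Tapirus terrestris, fecal-DNA
microsatellite genotyping at 5 loci) is the reference study system this
package's defaults emulate.  The constants below are the study's printed
per-locus summary statistics and mating-system model log-likelihoods;
they serve as inputs to the arithmetic modules and as calibration targets
for the synthetic-data generator.
"""

from __future__ import annotations

from .demography import ModelLikelihood

#: locus name -> (N typed, allele count A, Ho, He, P(ID)unbiased, P(ID)sib)
BALBINA_LOCUS_SUMMARY: dict[str, tuple[int, int, float, float, float, float]] = {
    "Tte05": (31, 7, 0.77, 0.78, 0.077, 0.390),
    "Tte12": (29, 6, 0.72, 0.77, 0.080, 0.396),
    "TtGT137": (21, 10, 0.86, 0.86, 0.030, 0.339),
    "Tter4": (25, 5, 0.88, 0.81, 0.063, 0.374),
    "Tter5": (32, 5, 0.63, 0.63, 0.196, 0.494),
}

#: per-locus allele richness of the Balbina panel
BALBINA_ALLELE_COUNTS: tuple[int, ...] = tuple(
    v[1] for v in BALBINA_LOCUS_SUMMARY.values()
)

#: per-locus expected heterozygosity of the Balbina panel
BALBINA_HE: tuple[float, ...] = tuple(v[3] for v in BALBINA_LOCUS_SUMMARY.values())

#: maximum log-likelihoods (natural log) of the three mating-system models
BALBINA_MATING_MODELS: list[ModelLikelihood] = [
    ModelLikelihood("polygamy", -796.38),
    ModelLikelihood("polygyny_or_polyandry", -809.17),
    ModelLikelihood("monogamy", -815.89),
]

#: mutation-scaled population size estimates (Bayesian, maximum likelihood)
BALBINA_THETA = {"bayesian": 6.5, "maximum_likelihood": 7.1}

#: per-locus per-generation microsatellite mutation rates assumed
BALBINA_MU_RANGE = (1e-4, 5e-4)
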