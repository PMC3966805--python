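"""Shared fixtures: small hand-built panels and the synthetic study."""

import numpy as np
import pytest

from tapirkin import (
    AlleleFrequencyTable,
    GenotypePanel,
    IndividualGenotype,
    Locus,
    LocusFrequencies,
    default_scenario,
    make_locus_set,
)


@pytest.fixture(scope="session")
def table1_loci_freqs():
    """Loci and founder frequencies matching the reference panel
    (allele richness 7, 6, 10, 5, 5; He 0.78, 0.77, 0.86, 0.81, 0.63)."""
    return make_locus_set("table1", seed=1234)


@pytest.fixture(scope="session")
def table1_freqs(table1_loci_freqs):
    return table1_loci_freqs[1]


@pytest.fixture
def two_allele_freqs():
    """One locus, two equifrequent alleles."""
    return AlleleFrequencyTable(
        {"L1": LocusFrequencies("L1", {100: 0.5, 102: 0.5}, 20, False)}
    )


@pytest.fixture
def three_allele_freqs():
    """One locus with frequencies 0.5 / 0.3 / 0.2."""
    return AlleleFrequencyTable(
        {"L1": LocusFrequencies("L1", {100: 0.5, 102: 0.3, 104: 0.2}, 20, False)}
    )


@pytest.fixture
def small_panel():
    """Four fully typed individuals at two loci, on two margins."""
    loci = [Locus("L1", (100, 102, 104)), Locus("L2", (200, 202))]
    individuals = [
        IndividualGenotype(
            "I1", {"L1": (100, 102), "L2": (200, 202)}, 0.0, 0.0, "east"
        ),
        IndividualGenotype(
            "I2", {"L1": (100, 100), "L2": (200, 200)}, 3000.0, 4000.0, "east"
        ),
        IndividualGenotype(
            "I3", {"L1": (102, 104), "L2": (202, 202)}, 10000.0, 0.0, "west"
        ),
        IndividualGenotype(
            "I4", {"L1": (100, 104), "L2": (200, 202)}, 0.0, 8000.0, "west"
        ),
    ]
    return GenotypePanel(loci=loci, individuals=individuals)


@pytest.fixture(scope="session")
def zero_error_scenario():
    """Study-scale synthetic scenario with error-free PCRs: 20 individuals,
    4 recaptured twice -> 24 samples."""
    from tapirkin import ErrorModel

    return default_scenario(
        seed=42,
        n_founders=8,
        n_offspring=12,
        n_recaptures=4,
        error=ErrorModel(0.0, 0.0, 0.0),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
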