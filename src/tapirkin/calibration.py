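"""Simulation-based calibration of relatedness classification methods.

Dyads are simulated in known relationship categories (PO, FS, HS, UN, and
first cousins for hypothesis-test nulls) from a set of allele frequencies,
pushed through candidate classifiers, and scored with the four error
metrics standard for this design:

* type I   — unrelated pairs classified as related,
* type II  — related pairs classified as unrelated,
* misFO    — true first-order pairs (PO + FS) positively classified into a
  category that excludes first order (strict HS or UN),
* misHS/UN — HS or UN pairs classified as strictly first order.

Inconclusive (IN) is a refusal to classify, not a positive call: it counts
as neither related nor unrelated for the type I/II rates and not as a
misclassification for misFO (an ``mis_fo_incl_inconclusive`` column that
does count IN is reported alongside).  The HSFO1/HSFO2 bands of the CI
method include first order, so they are never misFO and never strict-FO
for misHS/UN.  This is the accounting under which a CI method with an
inconclusive class dominates point-estimate thresholds: IN absorbs the
hard cases that point estimators are forced to call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import classify_pair
from .popgen import AlleleFrequencyTable
from .relatedness import (
    CANONICAL_K,
    DyadEstimate,
    Genotype,
    KCoefficients,
    allele_sharing,
    bootstrap_ci,
    r_lr99,
    r_qg89,
)

logger = logging.getLogger("tapirkin")

RELATED_CALLS = {"FO", "HSFO1", "HSFO2", "HS"}
FO_COMPATIBLE_CALLS = {"FO", "HSFO1", "HSFO2"}


@dataclass
class SimulatedDyadSet:
    """Simulated genotype pairs of one relationship category."""

    category: str
    dyads: list[tuple[dict[str, Genotype], dict[str, Genotype]]]
    freqs: AlleleFrequencyTable
    seed: int | None
    ibd_states: np.ndarray | None = None  # (n_dyads, n_loci) realised states


@dataclass
class CalibrationReport:
    """Per-method error rates from simulated dyads."""

    rates: pd.DataFrame  # columns: method, type_one, type_two, mis_fo, mis_hsun
    n_per_category: int


def simulate_dyads(
    freqs: AlleleFrequencyTable,
    k: KCoefficients,
    n: int,
    seed: int | None = None,
    category: str = "custom",
    rng: np.random.Generator | None = None,
) -> SimulatedDyadSet:
    """Simulate ``n`` dyads with IBD coefficients ``k``.

    Per dyad and locus: the IBD state (0/1/2 shared alleles) is drawn from
    (k0, k1, k2); individual 1's genotype is an HWE draw; individual 2
    shares that many alleles identical by descent, remaining alleles drawn
    independently from the frequencies.  No genotyping error is applied.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    loci = freqs.locus_names
    allele_arrays = {
        name: (
            np.array(sorted(freqs[name].freqs)),
            np.array([freqs[name].freqs[a] for a in sorted(freqs[name].freqs)]),
        )
        for name in loci
    }
    dyads = []
    states = np.empty((n, len(loci)), dtype=np.int8)
    for d in range(n):
        gx: dict[str, Genotype] = {}
        gy: dict[str, Genotype] = {}
        for li, name in enumerate(loci):
            alleles, probs = allele_arrays[name]
            a1, a2 = (int(a) for a in rng.choice(alleles, size=2, p=probs))
            state = rng.choice(3, p=[k.k0, k.k1, k.k2])
            if state == 2:
                b1, b2 = a1, a2
            elif state == 1:
                shared = a1 if rng.random() < 0.5 else a2
                b1, b2 = shared, int(rng.choice(alleles, p=probs))
            else:
                b1, b2 = (int(a) for a in rng.choice(alleles, size=2, p=probs))
            gx[name] = (a1, a2) if a1 <= a2 else (a2, a1)
            gy[name] = (b1, b2) if b1 <= b2 else (b2, b1)
            states[d, li] = state
        dyads.append((gx, gy))
    return SimulatedDyadSet(
        category=category, dyads=dyads, freqs=freqs, seed=seed, ibd_states=states
    )


def simulate_category_sets(
    freqs: AlleleFrequencyTable,
    n_per_category: int,
    seed: int | None = None,
    categories: tuple[str, ...] = ("PO", "FS", "HS", "UN"),
) -> dict[str, SimulatedDyadSet]:
    """One simulated dyad set per named canonical category."""
    rng = np.random.default_rng(seed)
    return {
        cat: simulate_dyads(
            freqs, CANONICAL_K[cat], n_per_category, category=cat, rng=rng
        )
        for cat in categories
    }


# ---------------------------------------------------------------------------
# classifiers under test
# ---------------------------------------------------------------------------

class PointEstimateClassifier:
    """Nearest-expectation thresholds on a point estimate of r:
    FO if r >= 0.375, HS if 0.125 <= r < 0.375, else UN (midpoints between
    the category expectations 0.5 / 0.25 / 0)."""

    def __init__(self, freqs: AlleleFrequencyTable, estimator: str = "lr99"):
        self.freqs = freqs
        self.estimator = estimator
        self.name = f"point_{estimator}"

    def classify(self, gx, gy, rng: np.random.Generator) -> str:
        est = {"lr99": r_lr99, "qg89": r_qg89}[self.estimator]
        r = est(gx, gy, self.freqs)
        if r is None:
            return "IN"
        if r >= 0.375:
            return "FO"
        if r >= 0.125:
            return "HS"
        return "UN"


class CICascadeClassifier:
    """The bootstrap-CI decision cascade on a single estimator: the
    allele-sharing FO rule, then the CI bands (FO / HSFO1 / HSFO2 / UN /
    IN).  Returns the pre-collapse band so that calibration can score
    HSFO bands as first-order-compatible."""

    def __init__(
        self,
        freqs: AlleleFrequencyTable,
        estimator: str = "lr99",
        n_boot: int = 1000,
        use_sharing_rule: bool = True,
    ):
        self.freqs = freqs
        self.estimator = estimator
        self.n_boot = n_boot
        self.use_sharing_rule = use_sharing_rule
        self.name = f"ci_{estimator}"

    def classify(self, gx, gy, rng: np.random.Generator) -> str:
        frac, count, n_loci = allele_sharing(gx, gy)
        ci = bootstrap_ci(
            gx, gy, self.freqs, self.estimator, n_boot=self.n_boot, rng=rng
        )
        dyad = DyadEstimate(
            id1="a",
            id2="b",
            r_qg89=None,
            r_lr99=None,
            ci_qg89=ci if self.estimator == "qg89" else None,
            ci_lr99=ci if self.estimator == "lr99" else None,
            shared_loci_fraction=frac,
            shared_allele_count=count,
            n_shared_loci=n_loci,
        )
        cls = classify_pair(dyad, use_sharing_rule=self.use_sharing_rule)
        return cls.ci_category or cls.category


# ---------------------------------------------------------------------------
# error-rate computation
# ---------------------------------------------------------------------------

def error_rates(calls: dict[str, list[str]]) -> dict[str, float]:
    """The four calibration error rates from per-truth-category calls.

    ``calls`` maps truth category (PO/FS/HS/UN) to the list of classifier
    outputs for its dyads.
    """
    un_calls = calls.get("UN", [])
    related_calls = [c for cat in ("PO", "FS", "HS") for c in calls.get(cat, [])]
    fo_calls = [c for cat in ("PO", "FS") for c in calls.get(cat, [])]
    hs_un_calls = [c for cat in ("HS", "UN") for c in calls.get(cat, [])]
    return {
        "type_one": (
            sum(c in RELATED_CALLS for c in un_calls) / len(un_calls)
            if un_calls
            else float("nan")
        ),
        "type_two": (
            sum(c == "UN" for c in related_calls) / len(related_calls)
            if related_calls
            else float("nan")
        ),
        "mis_fo": (
            sum(c not in FO_COMPATIBLE_CALLS and c != "IN" for c in fo_calls)
            / len(fo_calls)
            if fo_calls
            else float("nan")
        ),
        "mis_fo_incl_inconclusive": (
            sum(c not in FO_COMPATIBLE_CALLS for c in fo_calls) / len(fo_calls)
            if fo_calls
            else float("nan")
        ),
        "mis_hsun": (
            sum(c == "FO" for c in hs_un_calls) / len(hs_un_calls)
            if hs_un_calls
            else float("nan")
        ),
    }


def calibrate(
    freqs: AlleleFrequencyTable,
    n_per_category: int = 100,
    classifiers: list | None = None,
    seed: int | None = None,
    sets: dict[str, SimulatedDyadSet] | None = None,
) -> CalibrationReport:
    """Simulate PO/FS/HS/UN dyad sets and score each classifier.

    PO and FS jointly form the first-order (FO) truth class.  Classifiers
    must expose ``name`` and ``classify(gx, gy, rng) -> category``.
    """
    if n_per_category < 10:
        logger.warning(
            "n_per_category=%d < 10: error rates will be unstable", n_per_category
        )
    if classifiers is None:
        classifiers = [
            PointEstimateClassifier(freqs, "qg89"),
            PointEstimateClassifier(freqs, "lr99"),
            CICascadeClassifier(freqs, "lr99"),
        ]
    if sets is None:
        sets = simulate_category_sets(freqs, n_per_category, seed=seed)
    rows = []
    for method in classifiers:
        rng = np.random.default_rng(seed)
        calls = {
            cat: [method.classify(gx, gy, rng) for gx, gy in s.dyads]
            for cat, s in sets.items()
        }
        rates = error_rates(calls)
        rows.append({"method": method.name, **rates})
    return CalibrationReport(
        rates=pd.DataFrame(rows), n_per_category=n_per_category
    )


def sharing_rule_precision(
    sets: dict[str, SimulatedDyadSet],
    min_alleles: int = 7,
    min_loci_fraction: float = 0.8,
) -> float | None:
    """Precision of the allele-sharing FO rule on simulated dyads:
    (FO dyads passing the rule) / (all dyads passing the rule); None when
    no dyad passes."""
    passing = 0
    passing_fo = 0
    for cat, s in sets.items():
        for gx, gy in s.dyads:
            frac, count, _ = allele_sharing(gx, gy)
            if count >= min_alleles and frac >= min_loci_fraction:
                passing += 1
                passing_fo += cat in ("PO", "FS")
    if passing == 0:
        logger.warning("sharing rule: no dyad passed the thresholds")
        return None
    return passing_fo / passing
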