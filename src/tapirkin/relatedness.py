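"""Pairwise relatedness estimation and pedigree likelihood-ratio tests.

Implements the two moment relatedness estimators used throughout the
microsatellite kinship literature — Queller & Goodnight's r (QG89) and
Lynch & Ritland's r (LR99) — with locus-bootstrap percentile confidence
intervals, allele-sharing statistics, IBD-coefficient dyad likelihoods
(k0, k1, k2 parameterisation) and Monte-Carlo likelihood-ratio tests of
the standard pedigree hypotheses (PO, FS, HS, first cousins, UN).

Both estimators are asymmetric in the choice of reference individual;
multilocus values here are the arithmetic mean of the two orientations,
with locus numerators/denominators pooled across loci before the ratio
(the convention of the programs practitioners use for these estimators).
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass

import numpy as np

from .popgen import AlleleFrequencyTable, LocusFrequencies

logger = logging.getLogger("tapirkin")

Genotype = tuple[int, int]


@dataclass(frozen=True)
class KCoefficients:
    """IBD-sharing probabilities (k0, k1, k2) of a dyad.

    k_i is the probability that the pair shares exactly i allele copies
    identical by descent at a locus.
    """

    k0: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        for v in (self.k0, self.k1, self.k2):
            if not 0.0 <= v <= 1.0:
                raise ValueError("k coefficients must lie in [0, 1]")
        if abs(self.k0 + self.k1 + self.k2 - 1.0) > 1e-9:
            raise ValueError("k coefficients must sum to 1")

    @property
    def expected_r(self) -> float:
        """Expected relatedness r = k1/2 + k2."""
        return self.k1 / 2 + self.k2


#: canonical IBD coefficients for the named relationship categories
CANONICAL_K: dict[str, KCoefficients] = {
    "PO": KCoefficients(0.0, 1.0, 0.0),
    "FS": KCoefficients(0.25, 0.5, 0.25),
    "HS": KCoefficients(0.5, 0.5, 0.0),
    "cousin": KCoefficients(0.75, 0.25, 0.0),
    "UN": KCoefficients(1.0, 0.0, 0.0),
}

#: most-related first; ties in hypothesis tests break toward the later entry
RELATEDNESS_ORDER = ["PO", "FS", "HS", "cousin", "UN"]

#: the five primary-vs-null pedigree comparisons tested for every dyad
LRT_COMPARISONS: list[tuple[str, tuple[str, ...]]] = [
    ("PO", ("FS", "UN")),
    ("FS", ("HS", "UN")),
    ("HS", ("cousin", "UN")),
    ("cousin", ("UN",)),
    ("UN", ("PO", "FS", "HS", "cousin")),
]


@dataclass
class LRTResult:
    """Per-hypothesis statistics and the accepted hypothesis."""

    tests: list[tuple[str, float, float]]  # (primary, log-LR statistic, p)
    accepted: str
    accepted_p: float


@dataclass
class DyadEstimate:
    """All pairwise quantities for one pair of individuals."""

    id1: str
    id2: str
    r_qg89: float | None
    r_lr99: float | None
    ci_qg89: tuple[float, float] | None
    ci_lr99: tuple[float, float] | None
    shared_loci_fraction: float
    shared_allele_count: int
    n_shared_loci: int
    lrt: LRTResult | None = None
    distance_m: float | None = None


def _shared_loci(gx: dict[str, Genotype | None], gy) -> list[str]:
    return [
        name
        for name, g in gx.items()
        if g is not None and gy.get(name) is not None
    ]


# ---------------------------------------------------------------------------
# moment estimators
# ---------------------------------------------------------------------------

def _qg_terms(ref: Genotype, other: Genotype, lf: LocusFrequencies):
    """Queller-Goodnight numerator/denominator with ``ref`` as reference."""
    a, b = ref
    c, d = other
    pa, pb = lf.freqs[a], lf.freqs[b]
    num = (
        0.5 * ((a == c) + (a == d) + (b == c) + (b == d)) - pa - pb
    )
    den = 1.0 + (a == b) - pa - pb
    return num, den


def _lr_terms(ref: Genotype, other: Genotype, lf: LocusFrequencies):
    """Lynch-Ritland weighted numerator and weight with ``ref`` as
    reference: the locus estimate is num/weight and multilocus pooling is
    sum(num)/sum(weight) (weights are the LR99 locus weights)."""
    a, b = ref
    c, d = other
    pa, pb = lf.freqs[a], lf.freqs[b]
    raw_num = (
        pa * ((b == c) + (b == d))
        + pb * ((a == c) + (a == d))
        - 4.0 * pa * pb
    )
    # locus estimate denominator and sampling weight share the same factor
    scale = 2.0 * pa * pb
    num = raw_num / scale
    weight = ((1.0 + (a == b)) * (pa + pb) - 4.0 * pa * pb) / scale
    return num, weight


def _estimator_components(
    gx: dict[str, Genotype | None],
    gy: dict[str, Genotype | None],
    freqs: AlleleFrequencyTable,
    estimator: str,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-locus (numerator, denominator) arrays, shape (L, 2): axis 1 is
    the reference orientation (x-as-reference, y-as-reference).  Loci with
    an undefined (zero) denominator for an orientation contribute (0, 0)
    to that orientation, which drops them from pooled sums."""
    terms = {"qg89": _qg_terms, "lr99": _lr_terms}[estimator]
    loci = _shared_loci(gx, gy)
    num = np.zeros((len(loci), 2))
    den = np.zeros((len(loci), 2))
    for i, name in enumerate(loci):
        lf = freqs[name]
        for o, (ref, other) in enumerate(((gx[name], gy[name]), (gy[name], gx[name]))):
            n, d = terms(ref, other, lf)
            if abs(d) > 1e-12:
                num[i, o] = n
                den[i, o] = d
    return num, den, loci


def _pooled_estimate(num: np.ndarray, den: np.ndarray) -> float | None:
    """Average over orientations of pooled-ratio estimates; orientations
    with no usable locus are skipped; None if neither is usable."""
    vals = []
    for o in range(2):
        d = den[:, o].sum()
        if abs(d) > 1e-12:
            vals.append(num[:, o].sum() / d)
    if not vals:
        return None
    return float(np.mean(vals))


def r_qg89(
    gx: dict[str, Genotype | None],
    gy: dict[str, Genotype | None],
    freqs: AlleleFrequencyTable,
) -> float | None:
    """Multilocus Queller-Goodnight (1989) relatedness; None when no locus
    yields a defined denominator for either orientation."""
    num, den, loci = _estimator_components(gx, gy, freqs, "qg89")
    if not loci:
        logger.warning("r_qg89: no mutually typed locus")
        return None
    return _pooled_estimate(num, den)


def r_lr99(
    gx: dict[str, Genotype | None],
    gy: dict[str, Genotype | None],
    freqs: AlleleFrequencyTable,
) -> float | None:
    """Multilocus Lynch-Ritland (1999) relatedness with the LR99 locus
    weights; None when no locus is informative (e.g. all monomorphic)."""
    num, den, loci = _estimator_components(gx, gy, freqs, "lr99")
    if not loci:
        logger.warning("r_lr99: no mutually typed locus")
        return None
    return _pooled_estimate(num, den)


def bootstrap_ci(
    gx: dict[str, Genotype | None],
    gy: dict[str, Genotype | None],
    freqs: AlleleFrequencyTable,
    estimator: str = "lr99",
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for a dyad's relatedness, resampling loci
    with replacement.  Resamples with an undefined estimator are redrawn
    (up to a 10x draw inflation) and then dropped."""
    num, den, loci = _estimator_components(gx, gy, freqs, estimator)
    n_loci = len(loci)
    if n_loci < 2:
        raise ValueError("bootstrap CI needs >=2 mutually typed loci")
    if rng is None:
        rng = np.random.default_rng(seed)
    estimates = np.full(n_boot, np.nan)
    needed = np.arange(n_boot)
    draws = 0
    while needed.size and draws < 10 * n_boot:
        idx = rng.integers(0, n_loci, size=(needed.size, n_loci))
        num_s = num[idx].sum(axis=1)  # (k, 2)
        den_s = den[idx].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(np.abs(den_s) > 1e-12, num_s / den_s, np.nan)
        vals = np.nanmean(ratios, axis=1)
        estimates[needed] = vals
        draws += needed.size
        needed = needed[np.isnan(vals)]
    estimates = estimates[~np.isnan(estimates)]
    if estimates.size == 0:
        raise ValueError("bootstrap produced no defined resamples")
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(estimates, [alpha, 1.0 - alpha])
    return float(lower), float(upper)


# ---------------------------------------------------------------------------
# allele sharing
# ---------------------------------------------------------------------------

def allele_sharing(
    gx: dict[str, Genotype | None], gy: dict[str, Genotype | None]
) -> tuple[float, int, int]:
    """Allele-sharing statistics over mutually typed loci.

    Per locus the shared-allele count is the size of the multiset
    intersection of the two unordered pairs (0, 1 or 2).  Returns
    (fraction of loci sharing >=1 allele, total shared alleles, number of
    mutually typed loci).
    """
    loci = _shared_loci(gx, gy)
    if not loci:
        raise ValueError("no mutually typed locus")
    total = 0
    loci_sharing = 0
    for name in loci:
        a = list(gx[name])
        shared = 0
        for allele in gy[name]:
            if allele in a:
                a.remove(allele)
                shared += 1
        total += shared
        loci_sharing += shared > 0
    return loci_sharing / len(loci), total, len(loci)


# ---------------------------------------------------------------------------
# dyad likelihoods under IBD coefficients
# ---------------------------------------------------------------------------

def _p_genotype(g: Genotype, lf: LocusFrequencies) -> float:
    a, b = g
    pa, pb = lf.freqs[a], lf.freqs[b]
    return pa * pa if a == b else 2.0 * pa * pb


def _t1(g1: Genotype, g2: Genotype, lf: LocusFrequencies) -> float:
    """P(G2 | G1, exactly one allele IBD): a uniformly chosen allele of G1
    is passed IBD, the other allele of G2 is an independent draw."""
    c, d = g2
    total = 0.0
    for e in g1:
        if c == d:
            p = lf.freqs[c] if e == c else 0.0
        elif e == c:
            p = lf.freqs[d]
        elif e == d:
            p = lf.freqs[c]
        else:
            p = 0.0
        total += 0.5 * p
    return total


def dyad_likelihood(
    g1: Genotype, g2: Genotype, lf: LocusFrequencies, k: KCoefficients
) -> float:
    """P(G1, G2 | k) at one locus:
    k0*P(G1)P(G2) + k1*P(G1)*T1(G2|G1) + k2*P(G1)*1[G1=G2]."""
    for allele in (*g1, *g2):
        if lf.freqs.get(allele, 0.0) <= 0.0:
            raise ValueError(
                f"allele {allele} has zero frequency at {lf.locus}"
            )
    p1 = _p_genotype(g1, lf)
    like = k.k0 * p1 * _p_genotype(g2, lf) + k.k1 * p1 * _t1(g1, g2, lf)
    if k.k2:
        like += k.k2 * p1 * (1.0 if g1 == g2 else 0.0)
    return like


def multilocus_dyad_likelihood(
    gx: dict[str, Genotype | None],
    gy: dict[str, Genotype | None],
    freqs: AlleleFrequencyTable,
    k: KCoefficients,
) -> float:
    """Product of per-locus dyad likelihoods over mutually typed loci."""
    loci = _shared_loci(gx, gy)
    if not loci:
        raise ValueError("no mutually typed locus")
    like = 1.0
    for name in loci:
        like *= dyad_likelihood(gx[name], gy[name], freqs[name], k)
    return like


# ---------------------------------------------------------------------------
# tabulated dyad model: fast likelihoods, simulation and LRTs
# ---------------------------------------------------------------------------

@dataclass
class _LocusTables:
    genotypes: list[Genotype]
    index: dict[Genotype, int]
    log_joint: dict[str, np.ndarray]  # category -> (G, G) log P(G1, G2 | k)
    joint_flat: dict[str, np.ndarray]  # category -> flattened joint probs


class DyadLikelihoodModel:
    """Per-locus genotype-pair likelihood tables for the canonical
    relationship categories, enabling vectorised likelihood evaluation,
    null-dyad simulation and Monte-Carlo LRT p-values.

    Null distributions of the LRT statistic depend only on the set of
    mutually typed loci, so they are cached per locus subset and reused
    across dyads (seeded independently of the dyads themselves).
    """

    def __init__(self, freqs: AlleleFrequencyTable, seed: int | None = None):
        self.freqs = freqs
        self.seed = seed
        self._tables: dict[str, _LocusTables] = {}
        self._null_cache: dict[tuple, np.ndarray] = {}
        for name in freqs.locus_names:
            self._tables[name] = self._build(freqs[name])

    def _build(self, lf: LocusFrequencies) -> _LocusTables:
        alleles = sorted(lf.freqs)
        genotypes = [
            (alleles[i], alleles[j])
            for i in range(len(alleles))
            for j in range(i, len(alleles))
        ]
        index = {g: i for i, g in enumerate(genotypes)}
        log_joint = {}
        joint_flat = {}
        for cat, k in CANONICAL_K.items():
            mat = np.array(
                [
                    [dyad_likelihood(g1, g2, lf, k) for g2 in genotypes]
                    for g1 in genotypes
                ]
            )
            with np.errstate(divide="ignore"):
                log_joint[cat] = np.log(mat)
            flat = mat.ravel()
            joint_flat[cat] = flat / flat.sum()
        return _LocusTables(genotypes, index, log_joint, joint_flat)

    # -- likelihood evaluation ------------------------------------------

    def log_likelihood(
        self,
        gx: dict[str, Genotype | None],
        gy: dict[str, Genotype | None],
        category: str,
    ) -> float:
        loci = _shared_loci(gx, gy)
        if not loci:
            raise ValueError("no mutually typed locus")
        total = 0.0
        for name in loci:
            t = self._tables[name]
            total += t.log_joint[category][t.index[gx[name]], t.index[gy[name]]]
        return total

    # -- simulation ------------------------------------------------------

    def simulate_pair_indices(
        self, loci: list[str], category: str, n: int, rng: np.random.Generator
    ) -> dict[str, np.ndarray]:
        """Draw n genotype-pair indices per locus from the joint
        distribution of the category (flattened G*G index per locus)."""
        out = {}
        for name in loci:
            t = self._tables[name]
            size = len(t.genotypes)
            out[name] = rng.choice(size * size, size=n, p=t.joint_flat[category])
        return out

    def simulate_dyad_genotypes(
        self, category: str, n: int, rng: np.random.Generator,
        loci: list[str] | None = None,
    ) -> list[tuple[dict[str, Genotype], dict[str, Genotype]]]:
        """Simulate n dyads with the category's IBD coefficients; genotypes
        drawn from HWE at the model's allele frequencies, no genotyping
        error."""
        if loci is None:
            loci = self.freqs.locus_names
        flat = self.simulate_pair_indices(loci, category, n, rng)
        dyads = []
        for i in range(n):
            gx: dict[str, Genotype] = {}
            gy: dict[str, Genotype] = {}
            for name in loci:
                t = self._tables[name]
                size = len(t.genotypes)
                idx = flat[name][i]
                gx[name] = t.genotypes[idx // size]
                gy[name] = t.genotypes[idx % size]
            dyads.append((gx, gy))
        return dyads

    # -- likelihood-ratio tests -----------------------------------------

    def _sim_log_likelihoods(
        self,
        loci: list[str],
        categories: tuple[str, ...],
        sim_flat: dict[str, np.ndarray],
        n: int,
    ) -> dict[str, np.ndarray]:
        """Log-likelihood of each simulated dyad under each category."""
        out = {cat: np.zeros(n) for cat in categories}
        for name in loci:
            t = self._tables[name]
            size = len(t.genotypes)
            i1 = sim_flat[name] // size
            i2 = sim_flat[name] % size
            for cat in categories:
                out[cat] += t.log_joint[cat][i1, i2]
        return out

    def _null_statistics(
        self,
        loci: tuple[str, ...],
        primary: str,
        nulls: tuple[str, ...],
        n_sims: int,
    ) -> np.ndarray:
        """Null distribution of logL(primary) - max logL(null) for dyads
        simulated under the equal-weight mixture of the null categories."""
        key = (loci, primary, nulls, n_sims)
        if key in self._null_cache:
            return self._null_cache[key]
        # independent, reproducible stream per (loci, comparison); the key
        # is hashed with a stable digest so runs are repeatable
        digest = int.from_bytes(
            hashlib.sha256(repr(key).encode()).digest()[:4], "little"
        )
        rng = np.random.default_rng(
            np.random.SeedSequence(
                entropy=0 if self.seed is None else self.seed,
                spawn_key=(digest,),
            )
        )
        loci_list = list(loci)
        cats = rng.integers(0, len(nulls), size=n_sims)
        sim_flat = {name: np.empty(n_sims, dtype=np.int64) for name in loci_list}
        for c, cat in enumerate(nulls):
            mask = cats == c
            n_c = int(mask.sum())
            if n_c == 0:
                continue
            drawn = self.simulate_pair_indices(loci_list, cat, n_c, rng)
            for name in loci_list:
                sim_flat[name][mask] = drawn[name]
        all_cats = tuple(dict.fromkeys((primary, *nulls)))
        logls = self._sim_log_likelihoods(loci_list, all_cats, sim_flat, n_sims)
        null_max = np.maximum.reduce([logls[c] for c in nulls])
        stats = logls[primary] - null_max
        self._null_cache[key] = stats
        return stats

    def lrt(
        self,
        gx: dict[str, Genotype | None],
        gy: dict[str, Genotype | None],
        n_null_sims: int = 1000,
    ) -> LRTResult:
        """Run the five standard pedigree hypothesis comparisons.

        Each statistic is logL(primary) - max over that comparison's null
        hypotheses of logL(null); its p-value is the add-one-corrected
        proportion of dyads simulated under the equal-weight null mixture
        with a statistic at least as large.  The accepted hypothesis is
        the primary with the lowest p-value, ties broken toward the less
        related hypothesis.
        """
        loci = tuple(sorted(_shared_loci(gx, gy)))
        if not loci:
            raise ValueError("no mutually typed locus")
        obs = {
            cat: self.log_likelihood(gx, gy, cat) for cat in RELATEDNESS_ORDER
        }
        if all(not math.isfinite(v) for v in obs.values()):
            raise ValueError("likelihood undefined under every hypothesis")
        tests = []
        for primary, nulls in LRT_COMPARISONS:
            stat = obs[primary] - max(obs[c] for c in nulls)
            null_stats = self._null_statistics(loci, primary, nulls, n_null_sims)
            p = (1 + int(np.sum(null_stats >= stat - 1e-12))) / (n_null_sims + 1)
            tests.append((primary, float(stat), float(p)))
        # lowest p wins; Monte-Carlo p-values are granular (floor 1/(n+1)),
        # so ties break first toward the hypothesis that fits best
        # (highest log-likelihood) and only then toward the less related one
        best = min(
            tests,
            key=lambda t: (
                t[2],
                -obs[t[0]],
                -RELATEDNESS_ORDER.index(t[0]),
            ),
        )
        return LRTResult(tests=tests, accepted=best[0], accepted_p=best[2])


def lrt_pedigree(
    gx: dict[str, Genotype | None],
    gy: dict[str, Genotype | None],
    freqs: AlleleFrequencyTable,
    n_null_sims: int = 1000,
    seed: int | None = None,
    model: DyadLikelihoodModel | None = None,
) -> LRTResult:
    """Convenience wrapper around :meth:`DyadLikelihoodModel.lrt`."""
    if model is None:
        model = DyadLikelihoodModel(freqs, seed=seed)
    return model.lrt(gx, gy, n_null_sims=n_null_sims)


# ---------------------------------------------------------------------------
# full per-pair estimation
# ---------------------------------------------------------------------------

def estimate_dyad(
    id1: str,
    id2: str,
    gx: dict[str, Genotype | None],
    gy: dict[str, Genotype | None],
    freqs: AlleleFrequencyTable,
    n_boot: int = 1000,
    n_null_sims: int = 1000,
    seed: int | None = None,
    model: DyadLikelihoodModel | None = None,
    distance_m: float | None = None,
    run_lrt: bool = True,
) -> DyadEstimate:
    """Compute every pairwise quantity for one dyad."""
    frac, count, n_loci = allele_sharing(gx, gy)
    rq = r_qg89(gx, gy, freqs)
    rl = r_lr99(gx, gy, freqs)
    rng = np.random.default_rng(seed)
    ci_q = ci_l = None
    if n_loci >= 2:
        if rq is not None:
            ci_q = bootstrap_ci(gx, gy, freqs, "qg89", n_boot=n_boot, rng=rng)
        if rl is not None:
            ci_l = bootstrap_ci(gx, gy, freqs, "lr99", n_boot=n_boot, rng=rng)
    lrt_result = None
    if run_lrt:
        lrt_result = lrt_pedigree(
            gx, gy, freqs, n_null_sims=n_null_sims, seed=seed, model=model
        )
    return DyadEstimate(
        id1=id1,
        id2=id2,
        r_qg89=rq,
        r_lr99=rl,
        ci_qg89=ci_q,
        ci_lr99=ci_l,
        shared_loci_fraction=frac,
        shared_allele_count=count,
        n_shared_loci=n_loci,
        lrt=lrt_result,
        distance_m=distance_m,
    )
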