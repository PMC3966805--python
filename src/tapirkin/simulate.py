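"""Synthetic study generator: loci, pedigree, landscape and noisy PCRs.

Generates a complete synthetic analogue of a non-invasive microsatellite
kinship study with full truth tables, so that every pipeline stage can be
tested end to end without external data:

* a locus set matching the reference panel's allele richness
  (7, 6, 10, 5, 5 alleles) and expected heterozygosities,
* a two-generation pedigree under a chosen mating system (monogamy,
  polygyny, polygamy) with spatial positions on a two-margin landscape,
* replicate-PCR observations with amplification failure, allelic dropout
  and false-allele errors, plus recaptured (duplicate) samples.

The default scenario mirrors the reference study's scale: 32 individuals,
5 loci, two margins, polygamous mating, a handful of recaptures.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import BALBINA_ALLELE_COUNTS, BALBINA_HE, BALBINA_LOCUS_SUMMARY
from .genotypes import Genotype, Locus
from .popgen import AlleleFrequencyTable, LocusFrequencies
from .relatedness import CANONICAL_K, KCoefficients

logger = logging.getLogger("tapirkin")


@dataclass
class LandscapeConfig:
    """A rectangular two-margin landscape (planar meters).

    The divider (a vertical line, emulating the open water between the
    reservoir's margins) splits individuals into east/west groups.
    Offspring settle at the mean parental position plus an
    exponential-kernel dispersal draw.
    """

    extent_x: float = 30_000.0
    extent_y: float = 20_000.0
    divider_x: float = 15_000.0
    dispersal_mean_m: float = 5_000.0

    def __post_init__(self) -> None:
        if self.extent_x <= 0 or self.extent_y <= 0:
            raise ValueError("extent must be positive")
        if self.dispersal_mean_m <= 0:
            raise ValueError("dispersal mean must be positive")

    def margin(self, x: float) -> str:
        return "west" if x < self.divider_x else "east"


@dataclass
class ErrorModel:
    """Per-PCR genotyping error rates for degraded (fecal) DNA.

    Dropout is per allele per PCR (a heterozygote appearing homozygous);
    false alleles are per PCR (one observed allele replaced by another of
    the locus); failure is whole-PCR non-amplification.
    """

    dropout_rate: float = 0.10
    false_allele_rate: float = 0.02
    failure_rate: float = 0.20

    def __post_init__(self) -> None:
        for v in (self.dropout_rate, self.false_allele_rate, self.failure_rate):
            if not 0.0 <= v < 1.0:
                raise ValueError("error rates must lie in [0, 1)")


ZERO_ERROR = ErrorModel(0.0, 0.0, 0.0)


@dataclass
class TruthTables:
    """Ground truth of a simulated population."""

    loci: list[Locus]
    freqs: AlleleFrequencyTable
    individuals: pd.DataFrame  # id, sex, generation, dam, sire, x, y, margin
    genotypes: dict[str, dict[str, Genotype]]
    mating: str

    def parents(self, ind_id: str) -> tuple[str | None, str | None]:
        row = self.individuals.set_index("individual_id").loc[ind_id]
        dam = None if pd.isna(row["dam"]) else row["dam"]
        sire = None if pd.isna(row["sire"]) else row["sire"]
        return dam, sire

    def pair_category(self, id1: str, id2: str) -> str:
        """True relationship category of a dyad from the pedigree."""
        d1, s1 = self.parents(id1)
        d2, s2 = self.parents(id2)
        if id1 in (d2, s2) or id2 in (d1, s1):
            return "PO"
        p1 = {p for p in (d1, s1) if p is not None}
        p2 = {p for p in (d2, s2) if p is not None}
        if p1 and p1 == p2:
            return "FS"
        if len(p1 & p2) == 1:
            return "HS"
        return "UN"

    def pair_k(self, id1: str, id2: str) -> KCoefficients:
        return CANONICAL_K[self.pair_category(id1, id2)]

    def truth_pairs(self) -> pd.DataFrame:
        """All unordered dyads with their true category and k row."""
        ids = list(self.individuals["individual_id"])
        rows = []
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                cat = self.pair_category(a, b)
                k = CANONICAL_K[cat]
                rows.append(
                    {
                        "id1": a,
                        "id2": b,
                        "category": cat,
                        "k0": k.k0,
                        "k1": k.k1,
                        "k2": k.k2,
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# locus set
# ---------------------------------------------------------------------------

def _he(p: np.ndarray) -> float:
    return float(1.0 - (p**2).sum())


def _frequencies_for_he(
    n_alleles: int, target_he: float, rng: np.random.Generator, tol: float = 0.03
) -> np.ndarray:
    """Dirichlet draw interpolated toward the uniform vector until the
    expected heterozygosity 1 - sum p^2 is within ``tol`` of the target
    (exact where attainable)."""
    uniform = np.full(n_alleles, 1.0 / n_alleles)
    he_max = _he(uniform)
    for _ in range(10_000):
        draw = rng.dirichlet(np.ones(n_alleles))
        if target_he >= he_max:
            if he_max >= target_he - tol:
                return uniform
            continue
        if _he(draw) > target_he:
            continue  # draw already more even than the target
        lo, hi = 0.0, 1.0  # p(t) = (1-t)*uniform + t*draw
        for _ in range(60):
            mid = (lo + hi) / 2
            if _he((1 - mid) * uniform + mid * draw) > target_he:
                lo = mid
            else:
                hi = mid
        p = (1 - hi) * uniform + hi * draw
        if abs(_he(p) - target_he) <= tol:
            return p
    raise RuntimeError(
        f"could not match He={target_he} with {n_alleles} alleles in 10000 draws"
    )


def make_locus_set(
    template: str = "table1",
    seed: int | None = None,
    allele_counts: tuple[int, ...] | None = None,
    target_he: tuple[float, ...] | None = None,
) -> tuple[list[Locus], AlleleFrequencyTable]:
    """Loci and founder allele frequencies.

    The ``table1`` template reproduces the reference panel: 5 loci with
    allele richness (7, 6, 10, 5, 5) and expected heterozygosities
    within 0.03 of (0.78, 0.77, 0.86, 0.81, 0.63); allele labels are
    realistic fragment sizes (bp).  The ``custom`` template takes
    explicit ``allele_counts`` and ``target_he``.
    """
    if template == "table1":
        names = list(BALBINA_LOCUS_SUMMARY)
        counts = BALBINA_ALLELE_COUNTS
        targets = BALBINA_HE
    elif template == "custom":
        if allele_counts is None or target_he is None:
            raise ValueError("custom template needs allele_counts and target_he")
        counts = tuple(allele_counts)
        targets = tuple(target_he)
        names = [f"L{i + 1}" for i in range(len(counts))]
    else:
        raise ValueError(f"unknown template {template!r}")
    rng = np.random.default_rng(seed)
    loci = []
    table = {}
    base_size = 140
    for name, a_count, he_t in zip(names, counts, targets):
        alleles = tuple(base_size + 2 * k for k in range(a_count))
        base_size += 2 * a_count + 10  # non-overlapping size ranges
        p = _frequencies_for_he(a_count, he_t, rng)
        loci.append(Locus(name, alleles))
        table[name] = LocusFrequencies(
            locus=name,
            freqs={a: float(pi) for a, pi in zip(alleles, p)},
            n_typed=0,
            monomorphic=a_count == 1,
        )
    return loci, AlleleFrequencyTable(table)


# ---------------------------------------------------------------------------
# pedigree + landscape
# ---------------------------------------------------------------------------

def _hwe_genotype(
    lf: LocusFrequencies, rng: np.random.Generator
) -> Genotype:
    alleles = sorted(lf.freqs)
    probs = [lf.freqs[a] for a in alleles]
    a, b = rng.choice(alleles, size=2, p=probs)
    return (int(a), int(b)) if a <= b else (int(b), int(a))


def _disperse(
    x: float, y: float, landscape: LandscapeConfig, rng: np.random.Generator
) -> tuple[float, float]:
    dist = rng.exponential(landscape.dispersal_mean_m)
    angle = rng.uniform(0.0, 2.0 * math.pi)
    nx = min(max(x + dist * math.cos(angle), 0.0), landscape.extent_x)
    ny = min(max(y + dist * math.sin(angle), 0.0), landscape.extent_y)
    return nx, ny


def simulate_population(
    loci: list[Locus],
    freqs: AlleleFrequencyTable,
    mating: str = "polygamy",
    n_founders: int = 12,
    n_offspring: int = 20,
    landscape: LandscapeConfig | None = None,
    seed: int | None = None,
    ensure_unique_genotypes: bool = True,
) -> TruthTables:
    """Simulate a two-generation population with known pedigree.

    Founders are unrelated HWE draws placed uniformly on the landscape;
    offspring genotypes are Mendelian and offspring settle at the mean
    parental position plus a dispersal draw.  Mating systems: monogamy
    (exclusive pairs), polygyny (each dam has one sire, sires may have
    several dams), polygamy (each offspring draws dam and sire
    independently).

    With ``ensure_unique_genotypes`` (default) the simulation redraws
    until every individual's multilocus genotype is distinct, so that
    genotype identity uniquely flags recaptures — the sampling regime the
    reference study's probability-of-identity analysis certifies.
    """
    if n_founders < 4:
        raise ValueError("need at least 4 founders")
    if mating not in ("monogamy", "polygyny", "polygamy"):
        raise ValueError(f"unknown mating system {mating!r}")
    if landscape is None:
        landscape = LandscapeConfig()
    root = np.random.default_rng(seed)
    for attempt in range(100):
        rng = np.random.default_rng(root.integers(2**31))
        truth = _simulate_once(
            loci, freqs, mating, n_founders, n_offspring, landscape, rng
        )
        if not ensure_unique_genotypes:
            return truth
        profiles = {
            tuple(sorted(g.items())) for g in truth.genotypes.values()
        }
        if len(profiles) == len(truth.genotypes):
            return truth
        logger.info("duplicate multilocus genotype drawn; redrawing population")
    raise RuntimeError("could not draw a population with unique genotypes")


def _simulate_once(
    loci, freqs, mating, n_founders, n_offspring, landscape, rng
) -> TruthTables:
    rows = []
    genotypes: dict[str, dict[str, Genotype]] = {}
    founders = [f"F{i + 1:02d}" for i in range(n_founders)]
    sexes = ["female", "male"] * (n_founders // 2 + 1)
    for ind_id, sex in zip(founders, sexes):
        x = float(rng.uniform(0, landscape.extent_x))
        y = float(rng.uniform(0, landscape.extent_y))
        rows.append(
            {
                "individual_id": ind_id,
                "sex": sex,
                "generation": 0,
                "dam": None,
                "sire": None,
                "x": x,
                "y": y,
                "margin": landscape.margin(x),
            }
        )
        genotypes[ind_id] = {
            locus.name: _hwe_genotype(freqs[locus.name], rng) for locus in loci
        }
    dams = [r["individual_id"] for r in rows if r["sex"] == "female"]
    sires = [r["individual_id"] for r in rows if r["sex"] == "male"]

    if mating == "monogamy":
        pairs = list(
            zip(rng.permutation(dams), rng.permutation(sires))
        )
        parent_draw = lambda: pairs[rng.integers(len(pairs))]
    elif mating == "polygyny":
        assigned = {dam: sires[rng.integers(len(sires))] for dam in dams}
        parent_draw = lambda: (
            (d := dams[rng.integers(len(dams))]),
            assigned[d],
        )
    else:  # polygamy
        parent_draw = lambda: (
            dams[rng.integers(len(dams))],
            sires[rng.integers(len(sires))],
        )

    positions = {r["individual_id"]: (r["x"], r["y"]) for r in rows}
    for j in range(n_offspring):
        ind_id = f"O{j + 1:02d}"
        dam, sire = parent_draw()
        genotype = {}
        for locus in loci:
            ga, gb = genotypes[dam][locus.name], genotypes[sire][locus.name]
            a = ga[rng.integers(2)]
            b = gb[rng.integers(2)]
            genotype[locus.name] = (a, b) if a <= b else (b, a)
        mx = (positions[dam][0] + positions[sire][0]) / 2
        my = (positions[dam][1] + positions[sire][1]) / 2
        x, y = _disperse(mx, my, landscape, rng)
        rows.append(
            {
                "individual_id": ind_id,
                "sex": ("female", "male")[int(rng.integers(2))],
                "generation": 1,
                "dam": dam,
                "sire": sire,
                "x": x,
                "y": y,
                "margin": landscape.margin(x),
            }
        )
        genotypes[ind_id] = genotype
    return TruthTables(
        loci=loci,
        freqs=freqs,
        individuals=pd.DataFrame(rows),
        genotypes=genotypes,
        mating=mating,
    )


# ---------------------------------------------------------------------------
# replicate-PCR observation
# ---------------------------------------------------------------------------

def _observe_once(
    g: Genotype, locus: Locus, error: ErrorModel, rng: np.random.Generator
) -> Genotype | None:
    """One PCR of one true genotype under the error model."""
    if rng.random() < error.failure_rate:
        return None
    alleles = [a for a in g if rng.random() >= error.dropout_rate]
    if not alleles:
        return None  # both copies dropped: no product
    if len(alleles) == 1:
        alleles = [alleles[0], alleles[0]]
    if error.false_allele_rate and rng.random() < error.false_allele_rate:
        pos = int(rng.integers(2))
        others = [a for a in locus.alleles if a != alleles[pos]]
        if others:
            alleles[pos] = int(others[rng.integers(len(others))])
    a, b = alleles
    return (a, b) if a <= b else (b, a)


def observe_replicates(
    truth: TruthTables,
    error: ErrorModel | None = None,
    n_replicates: int = 7,
    n_recaptures: int = 4,
    sample_ids: list[str] | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Emit a replicate-PCR table and sample metadata from the truth.

    Every individual (or the subset ``sample_ids``) yields one fecal
    sample; ``n_recaptures`` randomly chosen individuals yield a second
    sample at a nearby point (offset < 1 km).  Returns (replicate table,
    metadata, sample->individual truth map).
    """
    if error is None:
        error = ErrorModel()
    rng = np.random.default_rng(seed)
    ids = sample_ids or list(truth.individuals["individual_id"])
    pos = truth.individuals.set_index("individual_id")
    recaptured = list(
        rng.choice(ids, size=min(n_recaptures, len(ids)), replace=False)
    )
    samples = []  # (sample_id, individual_id, x, y)
    for ind_id in ids:
        x, y = float(pos.loc[ind_id, "x"]), float(pos.loc[ind_id, "y"])
        samples.append((f"S_{ind_id}", ind_id, x, y))
    for ind_id in recaptured:
        x, y = float(pos.loc[ind_id, "x"]), float(pos.loc[ind_id, "y"])
        offset = rng.uniform(50.0, 950.0)
        angle = rng.uniform(0.0, 2.0 * math.pi)
        samples.append(
            (
                f"S_{ind_id}_b",
                ind_id,
                x + offset * math.cos(angle),
                y + offset * math.sin(angle),
            )
        )
    loci_by_name = {locus.name: locus for locus in truth.loci}
    rep_rows = []
    for sample_id, ind_id, _, _ in samples:
        for name, g in truth.genotypes[ind_id].items():
            for rep in range(1, n_replicates + 1):
                call = _observe_once(g, loci_by_name[name], error, rng)
                rep_rows.append(
                    {
                        "sample_id": sample_id,
                        "locus": name,
                        "replicate_index": rep,
                        "allele1": None if call is None else call[0],
                        "allele2": None if call is None else call[1],
                    }
                )
    meta_rows = [
        {
            "sample_id": s,
            "x": x,
            "y": y,
            "margin": pos.loc[ind, "margin"],
        }
        for s, ind, x, y in samples
    ]
    sample_map = pd.DataFrame(
        [{"sample_id": s, "individual_id": ind} for s, ind, _, _ in samples]
    )
    return pd.DataFrame(rep_rows), pd.DataFrame(meta_rows), sample_map


def default_scenario(
    seed: int | None = None,
    mating: str = "polygamy",
    n_founders: int = 12,
    n_offspring: int = 20,
    n_recaptures: int = 4,
    error: ErrorModel | None = None,
) -> tuple[TruthTables, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """The study-scale synthetic scenario: reference-panel loci, 32
    individuals on a two-margin landscape, noisy replicate PCRs and a few
    recaptures.  Returns (truth, replicate table, metadata, sample map)."""
    seq = np.random.SeedSequence(seed if seed is not None else 0)
    s1, s2, s3 = (int(s.generate_state(1)[0] % (2**31)) for s in seq.spawn(3))
    loci, freqs = make_locus_set("table1", seed=s1)
    truth = simulate_population(
        loci,
        freqs,
        mating=mating,
        n_founders=n_founders,
        n_offspring=n_offspring,
        seed=s2,
    )
    replicates, metadata, sample_map = observe_replicates(
        truth, error=error, n_recaptures=n_recaptures, seed=s3
    )
    return truth, replicates, metadata, sample_map
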