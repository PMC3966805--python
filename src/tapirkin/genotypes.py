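"""Genotype containers, replicate-PCR consensus calling and panel I/O.

Non-invasive (fecal) DNA yields degraded template, so every sample x locus
combination is amplified several times ("multiple-tube" approach) and a
genotype is accepted only when the same unordered allele pair is observed
consistently across PCRs.  This module holds the data containers for that
workflow, the consensus rule, recapture identification (distinct samples
with identical multilocus genotypes are the same individual), completeness
filtering, and GenePop import/export.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import pandas as pd

logger = logging.getLogger("tapirkin")

#: unordered diploid genotype, stored sorted; ``None`` marks a missing call
Genotype = tuple[int, int]

MARGINS = ("east", "west", "unassigned")


class ParseError(ValueError):
    """A malformed input row (message names the offending line)."""


class AmbiguousConsensusError(ValueError):
    """Two distinct allele pairs both reached the consensus threshold.

    In the multiple-tube protocol this pattern signals cross-sample
    contamination rather than stochastic dropout, so it is an error and not
    a missing call.
    """


@dataclass(frozen=True)
class Locus:
    """A microsatellite locus: a name and its known allele sizes (bp)."""

    name: str
    alleles: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.alleles) < 1:
            raise ValueError(f"locus {self.name}: needs at least one allele")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"locus {self.name}: duplicate allele labels")


@dataclass
class ReplicateGenotypeSet:
    """Per-PCR allele calls for one sample at one locus, in PCR order.

    Each replicate is either ``None`` (amplification failure) or an
    unordered allele pair.
    """

    sample_id: str
    locus: str
    replicates: list[Genotype | None] = field(default_factory=list)


@dataclass
class IndividualGenotype:
    """Consensus multilocus genotype plus collection coordinates.

    Coordinates are planar meters (projected, e.g. UTM); distances derived
    from them are straight-line Euclidean.
    """

    individual_id: str
    genotype: dict[str, Genotype | None] = field(default_factory=dict)
    x: float | None = None
    y: float | None = None
    margin: str = "unassigned"

    def __post_init__(self) -> None:
        if self.margin not in MARGINS:
            raise ValueError(f"unknown margin {self.margin!r}")

    def typed_loci(self) -> list[str]:
        return [name for name, g in self.genotype.items() if g is not None]

    def n_typed(self) -> int:
        return len(self.typed_loci())

    def has_coordinates(self) -> bool:
        return self.x is not None and self.y is not None


@dataclass
class GenotypePanel:
    """A set of loci and the individuals genotyped at them."""

    loci: list[Locus]
    individuals: list[IndividualGenotype]

    def __post_init__(self) -> None:
        ids = [ind.individual_id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual ids in panel")
        known = {locus.name for locus in self.loci}
        for ind in self.individuals:
            extra = set(ind.genotype) - known
            if extra:
                raise ValueError(
                    f"{ind.individual_id}: genotype at unknown loci {sorted(extra)}"
                )

    @property
    def locus_names(self) -> list[str]:
        return [locus.name for locus in self.loci]

    def get(self, individual_id: str) -> IndividualGenotype:
        for ind in self.individuals:
            if ind.individual_id == individual_id:
                return ind
        raise KeyError(individual_id)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per individual x locus."""
        rows = []
        for ind in self.individuals:
            for name in self.locus_names:
                g = ind.genotype.get(name)
                rows.append(
                    {
                        "individual_id": ind.individual_id,
                        "locus": name,
                        "allele1": None if g is None else g[0],
                        "allele2": None if g is None else g[1],
                    }
                )
        return pd.DataFrame(rows)


def _norm_pair(a: int, b: int) -> Genotype:
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# replicate-table input
# ---------------------------------------------------------------------------

REPLICATE_COLUMNS = ["sample_id", "locus", "replicate_index", "allele1", "allele2"]


def read_replicate_table(
    path,
    format: str = "csv",
    loci: list[Locus] | None = None,
) -> list[ReplicateGenotypeSet]:
    """Read per-PCR allele calls into one :class:`ReplicateGenotypeSet`
    per (sample, locus).

    Expected columns: sample_id, locus, replicate_index, allele1, allele2.
    A row with both alleles blank is an amplification failure; a row with a
    single allele is read as a homozygote observation (electropherogram
    convention).  Replicate order follows ``replicate_index``.
    """
    sep = {"csv": ",", "tsv": "\t"}[format]
    table = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "locus": str})
    missing = [c for c in REPLICATE_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if table.empty:
        logger.warning("%s: empty replicate table", path)
        return []

    known = {locus.name: set(locus.alleles) for locus in loci} if loci else None
    sets: dict[tuple[str, str], list[tuple[int, Genotype | None]]] = {}
    for row in table.itertuples():
        line_no = row.Index + 2  # 1-based, after the header line
        a1, a2 = row.allele1, row.allele2
        if pd.isna(a1) and pd.isna(a2):
            call: Genotype | None = None
        else:
            if pd.isna(a1):
                a1 = a2
            if pd.isna(a2):
                a2 = a1
            try:
                call = _norm_pair(int(a1), int(a2))
            except (TypeError, ValueError) as exc:
                raise ParseError(f"{path} line {line_no}: bad allele call") from exc
        if known is not None:
            if row.locus not in known:
                raise ParseError(f"{path} line {line_no}: unknown locus {row.locus!r}")
            if call is not None and not set(call) <= known[row.locus]:
                raise ParseError(
                    f"{path} line {line_no}: allele outside locus {row.locus} set"
                )
        try:
            idx = int(row.replicate_index)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path} line {line_no}: bad replicate_index") from exc
        sets.setdefault((row.sample_id, row.locus), []).append((idx, call))

    out = []
    for (sample_id, locus_name), calls in sets.items():
        calls.sort(key=lambda item: item[0])
        out.append(
            ReplicateGenotypeSet(sample_id, locus_name, [c for _, c in calls])
        )
    return out


# ---------------------------------------------------------------------------
# multiple-tube consensus
# ---------------------------------------------------------------------------

def consensus_call(
    reps: ReplicateGenotypeSet,
    min_consistent: int = 3,
    max_reps: int = 7,
    max_consecutive_failures: int = 5,
) -> Genotype | None:
    """Collapse replicate PCRs into a consensus genotype.

    The consensus is the unordered allele pair observed in at least
    ``min_consistent`` of the first ``max_reps`` replicates.  A run of
    ``max_consecutive_failures`` failed PCRs before any pair reaches the
    threshold discards the sample-locus (returns missing).  Two distinct
    pairs both reaching the threshold raise
    :class:`AmbiguousConsensusError`.

    Replicates are evaluated in the order given: the consecutive-failure
    rule is sequential by design.
    """
    if not reps.replicates:
        raise ValueError(f"{reps.sample_id}/{reps.locus}: no replicates")
    counts: dict[Genotype, int] = {}
    consecutive_failures = 0
    reached: list[Genotype] = []
    for call in reps.replicates[:max_reps]:
        if call is None:
            consecutive_failures += 1
            if consecutive_failures >= max_consecutive_failures and not reached:
                return None
            continue
        consecutive_failures = 0
        counts[call] = counts.get(call, 0) + 1
        if counts[call] == min_consistent:
            reached.append(call)
    if len(reached) > 1:
        raise AmbiguousConsensusError(
            f"{reps.sample_id}/{reps.locus}: pairs {reached} all reached "
            f"{min_consistent} consistent observations"
        )
    return reached[0] if reached else None


def consensus_panel(
    replicate_sets: list[ReplicateGenotypeSet],
    loci: list[Locus],
    metadata: pd.DataFrame | None = None,
    min_consistent: int = 3,
    max_reps: int = 7,
    max_consecutive_failures: int = 5,
    on_ambiguity: str = "missing",
) -> GenotypePanel:
    """Apply :func:`consensus_call` to every sample x locus and assemble a
    per-sample panel (one entry per sample; recaptures not yet merged).

    ``metadata`` columns: sample_id, x, y, margin (x/y/margin optional).

    ``on_ambiguity`` controls what happens when two distinct pairs both
    reach the consensus threshold at one sample-locus: ``"missing"``
    (default) discards that sample-locus with a warning — allelic dropout
    can legitimately push a false homozygote to the threshold alongside
    the true heterozygote, and the protocol response at the PCR cap is to
    discard — while ``"raise"`` propagates the error.
    """
    meta: dict[str, dict] = {}
    if metadata is not None:
        for row in metadata.itertuples():
            meta[str(row.sample_id)] = {
                "x": None if pd.isna(getattr(row, "x", None)) else float(row.x),
                "y": None if pd.isna(getattr(row, "y", None)) else float(row.y),
                "margin": getattr(row, "margin", "unassigned"),
            }
    calls: dict[str, dict[str, Genotype | None]] = {}
    for reps in replicate_sets:
        try:
            call = consensus_call(
                reps, min_consistent, max_reps, max_consecutive_failures
            )
        except AmbiguousConsensusError:
            if on_ambiguity != "missing":
                raise
            logger.warning(
                "%s/%s: ambiguous consensus, sample-locus discarded",
                reps.sample_id,
                reps.locus,
            )
            call = None
        calls.setdefault(reps.sample_id, {})[reps.locus] = call
    individuals = []
    for sample_id, genotype in calls.items():
        info = meta.get(sample_id, {})
        margin = info.get("margin", "unassigned")
        if margin is None or (isinstance(margin, float) and math.isnan(margin)):
            margin = "unassigned"
        individuals.append(
            IndividualGenotype(
                individual_id=sample_id,
                genotype=genotype,
                x=info.get("x"),
                y=info.get("y"),
                margin=str(margin),
            )
        )
    return GenotypePanel(loci=loci, individuals=individuals)


# ---------------------------------------------------------------------------
# recapture identification
# ---------------------------------------------------------------------------

def _genotypes_match(
    a: IndividualGenotype, b: IndividualGenotype, min_shared_loci: int
) -> bool:
    shared = [n for n in a.typed_loci() if b.genotype.get(n) is not None]
    if len(shared) < min_shared_loci:
        return False
    return all(a.genotype[n] == b.genotype[n] for n in shared)


def identify_recaptures(
    panel: GenotypePanel, min_shared_loci: int = 3
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Merge samples with identical genotypes into unique individuals.

    Two samples are the same individual when their genotypes agree exactly
    at every mutually typed locus, with at least ``min_shared_loci`` such
    loci (exact-match identity is defensible when the multilocus P(ID)sib
    of the shared loci is small).  Returns the merged panel and a recapture
    table (individual_id, sample ids, distance between collection points).

    Merging uses a union-find over all matching pairs, so the result does
    not depend on sample order.
    """
    samples = panel.individuals
    n = len(samples)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _genotypes_match(samples[i], samples[j], min_shared_loci):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    merged: list[IndividualGenotype] = []
    records = []
    for root in sorted(groups):
        members = sorted(groups[root])
        rep = samples[members[0]]
        genotype: dict[str, Genotype | None] = dict(rep.genotype)
        for k in members[1:]:
            for name, g in samples[k].genotype.items():
                if g is None:
                    genotype.setdefault(name, None)
                elif genotype.get(name) is None:
                    genotype[name] = g
                elif genotype[name] != g:
                    # only possible through transitive matches on noisy
                    # calls: the locus is unreliable for this individual
                    logger.warning(
                        "recapture merge: conflicting calls at %s for %s; "
                        "locus set to missing",
                        name,
                        rep.individual_id,
                    )
                    genotype[name] = None
        margin = rep.margin
        if margin == "unassigned":
            for k in members[1:]:
                if samples[k].margin != "unassigned":
                    margin = samples[k].margin
                    break
        merged.append(
            replace(rep, genotype=genotype, margin=margin)
        )
        if len(members) > 1:
            for a_i, b_i in zip(members, members[1:]):
                a, b = samples[a_i], samples[b_i]
                dist = None
                if a.has_coordinates() and b.has_coordinates():
                    dist = math.hypot(a.x - b.x, a.y - b.y)
                records.append(
                    {
                        "individual_id": rep.individual_id,
                        "sample_a": a.individual_id,
                        "sample_b": b.individual_id,
                        "distance_m": dist,
                    }
                )
    recaptures = pd.DataFrame(
        records, columns=["individual_id", "sample_a", "sample_b", "distance_m"]
    )
    logger.info(
        "recapture merge: %d samples -> %d unique individuals", n, len(merged)
    )
    return GenotypePanel(loci=panel.loci, individuals=merged), recaptures


# ---------------------------------------------------------------------------
# completeness filter
# ---------------------------------------------------------------------------

def filter_by_completeness(panel: GenotypePanel, min_loci: int) -> GenotypePanel:
    """Keep individuals typed at >= ``min_loci`` loci."""
    if min_loci < 1:
        raise ValueError("min_loci must be >= 1")
    if min_loci > len(panel.loci):
        raise ValueError(
            f"min_loci={min_loci} exceeds the {len(panel.loci)} panel loci"
        )
    kept = [ind for ind in panel.individuals if ind.n_typed() >= min_loci]
    logger.info(
        "completeness filter (>=%d loci): kept %d, dropped %d",
        min_loci,
        len(kept),
        len(panel.individuals) - len(kept),
    )
    return GenotypePanel(loci=panel.loci, individuals=kept)


# ---------------------------------------------------------------------------
# GenePop interchange
# ---------------------------------------------------------------------------

def write_genepop(panel: GenotypePanel, path) -> None:
    """Write the panel as a GenePop file (3-digit allele codes, one Pop
    block per margin in east/west/unassigned order).

    Coordinates are not part of the GenePop format and are not written;
    the title line records the Pop-block margin order so that
    :func:`read_genepop` can restore margin labels.
    """
    for locus in panel.loci:
        for allele in locus.alleles:
            if not 0 < allele <= 999:
                raise ValueError(
                    f"allele {allele} at {locus.name} not encodable as 3 digits"
                )
    order = [
        m
        for m in MARGINS
        if any(ind.margin == m for ind in panel.individuals)
    ]
    lines = ["tapirkin export; pops=" + ",".join(order)]
    lines.extend(panel.locus_names)
    for margin in order:
        lines.append("Pop")
        for ind in panel.individuals:
            if ind.margin != margin:
                continue
            codes = []
            for name in panel.locus_names:
                g = ind.genotype.get(name)
                codes.append("000000" if g is None else f"{g[0]:03d}{g[1]:03d}")
            lines.append(f"{ind.individual_id} ,  " + " ".join(codes))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_genepop(path) -> GenotypePanel:
    """Read a GenePop file written by :func:`write_genepop`."""
    with open(path) as fh:
        raw = [line.rstrip("\n") for line in fh]
    title = raw[0]
    pop_order: list[str] = []
    if "pops=" in title:
        tail = title.split("pops=", 1)[1].strip()
        pop_order = [m for m in tail.split(",") if m]
    locus_names = []
    i = 1
    while i < len(raw) and raw[i].strip().lower() != "pop":
        if raw[i].strip():
            locus_names.append(raw[i].strip())
        i += 1
    individuals = []
    alleles: dict[str, set[int]] = {name: set() for name in locus_names}
    pop_idx = -1
    while i < len(raw):
        line = raw[i].strip()
        i += 1
        if not line:
            continue
        if line.lower() == "pop":
            pop_idx += 1
            continue
        ind_id, _, genostr = line.partition(",")
        codes = genostr.split()
        if len(codes) != len(locus_names):
            raise ParseError(f"{path} line {i}: expected {len(locus_names)} codes")
        genotype: dict[str, Genotype | None] = {}
        for name, code in zip(locus_names, codes):
            a, b = int(code[:3]), int(code[3:])
            if a == 0 or b == 0:
                genotype[name] = None
            else:
                genotype[name] = _norm_pair(a, b)
                alleles[name].update((a, b))
        margin = (
            pop_order[pop_idx]
            if 0 <= pop_idx < len(pop_order)
            else "unassigned"
        )
        individuals.append(
            IndividualGenotype(
                individual_id=ind_id.strip(), genotype=genotype, margin=margin
            )
        )
    # a locus with no typed individual still needs a non-empty allele set;
    # use a placeholder label (GenePop carries no allele inventory)
    loci = [
        Locus(name, tuple(sorted(alleles[name])) or (1,)) for name in locus_names
    ]
    return GenotypePanel(loci=loci, individuals=individuals)
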