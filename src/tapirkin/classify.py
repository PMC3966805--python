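"""Relationship classification of dyads from relatedness statistics.

Maps each dyad's bootstrap confidence intervals, allele-sharing pattern and
pedigree hypothesis tests onto a final relationship category:

* FO    — first-order relatives (parent-offspring or full sibs),
* HSFO1 — half-sib or first-order, CI lower bound in [0.25, 0.5),
* HSFO2 — half-sib or first-order, CI lower bound in [0.125, 0.25),
* UN    — unrelated,
* IN    — inconclusive.

The decision cascade is deterministic and audited: the allele-sharing FO
rule fires first, then the CI bands of both estimators (disagreements
resolved conservatively toward the less related category unless the
accepted pedigree hypothesis supports the more related one).  HSFO1/HSFO2
collapse to HS in final counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .relatedness import DyadEstimate

logger = logging.getLogger("tapirkin")

CI_CATEGORIES = ("FO", "HSFO1", "HSFO2", "UN", "IN")
FINAL_CATEGORIES = ("FO", "HS", "UN", "IN")

#: CI-band categories from most to least related (for conservative picks)
_CI_RANK = {"FO": 0, "HSFO1": 1, "HSFO2": 2, "IN": 3, "UN": 4}

#: accepted pedigree hypotheses compatible with each CI-band category
_HYPOTHESIS_SUPPORT = {
    "FO": {"PO", "FS"},
    "HSFO1": {"PO", "FS", "HS"},
    "HSFO2": {"PO", "FS", "HS"},
    "UN": {"UN"},
    "IN": set(),
}


@dataclass
class Classification:
    category: str  # final category: FO, HS, UN or IN
    ci_category: str | None  # pre-collapse CI band, if the CI rule fired
    rule: str  # which cascade rule decided: sharing / ci / ci-lrt / none


def classify_by_ci(ci: tuple[float, float]) -> str:
    """Classify a dyad from a bootstrap CI of its relatedness.

    Bands on the lower bound: >=0.5 FO; [0.25, 0.5) HSFO1;
    [0.125, 0.25) HSFO2.  UN when the upper bound is <= 0.  Inconclusive
    when the lower bound lies in (0, 0.125) or the interval spans zero
    and related values.
    """
    lower, upper = ci
    if lower > upper:
        raise ValueError(f"invalid interval ({lower}, {upper})")
    if lower >= 0.5:
        return "FO"
    if lower >= 0.25:
        return "HSFO1"
    if lower >= 0.125:
        return "HSFO2"
    if upper <= 0.0:
        return "UN"
    return "IN"


def classify_by_sharing(
    shared_allele_count: int,
    shared_loci_fraction: float,
    n_loci: int,
    min_alleles: int = 7,
    min_loci_fraction: float = 0.8,
) -> str | None:
    """Allele-sharing FO rule: FO iff the pair shares >= ``min_alleles``
    alleles at >= ``min_loci_fraction`` of the mutually typed loci;
    otherwise no call (None).  Requires >=4 mutually typed loci."""
    if n_loci < 4:
        raise ValueError("sharing rule requires >=4 mutually typed loci")
    if (
        shared_allele_count >= min_alleles
        and shared_loci_fraction >= min_loci_fraction
    ):
        return "FO"
    return None


def _collapse(ci_category: str) -> str:
    return "HS" if ci_category in ("HSFO1", "HSFO2") else ci_category


def classify_pair(dyad: DyadEstimate, use_sharing_rule: bool = True) -> Classification:
    """Apply the full decision cascade to one dyad.

    (a) the allele-sharing rule fires -> FO; (b) otherwise the CI rule on
    both estimators: agreement (or a single defined CI) decides; a
    disagreement goes to the LESS related band unless the accepted
    pedigree hypothesis (p < 0.05) supports the MORE related band;
    (c) HSFO1/HSFO2 report as HS in the final category.
    """
    if dyad.ci_lr99 is None and dyad.ci_qg89 is None:
        raise ValueError(f"{dyad.id1}-{dyad.id2}: no confidence interval")
    if use_sharing_rule and dyad.n_shared_loci >= 4:
        if (
            classify_by_sharing(
                dyad.shared_allele_count,
                dyad.shared_loci_fraction,
                dyad.n_shared_loci,
            )
            == "FO"
        ):
            return Classification("FO", None, "sharing")
    cats = [
        classify_by_ci(ci) for ci in (dyad.ci_lr99, dyad.ci_qg89) if ci is not None
    ]
    if len(cats) == 1 or cats[0] == cats[1]:
        cat = cats[0]
        return Classification(_collapse(cat), cat, "ci")
    less, more = sorted(cats, key=lambda c: _CI_RANK[c], reverse=True)
    chosen, rule = less, "ci"
    if dyad.lrt is not None and dyad.lrt.accepted_p < 0.05:
        if dyad.lrt.accepted in _HYPOTHESIS_SUPPORT[more]:
            chosen, rule = more, "ci-lrt"
        else:
            rule = "ci-lrt"
    return Classification(_collapse(chosen), chosen, rule)


def classify_all(
    dyads: list[DyadEstimate], use_sharing_rule: bool = True
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify every dyad; returns the relationship table (one row per
    unordered pair) and final category counts."""
    rows = []
    counts = {c: 0 for c in FINAL_CATEGORIES}
    for dyad in dyads:
        cls = classify_pair(dyad, use_sharing_rule=use_sharing_rule)
        counts[cls.category] += 1
        rows.append(
            {
                "id1": dyad.id1,
                "id2": dyad.id2,
                "mean_share": dyad.shared_loci_fraction,
                "allele_count": dyad.shared_allele_count,
                "n_loci": dyad.n_shared_loci,
                "r_lr99": dyad.r_lr99,
                "r_qg89": dyad.r_qg89,
                "ci_lr99_low": None if dyad.ci_lr99 is None else dyad.ci_lr99[0],
                "ci_lr99_high": None if dyad.ci_lr99 is None else dyad.ci_lr99[1],
                "ci_qg89_low": None if dyad.ci_qg89 is None else dyad.ci_qg89[0],
                "ci_qg89_high": None if dyad.ci_qg89 is None else dyad.ci_qg89[1],
                "lrt_accepted": None if dyad.lrt is None else dyad.lrt.accepted,
                "lrt_p": None if dyad.lrt is None else dyad.lrt.accepted_p,
                "conclusion": cls.category,
                "ci_band": cls.ci_category,
                "rule": cls.rule,
                "distance_m": dyad.distance_m,
            }
        )
    table = pd.DataFrame(rows)
    logger.info(
        "classified %d pairs: %s",
        len(rows),
        ", ".join(f"{k}={v}" for k, v in counts.items()),
    )
    return table, counts
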