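"""Spatial statistics for the kinship analysis.

Euclidean pairwise distances, a Mann-Whitney comparison of related versus
unrelated pair distances, a Mantel test of relatedness against geographic
distance, and Moran's I spatial autocorrelation of allele sharing at two
distance classes — an individual scale (pairs closer than a home-range
threshold, default 3 km) and a landscape scale (all farther pairs) — with
bootstrap confidence intervals over individuals.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypePanel

logger = logging.getLogger("tapirkin")


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray  # symmetric, meters, zero diagonal

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(m, m.T) or np.any(np.diag(m) != 0) or np.any(m < 0):
            raise ValueError("not a valid distance matrix")

    def get(self, id1: str, id2: str) -> float:
        i, j = self.ids.index(id1), self.ids.index(id2)
        return float(self.matrix[i, j])


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    n_permutations: int | None = None
    exact: bool = False


@dataclass
class SpatialAutocorrResult:
    scale: str  # "individual" (< threshold) or "landscape" (>= threshold)
    morans_i: float
    ci: tuple[float, float]
    boot_sd: float
    n_pairs: int


def pairwise_distances(panel: GenotypePanel) -> DistanceMatrix:
    """Straight-line planar distances (m) between located individuals;
    individuals without coordinates are excluded with a warning."""
    located = [ind for ind in panel.individuals if ind.has_coordinates()]
    skipped = len(panel.individuals) - len(located)
    if skipped:
        logger.warning("pairwise_distances: %d individuals lack coordinates", skipped)
    if len(located) < 2:
        raise ValueError("need >=2 located individuals")
    xy = np.array([[ind.x, ind.y] for ind in located])
    diff = xy[:, None, :] - xy[None, :, :]
    matrix = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(matrix, 0.0)
    return DistanceMatrix([ind.individual_id for ind in located], matrix)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def _w_statistic(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    n1 = len(x)
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)


def mann_whitney(
    distances_related: list[float], distances_unrelated: list[float]
) -> TestResult:
    """Two-sided Mann-Whitney U test (midranks for ties).

    The statistic W is the rank sum of the first sample minus
    n1(n1+1)/2 (R's wilcox.test convention).  The p-value is exact (full
    enumeration of group assignments) when n1+n2 <= 12, otherwise a
    normal approximation with tie correction and continuity correction.
    """
    x = np.asarray(distances_related, dtype=float)
    y = np.asarray(distances_unrelated, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    w = _w_statistic(x, y)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult("mann_whitney_W", w, 1.0, exact=True)
    if n1 + n2 <= 12:
        mu = n1 * n2 / 2
        count = 0
        total = 0
        idx = np.arange(n1 + n2)
        for comb in itertools.combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(comb)] = True
            w_perm = _w_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(w_perm - mu) >= abs(w - mu) - 1e-12:
                count += 1
        return TestResult("mann_whitney_W", w, count / total, exact=True)
    n = n1 + n2
    mu = n1 * n2 / 2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12 * ((n + 1) - tie_term)
    if var <= 0:
        return TestResult("mann_whitney_W", w, 1.0)
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    from scipy.stats import norm

    p = min(1.0, 2 * norm.sf(z))
    return TestResult("mann_whitney_W", w, p)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def _upper(matrix: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu]


def mantel(
    r_matrix: np.ndarray,
    distance_matrix: np.ndarray,
    n_permutations: int = 10_000,
    seed: int | None = None,
    tail: str = "negative",
) -> TestResult:
    """Mantel test: Pearson correlation of the upper triangles, with
    significance by simultaneous row/column permutation of one matrix.

    Missing entries (NaN) are masked pairwise.  The default tail is
    one-sided negative — the biological hypothesis is that relatives live
    closer, i.e. r decreases with distance.
    """
    a = np.asarray(r_matrix, dtype=float)
    b = np.asarray(distance_matrix, dtype=float)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    n = a.shape[0]

    def corr(mat_a: np.ndarray, mat_b: np.ndarray) -> float:
        va, vb = _upper(mat_a), _upper(mat_b)
        mask = ~(np.isnan(va) | np.isnan(vb))
        va, vb = va[mask], vb[mask]
        if va.size < 3 or np.std(va) == 0 or np.std(vb) == 0:
            raise ValueError("constant or empty matrix in Mantel test")
        return float(np.corrcoef(va, vb)[0, 1])

    stat = corr(a, b)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        stat_p = corr(a[np.ix_(perm, perm)], b)
        if tail == "negative":
            extreme = stat_p <= stat + 1e-12
        elif tail == "positive":
            extreme = stat_p >= stat - 1e-12
        else:
            extreme = abs(stat_p) >= abs(stat) - 1e-12
        hits += extreme
    p = (hits + 1) / (n_permutations + 1)
    return TestResult("mantel_r", stat, p, n_permutations=n_permutations)


# ---------------------------------------------------------------------------
# Moran's I of allele sharing by distance class
# ---------------------------------------------------------------------------

def _allele_dosage_matrix(panel: GenotypePanel, ids: list[str]) -> np.ndarray:
    """Individuals x (locus, allele) matrix of allele dosages / 2
    (0, 0.5 or 1); missing genotypes imputed at the column mean so that
    centering is unaffected."""
    individuals = {ind.individual_id: ind for ind in panel.individuals}
    cols = []
    for locus in panel.loci:
        for allele in locus.alleles:
            col = np.full(len(ids), np.nan)
            for i, ind_id in enumerate(ids):
                g = individuals[ind_id].genotype.get(locus.name)
                if g is not None:
                    col[i] = (g[0] == allele) / 2 + (g[1] == allele) / 2
            if np.all(np.isnan(col)):
                continue
            mean = np.nanmean(col)
            col = np.where(np.isnan(col), mean, col)
            cols.append(col)
    return np.column_stack(cols)


def morans_i(values: np.ndarray, weights: np.ndarray) -> float:
    """Multi-allele Moran's I: per-column I combined with allele-variance
    weights, equivalent to pooling numerators and denominators.

    ``values`` is individuals x alleles; ``weights`` a symmetric binary
    (or non-negative) weight matrix with zero diagonal.
    """
    z = values - values.mean(axis=0, keepdims=True)
    denom = (z**2).sum()
    if denom <= 0:
        raise ValueError("zero genetic variance: Moran's I undefined")
    w_total = weights.sum()
    if w_total <= 0:
        raise ValueError("empty weight class")
    n = values.shape[0]
    num = np.einsum("ij,ia,ja->", weights, z, z)
    return float((n / w_total) * num / denom)


def morans_i_by_scale(
    panel: GenotypePanel,
    distances: DistanceMatrix,
    threshold_m: float = 3000.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> list[SpatialAutocorrResult]:
    """Moran's I of allele sharing at the individual (< threshold) and
    landscape (>= threshold) scales, with 95% percentile bootstrap CIs
    over individuals.

    A pair at exactly the threshold belongs to the landscape class.  In
    bootstrap resamples, pairs formed by two copies of the same original
    individual are excluded (self-comparisons carry no information).
    """
    ids = distances.ids
    n = len(ids)
    values = _allele_dosage_matrix(panel, ids)
    d = distances.matrix
    off_diag = ~np.eye(n, dtype=bool)
    classes = {
        "individual": (d < threshold_m) & off_diag,
        "landscape": (d >= threshold_m) & off_diag,
    }
    results = []
    rng = np.random.default_rng(seed)
    for scale, w in classes.items():
        n_pairs = int(w.sum() // 2)
        if n_pairs == 0:
            raise ValueError(f"no pairs in the {scale} distance class")
        if np.unique(np.nonzero(w)[0]).size < 3:
            raise ValueError(f"fewer than 3 individuals in the {scale} class")
        i_obs = morans_i(values, w.astype(float))
        boots = []
        attempts = 0
        while len(boots) < n_boot and attempts < 10 * n_boot:
            attempts += 1
            idx = rng.integers(0, n, size=n)
            wb = w[np.ix_(idx, idx)].astype(float)
            same = idx[:, None] == idx[None, :]
            wb[same] = 0.0
            try:
                boots.append(morans_i(values[idx], wb))
            except ValueError:
                continue
        boots_arr = np.array(boots)
        if boots_arr.size == 0:
            raise ValueError(f"bootstrap failed in the {scale} class")
        lower, upper = np.quantile(boots_arr, [0.025, 0.975])
        results.append(
            SpatialAutocorrResult(
                scale=scale,
                morans_i=i_obs,
                ci=(float(lower), float(upper)),
                boot_sd=float(boots_arr.std(ddof=1)),
                n_pairs=n_pairs,
            )
        )
    return results


# ---------------------------------------------------------------------------
# per-category distance summaries
# ---------------------------------------------------------------------------

def distance_by_category_summary(
    relationship_table: pd.DataFrame,
    categories: tuple[str, ...] = ("FO", "HS", "UN"),
) -> pd.DataFrame:
    """Five-number distance summary (km) per final relationship category.

    Uses the ``conclusion`` and ``distance_m`` columns of the
    relationship table; quartiles use the midpoint-interpolation
    convention.  Categories with no located pair are omitted.
    """
    rows = []
    for cat in categories:
        dist = relationship_table.loc[
            relationship_table["conclusion"] == cat, "distance_m"
        ].dropna()
        if dist.empty:
            logger.warning("distance summary: no located pairs in %s", cat)
            continue
        km = dist.to_numpy() / 1000.0
        rows.append(
            {
                "category": cat,
                "n": len(km),
                "min_km": float(km.min()),
                "q1_km": float(np.quantile(km, 0.25, method="midpoint")),
                "median_km": float(np.median(km)),
                "q3_km": float(np.quantile(km, 0.75, method="midpoint")),
                "max_km": float(km.max()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["category", "n", "min_km", "q1_km", "median_km", "q3_km", "max_km"],
    )
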