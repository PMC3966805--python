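"""End-to-end analysis pipeline.

Orchestrates the full workflow on a replicate-PCR table plus sample
metadata: consensus genotyping, recapture merging, completeness filtering,
per-locus population summaries, pairwise relatedness with bootstrap CIs
and pedigree LRTs, relationship classification, spatial statistics, and
(optionally) mating-system model arithmetic from supplied log-likelihoods.

Every stochastic stage draws its seed from one root seed via named
substreams, so outputs are pure functions of (inputs, config).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as _classify
from . import demography, popgen, spatial
from .genotypes import (
    Locus,
    consensus_panel,
    filter_by_completeness,
    identify_recaptures,
    read_replicate_table,
    write_genepop,
)
from .relatedness import DyadLikelihoodModel, estimate_dyad

logger = logging.getLogger("tapirkin")


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name and underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All inputs and parameters of a pipeline run."""

    replicates_path: str
    metadata_path: str | None = None
    loglik_path: str | None = None
    out_dir: str = "tapirkin_out"
    input_format: str = "csv"
    min_consistent: int = 3
    max_reps: int = 7
    max_consecutive_failures: int = 5
    min_shared_loci_recapture: int = 3
    min_loci_population: int = 3
    min_loci_kinship: int = 4
    n_boot: int = 1000
    n_null_sims: int = 1000
    n_hwe_montecarlo: int = 10_000
    n_permutations: int = 1000
    threshold_km: float = 3.0
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stage_seed(config: RunConfig, stage: str) -> int:
    digest = hashlib.sha256(f"{config.seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class RunReport:
    """Computed outputs of a run (tables in memory; also written to disk)."""

    config: RunConfig
    n_samples: int = 0
    n_unique_individuals: int = 0
    recaptures: pd.DataFrame | None = None
    locus_summary: pd.DataFrame | None = None
    p_id_products: dict = field(default_factory=dict)
    hwe: pd.DataFrame | None = None
    gene_diversity: tuple[float, float] | None = None
    f_stats: popgen.FStatsResult | None = None
    relationship_table: pd.DataFrame | None = None
    category_counts: dict = field(default_factory=dict)
    spatial_tests: list = field(default_factory=list)
    moran: list = field(default_factory=list)
    distance_summary: pd.DataFrame | None = None
    model_table: pd.DataFrame | None = None


def _write(df: pd.DataFrame, out: Path, name: str, config_hash: str) -> None:
    path = out / name
    df = df.copy()
    df.attrs["config_hash"] = config_hash
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(
    config: RunConfig, loci: list[Locus] | None = None
) -> RunReport:
    """Execute all stages in order; outputs are written to
    ``config.out_dir`` as they complete (a later stage failure keeps the
    earlier outputs)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    report = RunReport(config=config)
    t0 = time.time()
    logger.info("pipeline start (config hash %s, seed %d)", chash, config.seed)

    stage = "consensus"
    try:
        replicate_sets = read_replicate_table(
            config.replicates_path, format=config.input_format, loci=loci
        )
        if loci is None:
            observed: dict[str, set[int]] = {}
            for reps in replicate_sets:
                pool = observed.setdefault(reps.locus, set())
                for call in reps.replicates:
                    if call is not None:
                        pool.update(call)
            loci = [
                Locus(name, tuple(sorted(alleles)))
                for name, alleles in sorted(observed.items())
            ]
        metadata = None
        if config.metadata_path:
            metadata = pd.read_csv(config.metadata_path)
        panel = consensus_panel(
            replicate_sets,
            loci,
            metadata,
            min_consistent=config.min_consistent,
            max_reps=config.max_reps,
            max_consecutive_failures=config.max_consecutive_failures,
        )
        report.n_samples = len(panel.individuals)

        stage = "recaptures"
        unique_panel, recaptures = identify_recaptures(
            panel, min_shared_loci=config.min_shared_loci_recapture
        )
        report.n_unique_individuals = len(unique_panel.individuals)
        report.recaptures = recaptures
        _write(recaptures, out, "recaptures.tsv", chash)

        stage = "completeness"
        pop_panel = filter_by_completeness(unique_panel, config.min_loci_population)
        kin_panel = filter_by_completeness(unique_panel, config.min_loci_kinship)
        _write(pop_panel.to_frame(), out, "consensus_panel.tsv", chash)
        write_genepop(pop_panel, out / "panel.gen")

        stage = "popgen_summary"
        freqs = popgen.allele_frequencies(pop_panel)
        summary = popgen.locus_summary_table(pop_panel)
        report.locus_summary = summary
        unbiased = [v for v in summary["p_id_unbiased"] if v is not None]
        report.p_id_products = {
            "p_id_unbiased": popgen.p_id_multilocus(unbiased) if unbiased else None,
            "p_id_sib": popgen.p_id_multilocus(list(summary["p_id_sib"])),
        }
        hwe_rows = []
        for locus in pop_panel.locus_names:
            p = popgen.hwe_exact_test(
                pop_panel,
                locus,
                n_montecarlo=config.n_hwe_montecarlo,
                seed=_stage_seed(config, f"hwe:{locus}"),
            )
            hwe_rows.append({"locus": locus, "p_value": p})
        hwe = pd.DataFrame(hwe_rows)
        threshold, decisions = popgen.bonferroni_adjust(list(hwe["p_value"]))
        hwe["bonferroni_alpha"] = threshold
        hwe["reject"] = decisions
        report.hwe = hwe
        gd = popgen.gene_diversity(pop_panel)
        report.gene_diversity = (gd.mean, gd.sd)
        _write(summary, out, "locus_summary.tsv", chash)
        _write(hwe, out, "hwe.tsv", chash)

        stage = "f_statistics"
        margins = {ind.margin for ind in pop_panel.individuals} - {"unassigned"}
        if len(margins) >= 2:
            try:
                report.f_stats = popgen.wc_f_statistics(
                    pop_panel,
                    n_permutations=config.n_permutations,
                    seed=_stage_seed(config, "fstats"),
                )
            except ValueError as exc:
                logger.warning("F-statistics skipped: %s", exc)

        stage = "relatedness"
        model = DyadLikelihoodModel(freqs, seed=_stage_seed(config, "lrt"))
        located = {
            ind.individual_id: ind
            for ind in kin_panel.individuals
            if ind.has_coordinates()
        }
        dist = None
        if len(located) >= 2:
            dist = spatial.pairwise_distances(kin_panel)
        dyads = []
        inds = kin_panel.individuals
        for i, a in enumerate(inds):
            for b in inds[i + 1 :]:
                d_m = None
                if (
                    dist is not None
                    and a.individual_id in dist.ids
                    and b.individual_id in dist.ids
                ):
                    d_m = dist.get(a.individual_id, b.individual_id)
                dyads.append(
                    estimate_dyad(
                        a.individual_id,
                        b.individual_id,
                        a.genotype,
                        b.genotype,
                        freqs,
                        n_boot=config.n_boot,
                        n_null_sims=config.n_null_sims,
                        seed=_stage_seed(
                            config, f"dyad:{a.individual_id}:{b.individual_id}"
                        ),
                        model=model,
                        distance_m=d_m,
                    )
                )

        stage = "classification"
        table, counts = _classify.classify_all(dyads)
        report.relationship_table = table
        report.category_counts = counts
        _write(table, out, "relationships.tsv", chash)

        stage = "spatial"
        if dist is not None:
            related = table.loc[
                table["conclusion"].isin(["FO", "HS"]), "distance_m"
            ].dropna()
            unrelated = table.loc[
                table["conclusion"] == "UN", "distance_m"
            ].dropna()
            if len(related) and len(unrelated):
                report.spatial_tests.append(
                    spatial.mann_whitney(list(related), list(unrelated))
                )
            n = len(dist.ids)
            idx = {ind_id: i for i, ind_id in enumerate(dist.ids)}
            for col in ("r_qg89", "r_lr99"):
                r_mat = np.full((n, n), np.nan)
                for row in table.itertuples():
                    if row.id1 in idx and row.id2 in idx and pd.notna(
                        getattr(row, col)
                    ):
                        i, j = idx[row.id1], idx[row.id2]
                        r_mat[i, j] = r_mat[j, i] = getattr(row, col)
                try:
                    report.spatial_tests.append(
                        spatial.mantel(
                            r_mat,
                            dist.matrix,
                            n_permutations=config.n_permutations,
                            seed=_stage_seed(config, f"mantel:{col}"),
                        )
                    )
                except ValueError as exc:
                    logger.warning("Mantel (%s) skipped: %s", col, exc)
            try:
                report.moran = spatial.morans_i_by_scale(
                    kin_panel,
                    dist,
                    threshold_m=config.threshold_km * 1000.0,
                    n_boot=config.n_boot,
                    seed=_stage_seed(config, "moran"),
                )
            except ValueError as exc:
                logger.warning("Moran's I skipped: %s", exc)
            report.distance_summary = spatial.distance_by_category_summary(table)
            if report.distance_summary is not None:
                _write(report.distance_summary, out, "distance_summary.tsv", chash)

        stage = "models"
        if config.loglik_path:
            loglik = pd.read_csv(config.loglik_path, sep=None, engine="python")
            models = [
                demography.ModelLikelihood(r.model, float(r.log_likelihood))
                for r in loglik.itertuples()
            ]
            report.model_table = demography.model_posteriors(models)
            _write(report.model_table, out, "mating_models.tsv", chash)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    _write_report(report, out, chash)
    logger.info("pipeline done in %.1f s", time.time() - t0)
    return report


def _write_report(report: RunReport, out: Path, chash: str) -> None:
    lines = [
        f"config_hash: {chash}",
        f"seed: {report.config.seed}",
        f"n_samples: {report.n_samples}",
        f"n_unique_individuals: {report.n_unique_individuals}",
    ]
    for key, value in report.p_id_products.items():
        lines.append(f"{key}: {value}")
    if report.gene_diversity:
        lines.append(f"gene_diversity_mean: {report.gene_diversity[0]:.4f}")
        lines.append(f"gene_diversity_sd: {report.gene_diversity[1]:.4f}")
    if report.f_stats:
        lines.append(f"f_st: {report.f_stats.f_st:.4f} (p={report.f_stats.p_st:.3f})")
        lines.append(f"f_is: {report.f_stats.f_is:.4f} (p={report.f_stats.p_is:.3f})")
    for cat, count in report.category_counts.items():
        lines.append(f"count_{cat}: {count}")
    for test in report.spatial_tests:
        lines.append(f"{test.name}: {test.statistic:.4g} (p={test.p_value:.3f})")
    for res in report.moran:
        lines.append(
            f"moran_{res.scale}: {res.morans_i:.4f} "
            f"ci=({res.ci[0]:.4f}, {res.ci[1]:.4f}) n_pairs={res.n_pairs}"
        )
    (out / "report.txt").write_text("\n".join(lines) + "\n")
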