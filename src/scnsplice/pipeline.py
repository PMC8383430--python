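"""Stage orchestration: trajectory, splicing and sQTL analyses of a cohort.

These functions connect the per-module operations into the analyses the
package exists for, working on in-memory objects; the CLI and any script
front-end are thin wrappers over them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import CountingBin, MxePair
from .counting import ExonMatrix, JunctionTable
from .splicing import (
    DmGlmResult,
    MxeConsistency,
    SashimiSummary,
    SpliceCluster,
    cluster_junctions,
    dm_glm_test,
    mxe_consistency,
    mxe_window_geometry,
    sashimi_summary,
)
from .sqtl import bh_fdr, filter_variants, genotype_pcs, run_sqtl
from .trajectories import (
    DEFAULT_STAGE_BOUNDARIES,
    FETAL,
    MATURE,
    LoessFit,
    PairwiseScreen,
    RatioSeries,
    StageContrast,
    TrendFit,
    add_stage_column,
    compute_ratio_series,
    fit_loglog_trend,
    loess_smooth,
    pairwise_ratio_screen,
    stage_geometric_mean_ratios,
    wilcoxon_ranksum,
)


@dataclass
class PairTrajectoryReport:
    pair: MxePair
    ratio_series: RatioSeries
    trend: TrendFit
    loess: LoessFit
    contrast: StageContrast
    stage_ratios: dict[str, float]
    table: pd.DataFrame  # per-sample: age, stage, cpm_a, cpm_n, ratio


def analyze_pair_trajectory(
    matrix: ExonMatrix,
    meta: pd.DataFrame,
    pair: MxePair,
    boundaries: tuple[float, float] = DEFAULT_STAGE_BOUNDARIES,
    zero_policy: str = "exclude",
    loess_span: float = 0.75,
    loess_degree: int = 1,
) -> PairTrajectoryReport:
    """Ratio trajectory, trend, Loess smooth, and fetal-vs-mature contrast."""
    meta = add_stage_column(meta, boundaries)
    series = compute_ratio_series(matrix, pair, zero_policy=zero_policy)
    ratios = series.ratios
    ages = meta.loc[ratios.index, "age_pcd"].astype(float)
    stages = meta.loc[ratios.index, "stage"]

    trend = fit_loglog_trend(ages.to_numpy(), ratios.to_numpy())
    loess = loess_smooth(
        np.log2(ages.to_numpy()), np.log2(ratios.to_numpy()),
        span=loess_span, degree=loess_degree,
    )
    log_ratio = np.log2(ratios)
    contrast = wilcoxon_ranksum(
        log_ratio[stages == FETAL].to_numpy(), log_ratio[stages == MATURE].to_numpy()
    )
    stage_ratios = stage_geometric_mean_ratios(ratios, stages)

    key_a = f"{pair.gene_id}:{pair.bin_a}"
    key_n = f"{pair.gene_id}:{pair.bin_n}"
    table = pd.DataFrame(
        {
            "age_pcd": meta["age_pcd"],
            "stage": meta["stage"],
            "cpm_a": matrix.cpm.loc[key_a],
            "cpm_n": matrix.cpm.loc[key_n],
            "ratio": ratios.reindex(meta.index),
        }
    )
    return PairTrajectoryReport(
        pair=pair,
        ratio_series=series,
        trend=trend,
        loess=loess,
        contrast=contrast,
        stage_ratios=stage_ratios,
        table=table,
    )


@dataclass
class SplicingReport:
    clusters: list[SpliceCluster]
    dropped: list[tuple[tuple, str]]
    results: pd.DataFrame  # cluster_id, lrt, df, p, q
    dm_by_cluster: dict[str, DmGlmResult]
    sashimi: dict[str, SashimiSummary]  # per gene window
    consistency: dict[str, MxeConsistency]  # per gene


def analyze_splicing(
    junctions: JunctionTable,
    meta: pd.DataFrame,
    genes: list[tuple[list[CountingBin], MxePair, str]],  # (bins, pair, chrom)
    boundaries: tuple[float, float] = DEFAULT_STAGE_BOUNDARIES,
    min_cluster_reads: int = 30,
    min_junction_fraction: float = 0.001,
    prenatal_cutoff_pcd: float | None = None,
) -> SplicingReport:
    """Cluster junctions, test prenatal-vs-postnatal shifts, score MXE usage.

    The group contrast splits samples at birth (266 pcd by default, or
    the fetal boundary when ``prenatal_cutoff_pcd`` is given).
    """
    cutoff = 266.0 if prenatal_cutoff_pcd is None else prenatal_cutoff_pcd
    group = pd.Series(
        np.where(meta["age_pcd"] < cutoff, "prenatal", "postnatal"), index=meta.index
    )
    clusters, dropped = cluster_junctions(
        junctions, min_cluster_reads=min_cluster_reads,
        min_junction_fraction=min_junction_fraction,
    )
    dm_by_cluster: dict[str, DmGlmResult] = {}
    rows = []
    for cl in clusters:
        res = dm_glm_test(cl.counts, group)
        dm_by_cluster[cl.cluster_id] = res
        rows.append(
            {
                "cluster_id": cl.cluster_id,
                "chrom": cl.chrom,
                "start": cl.span[0],
                "end": cl.span[1],
                "n_junctions": len(cl.junctions),
                "lrt": res.lrt_statistic,
                "df": res.df,
                "p": res.p_value,
            }
        )
    results = pd.DataFrame(rows)
    if len(results):
        results["q"] = bh_fdr(results["p"].to_numpy())

    sashimi: dict[str, SashimiSummary] = {}
    consistency: dict[str, MxeConsistency] = {}
    for bins, pair, chrom in genes:
        geometry = mxe_window_geometry(bins, pair, chrom=chrom)
        lo = geometry["flank_up"][0]
        hi = geometry["flank_down"][1]
        has_junctions = any(
            k[0] == chrom and k[1] >= lo and k[2] <= hi
            for k in junctions.counts.index
        )
        if has_junctions:
            sashimi[pair.gene_id] = sashimi_summary(junctions, group, (chrom, lo, hi))
        consistency[pair.gene_id] = mxe_consistency(junctions, geometry)
    return SplicingReport(
        clusters=clusters,
        dropped=dropped,
        results=results,
        dm_by_cluster=dm_by_cluster,
        sashimi=sashimi,
        consistency=consistency,
    )


def analyze_screen(
    matrix: ExonMatrix,
    meta: pd.DataFrame,
    bin_keys: list[str],
    min_cpm: float = 1.0,
    distinct_threshold: float = 0.3,
) -> PairwiseScreen:
    ages = meta["age_pcd"].astype(float)
    return pairwise_ratio_screen(
        matrix, bin_keys, ages, min_cpm=min_cpm, distinct_threshold=distinct_threshold
    )


def splicing_phenotypes(
    matrix: ExonMatrix,
    pairs: list[MxePair],
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Per-gene log2 A:N ratio phenotypes (pseudocounted, so every sample is defined)."""
    rows = {}
    for pair in pairs:
        series = compute_ratio_series(
            matrix, pair, zero_policy="pseudocount", pseudocount=pseudocount
        )
        rows[f"{pair.gene_id}_log2_a_n"] = np.log2(series.ratios)
    return pd.DataFrame(rows).T


def analyze_sqtl(
    phenotypes: pd.DataFrame,
    dosage: pd.DataFrame,
    meta: pd.DataFrame,
    boundaries: tuple[float, float] = DEFAULT_STAGE_BOUNDARIES,
    n_pcs: int = 5,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-12,
    age_adjust: str | None = "loess",
) -> pd.DataFrame:
    """Variant filters, genotype PCs, covariate-adjusted OLS, BH FDR.

    Developmental splicing phenotypes follow strongly non-linear (sigmoid)
    age trajectories, so ``age_adjust='loess'`` residualizes each
    phenotype against its Loess trend on log2(age) before association
    (genotype is independent of age, so the smooth cannot absorb a true
    cis effect); ``'linear'`` instead adds log2(age) as a covariate;
    ``None`` leaves age unadjusted.
    """
    meta = add_stage_column(meta, boundaries)
    groups = pd.Series(
        np.where(meta["age_pcd"] < boundaries[0], "prenatal", "postnatal"),
        index=meta.index,
    )
    kept = filter_variants(dosage, groups, maf_min=maf_min, hwe_p_min=hwe_p_min)
    if kept.empty:
        return pd.DataFrame(
            columns=["phenotype_id", "variant_id", "beta", "se", "t", "p", "n", "q"]
        )
    covariates = genotype_pcs(kept, k=min(n_pcs, len(kept) - 1))
    log_age = np.log2(meta["age_pcd"].astype(float))
    if age_adjust == "loess":
        phenotypes = phenotypes.apply(
            lambda row: _residualize_on_age(row, log_age), axis=1
        )
    elif age_adjust == "linear":
        covariates = covariates.join(log_age.rename("log2_age"))
    elif age_adjust is not None:
        raise ValueError(f"unknown age_adjust {age_adjust!r}")
    return run_sqtl(phenotypes, kept, covariates)


def _residualize_on_age(
    phenotype: pd.Series, log_age: pd.Series, span: float = 0.3
) -> pd.Series:
    """Remove the Loess age trend from a splicing phenotype.

    The detrending span (0.3) is deliberately smaller than the display
    smooth's: the N-to-A switch is sharp on the log-age axis and a wide
    window would leave the transition in the residuals.
    """
    values = phenotype.dropna()
    x = log_age.reindex(values.index).to_numpy()
    fit = loess_smooth(x, values.to_numpy(), span=span, degree=1, grid=x)
    return pd.Series(values.to_numpy() - fit.fitted, index=values.index).reindex(
        phenotype.index
    )
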