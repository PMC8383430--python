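"""Synthetic developmental cohorts with known splicing switch parameters.

The generator emulates the statistical structure of a bulk RNA-seq brain
development cohort (ages log-spread from early fetal to young adult, here
42-7566 post-conceptual days as in a 6-post-conception-week to 20-year
design): per-gene expression trajectories, a logistic switch between the
mutually exclusive A and N exon copies, negative-binomial exon counts,
junction reads drawn consistently with the isoform fractions, and
Hardy-Weinberg genotypes with an optional planted splicing QTL.

The N-exon inclusion fraction follows a logistic in log-age,

    f_N(t) = f1 + (f0 - f1) / (1 + (t / t50)^h),

so the transition appears linear on the log-age axes used throughout the
analysis.  Every random draw is recorded in a ``SyntheticTruth`` ledger
against which the downstream counting, trajectory, splicing and sQTL
stages can be asserted exactly or statistically.

Default switch parameters mirror the reported human cortex A:N ratio
shifts used as simulation inputs: SCN2A-like 0.27 (fetal) to 11.4
(mature), SCN3A-like 1.0 to 5.7, SCN8A-like 0.7 to 4.2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    CountingBin,
    GeneModel,
    MxePair,
    Transcript,
    classify_bins,
    flatten_gene_model,
    register_mxe_pair,
    write_bins_bed,
    write_gtf,
    write_mxe_json,
)
from .counting import (
    ExonMatrix,
    JunctionTable,
    ReadPlacement,
    cpm_normalize,
    write_junctions_tsv,
    write_matrix_tsv,
    write_placements_tsv,
)


def logistic_switch(t, f0: float, f1: float, t50: float, steepness: float):
    """f(t) = f1 + (f0 - f1) / (1 + (t/t50)^h): logistic in log-age."""
    t = np.asarray(t, dtype=float)
    return f1 + (f0 - f1) / (1.0 + (t / t50) ** steepness)


@dataclass(frozen=True)
class SwitchSpec:
    """Parameters of one gene's mutually exclusive exon switch."""

    gene_id: str
    label: str = "5A/5N"
    f_fetal: float = 0.5  # N-inclusion fraction, fetal asymptote
    f_mature: float = 0.5  # N-inclusion fraction, mature asymptote
    t50_pcd: float = 450.0  # switch midpoint, post-conceptual days
    steepness: float = 6.0
    skip_fetal: float = 0.0  # double-skip fraction trajectory (18A/18N style)
    skip_mature: float = 0.0
    skip_t50_pcd: float = 450.0
    skip_steepness: float = 6.0

    def __post_init__(self):
        for f in (self.f_fetal, self.f_mature):
            if not 0 < f < 1:
                raise ValueError("N fractions must lie in (0, 1)")
        if self.t50_pcd <= 0 or self.steepness <= 0:
            raise ValueError("t50 and steepness must be positive")

    def f_n(self, t):
        return logistic_switch(t, self.f_fetal, self.f_mature, self.t50_pcd, self.steepness)

    def f_skip(self, t):
        if self.skip_fetal == 0 and self.skip_mature == 0:
            return np.zeros_like(np.asarray(t, dtype=float))
        return logistic_switch(
            t, self.skip_fetal, self.skip_mature, self.skip_t50_pcd, self.skip_steepness
        )

    @classmethod
    def from_ratios(
        cls,
        gene_id: str,
        fetal_ratio: float,
        mature_ratio: float,
        t50_pcd: float = 450.0,
        steepness: float = 6.0,
        **kwargs,
    ) -> "SwitchSpec":
        """Build a spec from asymptotic A:N expression ratios."""
        return cls(
            gene_id=gene_id,
            f_fetal=1.0 / (1.0 + fetal_ratio),
            f_mature=1.0 / (1.0 + mature_ratio),
            t50_pcd=t50_pcd,
            steepness=steepness,
            **kwargs,
        )


@dataclass
class PlantedSqtl:
    gene_id: str
    effect: float = 0.4  # shift of logit f_N per alternate allele
    maf: float = 0.3
    variant_id: str = "rs_planted"


@dataclass
class CohortSpec:
    """The study conditions the generator emulates."""

    n_samples: int = 176
    age_range_pcd: tuple[float, float] = (42.0, 7566.0)
    mean_fragments: float = 500.0  # expected fragments per gene per sample
    expr_slope: float = 0.0  # power-law exponent of gene expression on age
    # Gene-level dispersion: one Gamma(1/phi, phi) factor per gene and
    # sample multiplies all that gene's bin means, with Poisson bin draws
    # given the factor.  Each bin count is marginally NB with variance
    # mean + phi * mean^2, while within-sample ratios between bins of a
    # gene cancel the shared factor -- the structure the ratio analysis
    # relies on in real data, where overdispersion is largely gene-level.
    nb_dispersion: float = 0.1
    junction_depth: float = 0.4  # expected junction reads per gene fragment
    read_length: int = 100
    logit_noise_sd: float = 0.3  # per-sample biological noise on logit f_N
    n_variants: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    sqtl: PlantedSqtl | None = None
    seed: int = 0


@dataclass
class MxeGeneGeometry:
    """A toy MXE gene: model, classified bins, registered pair, junction map."""

    model: GeneModel
    bins: list[CountingBin]
    pair: MxePair
    roles: dict[str, str]  # bin key -> {const, A, N}
    # junction name -> ((donor_end, acceptor_start), (left bin key, right bin key))
    junction_map: dict[str, tuple[tuple[int, int], tuple[str, str]]]

    @property
    def gene_id(self) -> str:
        return self.model.gene_id

    @property
    def has_skip(self) -> bool:
        return "skip" in self.junction_map


def make_mxe_gene(
    gene_id: str,
    chrom: str,
    origin: int = 100_000,
    flank_len: int = 150,
    mxe_len: int = 92,
    intron_len: int = 500,
    n_flanks: int = 2,
    include_skip_transcript: bool = False,
    label: str = "5A/5N",
    strand: str = "+",
) -> MxeGeneGeometry:
    """Construct a toy sodium-channel-like gene with one MXE pair.

    Layout (ascending coordinates): ``n_flanks`` constitutive exons, the
    A exon, the N exon, then ``n_flanks`` constitutive exons, with
    ``intron_len`` between consecutive exons.  Exon copies are 92 bp by
    default, the length of the human 5A/5N exons.
    """
    coords = []
    pos = origin
    lens = [flank_len] * n_flanks + [mxe_len, mxe_len] + [flank_len] * n_flanks
    for length in lens:
        coords.append((pos, pos + length))
        pos += length + intron_len
    up = coords[:n_flanks]
    exon_a, exon_n = coords[n_flanks], coords[n_flanks + 1]
    down = coords[n_flanks + 2 :]

    transcripts = [
        Transcript(f"{gene_id}-TA", tuple(up + [exon_a] + down)),
        Transcript(f"{gene_id}-TN", tuple(up + [exon_n] + down)),
    ]
    if include_skip_transcript:
        transcripts.append(Transcript(f"{gene_id}-TS", tuple(up + down)))
    model = GeneModel(
        gene_id=gene_id,
        gene_name=gene_id,
        chrom=chrom,
        strand=strand,
        transcripts=tuple(transcripts),
    )
    bins = classify_bins(model, flatten_gene_model(model))
    by_interval = {(b.start, b.end): b for b in bins}
    bin_a = by_interval[exon_a]
    bin_n = by_interval[exon_n]
    pair = register_mxe_pair(model, bins, bin_a.bin_id, bin_n.bin_id, label)

    roles = {b.key: "const" for b in bins}
    roles[bin_a.key] = "A"
    roles[bin_n.key] = "N"

    flank_up = by_interval[up[-1]]
    flank_down = by_interval[down[0]]
    junction_map = {
        "up_a": ((flank_up.end, bin_a.start), (flank_up.key, bin_a.key)),
        "a_down": ((bin_a.end, flank_down.start), (bin_a.key, flank_down.key)),
        "up_n": ((flank_up.end, bin_n.start), (flank_up.key, bin_n.key)),
        "n_down": ((bin_n.end, flank_down.start), (bin_n.key, flank_down.key)),
    }
    if include_skip_transcript:
        junction_map["skip"] = ((flank_up.end, flank_down.start), (flank_up.key, flank_down.key))
    return MxeGeneGeometry(
        model=model, bins=bins, pair=pair, roles=roles, junction_map=junction_map
    )


def sodium_channel_toy_genes() -> list[MxeGeneGeometry]:
    """Three MXE genes with distinct loci, one per emulated channel gene."""
    return [
        make_mxe_gene("SCN2A", "chr2", origin=100_000),
        make_mxe_gene("SCN3A", "chr2", origin=400_000),
        make_mxe_gene("SCN8A", "chr12", origin=100_000),
    ]


def default_switch_specs() -> dict[str, SwitchSpec]:
    """Switch parameters from the reported human cortex A:N ratio shifts."""
    return {
        "SCN2A": SwitchSpec.from_ratios("SCN2A", fetal_ratio=0.27, mature_ratio=11.4),
        "SCN3A": SwitchSpec.from_ratios("SCN3A", fetal_ratio=1.0, mature_ratio=5.7),
        "SCN8A": SwitchSpec.from_ratios("SCN8A", fetal_ratio=0.7, mature_ratio=4.2),
    }


def nb_sample(rng: np.random.Generator, mean, dispersion: float) -> np.ndarray:
    """Negative binomial draws with variance mean + dispersion * mean^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p / (1.0 - p))


@dataclass
class SyntheticTruth:
    """Generating parameters and exact per-read accounting."""

    f_n: pd.DataFrame  # genes x samples, realized N fraction
    f_skip: pd.DataFrame
    gene_factors: pd.DataFrame  # genes x samples, shared overdispersion factor
    bin_mean: pd.DataFrame  # expected NB mean per bin x sample (factor excluded)
    exon_fragments: pd.DataFrame  # NB-drawn single-bin fragments, bin x sample
    bin_ledger: pd.DataFrame  # expected count_bins output (exon + junction hits)
    junction_ledger: pd.DataFrame  # expected extract_junctions output
    switch_specs: dict[str, SwitchSpec]
    cohort_spec: CohortSpec
    planted: PlantedSqtl | None = None


@dataclass
class SimulatedCohort:
    meta: pd.DataFrame  # sample_id-indexed: age_pcd, sex, region, species
    matrix: ExonMatrix  # counts == truth.bin_ledger, CPM self-contained
    junctions: JunctionTable
    dosage: pd.DataFrame  # variants x samples
    variant_meta: pd.DataFrame
    genes: list[MxeGeneGeometry]
    truth: SyntheticTruth

    @property
    def sample_ids(self) -> list[str]:
        return list(self.meta.index)


def simulate_genotypes(
    n_samples: int,
    n_variants: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    sample_ids=None,
    chrom: str = "chr2",
    start_pos: int = 50_000,
    spacing: int = 10_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hardy-Weinberg dosages: dosage_sv ~ Binomial(2, MAF_v), MAF ~ U(range)."""
    lo, hi = maf_range
    if not 0 < lo <= hi <= 0.5:
        raise ValueError("MAF range must lie within (0, 0.5]")
    rng = np.random.default_rng(seed)
    if sample_ids is None:
        sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    mafs = rng.uniform(lo, hi, n_variants)
    dose = rng.binomial(2, mafs[:, None], size=(n_variants, n_samples)).astype(float)
    ids = [f"var{i + 1:04d}" for i in range(n_variants)]
    dosage = pd.DataFrame(dose, index=ids, columns=sample_ids)
    meta = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": [start_pos + i * spacing for i in range(n_variants)],
            "ref": "C",
            "alt": "T",
            "maf": mafs,
        },
        index=ids,
    )
    return dosage, meta


def simulate_cohort(
    spec: CohortSpec,
    genes: list[MxeGeneGeometry] | None = None,
    switch_specs: dict[str, SwitchSpec] | None = None,
) -> SimulatedCohort:
    """Generate a full cohort: metadata, counts, junctions, genotypes, truth.

    Counts follow the generating model: per-sample gene depth modulated by
    a power-law age trajectory, split over bins by length and isoform
    fraction, with NB noise; junction reads are multinomial over the
    flank/A/N(/skip) junctions with weights proportional to isoform
    abundance.  The returned ExonMatrix counts equal the truth ledger, so
    re-counting emitted placements reproduces them exactly.
    """
    if genes is None:
        genes = sodium_channel_toy_genes()
    if switch_specs is None:
        switch_specs = default_switch_specs()
    gene_ids = {g.gene_id for g in genes}
    for gid in switch_specs:
        if gid not in gene_ids:
            raise ValueError(f"switch spec references absent gene {gid}")
    for g in genes:
        if g.gene_id not in switch_specs:
            raise ValueError(f"gene {g.gene_id} has no switch spec")

    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    lo, hi = spec.age_range_pcd
    ages = np.exp(rng.uniform(np.log(lo), np.log(hi), n))
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "age_pcd": ages,
            "sex": rng.choice(["M", "F"], n),
            "region": "DLPFC",
            "species": "human",
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    first_chrom = genes[0].model.chrom
    dosage, variant_meta = simulate_genotypes(
        n,
        spec.n_variants,
        spec.maf_range,
        seed=spec.seed + 1,
        sample_ids=sample_ids,
        chrom=first_chrom,
    )
    if spec.sqtl is not None:
        planted_rng = np.random.default_rng(spec.seed + 2)
        dosage.loc[spec.sqtl.variant_id] = planted_rng.binomial(
            2, spec.sqtl.maf, n
        ).astype(float)
        variant_meta.loc[spec.sqtl.variant_id] = {
            "chrom": first_chrom,
            "pos": 166_053_034,
            "ref": "C",
            "alt": "T",
            "maf": spec.sqtl.maf,
        }

    geo_mean_age = float(np.sqrt(lo * hi))
    depth = spec.mean_fragments * (ages / geo_mean_age) ** spec.expr_slope

    all_bins = [b for g in genes for b in g.bins]
    bin_keys = [b.key for b in all_bins]
    bin_len = {b.key: b.length for b in all_bins}

    f_n_rows, f_skip_rows = [], []
    mean_rows = {}
    factor_rows = []
    gene_of_bin = {}
    for g in genes:
        if spec.nb_dispersion > 1e-12:
            factor = rng.gamma(
                shape=1.0 / spec.nb_dispersion, scale=spec.nb_dispersion, size=n
            )
        else:
            factor = np.ones(n)
        factor_rows.append(pd.Series(factor, index=sample_ids, name=g.gene_id))
        for b in g.bins:
            gene_of_bin[b.key] = g.gene_id
        sw = switch_specs[g.gene_id]
        z = logit(sw.f_n(ages)) + rng.normal(0.0, spec.logit_noise_sd, n)
        if spec.sqtl is not None and spec.sqtl.gene_id == g.gene_id:
            z = z + spec.sqtl.effect * dosage.loc[spec.sqtl.variant_id].to_numpy()
        f_n = sigmoid(z)
        f_skip = np.asarray(sw.f_skip(ages), dtype=float)
        # keep fractions a valid composition
        f_n = np.clip(f_n, 1e-6, 1.0 - 1e-6) * (1.0 - f_skip)
        f_n_rows.append(pd.Series(f_n, index=sample_ids, name=g.gene_id))
        f_skip_rows.append(pd.Series(f_skip, index=sample_ids, name=g.gene_id))

        frac = {}
        for b in g.bins:
            role = g.roles[b.key]
            if role == "const":
                frac[b.key] = np.ones(n)
            elif role == "A":
                frac[b.key] = 1.0 - f_n - f_skip
            else:
                frac[b.key] = f_n
        weights = {k: bin_len[k] * v for k, v in frac.items()}
        total_w = np.sum(list(weights.values()), axis=0)
        for k, w in weights.items():
            mean_rows[k] = depth * w / total_w

    f_n_df = pd.DataFrame(f_n_rows)
    f_skip_df = pd.DataFrame(f_skip_rows)
    factors = pd.DataFrame(factor_rows)
    bin_mean = pd.DataFrame([mean_rows[k] for k in bin_keys], index=bin_keys, columns=sample_ids)
    bin_factors = np.stack([factors.loc[gene_of_bin[k]].to_numpy() for k in bin_keys])
    exon_fragments = pd.DataFrame(
        rng.poisson(bin_mean.to_numpy() * bin_factors),
        index=bin_keys,
        columns=sample_ids,
    )

    # junction reads: multinomial over junction categories, weights
    # proportional to the abundance of the isoform carrying each junction
    junction_rows: dict[tuple, np.ndarray] = {}
    junction_bins: dict[tuple, tuple[str, str]] = {}
    for g in genes:
        chrom, strand = g.model.chrom, g.model.strand
        a_frac = 1.0 - f_n_df.loc[g.gene_id].to_numpy() - f_skip_df.loc[g.gene_id].to_numpy()
        n_frac = f_n_df.loc[g.gene_id].to_numpy()
        k_frac = f_skip_df.loc[g.gene_id].to_numpy()
        names = list(g.junction_map)
        w = {"up_a": a_frac, "a_down": a_frac, "up_n": n_frac, "n_down": n_frac, "skip": k_frac}
        W = np.stack([w[name] for name in names])  # categories x samples
        W = W / W.sum(axis=0, keepdims=True)
        totals = rng.poisson(spec.junction_depth * depth * factors.loc[g.gene_id].to_numpy())
        draws = np.zeros((len(names), n), dtype=np.int64)
        for s in range(n):
            draws[:, s] = rng.multinomial(totals[s], W[:, s])
        for ci, name in enumerate(names):
            (donor, acceptor), bins_touched = g.junction_map[name]
            key = (chrom, donor, acceptor, strand)
            junction_rows[key] = draws[ci]
            junction_bins[key] = bins_touched

    jidx = pd.MultiIndex.from_tuples(sorted(junction_rows), names=JunctionTable.INDEX_NAMES)
    junction_ledger = pd.DataFrame(
        [junction_rows[k] for k in jidx], index=jidx, columns=sample_ids
    )
    junctions = JunctionTable(junction_ledger.copy())

    # junction reads also overlap the two bins they anchor in
    contrib = pd.DataFrame(0, index=bin_keys, columns=sample_ids, dtype=np.int64)
    for key in jidx:
        left, right = junction_bins[key]
        contrib.loc[left] += junction_ledger.loc[key]
        contrib.loc[right] += junction_ledger.loc[key]
    bin_ledger = exon_fragments + contrib

    matrix = cpm_normalize(ExonMatrix(counts=bin_ledger.copy()))
    truth = SyntheticTruth(
        f_n=f_n_df,
        f_skip=f_skip_df,
        gene_factors=factors,
        bin_mean=bin_mean,
        exon_fragments=exon_fragments,
        bin_ledger=bin_ledger,
        junction_ledger=junction_ledger,
        switch_specs=dict(switch_specs),
        cohort_spec=spec,
        planted=spec.sqtl,
    )
    return SimulatedCohort(
        meta=meta,
        matrix=matrix,
        junctions=junctions,
        dosage=dosage,
        variant_meta=variant_meta,
        genes=genes,
        truth=truth,
    )


def emit_read_placements(cohort: SimulatedCohort, seed: int | None = None):
    """Yield one ReadPlacement per ledger fragment.

    Exon fragments become single blocks placed uniformly inside their
    bin; junction reads become two anchored blocks meeting exactly at the
    recorded donor/acceptor coordinates.  Counting the emitted placements
    therefore reproduces the truth ledgers exactly.
    """
    spec = cohort.truth.cohort_spec
    rng = np.random.default_rng(spec.seed + 3 if seed is None else seed)
    read_len = spec.read_length
    bins_by_key = {b.key: b for g in cohort.genes for b in g.bins}
    gene_by_id = {g.gene_id: g for g in cohort.genes}

    for key, row in cohort.truth.exon_fragments.iterrows():
        b = bins_by_key[key]
        g = gene_by_id[b.gene_id]
        chrom, strand = g.model.chrom, g.model.strand
        length = min(read_len, b.length)
        hi = b.end - length
        for sample_id, count in row.items():
            if count == 0:
                continue
            starts = rng.integers(b.start, hi + 1, size=int(count))
            for s in starts:
                yield ReadPlacement(
                    sample_id=sample_id,
                    chrom=chrom,
                    strand=strand,
                    blocks=((int(s), int(s) + length),),
                )

    junction_bins = {}
    for g in cohort.genes:
        for (donor, acceptor), touched in g.junction_map.values():
            junction_bins[(g.model.chrom, donor, acceptor, g.model.strand)] = touched
    for key, row in cohort.truth.junction_ledger.iterrows():
        chrom, donor, acceptor, strand = key
        left, right = junction_bins[key]
        anchor_l = min(read_len // 2, bins_by_key[left].length)
        anchor_r = min(read_len - read_len // 2, bins_by_key[right].length)
        blocks = ((donor - anchor_l, donor), (acceptor, acceptor + anchor_r))
        for sample_id, count in row.items():
            for _ in range(int(count)):
                yield ReadPlacement(
                    sample_id=sample_id, chrom=chrom, strand=strand, blocks=blocks
                )


def simulate_screen_cohort(
    n_samples: int = 200,
    n_const_bins: int = 5,
    switching: bool = True,
    fold: float = 10.0,
    t50_pcd: float = 450.0,
    steepness: float = 6.0,
    mean_fragments: float = 2000.0,
    nb_dispersion: float = 0.1,
    age_range_pcd: tuple[float, float] = (42.0, 7566.0),
    seed: int = 0,
) -> tuple[ExonMatrix, pd.Series, str | None]:
    """A single-gene matrix for the all-pairs ratio screen.

    ``n_const_bins`` bins share the gene trajectory; one optional extra
    bin's relative usage declines ``fold``-fold across development
    (logistic in log-age).  Returns (CPM matrix, ages, switching bin key).
    """
    rng = np.random.default_rng(seed)
    lo, hi = age_range_pcd
    ages = np.exp(rng.uniform(np.log(lo), np.log(hi), n_samples))
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    keys = [f"GENE:{i + 1:03d}" for i in range(n_const_bins + (1 if switching else 0))]
    weights = [np.ones(n_samples) for _ in range(n_const_bins)]
    switch_key = None
    if switching:
        switch_key = keys[-1]
        rel = logistic_switch(ages, 1.0, 1.0 / fold, t50_pcd, steepness)
        weights.append(rel)
    W = np.stack(weights)
    mean = mean_fragments * W / W.sum(axis=0, keepdims=True)
    if nb_dispersion > 1e-12:
        factor = rng.gamma(1.0 / nb_dispersion, nb_dispersion, n_samples)
    else:
        factor = np.ones(n_samples)
    counts = rng.poisson(mean * factor[None, :])
    matrix = cpm_normalize(
        ExonMatrix(counts=pd.DataFrame(counts, index=keys, columns=sample_ids))
    )
    ages_series = pd.Series(ages, index=sample_ids, name="age_pcd")
    return matrix, ages_series, switch_key


def write_cohort(cohort: SimulatedCohort, outdir: str | Path, placements: bool = False) -> dict:
    """Write the cohort in the pipeline's portable TSV/JSON formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "metadata": outdir / "metadata.tsv",
        "counts": outdir / "counts.tsv",
        "cpm": outdir / "cpm.tsv",
        "junctions": outdir / "junctions.tsv",
        "dosages": outdir / "dosages.tsv",
        "annotation": outdir / "annotation.gtf",
        "bins": outdir / "bins.bed",
        "mxe_pairs": outdir / "mxe_pairs.json",
        "truth": outdir / "truth.json",
    }
    cohort.meta.to_csv(paths["metadata"], sep="\t")
    write_matrix_tsv(cohort.matrix, paths["counts"], paths["cpm"])
    write_junctions_tsv(cohort.junctions, paths["junctions"])
    meta_cols = cohort.variant_meta[["chrom", "pos", "ref", "alt"]]
    meta_cols.join(cohort.dosage).to_csv(paths["dosages"], sep="\t", index_label="variant_id")
    models = [g.model for g in cohort.genes]
    write_gtf(models, paths["annotation"])
    write_bins_bed(models, {g.gene_id: g.bins for g in cohort.genes}, paths["bins"])
    write_mxe_json([g.pair for g in cohort.genes], paths["mxe_pairs"])
    truth_payload = {
        "switch_specs": {k: asdict(v) for k, v in cohort.truth.switch_specs.items()},
        "cohort_spec": {
            **{k: v for k, v in asdict(cohort.truth.cohort_spec).items() if k != "sqtl"},
            "sqtl": asdict(cohort.truth.cohort_spec.sqtl) if cohort.truth.cohort_spec.sqtl else None,
        },
        "f_n": {g: cohort.truth.f_n.loc[g].round(6).to_dict() for g in cohort.truth.f_n.index},
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_payload, fh, indent=2)
    if placements:
        paths["placements"] = outdir / "placements.tsv"
        write_placements_tsv(emit_read_placements(cohort), paths["placements"])
    return {k: str(v) for k, v in paths.items()}
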