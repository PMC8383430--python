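"""Splicing quantitative trait locus (sQTL) testing.

Common variants within a cis window of a gene are tested for association
with per-sample splicing phenotypes (e.g. log2 A:N ratio) by ordinary
least squares with covariates (genotype principal components, optionally
age), after the standard filters: minor allele frequency >= 5% in every
sample group and Hardy-Weinberg exact-test p >= 1e-12 on pooled
genotypes.  Multiple testing over all variant x phenotype pairs is
controlled with Benjamini-Hochberg q-values; an empirical permutation
p-value per phenotype is available as a small-sample alternative to the
nominal t-test.

Genotypes are held as a dosage matrix (variants x samples, values
0/1/2 or missing) read from a dosage TSV or a VCF GT field.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests


@dataclass
class AssociationResult:
    variant_id: str
    phenotype_id: str
    beta: float
    se: float
    t: float
    p: float
    n: int
    q: float | None = None


def hwe_exact_test(n_aa_major: int, n_het: int, n_aa_minor: int) -> float:
    """Exact conditional Hardy-Weinberg test (Wigginton-style).

    Given the genotype counts, the p-value sums the conditional
    probabilities (given allele counts) of all heterozygote counts whose
    probability does not exceed that of the observed table.
    """
    if min(n_aa_major, n_het, n_aa_minor) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa_major + n_het + n_aa_minor
    if n == 0:
        return 1.0
    rare = 2 * min(n_aa_major, n_aa_minor) + n_het
    # heterozygote counts share the parity of the rare allele count
    het_values = list(range(rare % 2, rare + 1, 2))
    probs = {}
    # start from the modal het count and recurse outward (numerically stable)
    mid = int(round(rare * (2 * n - rare) / (2.0 * n)))
    if mid % 2 != rare % 2:
        mid += 1
    mid = min(max(mid, het_values[0]), het_values[-1])
    probs[mid] = 1.0
    # P(h-2)/P(h) = h(h-1) / ((rare-h+2)(2n-rare-h+2))
    h = mid
    while h - 2 >= het_values[0]:
        probs[h - 2] = probs[h] * h * (h - 1) / ((rare - h + 2) * (2 * n - rare - h + 2))
        h -= 2
    h = mid
    while h + 2 <= het_values[-1]:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
        h += 2
    total = sum(probs.values())
    obs = probs[n_het] / total
    p = sum(v / total for v in probs.values() if v / total <= obs * (1 + 1e-12))
    return float(min(p, 1.0))


def minor_allele_frequency(dosages: np.ndarray) -> float:
    """Folded allele frequency from 0/1/2 dosages (NaN = missing)."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if len(d) == 0:
        return float("nan")
    freq = d.mean() / 2.0
    return float(min(freq, 1.0 - freq))


def filter_variants(
    dosage: pd.DataFrame,
    groups: pd.Series,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-12,
) -> pd.DataFrame:
    """Keep variants with MAF >= maf_min in every group and HWE p >= hwe_p_min.

    ``dosage`` is variants x samples; ``groups`` labels each sample (the
    MAF filter must pass separately in each label's subset, mirroring the
    prenatal/postnatal rule).  HWE is tested on pooled hard genotypes.
    """
    groups = groups.reindex(dosage.columns)
    keep = []
    for vid, row in dosage.iterrows():
        ok = True
        for level in pd.unique(groups.dropna()):
            maf = minor_allele_frequency(row[groups == level].to_numpy())
            if not np.isfinite(maf) or maf < maf_min:
                ok = False
                break
        if not ok:
            continue
        hard = np.round(row.dropna().to_numpy()).astype(int)
        counts = [(hard == g).sum() for g in (0, 1, 2)]
        if hwe_exact_test(counts[0], counts[1], counts[2]) < hwe_p_min:
            continue
        keep.append(vid)
    return dosage.loc[keep]


def genotype_pcs(dosage: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Top-k sample principal components of the standardized dosage matrix.

    Dosages are column-centered (per variant) and scaled by the binomial
    allele-frequency standard deviation sqrt(2 p (1-p)); zero-variance
    variants are dropped and missing entries imputed at the variant mean.
    """
    X = dosage.to_numpy(dtype=float).T  # samples x variants
    n_samples, n_variants = X.shape
    if n_variants < k or n_samples < k + 1:
        raise ValueError(f"need >= {k} variants and >= {k + 1} samples for {k} PCs")
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    p = col_mean / 2.0
    sd = np.sqrt(2.0 * p * (1.0 - p))
    ok = sd > 0
    Xs = (X[:, ok] - col_mean[ok]) / sd[ok]
    U, S, _ = np.linalg.svd(Xs, full_matrices=False)
    pcs = U[:, :k] * S[:k]
    return pd.DataFrame(
        pcs, index=dosage.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )


def associate(
    phenotype: pd.Series,
    dosage: pd.Series,
    covariates: pd.DataFrame | None = None,
    variant_id: str = "",
    phenotype_id: str = "",
) -> AssociationResult:
    """OLS of phenotype on dosage (+ covariates + intercept); t-test on dosage."""
    df = pd.DataFrame({"phenotype": phenotype, "dosage": dosage})
    if covariates is not None:
        df = df.join(covariates, how="inner")
    df = df.dropna()
    n_cov = 0 if covariates is None else covariates.shape[1]
    if len(df) < n_cov + 3:
        raise ValueError(f"need >= {n_cov + 3} complete cases, got {len(df)}")
    X = sm.add_constant(df.drop(columns="phenotype"), has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the offending columns for the caller
        bad = []
        cols = list(X.columns)
        for i in range(1, X.shape[1]):
            sub = X.iloc[:, : i + 1].to_numpy()
            if np.linalg.matrix_rank(sub) < sub.shape[1]:
                bad.append(cols[i])
        raise ValueError(f"rank-deficient design; collinear column(s): {bad}")
    fit = sm.OLS(df["phenotype"], X).fit()
    return AssociationResult(
        variant_id=variant_id,
        phenotype_id=phenotype_id,
        beta=float(fit.params["dosage"]),
        se=float(fit.bse["dosage"]),
        t=float(fit.tvalues["dosage"]),
        p=float(fit.pvalues["dosage"]),
        n=len(df),
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_sqtl(
    phenotypes: pd.DataFrame,
    dosage: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    permutations: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """All variant x phenotype associations with BH FDR across every test.

    ``phenotypes`` is phenotype_id x samples; ``dosage`` variants x
    samples.  With ``permutations`` > 0, each phenotype additionally gets
    an empirical p-value for its best variant from label permutations.
    """
    rows = []
    for pid, pheno in phenotypes.iterrows():
        for vid, dose in dosage.iterrows():
            res = associate(pheno, dose, covariates, variant_id=str(vid), phenotype_id=str(pid))
            rows.append(res)
    out = pd.DataFrame(
        {
            "phenotype_id": [r.phenotype_id for r in rows],
            "variant_id": [r.variant_id for r in rows],
            "beta": [r.beta for r in rows],
            "se": [r.se for r in rows],
            "t": [r.t for r in rows],
            "p": [r.p for r in rows],
            "n": [r.n for r in rows],
        }
    )
    out["q"] = bh_fdr(out["p"].to_numpy())

    if permutations > 0:
        rng = np.random.default_rng(seed)
        perm_ps = {}
        for pid, pheno in phenotypes.iterrows():
            obs = out.loc[out["phenotype_id"] == str(pid), "p"].min()
            hits = 0
            vals = pheno.to_numpy()
            for _ in range(permutations):
                shuffled = pd.Series(rng.permutation(vals), index=pheno.index)
                pmin = min(
                    associate(shuffled, dose, covariates).p for _, dose in dosage.iterrows()
                )
                if pmin <= obs:
                    hits += 1
            perm_ps[str(pid)] = (hits + 1) / (permutations + 1)
        out["permutation_p"] = out["phenotype_id"].map(perm_ps)
    return out


def cis_window_variants(
    variant_meta: pd.DataFrame,
    chrom: str,
    gene_start: int,
    gene_end: int,
    window: int = 1_000_000,
) -> list[str]:
    """Variant ids within ``window`` bp of a gene (1-based positions)."""
    sel = variant_meta[
        (variant_meta["chrom"] == chrom)
        & (variant_meta["pos"] >= gene_start - window)
        & (variant_meta["pos"] <= gene_end + window)
    ]
    return list(sel.index)


def read_dosage_tsv(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a dosage TSV: variant_id, chrom, pos, ref, alt, then one column per sample."""
    df = pd.read_csv(path, sep="\t", index_col="variant_id")
    meta_cols = ["chrom", "pos", "ref", "alt"]
    meta = df[meta_cols]
    dosage = df.drop(columns=meta_cols).astype(float)
    return dosage, meta


def write_dosage_tsv(dosage: pd.DataFrame, meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.join(dosage)
    out.to_csv(path, sep="\t", index_label="variant_id")


def read_vcf_dosages(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read biallelic GT dosages from a VCF via pysam."""
    import pysam

    rows, meta_rows, ids = [], [], []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            dose = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    dose.append(np.nan)
                else:
                    dose.append(float(sum(1 for a in gt if a != 0)))
            vid = rec.id or f"{rec.chrom}:{rec.pos}:{rec.ref}>{rec.alts[0]}"
            ids.append(vid)
            rows.append(dose)
            meta_rows.append((rec.chrom, rec.pos, rec.ref, rec.alts[0]))
    dosage = pd.DataFrame(rows, index=ids, columns=samples)
    meta = pd.DataFrame(meta_rows, index=ids, columns=["chrom", "pos", "ref", "alt"])
    return dosage, meta
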