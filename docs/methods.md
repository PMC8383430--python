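# Methods

`scnsplice` quantifies developmental changes in mutually exclusive exon
(MXE) usage of voltage-gated sodium channel genes (SCN1A/2A/3A/8A-style
loci) from exon-level and junction-level RNA-seq evidence. This note
documents the models, the parameters that matter, what the synthetic
cohort generator does and does not emulate, and the numerical choices.

## Counting model

**Flattening.** Overlapping transcript CDS intervals are flattened into
disjoint counting bins by grouping contiguous bases with an identical
transcript-membership signature. Every bin is therefore wholly inside or
wholly outside each transcript's exon set, bins are disjoint, and their
union equals the exon union. Bin ids are 3-digit ordinals ascending with
genomic start (negative-strand genes keep ascending ids; presentation
may reverse them). A `cds_index` numbers bins by CDS exon of the longest
annotated transcript walked in translation order; this mapping is a
package choice — annotations do not define a canonical CDS numbering
when transcripts disagree. Only CDS features of protein-coding
transcripts are binned; UTR and non-coding exons are out of scope.

**Counting rule.** A fragment adds +1 to every bin any of its aligned
blocks overlaps by at least one base, and at most +1 per bin. Gaps of at
least `min_intron` (default 20 bases) between consecutive blocks are
junction observations; shorter gaps are treated as deletions. No
mapping-quality or duplicate filtering is applied by default. Counts are
normalized to counts per million (CPM) with externally supplied library
sizes, or in self-contained mode by the per-sample sum of bin counts
(within-sample ratios are identical under either choice).

## Ratio trajectories

For a registered MXE pair the per-sample ratio is `r_s = CPM_A / CPM_N`.
Under the default `zero_policy="exclude"`, samples with zero CPM in
either exon are excluded and counted; the alternative pseudocount policy
(`c = 0.01` CPM) keeps all samples and is used in the all-pairs screen,
where exclusion would bias weakly expressed bins. All transforms use
log base 2.

* **Trend:** OLS of `log2 r` on `log2 age` (age in post-conceptual days,
  pcd); R² = 1 − SS_res/SS_tot; two-sided p from the slope t statistic.
  A constant response is reported as slope 0, R² 0, p 1.
* **Stages:** fetal below 259 pcd (37 post-conceptual weeks, term
  birth), mature from 730 pcd (2 years post-conception), transitional
  between; both boundaries are configuration knobs since stage
  membership, not printed cutoffs, defines cohort groupings.
* **Contrast:** two-tailed Wilcoxon rank-sum of `log2 r` between fetal
  and mature samples. Exact enumeration when the pooled size is ≤ 12
  with no ties, otherwise the normal approximation with tie and
  continuity corrections (via `scipy.stats.mannwhitneyu`).
* **Loess:** at each grid point the nearest `ceil(span·n)` points are
  tri-cube weighted, `w = (1 − (d/d_max)^3)^3`, and a degree-1 (default)
  or degree-2 polynomial is fit by weighted least squares. The 95% band
  is `±1.96·SE` with SE from the local linear operator and a residual
  variance estimated with `n − degree − 1` degrees of freedom, so
  exactly reproduced signals get zero-width bands. Default span 0.75.
* **All-pairs screen:** every unordered bin pair of a gene gets the R²
  of the log-log trend of its pseudocounted CPM ratio, dropping samples
  where both bins fall below `min_cpm` (default 1 CPM). A bin whose
  median off-diagonal R² exceeds 0.3 is flagged as having a distinct
  trajectory; the threshold operationalizes what is otherwise a visual
  heat-map judgement.

## Junction splicing model

Junctions sharing a donor or acceptor coordinate (same chromosome and
strand) form clusters as connected components; junctions carrying less
than `min_junction_fraction` (default 0.001) of their component's reads
are pruned iteratively, and components with fewer than 2 junctions or
fewer than `min_cluster_reads` (default 30) pooled reads are dropped
with the reason recorded — so a pair too weakly expressed to cluster is
an observable outcome, not a silent absence.

Within a cluster, per-sample junction counts follow a
Dirichlet-multinomial: the log-likelihood is

    sum_s [ lnG(a) − lnG(n_s + a) + sum_j ( lnG(y_sj + a p_sj) − lnG(a p_sj) ) ]

with concentration `a` and proportions `p_sj = softmax(mu_j + x_s b_j)`
(`x_s` ∈ {0,1} the group label; null model `b = 0`). `mu` and `b` are
sum-to-zero for identifiability; `(mu, b, log a)` is optimized by
L-BFGS-B with the analytic gradient, starting from moment estimates plus
2 jittered restarts, and the alternative additionally starts from the
null solution so the likelihood ratio is non-negative by construction.
The LRT is referred to chi-square with J−1 degrees of freedom; an
empirical permutation p-value is available for small cohorts. All-zero
junctions are dropped with a warning before fitting.

**Mutual-exclusivity score.** Split reads in the flank–A/N–flank window
are classed as consistent (flank↔A, flank↔N), cross (A↔N), or
double-skip (flank→flank). The consistency fraction is
consistent/(consistent+cross); double-skip is reported separately
because skipping both exon copies is a real isoform for the second
(18A/18N-style) pair, not an inconsistency. Sashimi summaries report
each junction's share of pooled split reads in the window per group.

## sQTL stage

Variants are filtered to minor allele frequency ≥ 5% separately in
every sample group (prenatal and postnatal must both pass) and
Hardy-Weinberg exact-test p ≥ 1e−12 on pooled hard genotypes. The HWE
test is the conditional exact test over heterozygote counts given
allele counts, computed by a numerically stable recurrence from the
modal table. Genotype principal components (default 5) come from the
SVD of the dosage matrix centered per variant and scaled by
`sqrt(2p(1−p))`.

Associations are OLS of the splicing phenotype on dosage plus
covariates with a two-sided t-test on the dosage coefficient, and BH
q-values across all variant × phenotype tests; an optional empirical
permutation p-value per phenotype replaces the beta-approximated
permutation scheme of dedicated QTL engines while preserving the same
contract (sQTL yes/no at an FDR threshold).

**Age adjustment.** Splicing phenotypes follow sigmoid trajectories on
log-age, so a linear age covariate leaves large structured residuals
that mask genotype effects. The default therefore residualizes each
phenotype against its Loess trend on `log2 age` before association,
with a deliberately narrow span (0.3) so the sharp switch is captured;
genotype is independent of age, so the smooth cannot absorb a true cis
effect. Linear adjustment and no adjustment remain available.

## Synthetic cohorts

The generator emulates a bulk RNA-seq brain-development cohort:

* **Ages:** log-uniform over 42–7566 pcd (a 6-post-conception-week to
  20-year design), default 176 samples.
* **Switch:** N-exon inclusion `f_N(t) = f1 + (f0 − f1)/(1 + (t/t50)^h)`
  — logistic in log-age, so the transition appears linear on log-age
  axes. Default parameters are back-computed from reported mature/fetal
  A:N ratio shifts used as inputs (0.27→11.4, 1.0→5.7, 0.7→4.2), with
  midpoint 450 pcd and steepness 6 so the asymptotes hold across the
  fetal and mature windows. An optional skip trajectory of the same
  form models double-skip isoforms. Per-sample biological noise (sd 0.3
  on the logit) and an optional planted sQTL (logit shift per alternate
  allele) act on `f_N`.
* **Counts:** per-gene depth (default 500 fragments/sample, the
  coverage of a highly expressed gene at typical library sizes) is
  modulated by a power-law age trajectory and split over bins by
  length × isoform fraction. Dispersion is gene-level: one
  Gamma(1/φ, φ) factor per gene and sample multiplies all bin means,
  with Poisson draws given the factor (φ default 0.1). Each bin count
  is marginally NB with variance mean + φ·mean², while within-gene
  ratios cancel the shared factor — matching real data, where
  overdispersion is predominantly gene-level; independent per-bin NB
  noise would make ratios unrealistically noisy.
* **Junctions:** per-sample totals are Poisson at `junction_depth`
  (default 0.4) times gene depth, split multinomially over the
  flank→A, A→flank, flank→N, N→flank (and skip) junctions with weights
  proportional to isoform abundance.
* **Placements:** every ledger fragment is emitted as a read placement
  (single block inside its bin, or two anchored blocks meeting at the
  recorded donor/acceptor), so re-counting reproduces the per-bin and
  per-junction ledgers exactly.
* **Genotypes:** dosages are Binomial(2, MAF) with MAF uniform on
  [0.05, 0.5] (Hardy-Weinberg by construction), 50 variants by default.

**What passing tests do not show.** The generator has no batch effects,
no cell-type composition shifts (bulk tissue), no alignment or
mappability artifacts, no sequence-level errors, and its toy gene
models have a single MXE pair with clean flanks. Recovery of switch
parameters and planted QTLs on these cohorts validates the estimators
and their plumbing, not robustness to those real-data complications.

## Numerical choices and degenerate inputs

* Internal coordinates 0-based half-open; GTF converts at the boundary.
* DM optimizer tolerance 1e−8 on the log-likelihood; LRT clipped at 0.
* Loess at a grid point with zero distance spread uses unit weights;
  `k` is floored at degree+2.
* Constant-response trend fits return R² 0 / p 1 rather than NaN.
* Zero-read samples and all-zero junctions are dropped from DM fits;
  clusters must keep ≥ 2 junctions and ≥ 2 non-empty samples per group.
* HWE exact p is capped at 1; monomorphic tables return p 1.
* Problem sizes used by the test suite and acceptance script (cohorts
  of 30–176 samples, 500 random gene structures, 500 null clusters,
  20 sQTL seeds) were chosen to make the statistical assertions stable
  at desk scale.

## Known limitations

* Fragment pairing is taken from the placement table (one row per
  fragment); the BAM adapter emits one placement per primary alignment
  and does not merge mates by name.
* Clustering is intended for configured gene windows, not
  transcriptome-wide scans (mathematically identical, but memory/time
  profiles differ).
* The screen's `distinct` flag and the stage boundaries are explicit
  operationalizations of judgements that are made visually or by cohort
  membership in typical study designs; both are configuration knobs.
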