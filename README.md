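# scnsplice

Developmental quantification of mutually exclusive exon (MXE) usage in
voltage-gated sodium channel genes from bulk RNA-seq evidence.

The sodium channel genes *SCN1A*, *SCN2A*, *SCN3A*, and *SCN8A* each
carry two mutually exclusive copies of their fifth protein-coding exon —
a "neonatal" copy (5N) and an "adult" copy (5A); *SCN8A* carries a second
such pair (18A/18N). Which copy is spliced in changes the channel's
biophysics, and the balance shifts dramatically across brain
development. `scnsplice` is a tested pipeline for measuring that shift:
it is written for computational biologists who want to quantify exon-bin
expression, track A:N ratio trajectories across developmental age, test
junction-level splicing contrasts, screen all exon pairs of a gene for
distinct trajectories, and run a light splicing-QTL (sQTL) stage —
end-to-end, on cohorts with known ground truth.

## What it computes

* **Counting bins.** Transcript CDS intervals are flattened into
  disjoint bins (each wholly inside or outside every transcript), read
  placements are counted per bin (a fragment adds +1 to every bin it
  touches, at most once), and counts are CPM-normalized.
* **Ratio trajectories.** For a registered MXE pair, the per-sample
  ratio r_s = CPM_A / CPM_N; its trend as OLS of log2(r) on log2(age in
  post-conceptual days); a tri-cube-weighted Loess smooth with 95%
  bands; and a fetal-vs-mature two-tailed Wilcoxon rank-sum contrast.
* **Junction splicing.** Exon–exon junction reads are clustered over
  shared splice sites; within a cluster, per-sample junction counts
  follow a Dirichlet-multinomial GLM,
  p_sj = softmax(mu_j + x_s b_j), tested prenatal-vs-postnatal by
  likelihood ratio against chi-square(J−1). Sashimi-style per-group
  junction proportions and a mutual-exclusivity consistency score
  (flank↔A / flank↔N reads vs A↔N reads, with double-skip reported
  separately) validate the exon-level picture.
* **All-pairs exon-ratio screen.** The log-log trend R² of every exon
  pair of a gene, flagging bins whose trajectory departs from the rest
  of the gene.
* **sQTL stage.** MAF/HWE variant filters, genotype principal
  components, OLS association of splicing phenotypes with dosage after
  Loess age-detrending, and Benjamini-Hochberg FDR.
* **Synthetic cohorts.** A generator producing log-spread ages, a
  logistic N→A switch f_N(t) = f1 + (f0−f1)/(1+(t/t50)^h), gene-level
  negative-binomial counts, junction reads consistent with isoform
  fractions, Hardy-Weinberg genotypes, and an optional planted sQTL —
  with an exact per-read truth ledger for every downstream assertion.

See `docs/methods.md` for models, parameters, and numerical choices.

## Worked example

Simulate a 60-sample cohort (switch parameters default to the reported
human-cortex ratio shifts: SCN2A-like A:N 0.27 fetal → 11.4 mature,
SCN3A-like 1.0 → 5.7, SCN8A-like 0.7 → 4.2), run all stages, render a
report:

```bash
cat > config.yaml <<'YAML'
seed: 1
simulate:
  n_samples: 60
YAML
scnsplice simulate --config config.yaml --out cohort/
scnsplice run --config config.yaml --in cohort/ --out run/
scnsplice report --in run/
```

which prints:

```
scnsplice report
================
SCN2A 5A/5N: fetal ratio 0.301, mature 13.4, trend slope 1.06 (R^2 0.821), Wilcoxon p 1.47e-08
SCN3A 5A/5N: fetal ratio 0.977, mature 5.97, trend slope 0.511 (R^2 0.754), Wilcoxon p 1.47e-08
SCN8A 5A/5N: fetal ratio 0.775, mature 4.15, trend slope 0.479 (R^2 0.676), Wilcoxon p 1.47e-08
SCN2A: MXE-consistent split reads 100.00% of 12311
SCN3A: MXE-consistent split reads 100.00% of 12563
SCN8A: MXE-consistent split reads 100.00% of 12776
```

Reading the output: the stage-binned geometric-mean A:N ratios recover
the generating values within sampling error at n=60 (0.30 vs 0.27 fetal,
13.4 vs 11.4 mature for the SCN2A-like gene); the positive log-log trend
slope with R² ≈ 0.8 is the developmental switch; the Wilcoxon p is the
fetal-vs-mature contrast; and 100% of junction reads are consistent with
mutually exclusive usage, as generated. `run/` also contains per-gene
trajectory tables, screen R² matrices, splice-cluster test results with
q-values, sQTL results, and a `summary.json`.

The same analyses are available as library functions
(`scnsplice.pipeline.analyze_pair_trajectory`, `analyze_splicing`,
`analyze_screen`, `analyze_sqtl`) on in-memory objects.

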