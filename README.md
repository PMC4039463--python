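# cnadose

Copy-number burden, gene-dosage expression attribution and survival analysis
for tumor cohorts.

## The problem

In many solid tumors — cervical carcinoma is the motivating case — large
chromosomal gains and losses are ubiquitous, yet genome-wide the expression
of most copy-number-altered genes barely moves. `cnadose` implements the
complete analysis chain used to quantify this: how much of a tumor's
transcriptional deregulation can be attributed *directly* to gene dosage
(a gene sits inside a gained or deleted segment), and how much arises *in
trans*, driven by the overall burden of alteration (typically dominated by
one recurrently amplified arm such as 3q).

The pipeline runs from raw marker-level log2 copy ratios to survival curves:

1. **Segmentation** (`cnadose.segmentation`) — a 5-state Gaussian HMM
   (states 0–4 = homozygous deletion … amplification) decoded with Viterbi
   after a short running-mean smoother; copy-number alterations (CNAs) are
   segments with ≥50 altered markers, ≥500 kb, and ≤50% overlap with
   germline CNVs; states 3 and 4 are pooled.
2. **Burden** (`cnadose.burden`) — %CN-AG, the percent of the haploid
   genome (3,000 Mb convention) inside CNAs larger than 2.5 Mb, overall and
   per arm; tumors stratified into low/medium/high burden groups; per-gene
   dosage status CN1/CN2/CN3 by interval overlap; recurrence curves.
3. **Expression status** (`cnadose.expression`) — per-tumor dual-cutoff
   calls (up: intensity ≥ 2·x̄ and > x̄+1s of controls; down: ≤ 0.5·x̄ and
   < x̄−1s), and a from-scratch two-class SAM
   (d = Δmean/(s_i + s₀), permutation FDR, fold-change ≥ 1.5 filter),
   per-arm chi-square enrichment, and average-linkage clustering of sample
   profiles.
4. **Dosage attribution** (`cnadose.attribution`) — the core statistic: the
   pooled deregulation rate among CN-altered genes minus the rate among
   two-copy genes (the *dosage difference*, in percentage points); OLS of
   deregulated-gene counts on burden; forward-stepwise decomposition of
   burden onto arms; the exclusive-set analysis (genes deregulated only in
   high-burden tumors) with recurrence bounds; per-gene correlation with an
   arm's burden.
5. **Survival** (`cnadose.survival`) — Kaplan–Meier curves, k-group
   log-rank tests, a Youden-index ROC cutoff on burden, Cox models with
   FIGO stage, and Spearman co-linearity checks.

A first-class synthetic-cohort generator (`cnadose.cohort`) plants known
ground truth — a skewed burden distribution, a preferentially amplified
arm, a chosen fraction of dosage-responsive genes, trans-regulated genes
and burden-linked survival — so every stage is testable end to end.

## Worked example

```python
import cnadose as cd

cohort = cd.generate_cohort(cd.CohortConfig(marker_spacing=10_000), seed=1)
res = cd.analyze_cohort(cohort.markers, cohort.tumor_expr,
                        cohort.control_expr, cohort.genome, cohort.clinical,
                        params=cd.PipelineParams(seed=1))
att = res.attribution
print(f"CN-altered genes deregulated: {att.rate_altered:.1f}%")
print(f"two-copy genes deregulated:   {att.rate_cn2:.1f}%")
print(f"dosage difference:            {att.dosage_difference:.1f} points")
```

prints

```
CN-altered genes deregulated: 5.7%
two-copy genes deregulated:   0.9%
dosage difference:            4.8 points
```

The generator planted a 5% fraction of dosage-responsive genes; the
cross-tabulation recovers it as a 4.8-point excess of deregulation among
CN-altered genes. On the same run, forward-stepwise regression selects the
amplified arm (`3q`) first, attributing 95% of the burden variance to it.

The package also ships transcriptions of a published cervical-carcinoma
cohort's per-tumor summary tables (`cnadose.datasets`). Recomputing from
them:

```bash
cnadose reproduce-tables
```

reports, among others, a mean burden of 8.1% (groups 0.5/5.4/19.2%),
deregulation rates of 14.4% (CN-altered) vs 9.1% (two-copy) — a dosage
difference of 5.3 points — a burden regression of y = 32x + 1734 (r = 0.5),
exclusive-set statistics 81.1/49.1/22.9%, and a 64.3% overall survival rate
with a mean time to death of 19 months.

## Command line

`cnadose` exposes subcommands `simulate`, `segment`, `burden`, `express`,
`attribute`, `cluster`, `survive`, `run-all` and `reproduce-tables`; stage
commands take a YAML config naming the input TSV/BED files, thresholds and
seeds, and write TSV outputs plus a content-hash manifest (identical
configs reproduce identical hashes).

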