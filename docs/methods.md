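# Methods

This note documents the models, conventions and numerical choices behind
`cnadose`, and what the synthetic cohort does and does not emulate.

## Coordinates and formats

All genomic intervals are 0-based half-open, in base pairs, both in memory
and in BED files; conversion happens only at I/O boundaries. Matrices are
TSV with `gene_id` row keys; expression matrices declare their scale
(`# scale=linear|log2`) in a header comment, and generator outputs record
their seed the same way.

## Copy-number segmentation

Marker-level log2 ratios are modeled with a five-state Gaussian HMM.
Emission means default to log2(CN/2) — (−2.0, −1.0, 0.0, +0.585, +1.0) —
with the zero-copy state floored at −2.0 to avoid −∞; the emission SD
defaults to 0.25, matching typical SNP-array noise. Transitions are
homogeneous (no genomic-distance scaling) with a per-marker self-transition
of 0.999 and the remainder spread uniformly over the other four states.
Decoding is exact Viterbi in log space (numba-accelerated); a test oracle
enumerates all 5^n paths on short sequences to confirm exactness, and
`hmmlearn` decoding serves as an independent cross-check.

Before decoding, each arm's ratios pass through a 5-marker running mean
(`smooth_window`, set to 1 to disable). Raw per-marker decoding leaves
segment-boundary placement noise-limited: at a 0.585 log2 step with SD
0.25, the maximum-likelihood change point is off by three or more markers
in roughly one replicate in ten, irrespective of decoder settings. The
short running mean trades resolution below the window width for a large
variance reduction, bringing ±2-marker breakpoint recovery above 95%.
Segment boundaries fall at the integer midpoint between flanking markers of
differing state, so segments tile the marker span exactly and adjacent
segments always differ in state.

CNA filters follow array-calling practice: non-diploid state, ≥50 altered
markers, ≥500 kb, and ≤50% overlap (boundary inclusive) with the union of
germline CNV intervals (union prevents double-counting). States 3 and 4
are pooled afterwards (amplifications are rare and never highly
recurrent), merging adjacent same-state segments with marker counts
summed. The separate >2.5 Mb size threshold used for burden is applied
downstream in the burden stage, so the ≥500 kb call set remains available
for cross-platform concordance, which scores a segment as concordant when
at least half its bases are covered by same-direction calls on the other
platform.

## Burden and gene dosage

%CN-AG is 100 × (total length of CNAs strictly longer than 2.5 Mb) /
(haploid genome size). The denominator is the 3,000 Mb haploid-genome
convention for real data and the explored genome size for synthetic
cohorts; both are configurable. Tumors are sorted by burden and split into
low/medium/high groups with any remainder assigned to the earliest groups
(n = 31 → 11/10/10), ties broken by sample id so the grouping is
order-invariant.

Genes take status CN1/CN3 from any (≥1 bp) overlap with a loss/gain CNA —
the simplest rule consistent with the near-perfect correlation (r = 0.99)
between altered-gene counts and burden in the reference cohort. A gene hit
by both directions in one tumor takes the larger base overlap, ties going
to the gain (gains dominate in this disease); this heuristic is exercised
by a per-base brute-force oracle in the tests.

## Expression status and SAM

The per-tumor dual-cutoff rule operates on **linear** intensities
(2^RMA-log2): up requires ≥2× the control mean *and* > mean+1 SD; down
requires ≤0.5× *and* < mean−1 SD. A doubling rule on log2 values would be
biologically implausible; the scale is declared in file headers and
configurable. With a positive control mean the two conditions are mutually
exclusive (property-tested).

SAM is the Tusher-style two-class statistic d = (x̄₁−x̄₂)/(s_i+s₀) computed
on log2 intensities, with s_i the pooled standard error. s₀ is chosen on
the percentile grid {0,5,…,100} of s_i by minimizing the coefficient of
variation of window-wise MADs of d. The permutation null uses all label
assignments when C(n₁+n₂,n₁) ≤ 2000 (e.g. all 924 at 6+6), otherwise a
seeded Monte-Carlo sample (default 1000). The delta threshold is the
smallest value whose **median** permutation false-call count yields an FDR
at or below the target (default 0); the **reported** FDR estimate uses the
mean permuted false count at the chosen cuts, which tracks the expected
false discovery proportion (the median-based value is exactly zero at the
operating point by construction). π₀ is fixed at 1 (conservative). Called
genes must also pass the linear fold-change filter (≥1.5 up, ≤1/1.5 down).
A per-gene local false discovery estimate π₀·f₀(d)/f(d) is reported from
Gaussian KDEs of the permutation null (subsampled to 20k points) and the
observed d; it is informational and not part of the calling rule.

Per-arm enrichment uses a 2×2 chi-square (arm vs rest, no continuity
correction) with a one-sided flag (rate above the rest-of-genome rate and
p < 0.05). Sample clustering is average-linkage on Euclidean distances
between sample profiles (scipy), cut into k branches; association with
burden groups uses an exact r×c Fisher test computed by exhaustive
enumeration of fixed-margin tables when the total is ≤60, else a seeded
Monte-Carlo.

## Dosage attribution

Pooled rates use the **ratio of means** (mean per-tumor deregulated count
divided by mean per-tumor group size) — the convention that reproduces the
reference cohort's printed 14.4%/9.1% row — and the dosage difference is
their gap in percentage points, with a chi-square on the pooled 2×2. The
burden regression is ordinary least squares with the Pearson-r t-test
p-value. The arm decomposition is forward-stepwise OLS with a partial-F
entry criterion of p < 0.05, skipping candidates that push the design
matrix condition number above 1e8; each predictor's incremental R² is
reported as a share of the final model's R² (the first entry's share is
the "fraction of variation accounted for" headline). An exhaustive
best-subset enumeration serves as the test oracle.

The exclusive-set analysis takes the SAM call sets of the high- and
low-burden groups against the same controls: pct_shared =
|high∩low|/|low|, pct_exclusive = |high∖low|/|high|, and a conservative
dosage bound = the fraction of the exclusive set CN-altered in ≥4 (default)
high-group tumors, with recurrence strata reported at ≥6 / 4–5 / 1–3 / 0.
Per-gene burden correlations use raw p < 0.05 with no multiplicity
correction (matching the screen they reproduce); a BH option exists but is
off by default.

## Survival

Analysis is cause-specific: untreated patients are excluded, deaths of
other or unknown cause are censored at the death time, and only
primary-tumor deaths are events. The "overall survival rate" is the
end-of-follow-up surviving proportion (alive plus censored). FIGO stages
are coded ordinally IB1 < IB2 < IIA < IIB < IIIB < IVA < IVB. KM, k-group
log-rank and Cox (Breslow ties, Newton convergence tightened to 1e−10) are
provided by lifelines behind the module surface; perfect-separation fits
are flagged and refit with a small ridge, coefficients capped at ±20. The
burden cutoff maximizes Youden's J over observed values with ties resolved
toward the lower cutoff; Spearman co-linearity uses mid-ranks with the
t-approximation.

## Synthetic cohort

Defaults are the desk-scale study conditions: a 300 Mb genome over 8 arms
(one-tenth of the human genome, arm "3q" the preferentially amplified
analog), 2 kb marker spacing, 2,000 non-overlapping 30 kb genes, 31 tumors
and 17 controls. Per-tumor burden targets are drawn from three strata
(means 0.5/5.4/19.2%, SDs 0.6/2.4/6.6, sizes 11/10/10) and realized as
planted segments of ≥2.6 Mb (so each counts toward burden) with an
exponential length tail; about 55% of gained bases go to the 3q analog
first (snapping to a whole-arm gain when close), the rest scatter over
free intervals; gains are CN 3 (15% CN 4), losses CN 1 (10% CN 0).
Markers emit log2(CN/2) + N(0, 0.25) with CN 0 floored at −2.

Control expression is log-normal (log2 mean 6, SD 1.5 — RMA-scale
intensities) with residual SD 0.35 (log2) per sample; at that noise the
dual-cutoff false-call rate stays below 1%, which is what makes the
planted fraction recoverable. A fraction (default 5%) of genes is
dosage-responsive: their expression is multiplied by (CN/2)^3 where
altered — the exponent is chosen so a single-copy gain (1.5×) crosses the
2× call threshold, i.e. planted "direct dosage" genes are genes whose
dosage response is strong enough to be called. A further 3.2% of genes
(off the amplified arm, mirroring the reference cohort's share of
trans-only deregulated genes) shift by 1.5 log2 units per unit of
3q-analog gain fraction. Survival times are exponential with hazard
0.005·exp(0.10·burden%) per month, administrative censoring uniform on
60–86 months, a 3% competing non-tumor death rate and 10% untreated
patients; FIGO stage is drawn from burden-rank quantiles mixed with noise
(weight 0.6) to target a Spearman correlation near 0.5 with burden.

What the generator does **not** emulate: probe-level chemistry and GC
waves, tumor purity and subclonality, allele-specific copy number,
correlated co-expression modules, and epigenetic repression inside
amplified regions. Passing the planted-truth recoveries therefore shows
the pipeline's inference is correct under its own model, not that the
biological estimates from real arrays are unbiased.

## Problem sizes and determinism

Replicate-heavy checks run the same generator at coarser marker spacing
(10 kb for attribution recovery, 500 kb with no genes for survival
calibration) — burden and expression statistics are insensitive to marker
density well above the segment scale, and this keeps full-suite runtimes
in minutes. All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; identical (config, seed) pairs produce
byte-identical outputs, which the manifest hashes verify end to end.

## Known limitations

The HMM has no distance-dependent transitions, so very sparse arms
segment the same as dense ones; the SAM local-FDR is a KDE approximation
without a published reference implementation to match; the r×c Fisher
enumeration is exponential and falls back to Monte-Carlo above a total of
60; and the survival module does not model competing risks — non-tumor
deaths are censored, which is standard but optimistic if competing risks
correlate with burden.
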