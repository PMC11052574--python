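# Methods

## The interaction model

For a trio (gene, variant, peak) with sample-aligned vectors, expression is
modelled as

    y_i = β0 + β1·x1_i + β2·x2_i + β3·x1_i·x2_i + ε_i,   ε_i ~ N(0, σ²)

with `x1` the dosage genotype (0 = reference homozygote, 1 = heterozygote,
2 = non-reference homozygote; the heterozygote is the midpoint by
construction, and multi-allelic markers are out of scope) and `x2` a
continuous, non-negative open-chromatin intensity on a TMM-like scale. The
fit is ordinary least squares. Assumptions are the usual ones: independent
samples, homoscedastic Gaussian residuals, and a linear-in-dosage genetic
effect. No kinship/covariate correction is modelled.

Two decisions interact here and are computed independently of one another:

* **Term selection** is backward elimination from the full model on
  `AIC = n·ln(RSS/n) + 2k` (k = number of estimated coefficients, intercept
  included; the additive Gaussian-likelihood constant cancels at fixed n).
  Marginality is enforced — the interaction must be dropped before either
  main effect. At each step the drop that most lowers AIC is taken; the
  search stops when no drop lowers AIC. Ties within 1e-12 prefer dropping
  the interaction, then `x2`, making output deterministic. The retained set
  maps to the model class: `{x1,x2,x1x2}` interacting, `{x1,x2}` additive,
  `{x1}` genotype-only, `{x2}` ATAC-only, `{}` null.
* **Significance** is a partial F-test of the interaction against the
  additive null, `F = (RSS_add − RSS_full) / (RSS_full/(n−4))` on (1, n−4)
  df, Bonferroni-adjusted over the family and thresholded at adjusted
  p < 1×10⁻⁷. Whether selection should gate the test is genuinely open; both
  are computed unconditionally for every trio and a "significant model" in
  downstream analyses means *interaction retained by AIC and adjusted
  F-test p below α*. This matters: AIC alone retains the interaction for
  roughly 16% of pure-noise trios (the known behaviour of AIC with a single
  extra parameter, retention when F ≳ 2), so AIC retention is a model
  *class* label, not an evidence claim.

**Bonferroni family.** The family is the number of successfully fit trios in
the batch. Trios skipped as degenerate (monomorphic marker or zero-variance
peak) and fits flagged collinear are excluded but counted in the manifest,
so a user who wants the stricter family can recompute.

**Numerical choices.** Single-trio fits use QR/SVD least squares
(`numpy.linalg.lstsq`); the batched scan solves 4×4 Gram systems per trio,
chunked, with a condition-number guard (cond > 1e12 flags the design
collinear; its F is undefined and it leaves the family). Nested-model RSS is
clamped monotone. Inside AIC, RSS is floored at `1e-12·(yᵀy + 1)`: with
exactly noiseless planted data all submodels containing the truth have RSS
at round-off level, their floored AICs tie, and the 2k penalty then selects
the simplest true model instead of amplifying round-off noise. The floor is
far below any realistic residual and is inert on noisy data. Degenerate
cases: constant `y` yields β1=β2=β3=0, F=0, p=1; constant `x1` or `x2`
raises a degenerate-input signal.

## Scan plans

*Random intrachromosomal*: `n_models` distinct (gene, variant, peak) trios
drawn uniformly (seeded) from all same-chromosome combinations.
*TAD-constrained*: chromosomes are partitioned into alternating TAD and
inter-TAD regions; for each gene the enumeration window runs from the start
of the region immediately upstream of the region containing the gene's TSS
to the end of the region immediately downstream, and all variants (by locus)
and peaks (by midpoint) inside the window are crossed. Anchors everywhere:
gene = strand-aware TSS, variant = locus, peak = midpoint; coordinates are
0-based half-open.

## TAD geometry

TADs are loops: for loop-relative statistics the two boundaries are
identified as a single joined point, so intra-TAD positions live on a circle
of circumference L and the loop distance is `min(|a−b|, L−|a−b|)` (max
L/2). Standardized coordinates divide by L and take the sign from the linear
offset of the peak from the TSS, giving gene-centered profiles on [−0.5,
0.5].

The intra-TAD enrichment table is built from deduplicated *tested* (gene,
peak) pairs: rows intra (peak midpoint in the gene's TAD) vs not, columns in
≥1 significant interacting model vs not, Fisher exact two-sided, odds ratio
(a·d)/(b·c) with a Haldane–Anscombe 0.5 correction (flagged) when a cell is
empty. Peaks within 200 kb of a TAD boundary are ambiguous at boundary
resolution and are excluded by default (the count is reported); a flag keeps
them. The capture window takes, per significant interacting model, how far
upstream/downstream of the TSS its farthest element lies, and returns the
q-th "higher" order-statistic quantile of each side separately — marginal
quantiles match the asymmetric (upstream, downstream) pair this statistic is
meant to summarise; a joint-coverage definition would be underdetermined.
Fewer than 20 significant models refuses (quantile unstable).

Search-efficiency profiles bin tested (gene, peak) pairs by signed TSS
offset; linear mode counts all pairs in a bin, TAD mode only pairs sharing
the gene's TAD. Reported per bin: pair count and percent interacting.

## Effect taxonomy

Signs of (β1, β2, β3) on significant interacting models: all equal →
synergy; mains agree, interaction opposes → redundancy/interference; mains
disagree → mixed; any required term not retained → incomplete. Coefficients
within 1e-12 of zero take sign 0 and are flagged (OLS on float data never
returns exact zeros outside degenerate constructions). Magnitude summaries
report the fraction of models with |β3| exceeding |β2|, |β1|, or both, and
the fraction with β2 < 0, over significant interacting models by default
(a flag widens to all significant models).

## PWM scanning

Windows on both strands are scored with log2(P(window|PWM)/P(window|bg));
zero probabilities are floored at 2⁻⁶⁴ in log space. P-values are exact
tails of the score distribution under the background, computed by dynamic
programming after rounding the log-odds matrix to integer multiples of a bin
width (1000 bins across the matrix score range, configurable). Because the
observed window scores use the *same* rounded matrix, the p-value is exact
for the discretized score — the approximation is the matrix rounding, not
the tail computation. Windows containing N are skipped. Annotation uses a
midpoint rule (a peak belongs to a category when its midpoint falls in any
category interval; categories non-exclusive) — unambiguous and order-free
where partial-overlap rules are not. The background defaults to uniform
0.25 and is configurable. Negative-effector peaks: ≥10 significant
interacting models with ≥50% negative β2; the complementary
qualifying peaks are positive effectors.

## Strain ChIP validation

A peak is consensus when detected (fold enrichment above a detection floor,
default 1.0, configurable — peak calling itself is upstream of this package)
in ≥2 replicates of ≥1 strain; the strain-sharing distribution counts
strains with ≥1 detected replicate among consensus peaks. Binding variance
is the per-peak sample variance (ddof 1) across all samples, with the
fraction exceeding 10 reported. Genotype–binding association groups samples
by the allele their strain carries at a site's biallelic SNP and compares
fold enrichment with **Welch's two-sample t-test** by default. A paired test
is sometimes quoted for this design, but replicate groups split by allele
across strains have no natural pairing, so the unpaired unequal-variance
test is the defensible default; a pooled-variance Student switch
(`equal_var=True`) is provided. Groups with <2 samples per allele are
flagged untestable. Subset significance rates report the fraction of
testable peaks with p < 0.05 per named subset; standard subsets (all, under
ATAC peaks, additive, interacting, negative/positive effectors, dense-model
regions) are wired where the linking inputs exist. "Dense-model regions" are
TADs containing more significant models than the genome-wide mean — the TAD
is the natural region unit for this package.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, not
sequencing data:

* **Genome/TADs**: configurable chromosomes tiled left-to-right with TAD
  lengths drawn log-normally (mean 1.1 Mb, SD 0.4 Mb by default — the
  reported scale of mammalian domains), optional inter-TAD gaps
  (probability 0.25, exponential mean 60 kb), optional tiling to the
  chromosome end. Features (genes with strand and TSS, point markers, peaks
  ~500 bp) are placed uniformly.
* **Genotypes**: per-marker binomial(2, f), f uniform in [0.2, 0.8] —
  balanced allele frequencies as in a randomized outbred panel. Markers are
  independent; linkage structure is deliberately not simulated (the scan
  treats markers as given), so synthetic recovery results say nothing about
  causal-variant resolution under LD.
* **Intensities**: log-normal(μ=1, σ=0.5) — no distribution is prescribed
  for real TMM intensities beyond continuous and non-negative; this is a
  placeholder exposed in config.
* **Expression**: the interaction model with per-gene class mixture,
  coefficient magnitudes uniform in configurable ranges with negative signs
  at probability 0.4, residual SD 0.5 log2-TPM by default (also a
  placeholder — the real residual scale is not prescribed). Causal elements
  are intra-TAD with configurable probability; forcing intra-TAD placement
  where no intra-TAD marker/peak exists raises.
* **Sample count** defaults to 176.
* **CTCF world**: motif-consensus instances embedded in random sequence,
  biallelic SNPs in a configurable fraction of sites with per-strain
  alleles, replicate fold enrichment = log-normal base × allele multiplier
  (default 0.2) + Gaussian noise, clipped at 0; `effect_rate` decouples
  SNP presence from effect so null worlds calibrate at ~5%.

Passing tests on these worlds demonstrate correctness of the machinery and
calibration under the model's own assumptions; they do not demonstrate
robustness to LD, batch structure, non-Gaussian residuals, or shared-peak
correlation present in real data.

## Problem sizes used in tests and the acceptance script

Scan worlds use two 8-Mb chromosomes, 200 genes, 350 markers, 350 peaks and
176 samples (≈1M TAD-window trios); null calibration uses 10⁵ random trios;
PWM checks use a length-6 motif (4096-window enumeration) and 200–300 kb of
background sequence; ChIP worlds use 500–1500 sites with 4 strains × 3
replicates. These sizes make every property measurable with comfortable
statistical margins while keeping a full run to a few minutes.

## Known limitations

* Marker independence means intra-TAD enrichment odds ratios on synthetic
  worlds are far larger than anything achievable with LD-limited variant
  resolution; compare orderings and calibrations, not magnitudes.
* The exhaustive-submodel AIC oracle and the greedy backward path agree on
  all tested data, but greedy backward search is not globally optimal in
  pathological AIC landscapes; it is the standard and the documented
  behaviour.
* PWM p-values inherit matrix-rounding granularity (~1/1000 of the score
  range); ties at bin edges move p by at most one bin mass.
* `annotate_peaks` and the enrichment table use point anchors (midpoints);
  interval-overlap semantics would change percentages for wide peaks.
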