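# Methods

## Scientific setting

Knee osteoarthritis (OA) is diagnosed radiographically, yet in biobank
cohorts case status usually comes from billing codes (ICD-10 M17) that
under-report the disease. When an image is available, two better
phenotypes can be read off it: a radiographic case/control call
(Kellgren–Lawrence grade ≥ 3), and the *minimum joint-space width*
(mJSW) — the narrowest femur–tibia distance on an anterior-posterior
view — a quantitative endophenotype that tracks severity. The package
implements the measurement of mJSW from bone segmentation masks and
the downstream statistical comparison of three phenotype definitions
(quantitative mJSW, dichotomized radiographic status, and a thinned
health-record label) in genetic and epidemiological association, all
on synthetic data whose ground truth is known.

## Phantom generator

Phantoms are drawn as filled polygons on an 8-bit raster with a
parallel label mask (0 background, 1 femur, 2 tibia, 3 fibula): a
flat (optionally slightly tilted) tibial plateau, a femoral condyle
block with a rounded upper outline, bone shafts, and a fibula placed
on the lateral side strictly outside the femur–tibia overlap so it can
never affect a gap measurement. The per-column femur–tibia gap is
controlled exactly: three anchor gaps (lateral/center/medial, mm) are
interpolated by a Lagrange quadratic across the overlap and rounded to
pixels at the phantom's pixel spacing, and the resulting integer
profile is stored with the scan as ground truth. Anchor recovery is
therefore exact up to half a pixel spacing of rounding. Specs whose
smallest gap falls below one pixel are rejected as unresolvable.
Image noise is additive Gaussian on the rendered intensities only;
masks are noise-free (segmentation error is out of scope — the
pipeline consumes masks, standing in for a trained segmenter).

The default resolution set is three pixel spacings, 0.20 / 0.25 /
0.30 mm per pixel, with image sizes (800×1000, 720×920, 640×840) at or
below the 800×1000 standardization target. Several spacings exist
purely to exercise resolution normalization.

## Measurement pipeline

1. **Standardization.** Scans are zero-padded to 800×1000 with content
   centered (ties broken toward the top-left); scans larger than the
   target in either axis are rejected as resolution outliers.
2. **Gap profile.** For every column containing both femur and tibia
   pixels, gap(x) = (topmost tibia row) − (bottommost femur row) − 1,
   floored at zero so touching bones read 0. The measurement is
   vertical within a column (not nearest-neighbour Euclidean): it is
   simple, axis-aligned, and checkable against an exhaustive row scan.
   Fibula pixels are ignored.
3. **Nine-point average.** The overlap is split into three equal
   contiguous thirds (lateral/center/medial; identity from scan side,
   the fibula side being lateral) and each third is sampled at the
   columns nearest its 25%, 50% and 75% positions. The per-leg value
   is the mean of the nine sampled gaps. Fixed relative positions make
   the rule deterministic and resolution-stable; a joint narrower than
   nine columns is rejected.
4. **Per-subject reduction.** mJSW = min over available legs; a single
   available leg stands alone.
5. **Normalization.** Raw pixel values are not comparable across pixel
   spacings. Within each resolution group, raw mJSW (px) is regressed
   on subject height (OLS); the scaling factor of group *g* is
   slope(reference)/slope(g), and the normalized value is
   raw × factor × reference spacing, a mm-equivalent. The slope-ratio
   form is this package's explicit choice: because the raw-px height
   slope of a group scales as 1/spacing, the ratio estimates
   spacing(g)/spacing(reference) without ever reading the spacing
   metadata, which is exactly the situation the height regression is
   meant to rescue. Groups with non-positive slopes cannot be scaled
   and are flagged invalid; a single-group model is the identity.

### Geometry validation design

The geometry suite renders 200 phantoms (100 subjects, both legs,
cycling the three spacings) from a cohort whose joint width is exactly
its height-linear component (4.0 mm + 0.06 mm/cm × height deviation),
with zero image noise. With no subject-level scatter around the height
line, normalization-factor estimation error is negligible at n ≈ 33
per group and the residual disagreement is pure discretization, well
inside the two-pixel-spacing acceptance band (observed maximum ≈ 0.1
mm). With realistic subject scatter (≈ 0.55 mm sd) the factor error at
this cohort size dominates — a small-sample limitation of
height-regression normalization, not of the geometry; at biobank scale
each resolution group has thousands of subjects and the factor error
vanishes as 1/√n.

## Synthetic cohort and traits

Covariates follow the reference imaging cohort: 50.2% male, age from a
truncated normal on [46, 81] solved to have mean 64 and sd 7.5 after
truncation, sex-specific height (176.2 ± 6.6 / 162.8 ± 6.2 cm) and BMI
(27.0 ± 3.9 / 26.0 ± 4.6), ~1% steroid and knee-trauma flags. Body-fat
percentage has no published moments in that table; defaults (25 ± 6% /
36 ± 7%) are typical for the age range.

Genotypes are hard-call dosages built from two haplotype draws of a
block-exchangeable Gaussian copula (block size 10, latent correlation
ρ = 0.8, MAF uniform on [0.05, 0.5]), thresholded at each SNP's MAF
quantile. Dosage correlation is attenuated relative to the latent ρ
(tests pin it against a Monte-Carlo oracle). Blocks sit 2 Mb apart
with 5 kb spacing inside, so the 250 kb clumping window and the
1000 kb LD-score window stay within one block, which makes locus
counts and LD scores analyzable.

The quantitative trait is y = g + e with g a polygenic score over
`m_causal` random causal SNPs standardized to sample variance exactly
h², and e standardized to 1 − h². Disease liability equals y; a true
case is liability above the upper-K normal quantile. The
health-record label keeps each true case with probability
`ehr_sensitivity` (default 1085/3016 ≈ 0.36, the ratio of record to
image-ascertained cases in the reference cohort) and, at the default
specificity of 1, adds no false positives — the record documents
under-diagnosis, not over-diagnosis; specificity is still exposed as
configuration. mJSW in mm is an affine map of liability (4.0 mm mean,
0.55 mm/sd, narrower = sicker) plus a 0.06 mm/cm height component.
Pain items are conditionally independent given case status with the
reference case/control rates (past-month 49.4%/27.2%, chronic
80.4%/70.6%, 0–10 rating means 3.33/2.58, drawn as Binomial(10, μ/10));
fracture-in-5-years comes from a logistic model in mJSW (−0.30 per
mm), height, sex, age and body fat with an intercept near 3%
prevalence.

## Association and downstream estimation

Per-SNP tests are covariate-adjusted (sex, age, BMI, height by
default): OLS with t-based two-sided p for quantitative traits, full
per-SNP logistic Newton/IRLS fits with Wald z for binary traits
(batched across SNPs; non-convergence or |β| > 12 is flagged and the
SNP excluded from locus counts). Wald tests throughout — the simplest
internally consistent choice. Underflowing p-values are floored at the
smallest positive double, never 0. Genomic inflation is
λ = median(χ²)/0.4549.

Clumping is the standard greedy algorithm: candidates with p ≤ 5×10⁻⁸
visited in ascending p (ties by position, then id); each index absorbs
unassigned SNPs with p ≤ 1×10⁻⁴ within 250 kb and r² ≥ 0.1, with r²
computed on dosages in the analysis sample, as clumping tools do.

LD scores sum r² over a 1000 kb window including the self term; kb
windows stand in for the usual 1 cM because the simulated map has no
genetic distances. Heritability is unweighted OLS of χ² on LD score
with a free intercept — E[χ²] = 1 + N·h²·l/M — and h² = slope·M/N,
with a 20-block delete-one jackknife SE. Genetic correlation regresses
z₁z₂ on l the same way (gencov = slope·M/√(N₁N₂), r̂g =
gencov/√(h²₁h²₂)); sample overlap moves only the free intercept.
Binary-trait heritability is reported on the observed scale only; no
liability-scale transformation is applied. Genetic correlation via
cross-trait LD score regression (rather than a GREML-style variance
component model) keeps the module self-contained and testable on
summary statistics.

An important desk-scale caveat established during validation: LD score
regression assumes polygenicity. With only a few hundred causal SNPs
among a few thousand, the per-draw exact-variance standardization of
the genetic value couples realized genetic variance to block-level
tagging and visibly attenuates the χ²-on-l slope (h² recovered ≈ 0.205
instead of 0.24). The recovery suites therefore simulate the
infinitesimal architecture (every SNP causal), under which the
estimator is unbiased here; the power-ordering suite keeps its sparse
20-causal architecture, where LDSC output is reported but should not
be trusted. The default experiment's per-phenotype h² estimates carry
the same caveat.

Polygenic scores are clumping + thresholding: one clump at the loosest
threshold, per-threshold retention of index SNPs at the seven
thresholds 1 … 1×10⁻⁶ (nested by construction), weights equal to GWAS
betas. Scores are z-scored in the hold-out sample and tested in a
covariate-adjusted logistic model; Bonferroni uses a fixed denominator
of 21 (3 phenotypes × 7 thresholds).

## Benchmark suites and problem sizes

Sizes were chosen for a single-CPU desk run:

- geometry: 200 phantoms over 3 spacings (pass band: 2 pixel spacings);
- null calibration: h² = 0, N = 2000, M = 5000 unlinked SNPs, averaged
  over 10 replicate draws because one draw's median-based λ carries
  ≈ 0.03 Monte-Carlo noise;
- h² recovery: 50 seeds at N = M = 5000, truth 0.24;
- rg recovery: 25 seeds at N = 5000, M = 2000, truth −0.9. The genetic
  covariance is normalized by the known simulated heritabilities: a
  single desk-scale seed's own h² estimate is noisy enough (sd ≈ 0.17
  at this M) that dividing by it makes the per-seed rg heavy-tailed,
  so estimated-h² normalization would test a ratio's tails rather
  than recovery of the correlation. Estimated-h² normalization is
  still exercised (and behaves) in the unit tests at the module level;
- power ordering: 25 seeds at N = 4000 + 2000 hold-out, M = 2000,
  20 causal SNPs, h² = 0.25, prevalence 0.10, record sensitivity 0.36.

At these sizes the expected behaviour follows liability-threshold
theory: thresholding at K = 0.10 multiplies per-SNP non-centrality by
z²/(K(1−K)) ≈ 0.34 (z the normal density at the threshold), and record
thinning cuts cases roughly threefold again, so genome-wide-significant
locus counts fall sharply at each step (observed means ≈ 9.6 / 3.5 /
0.6) while PRS transfer degrades more gently (≈ 7.0 / 6.8 / 4.5
significant thresholds).

## What the synthetic data does not emulate

No DXA physics (beam hardening, scatter, patient positioning), no
weight-bearing geometry or osteophytes, no segmentation error, no
real LD (block-exchangeable correlation only), no population
structure or relatedness (hence no principal-component covariates),
no genotype missingness, and no ascertainment bias in who gets imaged.
Passing tests therefore demonstrate the correctness and calibration
of the measurement and statistical machinery under known ground
truth — not performance on real radiographs or real genomes. The
reference cohort's headline empirical results (18 loci, h² = 0.24,
λ = 1.06) depend on its real images and genotypes and are not
reproducible here; printed-count arithmetic aside, the suites check
recovery of simulated truths and the qualitative power ordering, not
those numbers.

## Numerical and degenerate-input conventions

Dichotomization uses the k = ⌊target·n⌋ smallest value as cutoff and
includes ties (degenerate all-equal input becomes all cases, with the
realized fraction reported). Pearson chi-square is used without
continuity correction and the rating contrast is a Welch (unequal
variance) t-test — the plainest forms consistent with large-sample
statistics. Reported percentage increases are rounded to integers.
Perfect separation in logistic fits is flagged, not estimated. All
generators are pure functions of (config, seed); the experiment
expands one global seed into per-stage seeds through a counter scheme
so stages can be re-run independently.
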