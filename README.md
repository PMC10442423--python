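# oa-phenopower

Image-derived phenotyping of knee osteoarthritis (OA) and the
statistical power it buys, as a tested, desk-scale analysis pipeline
on fully synthetic data.

Knee OA is diagnosed radiographically, but biobank case/control labels
usually come from billing codes (ICD-10 M17) that miss most cases.
When a knee scan is available one can instead measure the **minimum
joint-space width (mJSW)** — the narrowest femur–tibia distance, a
quantitative severity endophenotype — or call radiographic
case/control status directly. This package implements, end to end:

- a **phantom generator** producing AP-view knee rasters + label masks
  (femur/tibia/fibula) with exactly known per-column joint gaps, plus
  generators for a covariate cohort, LD-blocked genotype dosages, and
  liability-threshold traits with health-record under-reporting;
- the **mJSW measurement pipeline**: padding/QC to 800×1000, exhaustive
  per-column gap profiles from masks, nine-point per-leg averaging
  (three sampled columns in each third of the joint), per-subject
  minimum over legs, and height-regression normalization across image
  resolutions;
- **case-ascertainment analytics**: a prevalence-targeted dichotomizer
  (the stand-in for an image classifier), inter-rater confusion tables
  as proportions of 100, sensitivity/specificity, record-vs-model case
  accounting, and pain/fracture association statistics;
- **genetic association**: covariate-adjusted per-SNP linear and
  logistic GWAS (batched Newton/IRLS), genomic inflation λ, greedy LD
  clumping (p₁ = 5×10⁻⁸, p₂ = 1×10⁻⁴, r² ≥ 0.1, 250 kb);
- **architecture estimation**: LD scores, LD-score-regression
  heritability (h² = slope·M/N from E[χ²] = 1 + N·h²·l/M, jackknife
  SEs), cross-trait genetic correlation, and clumping+thresholding
  polygenic scores evaluated on a hold-out with Bonferroni correction.

The scientific claim the pipeline reproduces in miniature: under a
liability-threshold model, dichotomizing a heritable quantitative
trait at prevalence K multiplies per-SNP non-centrality by
z²/(K(1−K)) (≈ 0.34 at K = 0.10), and record under-reporting thins
cases further — so the quantitative phenotype yields many times more
genome-wide-significant loci than either binary label, even though the
phenotypes are near-perfectly genetically correlated.

## Worked example

Numbered drivers under `analysis/` run each stage and write tables to
`results/`. The first recomputes the reference cohort's printed case
accounting (29,257 imaged participants, 1085 record cases, 3016
image-ascertained cases):

```text
$ python analysis/01_worked_examples.py
                quantity   computed   reported  match
         new_model_cases  1931.0000  1931.0000   True
       pct_case_increase   178.0000   178.0000   True
            ehr_controls 28172.0000 28172.0000   True
 implied_ehr_sensitivity     0.3600     0.3600   True
   model_case_prevalence     0.1031     0.1031   True
skeletal_single_gene_pct    57.0000    57.0000   True
```

The geometry driver renders 200 noiseless phantoms across three pixel
spacings and pushes them through the full measurement pipeline:

```text
$ python analysis/02_geometry_accuracy.py
phantoms measured: 200
max |normalized - truth|: 0.1107 mm
fraction within 2 pixel spacings: 1.000
```

i.e. every normalized mJSW lands within two pixel spacings of the
generator's ground truth; the residual ≈ 0.1 mm is pixel rounding.

The full experiment (N = 4000 + 2000 hold-out, M = 2000 SNPs,
20 causal, h² = 0.25, 10% prevalence, 36% record sensitivity) compares
the three phenotype definitions on one cohort:

```text
$ python analysis/03_case_ascertainment.py
model cases: 400, record cases: 153, new cases: 328 (+214%)
classifier stand-in vs latent truth: sensitivity 0.45, specificity 0.94
pain-month chi2 = 9.7 (case rate 0.360 vs control 0.285)
fracture ~ mJSW estimate -0.384 (p = 0.098)
{
  "loci_quantitative": 11,
  "loci_model_binary": 2,
  "loci_ehr_binary": 3
}
```

`analysis/04_gwas_power.py` repeats the comparison over 25 seeds
(mean loci ≈ 9.6 / 3.5 / 0.6 for quantitative / dichotomized /
record-thinned; mean Bonferroni-significant PRS thresholds ≈ 7.0 /
6.8 / 4.5), and `analysis/05_heritability_recovery.py` checks that LD
score regression recovers a simulated h² of 0.24 and a genetic
correlation of −0.9 within Monte-Carlo error, alongside null-GWAS
calibration (λ ≈ 1.00, type-I ≈ 0.05).

A `oa-phenopower` CLI exposes the stages individually
(`simulate phantoms|cohort|genotypes|traits`, `measure`, `phenotype`,
`gwas`, `clump`, `ldsc`, `prs`, `run`, `worked-examples`); see
`oa-phenopower --help`.

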