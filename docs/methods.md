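# Methods

## Model and estimators

The causal target is the effect of a 1 SD increase in serum iron
(6.1 μmol/L in the source GWAS population) on the log odds of each
phenotype. Identification rests on the usual instrumental-variable
assumptions: the SNPs associate with iron status, share no confounder
with the outcomes (plausible by Mendelian inheritance), and affect
outcomes only through iron status. The third assumption is the fragile
one; the pipeline's heterogeneity screen and weighted-median sensitivity
estimate both exist to probe it.

**Ratio estimate.** β_j = Γ_j/γ_j per instrument, where Γ_j is the
covariate-adjusted log-OR per effect allele from logistic PheWAS and γ_j
the SNP–serum-iron association in SD units. The SE uses the two-term
("second-order") delta expansion se_j² = σ_Γ²/γ² + Γ²σ_γ²/γ⁴ with zero
γ–Γ covariance — exact for two independent samples. The Monte-Carlo
check in the tests shows this SE tracks the empirical SD of the ratio to
well under 5% whenever the instrument is strong (|γ|/σ_γ > 10), which
all three iron instruments are by a wide margin.

**IVW pooling.** Fixed-effect, w_j = 1/se_j²; with only three
instruments a random-effects variance is not estimable with any
stability, and heterogeneity is instead screened explicitly via
Q = Σw_j(β_j − β_IVW)², df = 2, interpreting P < 0.05 as evidence of
pleiotropy. Significant-and-homogeneous outcomes form the "consistent"
list; significant-but-heterogeneous outcomes are reported separately and
not followed up.

**Weighted median.** Per-SNP ratios are ordered; normalized weights
define breakpoints s_j = Σ_{k≤j}w′_k − w′_j/2; the estimate linearly
interpolates the (s_j, β_(j)) step curve at 0.5 and clamps to the
extreme estimate when 0.5 falls outside [s_1, s_k]. It is consistent
when instruments carrying > 50% of the weight are valid. The SE is the
SD of the estimate over parametric bootstrap resamples in which *both*
Γ*_j ~ N(Γ_j, σ_Γj²) and γ*_j ~ N(γ_j, σ_γj²) are redrawn (n_boot = 1000
by default, seeded); redrawing only the numerators would understate the
uncertainty that the second-order weights deliberately keep.

**Multiplicity.** Benjamini–Hochberg step-up at q = 0.05 on the IVW
p-values across all analysed phecodes, applied before the heterogeneity
screen. BH rather than Benjamini–Yekutieli, although PheWAS outcomes are
correlated: with 19 discoveries among 904 phenotypes the realized
step-up threshold is (19/904)·0.05 ≈ 1.1×10⁻³, and BH's behaviour under
the positive dependence typical of nested diagnoses is well understood.
BY remains available as a flag. Reported p-values are floored at
10⁻³⁰⁰.

**CIs** use normal quantiles (±1.96·se) throughout; with three
instruments no t correction has a principled df anyway.

## PheWAS regression

Plain maximum-likelihood logistic regression (Newton, coefficient
tolerance 10⁻¹⁰, 100 iterations) of case status on additive dosage plus
age, sex, genotyping array, and 4 principal components, fitted on
cases ∪ controls with the exclusion-range carriers omitted. Firth
correction is available as an opt-in for rare-outcome separation but is
not the default — the scan mirrors standard PheWAS practice, and
separation or non-convergence produces a flagged failure record that
never aborts the phenome scan (phecodes lacking a converged estimate for
every instrument are dropped from MR and counted in the manifest). In
sex-stratified reruns the sex covariate is dropped and the minimum-case
filter is re-applied within the stratum.

## Phecode engine

ICD matching is exact on normalized codes (dots stripped, uppercase,
version-aware); no prefix truncation, because truncation rules differ
across map versions and silent fuzzy matching is worse than an unmapped
count. Unmapped and malformed codes are counted and logged, never fatal.
"Related phecodes" are operationalized as a shared exclusion root,
defaulting to the phecode's integer part; maps supplying explicit roots
are honored. The packaged map is a small hand-built synthetic dialect
for testing — real analyses should supply a published phecode map in the
same six-column shape. Relatedness pruning resolves pairs above kinship
0.0884 greedily in table order with a seeded coin flip; for the disjoint
pairs the generator emits, the retained count is seed-invariant.

## Synthetic cohort generator

The generator emulates exactly the structure the analysis assumes, which
is what makes passing tests informative and also bounds what they show:

- **Genotypes**: independent HWE draws, dosage ~ Binomial(2, EAF), for
  the three instruments (measured LD between them is negligible, and no
  LD is simulated).
- **Biomarkers**: serum iron is the genetic score plus Gaussian noise
  sized for unit marginal variance; instrument effects are calibrated so
  the three SNPs explain exactly 3.8% of its variance. Ferritin is
  generated directly on the log₁₀ scale. The other three biomarkers are
  fixed loadings on serum iron (+0.45 log-ferritin, −0.60 transferrin,
  +0.75 saturation) plus independent noise, unit-variance, reproducing
  the concordant sign pattern.
- **Disease**: per phecode, Bernoulli with
  logit = logit(prevalence) + θ·iron + Σ_j δ_j·dosage_j + 0.02·(age−55)
  + logit(sex_ratio)·female. θ is the causal effect, δ_j injects
  pleiotropy, and the modest age default keeps covariate adjustment
  exercised (overridable to zero). Cases emit one mapped ICD event;
  events carry no dates, since prevalent and incident cases are treated
  identically.
- **Kinship**: disjoint pairs with coefficients uniform on a configured
  range, above or below the pruning threshold as the scenario requires.

Not emulated: LD, population stratification beyond 4 null PCs,
diagnosis misclassification, non-normal biomarker tails, correlated
comorbid phecodes, dosage uncertainty (hard calls only — the regression
accepts fractional dosages regardless). Tests passing on this generator
therefore validate the estimators and the pipeline plumbing, not
robustness to those real-data features.

## Problem sizes and scenario defaults

The phenome-scale scenario uses 904 phecodes (10 causal at OR 0.72 per
SD iron, 4 single-SNP pleiotropic at OR 1.5, 890 null) on 50,000
individuals — a deliberately scaled-down cohort that keeps a full scan
in minutes on one CPU. At 1/8th of biobank scale, rare causal outcomes
are undetectable after FDR correction, so the non-null blocks are drawn
as common outcomes (prevalence 0.08, matching the fact that phenome-scan
discoveries at the original scale were common diagnoses with thousands
of cases); null prevalences are log-uniform on [0.008, 0.10]. Parameter
recovery and coverage are checked on single-phecode cohorts of 100,000;
null calibration on 500 phecodes of 20,000.

## Numerical and design notes

- One RNG stream per (seed, stage-name): cohorts are byte-identical
  under a fixed seed and each stage is independently reproducible; the
  weighted-median bootstrap seed is derived per (phecode, stratum).
- Harmonization aligns outcome to instrument effect alleles by exact
  unordered allele-pair match; incompatible pairs are a hard error — the
  three instruments are non-palindromic, so strand ambiguity indicates
  corrupted input, and guessing flips silently is how sign errors enter
  MR pipelines.
- The approximate-power column (normal approximation from case/control
  counts and instrument R² = 0.038) is advisory; the ≥200-case rule is
  the only gate.
- Degenerate inputs: γ = 0 is an undefined-ratio error; empty cohorts,
  unknown ids in kinship pairs, and phecodes without mapped codes are
  validation errors; an unreachable minimum-case threshold yields an
  empty, successful run with an explanatory manifest.

## Limitations

Three instruments give Cochran Q only 2 df, so the heterogeneity screen
has limited power against balanced pleiotropy, and the weighted median's
">50% valid weight" condition is untestable from data. The second-order
SE is itself an approximation whose quality degrades for weak
instruments. FDR control under arbitrary dependence is not guaranteed by
BH; the synthetic phenome generates independent outcomes, so the null
calibration results here do not certify behaviour under strong phenotype
correlation.
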