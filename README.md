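# mrphewas

Two-sample Mendelian randomization across the phenome (MR–PheWAS), built
around the genetics of systemic iron status. The package is for
epidemiologists and statistical geneticists who want to run — or study the
statistical behaviour of — a phenome-wide causal scan: from ICD-coded
hospital events and instrument SNP genotypes to FDR-controlled,
heterogeneity-screened causal effect estimates per phenotype. A seeded
synthetic cohort generator stands in for biobank-scale individual-level
data, so the entire chain is testable offline.

## The method

Three SNPs (rs1800562 and rs1799945 in *HFE*, rs855791 in *TMPRSS6*)
concordantly raise serum iron, ferritin, and transferrin saturation and
lower transferrin, and together explain about 3.8% of the variance in
serum iron — they instrument systemic iron status.

For each phecode (a clinical case grouping of ICD-9/10 codes), cases are
individuals with ≥1 mapped hospital event and controls those with no
record of the phecode or its exclusion-range relatives; one member of each
relative pair (kinship coefficient > 0.0884) is dropped, and phecodes with
fewer than 200 cases are not analysed. Logistic regression of case status
on allele dosage — adjusted for age, sex, genotyping array, and 4 principal
components — yields per-SNP log odds ratios Γ_j with standard errors σ_Γj.

With γ_j the SNP–serum-iron association in SD units (1 SD = 6.1 μmol/L),
the per-SNP causal estimate is the Wald ratio

    β_j = Γ_j / γ_j ,   se_j² = σ_Γj²/γ_j² + Γ_j²·σ_γj²/γ_j⁴

(second-order weights: the γ uncertainty is retained). Estimates are
pooled by fixed-effect inverse-variance weighting, β_IVW = Σw_jβ_j / Σw_j
with w_j = 1/se_j²; between-instrument heterogeneity — a pleiotropy
signature — is screened with Cochran's Q (P < 0.05); multiplicity across
the phenome is handled with Benjamini–Hochberg FDR at 5% on the IVW
p-values. A precision-weighted median estimate with parametric-bootstrap
SE provides a pleiotropy-robust sensitivity analysis, and consistent
outcomes are re-expressed per SD of log₁₀ ferritin, transferrin, and
transferrin saturation and re-estimated within each sex.

## Worked example

```bash
mrphewas simulate cohort --preset paper-like --n 10000 --n-phecodes 20 --seed 5
# wrote cohort: 10000 individuals, 20 phecodes, 12914 ICD events -> cohort
mrphewas run cohort results --seed 5 --min-cases 150 --n-boot 200
# analyzed 17 phecodes; 4 FDR-significant (realized threshold 0.0118),
# 3 with consistent evidence, 1 excluded for heterogeneity
```

The simulated phenome has 20 phecodes: mostly null, a causal block
(OR 0.72 per SD serum iron, the iron-deficiency-anemia effect size) and a
pleiotropic block (a direct SNP→outcome path bypassing iron). Three of the
20 fall below the 150-case floor at this cohort size, leaving 17 analysed.
Of the 4 outcomes passing the realized BH threshold (0.0118 = 4/17·0.05),
the one driven by pleiotropy is caught by Cochran's Q and excluded; the 3
survivors are true causal outcomes. `results/results.tsv` holds one row
per phecode (per-SNP ratios, IVW OR with 95% CI, Q, weighted median, FDR
and heterogeneity flags, advisory power), `results/scatter.tsv` the
(γ, Γ) pairs for scatter/forest plots, and `results/manifest.json` the
seed, thresholds, and participant/phecode counts at every stage.

The same analysis is available as a library (`generate_cohort`,
`run_full_pipeline`), and `mr_from_summary_tables` runs the MR stage
directly from per-SNP summary-statistic tables with no individual-level
data.

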