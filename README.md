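# phenolink

Phenotype integration for biobank genetic studies.

Biobanks measure a few phenotypes deeply (structured diagnostic
questionnaires, completed by a minority of participants) and many
phenotypes shallowly (single-item self-reports, available for nearly
everyone).  GWAS on the deep phenotype is underpowered; GWAS on a shallow
proxy is powerful but genetically nonspecific.  `phenolink` implements the
integration workflow that bridges the gap, with every stage testable on a
synthetic biobank with known ground truth:

1. **Imputation** — nuclear-norm matrix completion (SoftImpute) of the
   phenome `min ½‖P_Ω(X−Z)‖² + λ‖Z‖_*`, with the penalty tuned by
   *realistic* masking cross-validation (held-out entries copy real
   missingness patterns from donor samples).  Per-phenotype accuracy R² and
   the post-imputation effective sample size `n_eff = N_obs + N_miss·R²`.
2. **Association scans** — vectorized OLS and per-SNP Newton logistic
   regression with covariates; λ_GC; loci at p < 5×10⁻⁸; Cochran's Q /
   DerSimonian–Laird heterogeneity; genotype PCs.
3. **Latent factors** — variance explained, split-half prediction strength,
   and factor scores as covariates for conditioned scans that strip
   nonspecific signal from shallow-phenotype GWAS.
4. **LD score regression** — SNP heritability (`E[χ²] = 1 + n·h²·ℓ/M`),
   genetic correlation, liability-scale conversion
   `h²_liab = h²_obs·K²(1−K)²/(P(1−P)φ(t)²)`, case-control effective n
   `4/(1/n_cases + 1/n_controls)`.
5. **Multi-trait combination** — per-SNP GLS of several traits' summary
   statistics under a genetic covariance Ω and error covariance Σ estimated
   by cross-trait LDSC; power-equivalent sample size
   `n_effect = n_single·(χ²_mtag−1)/(χ²_single−1)`.
6. **Polygenic scores** — clumping + thresholding, incremental Nagelkerke /
   partial R², joint cross-validation of the whole imputation→GWAS→PRS
   chain, and the **PRS pleiotropy** specificity metric
   `R²_secondary / R²_target` with its excess over a deep-target baseline.

## Worked example

The numbered drivers under `analysis/` run the full study on the standard
synthetic biobank (10,000 individuals, 2,000 SNPs, a deep binary target
that is 80% block-missing, five shallow proxies, three latent factors):

```bash
python analysis/01_simulate.py --seed 1       # writes results/data/
python analysis/02_impute.py   --seed 1
python analysis/03_factors.py  --seed 1
python analysis/04_gwas.py
python analysis/05_heritability.py
python analysis/06_mtag.py
python analysis/07_prs_pleiotropy.py --seed 1
```

Step 02 prints (seed 1):

```
selected lambda 2.197 (rank 31)
target held-out R2 0.280; n_eff 4235 = 1996 observed + 8004 x R2 (gain x2.12)
```

The deep target is observed for 1,996 of 10,000 individuals; imputing it
from the phenome at held-out R² = 0.28 raises the power-equivalent sample
size to ~4,200 — a 2.1× gain.  Step 04 then shows the GWAS consequence
(the combined observed+imputed scan tests all 10,000 samples and finds at
least as many of the target's true loci as the observed-only scan), and
step 05 the genetic architecture:

```
    scan  h2_obs  h2_se  intercept
observed  0.2700 0.1202      0.370
imp_all   0.1769 0.0762     -0.968
rg(imputed, observed) = 1.033 (SE 0.112)
```

Scans on imputed values give *attenuated* heritability (imputed scores have
deflated variance) while their genetic correlation with the observed target
is statistically indistinguishable from 1: imputation preserves the
trait's genetic identity.  Step 07 quantifies the power/specificity
trade-off of the resulting polygenic scores:

```
  method  mean_r2  ci_lo  ci_hi
observed   0.0904 0.0695 0.1113
 imp_all   0.1311 0.1110 0.1512
    mtag   0.1123 0.0824 0.1422

  score  mean_pleiotropy
   deep           0.0217
imputed           0.0596
shallow           0.2677
```

The imputation-based PRS predicts the held-out target better than the
observed-only PRS (0.131 vs 0.090 Nagelkerke R², 5-fold CV with imputation
re-run inside each training fold), and its pleiotropy spectrum stays close
to the deep target's — an order of magnitude more specific than the
shallow-proxy PRS (mean pleiotropy 0.06 vs 0.27).

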