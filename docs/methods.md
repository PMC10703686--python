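# Methods

`phenolink` implements a phenotype-integration workflow for biobank genetic
studies: a deep, expensively measured phenotype (a questionnaire-derived
diagnosis, say) is observed for only a fraction of the cohort, while dozens
to hundreds of correlated shallow phenotypes are observed for almost
everyone.  The package imputes the deep phenotype from the phenome, runs
association scans on observed and imputed values, characterizes the genetic
architecture of the results, combines summary statistics across traits, and
quantifies the power and the disorder-specificity of the resulting polygenic
scores.  Everything is exercised end-to-end on a synthetic biobank with
known ground truth.

## The synthetic biobank (`phenolink.simulate`)

**Genotypes.**  SNPs come in LD blocks (default 20 SNPs, 2 Mb apart, 1 kb
spacing within a block).  Each block shares one allele frequency drawn
uniformly from `maf_range` (default (0.05, 0.5]); haplotypes follow a
copying Markov chain along the block — the allele at SNP *j* copies SNP
*j−1* with probability `ld_decay` (default 0.9) and is otherwise redrawn
fresh — and the dosage is the sum of two independent haplotypes.  This
yields Hardy–Weinberg genotypes whose dosage autocorrelation is exactly
`ld_decay ** lag`, so the LD score of an interior SNP has the closed form
`1 + 2 * sum_d rho^(2d)`.  A latent-Gaussian-threshold construction was
considered and rejected: thresholding attenuates the dosage correlation
well below the nominal AR(1) parameter (at rho = 0.9 and MAF 0.25 the
indicator correlation is ≈ 0.8), which would make the generator's nominal
LD parameter a lie to every downstream consumer (clumping, LD scores).

**Phenotypes.**  Each liability is a sum of variance-1 components, each
rescaled *exactly* in-sample (removing Monte-Carlo slack from recovery
tests):

    L_p = g_p(lead) + g_p(tail) + sum_k lambda_pk F_k + w_p L_target + e_p

* `g_p(lead)`: a handful of large-effect causal SNPs (`n_causal`, variance
  `h2_targets[p]`).  Lead sets of different traits/factors are disjoint.
* `g_p(tail)`: a polygenic background (`n_poly` = 300 SNPs by default,
  variance `h2_poly[p]`).  A purely sparse architecture (~10 causal SNPs)
  makes LD score regression degenerate — the chi-square–on–LD-score
  regression has no stable slope — while a purely polygenic one gives no
  genome-wide-significant loci at desk-scale n.  The two-tier architecture
  supports both kinds of analysis, mirroring real complex traits (a few
  mapped loci atop a polygenic background).
* `F_k`: latent factors, optionally heritable through their own lead+tail
  SNPs.  Factors model the nonspecific axes of the phenome (help-seeking,
  SES, ...).
* `w_p L_target`: shallow proxies mix the deep target's liability with a
  nonspecific factor — the construction that generates the specificity
  contrast between deep and shallow measures.

Binary traits threshold the liability at its empirical `1−K` quantile, so
the case fraction equals the prevalence.  Block missingness removes whole
questionnaire blocks per sampled individual (all-or-none); an optional
logistic dependence on a covariate is available but defaults to block-MCAR,
since the real missingness mechanism is not characterized.

**Standard study conditions** (`biobank_config`): 10,000 samples x 2,000
SNPs; a deep binary target (prevalence 0.25; lead h² 0.15 over 3 SNPs +
0.10 polygenic; loadings 0.35/0.20 on two heritable factors) in an
80%-missing block with four symptom items; five fully observed proxies with
target-mixture weights ≈ 0.5; 21 background columns on three factors
(the third purely environmental).  Lead-SNP counts and shares follow a
design-time power calculation: per-lead association chi-square ≈ 40–90 at
these sample sizes, so lead loci are detectable at 5e-8 but not trivially
so.  `TruthSet.achievable_r2` is the in-sample OLS R² of each phenotype on
the phenotypes that can co-occur with it when it is missing (columns in a
shared missing block are excluded — they are never available for the rows
that need imputing).

**What the generator does not emulate:** realistic MAF spectra and
million-SNP scale, fine-scale LD (blocks are independent), assortative
mating and population structure in the phenome, informative (MNAR)
missingness by default, and measurement error that differs by phenotype
type.  Passing tests therefore show that the machinery is correct under
its stated model, not that biobank-scale effect sizes are reproduced.

## Imputation (`phenolink.impute`)

The model is nuclear-norm-penalized matrix completion over observed entries
of the column-standardized phenome (binary 0/1 columns standardized like
quantitative ones and imputed as continuous scores):

    minimize 0.5 * || P_obs(X − Z) ||_F^2 + lambda * ||Z||_*

The solver iterates fill-with-current-fit → SVD → soft-threshold.  Each
step is an exact proximal minimization of the majorizing surrogate, so the
penalized objective is monotone nonincreasing (asserted); at the column
counts used here (p ≤ ~50) full SVDs are trivial and the alternating-ridge
factored variant of the same objective offers no advantage.  Defaults:
`max_rank` 50, relative-objective tolerance 1e-5, 500 iterations, warm
starts along the penalty path.

**Realistic masking CV.**  Random test rows receive the union of their own
missingness pattern and a random donor row's pattern; entries observed in
the test row but missing in the donor are held out.  Held-out entries thus
follow the cohort's actual per-column missingness profile, unlike
entry-wise MCAR masking.  One masking round per penalty; 10% of samples as
test rows by default.

**Penalty selection** maximizes the mean *predictive* R² (1 − SSE/SStot)
over phenotypes; ties prefer the smallest penalty.  Predictive R² can be
negative, so overfitting a pure-noise phenome loses to the rank-0 fit —
squared-correlation R² (reported in `AccuracyReport`, as is conventional)
has a chance-level floor ~1/n_heldout and cannot make that distinction.
The per-phenotype accuracy is the squared Pearson correlation between
predictions and held-out truth, and the post-imputation effective sample
size is `n_eff = n_obs + n_miss * R²`.

`impute_values` assembles either ImpAll (observed entries verbatim, missing
entries predicted — observed entries are never altered) or ImpOnly
(predictions restricted to samples missing the target).

## Factors (`phenolink.factors`)

Variance explained per factor is `d_i² / ||X_obs||²` of the standardized
observed matrix.  Prediction strength splits samples 50/50, refits the
completion model per half, greedily matches factors by absolute correlation
of their column-loading vectors (loadings are the object shared across
halves; per-sample scores are not comparable across disjoint halves), and
reports the squared correlation of matched loadings, invariant to sign
flips.  No Procrustes rotation is applied: factors of equal variance are
identified only up to rotation, and the diagnostics report that honestly.
Factor scores `U·d` serve as covariates for conditioned scans.

## Association scans (`phenolink.assoc`)

Linear scans use Frisch–Waugh–Lovell residualization (project phenotype and
dosages off the covariates once; run the per-SNP simple regressions
vectorized), numerically identical to per-SNP OLS.  Logistic scans run
per-SNP Newton/IRLS warm-started at the covariates-only fit; separated or
non-convergent SNPs are flagged and excluded from loci.  P-values are
two-sided Wald (chi-square(1) on `(beta/se)²`) throughout.  Genomic
inflation is `median(chi²)/0.45494`.  Loci merge genome-wide-significant
SNPs (p < 5e-8) within ±500 kb greedily; lead SNP is the smallest p, ties
to smaller bp.  Heterogeneity meta-analysis uses inverse-variance fixed
effects, Cochran's Q with chi-square(k−1) p, and a DerSimonian–Laird
random-effects estimate.  Genotype PCs come from a seeded randomized SVD of
standardized dosages.  Scans on imputed values use linear regression even
for binary targets (the imputed values are continuous scores); observed
binary scans use logistic regression.

## LD score regression (`phenolink.ldsc`)

LD scores: `l2_j = sum_k [r²_jk − (1 − r²_jk)/(n_ref − 2)]` within a 1 Mb
window (including self).  Heritability: weighted regression of per-SNP
chi-square on `n·l2/M` with a free intercept; weights `1/max(l2, 1)`
(single pass — close to the reference behavior without full iterative
reweighting); standard errors by a 200-block delete-one jackknife.
Genetic correlation: slope of `z_a z_b` on `sqrt(n_a n_b)·l2/M`, normalized
by the two h² estimates, with the entire ratio jackknifed; |r_g| > 1.25 is
flagged as degenerate.  Liability conversion uses the standard
observed→liability formula with ascertainment,
`h²_liab = h²_obs · K²(1−K)² / (P(1−P)·phi(t)²)`; it is applied only to
genuinely binary scans — imputed continuous versions of binary traits are
treated as quantitative, since no principled prevalence exists for a
continuous score.  The case-control effective sample size is
`4/(1/n_cases + 1/n_controls)`.

## Multi-trait combination (`phenolink.mtag`)

Per SNP, trait effects (converted to the standardized scale via `z/sqrt(n)`)
are combined by GLS under a homogeneous genetic-covariance model: Omega
(traits x traits, per-SNP scale; diagonal `h²/M`) from single- and
cross-trait LD score regression slopes, Sigma (error covariance) from the
intercepts, both PSD-projected; the estimator for trait t is

    beta_t = gamma' A⁻¹ b / (gamma' A⁻¹ gamma),   gamma = Omega[:,t]/Omega[t,t],
    A = Omega − Omega[:,t]Omega[t,:]/Omega[t,t] + Sigma_j

A single input, or a diagonal Omega, returns the inputs unchanged.  A
"known-Omega/Sigma" injection path exists for exact tests.  The adjusted
statistics carry the GLS-precision effective sample size (`1/SE²` on the
standardized scale) in their N column — the sample-size entry downstream
LD score regression should use; the *power-equivalent* sample size
`n_single·(chi²_mtag − 1)/(chi²_single − 1)` over shared SNPs is a separate
reporting metric (it is defined to absorb the chi-square gain, so feeding
it to LDSC would cancel the very h² inflation the combination produces).
More than 10 input scans triggers a warning (combining many traits is known
to admit nonspecific false positives).  Outputs are on the
standardized-genotype scale; all downstream consumers (LDSC, clumping,
scoring, loci) are scale-free.

## Polygenic scores and specificity (`phenolink.prs`)

Clumping is greedy by ascending p (ties to smaller bp): a SNP is dropped if
within 250 kb of a retained SNP with dosage r² ≥ 0.1.  Scores sum aligned
weights x dosages over SNPs passing the p-threshold, chosen from
{5e-8, …, 1} to maximize *training* accuracy.  Accuracy is incremental over
a covariates-only model: Nagelkerke's pseudo-R² for binary phenotypes,
partial R² (1 − RSS_full/RSS_cov) for quantitative ones — the incremental
form isolates the score's contribution.

`crossval_pipeline` jointly cross-validates the entire chain: inside each
training fold it re-runs imputation (with its own penalty selection),
secondary-trait GWASs and the GLS combination for MTAG presets, clumping,
and threshold selection; the held-out 10% only ever sees the frozen score.
Fold LD for clumping comes from the genotype panel (genotypes are not
phenotype information).  The cross-fold CI is `mean ± 1.96·sd/sqrt(folds)`.
MTAG-preset input GWASs inside the CV use linear scans on observed values
(including binary ones); at these sample sizes the linear and logistic
z-scores are nearly identical and the linear scans are an order of
magnitude faster.

PRS pleiotropy for a score is `R²_secondary / R²_target` per secondary
phenotype (type-appropriate incremental metric, significance of the score
term at 0.05/m); excess pleiotropy subtracts a baseline spectrum
(conventionally the observed-deep-target score's).

## Numerical and procedural choices

* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical configs give bit-identical
  outputs.
* Monomorphic SNPs, perfect separation, exact fits, unalignable alleles,
  all-missing columns: flagged and excluded rather than guessed at.
* Allele alignment: effects flip sign when (A1, A2) are swapped; records
  matching neither orientation are dropped and logged.
* SNP filters: MAF > 0.05 enforced by the generator's frequency range; an
  INFO column, when present in summary-stats input, is a pass-through
  filter at 0.9.
* Test problem sizes: the biobank properties run at 10,000 x 2,000 over 10
  seeds (5 seeds for the joint-CV scoring study, with majority thresholds
  kept at the same per-seed rates); the LD score recovery study runs at
  5,000 x 20,000 over 10 trait draws on one shared panel.  The null
  calibration of the imputed-vs-observed genomic inflation is asserted on
  the mean over seeds (per-run "never exceeds" statements are not
  statistically meaningful for a median-based statistic at M = 2,000).

## Known limitations

* The completion model treats binary traits linearly; imputed scores are
  deflated in variance and their pairwise correlations are inflated
  relative to observed values (demonstrated in the tests).  The ImpAll
  concatenation of 0/1 observed values with deflated continuous predictions
  structurally attenuates per-SNP effects, so its h² sits below the
  observed scan's liability-scale h².  Pure imputed-value (ImpOnly) scans
  need *not* be attenuated: when the phenome's shared variance is largely
  heritable — as in this generator, where proxies mix the target liability
  with a 40%-heritable factor — the imputed composite is a denoised,
  genetically *enriched* phenotype whose h² can exceed the observed
  trait's.  Attenuation of ImpOnly h² requires substantial non-heritable
  shared variance among the predictors (demographics, socioeconomic items),
  which real questionnaire phenomes have and this generator deliberately
  keeps minimal.  The genetic correlation with the observed trait stays ~1
  either way.
* Under these study conditions, the summary-statistic GLS combination's
  held-out PRS accuracy lands between the observed-only and the
  imputation-based scores (a weak deep-target scan borrowing from strong
  nonspecific proxies inherits their specific signal); individual-level
  imputation uses strictly more information and wins.
* Factor-conditioned scans can remove shared (truly pleiotropic) signal
  along with nonspecific signal, and conditioning on heritable covariates
  can in principle introduce collider effects; the package observes, and
  does not correct, this behavior.
* Omega/Sigma estimation quality degrades at small SNP counts or extreme
  per-SNP signal: LDSC intercept noise at M = 20,000 enters Sigma with
  roughly threefold leverage on the effective-n ratio, so single-run
  ratios scatter widely around the closed-form doubling even though the
  GLS combination itself is exact given its inputs.
* The liability-scale conversion for continuous imputed versions of binary
  traits is undefined and deliberately not attempted.
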