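# Methods

This note documents the statistical machinery implemented in `mlearner`,
the assumptions behind it, the synthetic-data generator, and the numerical
and design choices that were genuinely open.

## 1. The polygenic G×T model and its causal identities

For outcome Y, standardized genotypes G and randomization probability
p = P(T = 1), the treatment indicator is coded T<sup>std</sup> ∈
{√((1−p)/p), −√(p/(1−p))} so that it has mean 0 and variance 1 when the
treated fraction equals p. Under the linear G×T model the CATE is
A + C·S with C = √((1−p)/p) + √(p/(1−p)) = 1/√(p(1−p)) and
S = Σ G<sub>j</sub>β<sub>Ij</sub> the polygenic efficacy score (PES).
`mlearner.causal` implements these identities plus the inverse-propensity
pseudo-outcome Y<sup>H</sup> = TY/e − (1−T)Y/(1−e), which satisfies
E[Y<sup>H</sup> | G] = CATE(G) whenever e is the true assignment
probability. We take e as the trial's known design probability; positivity
is enforced with a hard error outside [10⁻³, 1−10⁻³] rather than by
winsorizing — in an RCT an extreme propensity indicates user error, not a
data feature. No covariate-adjusted propensity model is provided: the
setting is randomized treatment with known e.

## 2. Individual-level pipeline

1. **Sequential cross-fitting.** Individuals are randomly partitioned into
   K ordered folds (default K = 5, balanced sizes); for k = 2..K a learner
   is fitted on (PRS, Y<sup>H</sup>) of folds 1..k−1 and predicts the CATE
   on fold k. Fold 1 receives no prediction and is excluded from all
   downstream inference. Registered learners: penalized linear (ridge with
   generalized cross-validation over the penalty), RBF support-vector
   regression, random forest, multilayer perceptron, and an intercept-only
   reference model. Hyperparameters are always selected inside the
   training folds (RidgeCV / 3-fold grid search), preserving the
   out-of-sample contract.
2. **Best linear projection.** OLS of Y<sup>H</sup> on the out-of-fold
   predictions with heteroskedasticity-robust (HC3) standard errors and a
   two-sided normal reference for the slope. HC3 was chosen because
   pseudo-outcomes are heavy-tailed (their variance is inflated by the
   1/e(1−e) factor). If the prediction variance falls below 10⁻¹², the
   test is declared degenerate with p = 1: constant predictions carry no
   heterogeneity information.
3. **Subgroup ATEs.** Predicted individuals are sorted by predicted CATE
   (ties broken by stable order on individual id, for determinism) and cut
   into q near-equal bins; each bin gets a difference-in-means ATE with
   the unpooled (Welch) standard error, a normal CI and a two-sided p.
4. **PRS importance.** For each PRS, the absolute t-statistic of its slope
   in a single-variable regression of the predicted CATE; zero-variance
   features (or degenerate predictions) get importance 0.
5. **Multiple learners.** Every learner's global p is reported; the
   headline combined p is Bonferroni across learners. Reporting only the
   best learner's p without correction would overstate significance, so
   the report carries an explicit note to that effect.

All randomness (fold partition, learner seeds) derives from one user seed
through a `SeedSequence` splitter, so runs are bit-reproducible.

**Finite-sample behaviour under the null.** The BLP test alone is well
calibrated (rejection ≈ 0.048 at the 5% level with independent
predictions, n = 800, 2000 replicates). The full sequential pipeline shows
a mild upward drift (≈ 0.065–0.072 over 500 null replicates at n = 1000)
because predictions on fold k are functions of the pseudo-outcomes of
earlier folds, which also appear as responses in the pooled BLP; this
residual dependence is inherent to pooling sequentially cross-fitted folds
and stays within three binomial standard errors of the nominal level at
the sizes tested.

## 3. Summary-statistic pipeline

For each candidate trait, GWAS marginal z-scores (or explicit scoring-file
weights) weight the GWIS interaction z-scores after allele harmonization:

  z = Σ w<sub>j</sub>Z<sub>Ij</sub> / √(Σ w<sub>j</sub>²),

standard normal under the null for LD-independent variants. Supplying an
LD-pruned panel is the caller's responsibility (documented precondition);
no LD-aware weighting is implemented, and the weight source is pluggable
precisely so a shrunk or LD-adjusted weight vector can be substituted.
Per-trait p-values are combined with the Cauchy combination test,
T = mean(tan((½ − p<sub>k</sub>)π)), p = ½ − arctan(T)/π, which equals the
standard-Cauchy upper tail of T and tolerates dependence among the
per-trait tests. Inputs are clipped to [10⁻¹⁵, 1−10⁻¹⁵] before the tangent
transform, which diverges at 0 and 1. The ranked trait list is the
ascending order of per-trait p-values; Bonferroni-adjusted per-trait
columns are included for follow-up of individual traits.

Harmonization drops strand-ambiguous palindromic variants (A/T, C/G) by
default — frequency-based strand resolution is deliberately out of scope —
and flips the z sign when effect/other alleles are swapped; allele pairs
that neither match nor swap are dropped and counted.

## 4. Power scaling laws

`mlearner.power` evaluates the expected PES×T interaction coefficient
E[α<sub>I</sub>] = Cov(S, Ŝ)/Var(Ŝ) under a random-effects polygenic model
for three estimation strategies (within-trial GWIS, single pre-trained
outcome PRS, best linear combination of K PRS — a quadratic form in the
trait covariance blocks), and the corresponding noncentrality
λ = √N<sub>test</sub>·Cov(S, Ŝ)/√Var(Ŝ) with unit outcome variance, giving
two-sided power 1 − Φ(z<sub>1−α/2</sub> − λ) + Φ(−z<sub>1−α/2</sub> − λ).
The `transfer_rho` curve parameterizes the estimated PES only through its
correlation ρ with the truth: λ = √(N·ρ²·σ²<sub>I</sub>). These are
normal-approximation formulas (no finite-sample t correction). The λ
expressions were validated against a matched Monte Carlo regression study
(agreement within 10% at n = 2500, 500 replicates) rather than taken on
faith, and Cov(S, PRS₁) is read as the product of the correlation and the
two standard deviations, r·√(σ²<sub>I</sub>σ²<sub>G</sub>).

## 5. Synthetic-data generator

One simulated trial draws:

* **Trait panel.** 1 + 25 traits (outcome baseline first). True scores are
  multivariate normal with a single-factor correlation target: loadings
  equally spaced in [−√0.8, √0.8] with the lower endpoint duplicated, so
  pairwise correlations a<sub>k</sub>a<sub>l</sub> span [−0.8, 0.8]
  exactly and the matrix is positive definite by construction. (An
  alternative — assigning an equally spaced sequence directly to the
  off-diagonals and projecting to the nearest correlation matrix — was
  implemented and rejected: the projection displaces individual entries by
  up to 1.2 and the realized correlations fail to span the intended
  range.) Including the outcome trait in the correlated panel is what
  makes a single outcome-PRS analysis partially informative about a linear
  PES, the behaviour expected of real trait panels.
* **Estimated PRS.** True score plus independent noise of variance
  M<sub>e</sub>/N<sub>GWAS</sub> (default 60,000/200,000 = 0.3), then
  re-standardized; corr(true, estimated) ≈ 1/√1.3 ≈ 0.877. Per-trait
  heritability draws ~N(0.5, 0.05) are carried as panel metadata. The
  estimated scores are produced by direct noise injection rather than by
  simulating the 200,000-person GWAS itself; under the random-effects
  model the two are equivalent in distribution for every quantity used
  downstream.
* **PES.** Linear: S ∝ 0.1·baseline + Σα<sub>k</sub>PRS<sub>k</sub> with
  weights equally spaced in [−0.6, 0.6]. Nonlinear: a fixed transform with
  strong linear, product, trigonometric, exponential, cubic and quadratic
  terms; the logarithmic term uses log(|PRS₇|+1) since log(PRS₇+1) is
  undefined for scores below −1. In both cases S is rescaled so its sample
  variance is exactly var_pes = 0.1 — i.e. the G×T component contributes
  exactly 10% of outcome variance, parallel to the baseline score's 10%.
* **Outcome.** Y = baseline + S·T<sup>std</sup> + 0.01·T<sup>std</sup> + ε
  with T ~ Bernoulli(0.5) and Gaussian ε absorbing the remaining variance
  so Var(Y) = 1. The null scenario sets S ≡ 0 and returns the noise share
  to ε. True S and true CATE are attached to every dataset for oracle
  checks and are never read by estimators.
* **Genotypes** (optional; needed only by SNP-level methods). Dosages ~
  Binomial(2, MAF), MAF ~ U(0.05, 0.5), at a desk-scale default of 2,000
  SNPs; per-SNP effects are drawn jointly across traits (rows ~
  MVN(0, Σ/J)) so the scores are genuine functions of the genotypes and
  SNP-level baselines see the same signal. Per-SNP heritability rescales
  automatically through the 1/J effect variance.

What the generator does **not** emulate: linkage disequilibrium, realistic
allele-frequency spectra, imputation error, population structure, or
non-Gaussian outcomes. Passing tests therefore demonstrate the estimators'
statistical properties under a clean polygenic architecture, not
robustness to the full messiness of real cohort data; QC fields
(info/missingness/HWE) exist only to exercise the variant filters.

Replicate r of any Monte Carlo study uses seed base + r; comparison tables
record the base seed.

## 6. Comparison baselines

All baselines consume the same `TrialDataset`. The within-trial GWIS PES
and the two-score prognostic/predictive model estimate per-SNP effects by
batched per-SNP OLS of Y on {1, G, T, G×T} on disjoint, seeded splits
(default: half for training; for the two-score model a quarter of the
training half is carved out as the tuning holdout). For the two-score
model the tuning grid selects top-|z| SNP subsets (keep fractions 1.0 to
0.05) for each weight vector, maximizing on the holdout the correlation of
the prognostic score with the outcome and of the predictive score with the
pseudo-outcome. A multiplicative shrinkage grid was considered and
discarded: rescaling a whole weight vector leaves the final interaction
test invariant, so it cannot tune anything. The SNP-level learner variant
is literally the PRS pipeline with standardized dosages as features —
verified bit-identical on shared features.

## 7. Numerical conventions and edge cases

* Standardization uses the analysis sample's own mean and population SD
  (ddof = 0), making variance contracts exact; near-constant vectors
  (SD < 10⁻¹²) raise rather than return inf.
* Dosage matrices are individuals × variants; dosages count scoring
  effect-allele copies; residual missing dosages are mean-imputed per
  variant (and logged) before scoring — high-missingness variants should
  already have been removed by QC.
* PRS columns of a trial are standardized in-sample at construction;
  summary-statistic p-values satisfy p = two-sided normal tail of z by
  construction.
* Variant QC thresholds default to info > 0.9, MAF ≥ 0.05, missing rate
  ≤ 0.01, HWE p ≥ 10⁻⁶; records lacking a QC field fail that filter
  unless explicitly run in permissive mode.
* Subgroup binning breaks ties by stable sort on individual id; fold
  partitions put remainder individuals in the earlier folds.

## 8. Problem sizes used in the shipped studies

The shipped Monte Carlo studies run at deliberately modest sizes chosen to
make the full suite convenient on a single CPU while keeping every check
statistically decisive: 500 replicates for calibration/uniformity studies
(binomial SE ≈ 0.01 at the 5% level), 100–200 replicates for power-ordering
and monotonicity patterns, trials of 400–3,000 individuals, and a
2,000-SNP genotype panel for SNP-level methods. The summary-statistic null
study uses 150 variants, enough that the residual dependence among
per-trait statistics (which share one GWIS z-vector and decays as 1/√J) no
longer distorts the combined p-value distribution.

## 9. Known limitations

* The summary-statistic interaction test assumes LD-independent variants;
  no LD-score-style correction is attempted.
* The sequential pipeline's pooled BLP inherits mild cross-fold dependence
  (Section 2); at small n this drifts the type-I error a few hundredths
  above nominal while remaining within Monte Carlo bands.
* PRS weight training, LD clumping and reference-panel imputation are out
  of scope; scoring files are consumed as given.
* The two-score baseline implements the final two-score interaction model
  with a simple selection-threshold tuner, not any published penalized
  estimator of the prognostic/predictive decomposition.
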