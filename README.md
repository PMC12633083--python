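# mlearner

Detection and characterization of **genetically driven heterogeneous
treatment effects (HTE)** in randomized controlled trials, using causal
transfer learning on panels of pre-trained polygenic risk scores (PRS).

## Who this is for

Statistical geneticists and trial biostatisticians who have (a) a completed
RCT with genotyped participants, or (b) only summary statistics from a
genome-wide SNP-by-treatment interaction study (GWIS), and want to know
whether — and through which genetic liabilities — treatment response varies
across patients.

## The model

Under a polygenic gene-by-treatment (G×T) model with standardized genotypes
G<sub>ij</sub> and a standardized treatment indicator
T<sub>i</sub> ∈ {√((1−p)/p), −√(p/(1−p))},

> Y<sub>i</sub> = Σ<sub>j</sub> G<sub>ij</sub>β<sub>Gj</sub> + T<sub>i</sub>β<sub>T</sub> + Σ<sub>j</sub> G<sub>ij</sub>T<sub>i</sub>β<sub>Ij</sub> + ε<sub>i</sub>,

the conditional average treatment effect (CATE) is linear in the
**polygenic efficacy score** S<sub>i</sub> = Σ<sub>j</sub> G<sub>ij</sub>β<sub>Ij</sub>:

> CATE<sub>i</sub> = A + C·S<sub>i</sub>, C = 1/√(p(1−p)).

Estimating the per-SNP interaction weights β<sub>Ij</sub> inside a small
trial is hopeless (the scaling laws in `mlearner.power` quantify exactly how
hopeless), so the package instead *transfers*: it compresses genome-wide
variation into K pre-trained PRS and learns the CATE as a function of those.

Two entry points:

* **Individual-level pipeline** (`mlearner.individual`): inverse-propensity
  pseudo-outcomes Y<sup>H</sup> = TY/e − (1−T)Y/(1−e) (whose conditional
  mean given G is the CATE) are regressed on PRS features by *sequential
  cross-fitting* — the model predicting fold k is trained only on folds
  1..k−1, so every prediction is strictly out-of-sample. Heterogeneity is
  tested by the **best linear projection** (BLP) of Y<sup>H</sup> on the
  predicted CATE (slope = 1 means calibrated predictions, slope = 0 means
  noise); subgroup ATEs by predicted-CATE quantiles and per-PRS importance
  scores (|t| from single-variable regressions) characterize the signal.
* **Summary-statistic pipeline** (`mlearner.summary`): per-trait
  PRS-by-treatment interaction z-scores computed from harmonized GWIS +
  GWAS z-scores, aggregated across the trait panel with the **Cauchy
  combination test** (robust to dependence) and ranked.

Supporting modules: file I/O, allele harmonization, variant QC and PRS
scoring (`mlearner.data`); the causal identities (`mlearner.causal`);
closed-form power scaling laws (`mlearner.power`); a synthetic RCT
generator with polygenic architecture (`mlearner.simulate`); and the four
standard comparison baselines (`mlearner.baselines`).

## Worked example

```python
import mlearner as ml

# a simulated 2000-person trial with a linear polygenic efficacy score
cfg = ml.SimConfig(n_rct=2000, pes_mode="linear")
data = ml.simulate_trial(cfg, seed=11)

report = ml.run_mlearner_i(data, ml.LearnerSpec("linear"), K=5, q=4, seed=11)
blp = report.per_learner["linear"]["blp"]
print(f"global p: {report.p_combined:.3g}")
print(f"BLP slope: {blp.beta_hat:.3f} (SE {blp.se_beta:.3f})")
print(report.per_learner["linear"]["subgroup"].table[["bin", "n", "ate", "se"]])
```

prints

```
global p: 9.46e-41
BLP slope: 1.102 (SE 0.082)
 bin   n    ate    se
   1 400 -0.672 0.092
   2 400 -0.253 0.093
   3 400  0.188 0.089
   4 400  0.931 0.095
```

The global p-value rejects the null of no genetically driven HTE; the BLP
slope near 1 says the cross-fitted CATE predictions are well calibrated;
and the quantile subgroups show treatment effects ranging from clearly
harmful (ATE −0.67 in the bottom quartile of predicted response) to
clearly beneficial (+0.93 in the top quartile) — the actionable output for
stratified treatment decisions. The importance table ranks the PRS driving
the heterogeneity (here PRS25/PRS01/PRS24, the traits given the largest
generative weights).

The analytic power of the downstream PES×T interaction test, at test size
2,500, G×T-explained variance 3% and true-vs-estimated-PES correlation
0.5:

```python
lam = ml.noncentrality("transfer_rho",
                       ml.PowerParams(N_test=2500, sigma2_I=0.03, rho=0.5))
ml.power_two_sided(lam, 0.05)   # 0.9911
```

A command-line interface mirrors the library:
`mlearner simulate|fit-i|fit-s|power|baselines|compare --help`.

## Documentation

`docs/methods.md` describes the statistical model, the synthetic-data
generator and its deliberate simplifications, all numerical choices and
known limitations.
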