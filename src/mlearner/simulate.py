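"""Synthetic RCT generator with polygenic architecture.

The generative model for one trial of n individuals:

    Y_i = PRS_i^baseline + S_i * T_i^std + 0.01 * T_i^std + eps_i,  Var(Y) = 1

where T ~ Bernoulli(p) is standardized to mean 0 / variance 1, the baseline
polygenic score contributes 10% of outcome variance, the polygenic efficacy
score S contributes 10% through its interaction with treatment (linear or
nonlinear in a panel of 25 correlated auxiliary PRS, or identically zero
under the null), and eps is Gaussian noise absorbing the remaining variance.

The auxiliary panel emulates transfer learning from external GWAS: 25 true
PRS are drawn with a correlation structure whose off-diagonal targets span
[-0.8, 0.8]; each "estimated" PRS adds independent estimation noise of
variance Me / N_GWAS (the random-effects noise of a score trained on N_GWAS
individuals with Me effective SNPs) and is re-standardized. The baseline
outcome trait is part of the same correlated panel, so the estimated outcome
PRS is informative about a linear S — mirroring the behaviour of a
single-outcome-PRS analysis on real data.

When genotypes are requested, the scores are built as G_std @ B with per-SNP
effects B drawn jointly across traits (so SNP-level methods can see the same
signal); otherwise scores are drawn directly from the equivalent
multivariate normal, which is distributionally identical for everything
downstream and much faster.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._utils import spawn_seeds, standardize
from .causal import interaction_scale
from .data import GenotypeMatrix, TrialDataset, standardize_treatment

__all__ = [
    "SimConfig",
    "PrsPanel",
    "simulate_genotypes",
    "target_correlation",
    "simulate_prs_panel",
    "pes_linear",
    "pes_nonlinear",
    "simulate_trial",
    "run_method_comparison",
]


def _default_weights() -> np.ndarray:
    return np.linspace(-0.6, 0.6, 25)


@dataclass
class SimConfig:
    """Study-design parameters of the simulation.

    Defaults are the generative conditions of the simulation study: trial
    sizes 500/1000/2000, a 25-trait auxiliary PRS panel with heritabilities
    ~N(0.5, 0.05) and pairwise correlation targets spanning [-0.8, 0.8],
    GWAS size 200,000 with 60,000 effective SNPs (estimation-noise variance
    Me/N_GWAS = 0.3 per score), baseline-PRS and G x T variance shares of
    10% each, treatment main effect 0.01, and randomization probability 1/2.
    ``n_snps`` defaults to a desk-scale 2,000-SNP panel for the SNP-level
    comparison methods.
    """

    n_rct: int = 1000
    n_snps: int = 2000
    n_aux_prs: int = 25
    h2_mean: float = 0.5
    h2_sd: float = 0.05
    corr_low: float = -0.8
    corr_high: float = 0.8
    var_baseline: float = 0.1
    var_pes: float = 0.1
    t_coef: float = 0.01
    n_gwas: int = 200_000
    Me: float = 60_000.0
    p_treat: float = 0.5
    pes_mode: str = "linear"  # linear | nonlinear | null
    weights: np.ndarray = field(default_factory=_default_weights)
    maf_low: float = 0.05
    maf_high: float = 0.5
    with_genotypes: bool = False
    seed: int = 0
    replicates: int = 500

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.pes_mode not in ("linear", "nonlinear", "null"):
            raise ValueError("pes_mode must be linear, nonlinear or null")
        if self.pes_mode == "linear" and self.weights.shape != (self.n_aux_prs,):
            raise ValueError("need one linear weight per auxiliary PRS")
        s_var = self.var_pes if self.pes_mode != "null" else 0.0
        if self.var_baseline + s_var + self.t_coef**2 >= 1.0:
            raise ValueError("variance components must sum below 1")
        if not 0.0 < self.p_treat < 1.0:
            raise ValueError("p_treat must lie in (0, 1)")

    @property
    def prs_noise_var(self) -> float:
        """Estimation-noise variance of each pre-trained PRS, Me / N_GWAS."""
        return self.Me / self.n_gwas


@dataclass
class PrsPanel:
    """True and estimated PRS panel for one simulated cohort."""

    true_aux: np.ndarray     # n x 25, columns standardized
    est_aux: np.ndarray      # n x 25, standardized after noise injection
    baseline_true: np.ndarray  # variance = var_baseline (enters the outcome)
    baseline_est: np.ndarray   # standardized estimated outcome PRS
    target_corr: np.ndarray  # (1 + n_aux) x (1 + n_aux), baseline first
    h2: np.ndarray           # per-aux-trait heritability draws (metadata)


def simulate_genotypes(
    n: int,
    J: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> GenotypeMatrix:
    """Binomial(2, MAF) dosages with per-variant MAF ~ Uniform(maf_range)."""
    lo, hi = maf_range
    if not 0.0 < lo <= hi <= 0.5:
        raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=J)
    dosages = rng.binomial(2, mafs, size=(n, J)).astype(float)
    ids = [f"rs{j + 1}" for j in range(J)]
    return GenotypeMatrix(dosages=dosages, variant_ids=ids, mafs=mafs)


def target_correlation(
    n_traits: int, corr_low: float = -0.8, corr_high: float = 0.8
) -> np.ndarray:
    """Correlation target for the trait panel, PSD by construction.

    Single-factor structure: trait k carries a factor loading a_k, the
    loadings equally spaced in [-sqrt(corr_high), sqrt(corr_high)] with the
    lower endpoint duplicated, giving corr(k, l) = a_k * a_l. Pairwise
    correlations then span [corr_low, corr_high] exactly (the two
    duplicated-extreme traits attain corr_high; opposite extremes attain
    corr_low) and the matrix a a' + diag(1 - a^2) is a valid correlation
    matrix with no numerical repair. Deterministic in its arguments.
    """
    if not 0.0 < corr_high < 1.0 or abs(corr_low + corr_high) > 1e-12:
        raise ValueError(
            "single-factor construction requires corr_low = -corr_high in (-1, 0)"
        )
    s = np.sqrt(corr_high)
    loadings = np.concatenate([[-s], np.linspace(-s, s, n_traits - 1)])
    m = np.outer(loadings, loadings)
    np.fill_diagonal(m, 1.0)
    return m


def _chol_psd(corr: np.ndarray) -> np.ndarray:
    jitter = 1e-10
    for _ in range(8):
        try:
            return np.linalg.cholesky(corr + jitter * np.eye(len(corr)))
        except np.linalg.LinAlgError:
            jitter *= 10
    raise np.linalg.LinAlgError("correlation target is numerically singular")


def _panel_from_true(
    true_panel_raw: np.ndarray, config: SimConfig, rng: np.random.Generator,
    target: np.ndarray, h2: np.ndarray,
) -> PrsPanel:
    """Standardize a raw (baseline + aux) score matrix and add GWAS noise."""
    true_std = standardize(true_panel_raw, axis=0)
    noise = rng.standard_normal(true_std.shape) * np.sqrt(config.prs_noise_var)
    est = standardize(true_std + noise, axis=0)
    return PrsPanel(
        true_aux=true_std[:, 1:],
        est_aux=est[:, 1:],
        baseline_true=np.sqrt(config.var_baseline) * true_std[:, 0],
        baseline_est=est[:, 0],
        target_corr=target,
        h2=h2,
    )


def simulate_prs_panel(n: int, config: SimConfig, seed: int = 0) -> PrsPanel:
    """Draw the correlated true PRS panel and its noisy estimated version.

    The panel holds 1 + n_aux traits (outcome baseline first). True scores
    come from a multivariate normal with the PSD-repaired correlation
    target; estimated scores add independent N(0, Me/N_GWAS) noise and are
    re-standardized, so corr(true, est) ~= 1/sqrt(1 + Me/N_GWAS).
    """
    rng = np.random.default_rng(seed)
    k = config.n_aux_prs + 1
    target = target_correlation(k, config.corr_low, config.corr_high)
    chol = _chol_psd(target)
    raw = rng.standard_normal((n, k)) @ chol.T
    h2 = np.clip(
        rng.normal(config.h2_mean, config.h2_sd, size=config.n_aux_prs),
        0.01, 0.99,
    )
    return _panel_from_true(raw, config, rng, target, h2)


def pes_linear(
    baseline_prs: np.ndarray,
    aux_prs: np.ndarray,
    weights: np.ndarray,
    var_pes: float = 0.1,
) -> np.ndarray:
    """Linear polygenic efficacy score.

    raw = 0.1 * baseline + sum_k alpha_k PRS_k, rescaled so that the sample
    variance of S is exactly ``var_pes``.
    """
    weights = np.asarray(weights, dtype=float)
    if aux_prs.shape[1] != weights.shape[0]:
        raise ValueError("one weight per auxiliary PRS required")
    raw = 0.1 * np.asarray(baseline_prs, dtype=float) + aux_prs @ weights
    if raw.std() < 1e-12:
        raise ValueError("PES combination has zero variance")
    return np.sqrt(var_pes) * standardize(raw)


def pes_nonlinear(
    baseline_prs: np.ndarray, aux_prs: np.ndarray, var_pes: float = 0.1
) -> np.ndarray:
    """Nonlinear polygenic efficacy score.

    f = 5 P1 + P2 P3 + sin P4 + cos P5 + exp P6 + log(|P7| + 1) + P8 P9
        - P10^3 + 0.1 * sum_{j=11..25} Pj^2

    (the absolute value keeps the logarithm defined for any score), then
    S = sqrt(var_pes) * standardize(0.1 * baseline + standardize(f)).
    """
    p = np.asarray(aux_prs, dtype=float)
    if p.shape[1] < 25:
        raise ValueError("nonlinear PES needs at least 25 auxiliary PRS")
    f = (
        5.0 * p[:, 0]
        + p[:, 1] * p[:, 2]
        + np.sin(p[:, 3])
        + np.cos(p[:, 4])
        + np.exp(p[:, 5])
        + np.log(np.abs(p[:, 6]) + 1.0)
        + p[:, 7] * p[:, 8]
        - p[:, 9] ** 3
        + 0.1 * np.sum(p[:, 10:25] ** 2, axis=1)
    )
    raw = 0.1 * np.asarray(baseline_prs, dtype=float) + standardize(f)
    return np.sqrt(var_pes) * standardize(raw)


def nonlinear_raw(aux_prs: np.ndarray) -> np.ndarray:
    """The unscaled nonlinear transform f (exposed for term-level checks)."""
    p = np.asarray(aux_prs, dtype=float)
    return (
        5.0 * p[:, 0] + p[:, 1] * p[:, 2] + np.sin(p[:, 3]) + np.cos(p[:, 4])
        + np.exp(p[:, 5]) + np.log(np.abs(p[:, 6]) + 1.0)
        + p[:, 7] * p[:, 8] - p[:, 9] ** 3
        + 0.1 * np.sum(p[:, 10:25] ** 2, axis=1)
    )


def simulate_trial(config: SimConfig, seed: int | None = None) -> TrialDataset:
    """Simulate one randomized trial under the polygenic G x T model.

    The returned dataset carries the estimated auxiliary PRS as features,
    the estimated outcome PRS under ``extras['baseline_est']``, and oracle
    truth attachments ``true_s`` / ``true_cate`` (CATE = A + C * S with
    C = 1/sqrt(p(1-p)) and A = C * t_coef).
    """
    seed = config.seed if seed is None else seed
    panel_seed, geno_seed, trt_seed, eps_seed = spawn_seeds(seed, 4)
    n = config.n_rct
    genotypes = None
    extras: dict = {}
    if config.with_genotypes:
        genotypes = simulate_genotypes(
            n, config.n_snps, (config.maf_low, config.maf_high), seed=geno_seed
        )
        rng = np.random.default_rng(panel_seed)
        k = config.n_aux_prs + 1
        target = target_correlation(k, config.corr_low, config.corr_high)
        chol = _chol_psd(target)
        # per-SNP effects drawn jointly across traits: rows ~ MVN(0, target/J)
        effects = rng.standard_normal((config.n_snps, k)) @ chol.T
        effects /= np.sqrt(config.n_snps)
        raw = genotypes.standardized() @ effects
        h2 = np.clip(
            rng.normal(config.h2_mean, config.h2_sd, size=config.n_aux_prs),
            0.01, 0.99,
        )
        panel = _panel_from_true(raw, config, rng, target, h2)
        extras["snp_effects"] = effects
    else:
        panel = simulate_prs_panel(n, config, seed=panel_seed)

    if config.pes_mode == "linear":
        s = pes_linear(panel.baseline_true, panel.true_aux, config.weights,
                       config.var_pes)
    elif config.pes_mode == "nonlinear":
        s = pes_nonlinear(panel.baseline_true, panel.true_aux, config.var_pes)
    else:
        s = np.zeros(n)

    rng_t = np.random.default_rng(trt_seed)
    t = rng_t.binomial(1, config.p_treat, size=n).astype(float)
    t_std = standardize_treatment(t, config.p_treat)
    s_var = config.var_pes if config.pes_mode != "null" else 0.0
    eps_var = 1.0 - config.var_baseline - s_var - config.t_coef**2
    eps = np.random.default_rng(eps_seed).standard_normal(n) * np.sqrt(eps_var)
    y = panel.baseline_true + s * t_std + config.t_coef * t_std + eps

    c = interaction_scale(config.p_treat)
    extras.update(
        baseline_est=panel.baseline_est,
        baseline_true=panel.baseline_true,
        target_corr=panel.target_corr,
        h2=panel.h2,
        t_std=t_std,
    )
    return TrialDataset(
        ids=[f"id{i + 1}" for i in range(n)],
        y=y,
        t=t,
        design_p=config.p_treat,
        prs=panel.est_aux,
        prs_labels=[f"PRS{k + 1:02d}" for k in range(config.n_aux_prs)],
        genotypes=genotypes,
        true_s=s,
        true_cate=c * config.t_coef + c * s,
        extras=extras,
    )


# ---------------------------------------------------------------------------
# method-comparison harness
# ---------------------------------------------------------------------------

_SNP_METHODS = {"within_gwis", "prspgx", "mlearner_snp", "mlearner_s"}
KNOWN_METHODS = {"mlearner_i", "single_prs"} | _SNP_METHODS


def _method_p_value(method: str, data: TrialDataset, config: SimConfig,
                    seed: int) -> float:
    from . import baselines
    from .individual import LearnerSpec, run_mlearner_i

    if method == "mlearner_i":
        report = run_mlearner_i(data, LearnerSpec("linear"), K=5, q=4, seed=seed)
        return report.p_combined
    if method == "single_prs":
        return baselines.single_prs_interaction(
            data, prs_values=data.extras["baseline_est"]
        ).p_value
    if method == "within_gwis":
        return baselines.within_gwis_pes(data, seed=seed).p_value
    if method == "prspgx":
        return baselines.prspgx(data, seed=seed).p_value
    if method == "mlearner_snp":
        return baselines.mlearner_snp(
            data, LearnerSpec("linear"), K=5, seed=seed
        ).p_value
    if method == "mlearner_s":
        return _mlearner_s_replicate(data, config, seed)
    raise ValueError(f"unknown method {method!r}; known: {sorted(KNOWN_METHODS)}")


def _mlearner_s_replicate(data: TrialDataset, config: SimConfig, seed: int) -> float:
    """Stylized summary-statistic run on one simulated replicate.

    GWIS z-scores come from per-SNP interaction regressions inside the
    trial; each trait's GWAS z-scores are sqrt(N_GWAS) times its per-SNP
    effects plus standard-normal sampling noise.
    """
    from .baselines import gwis_scan
    from .summary import cauchy_combine

    if data.genotypes is None or "snp_effects" not in data.extras:
        raise ValueError("mlearner_s harness needs genotype-based replicates")
    g_std = data.genotypes.standardized()
    t_std = data.extras["t_std"]
    scan = gwis_scan(g_std, t_std, data.y)
    z_i = scan["beta_I"].to_numpy() / scan["se_I"].to_numpy()
    effects = data.extras["snp_effects"][:, 1:]  # auxiliary traits only
    rng = np.random.default_rng(seed)
    z_gwas = np.sqrt(config.n_gwas) * effects + rng.standard_normal(effects.shape)
    from scipy import stats as _st

    pvals = []
    for k in range(z_gwas.shape[1]):
        w = z_gwas[:, k]
        z = float(w @ z_i / np.sqrt(np.sum(w**2)))
        pvals.append(float(2.0 * _st.norm.sf(abs(z))))
    return cauchy_combine(pvals)[1]


def run_method_comparison(
    config: SimConfig,
    methods: Sequence[str],
    replicates: int | None = None,
    seed: int = 0,
    alpha: float = 0.05,
    keep_pvalues: bool = False,
) -> pd.DataFrame:
    """Rejection rates of each method over seeded replicates.

    Replicate r uses seed ``seed + r``; power/type-I error is the fraction
    of replicates with p < alpha, reported with its binomial standard
    error. Genotypes are simulated only when a SNP-level method asks for
    them.
    """
    methods = list(methods)
    unknown = set(methods) - KNOWN_METHODS
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}")
    replicates = config.replicates if replicates is None else replicates
    need_geno = bool(set(methods) & _SNP_METHODS)
    cfg = replace(config, with_genotypes=config.with_genotypes or need_geno)
    pvals: dict[str, list[float]] = {m: [] for m in methods}
    for r in range(replicates):
        rep_seed = seed + r
        data = simulate_trial(cfg, seed=rep_seed)
        for m in methods:
            pvals[m].append(_method_p_value(m, data, cfg, rep_seed))
    rows = []
    for m in methods:
        p = np.asarray(pvals[m])
        rate = float(np.mean(p < alpha))
        rows.append({
            "method": m,
            "scenario": cfg.pes_mode,
            "n_rct": cfg.n_rct,
            "replicates": replicates,
            "rejection_rate": rate,
            "binomial_se": float(np.sqrt(rate * (1 - rate) / replicates)),
            "base_seed": seed,
        })
    out = pd.DataFrame(rows)
    if keep_pvalues:
        out.attrs["pvalues"] = {m: np.asarray(v) for m, v in pvals.items()}
    return out
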