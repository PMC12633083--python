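"""Comparison methods for detecting genetically driven HTE.

All four baselines consume the same :class:`~mlearner.data.TrialDataset`
and emit a :class:`BaselineResult`, so the comparison harness treats them
interchangeably:

* ``single_prs_interaction`` — tests whether one pre-trained PRS (typically
  the trial-outcome PRS) modifies treatment response in a four-term
  interaction regression.
* ``within_gwis_pes`` — re-estimates per-SNP interaction effects inside one
  half of the trial, builds a polygenic efficacy score from them, and tests
  the score-by-treatment interaction on the other half.
* ``prspgx`` — combines prognostic (additive) and predictive (interaction)
  SNP weights into two scores, tuned on a holdout and tested on held-out
  data.
* ``mlearner_snp`` — the individual-level learner pipeline run directly on
  standardized SNP dosages instead of PRS features (no transfer learning).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._utils import spawn_seeds, standardize
from .causal import pseudo_outcome
from .data import TrialDataset, standardize_treatment

__all__ = [
    "BaselineResult",
    "gwis_scan",
    "single_prs_interaction",
    "within_gwis_pes",
    "prspgx",
    "mlearner_snp",
]

_MAX_CONDITION = 1e8


@dataclass
class BaselineResult:
    method: str
    interaction_coef: float
    se: float
    p_value: float
    details: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _interaction_ols(y, t_std, score, method, extra_details=None,
                     prognostic=None) -> BaselineResult:
    """OLS Y ~ 1 + T + score + T*score (HC3), p for the interaction term.

    ``prognostic`` substitutes a different main-effect score, giving the
    two-score model Y ~ 1 + T + prog + T*pred."""
    main = score if prognostic is None else prognostic
    x = np.column_stack([np.ones_like(y), t_std, main, t_std * score])
    cond = np.linalg.cond(x)
    if cond > _MAX_CONDITION:
        raise ValueError(f"design matrix ill-conditioned (cond={cond:.2e})")
    fit = sm.OLS(y, x).fit(cov_type="HC3")
    beta = float(fit.params[3])
    se = float(fit.bse[3])
    z = beta / se
    details = {"n": int(len(y)), "n_params": x.shape[1]}
    details.update(extra_details or {})
    return BaselineResult(
        method=method, interaction_coef=beta, se=se,
        p_value=float(2.0 * stats.norm.sf(abs(z))), details=details,
    )


def single_prs_interaction(
    data: TrialDataset,
    prs_index: int | None = None,
    prs_values: np.ndarray | None = None,
) -> BaselineResult:
    """Single-PRS modifier test: Y ~ 1 + T + PRS + T x PRS.

    Pass either a column index into the dataset's PRS matrix or an explicit
    score vector (e.g. the trial-outcome PRS). Heteroskedasticity-robust
    (HC3) SE, two-sided normal p for the interaction coefficient.
    """
    if (prs_index is None) == (prs_values is None):
        raise ValueError("supply exactly one of prs_index or prs_values")
    score = data.prs[:, prs_index] if prs_values is None else np.asarray(prs_values, float)
    if score.std() < 1e-12:
        raise ValueError("chosen PRS column is constant")
    t_std = standardize_treatment(data.t, data.design_p)
    return _interaction_ols(data.y, t_std, standardize(score), "single_prs")


def gwis_scan(g_std: np.ndarray, t_std: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Per-SNP regressions Y ~ 1 + G_j + T + G_j x T, solved in batch.

    Returns additive (``beta_G``) and interaction (``beta_I``) estimates
    with their standard errors for every SNP. The 4 x 4 normal equations of
    all J regressions are assembled from cross-moments and solved jointly.
    """
    g_std = np.asarray(g_std, float)
    t_std = np.asarray(t_std, float)
    y = np.asarray(y, float)
    n, J = g_std.shape
    if n <= 4:
        raise ValueError("need more than 4 individuals per regression")
    ones = np.ones(n)
    t2 = t_std**2
    # moments of the design columns [1, g, t, g*t] per SNP
    s_g = g_std.sum(axis=0)
    s_g2 = (g_std**2).sum(axis=0)
    s_t = t_std.sum()
    s_t2 = t2.sum()
    s_gt = t_std @ g_std
    s_g2t = t_std @ g_std**2
    s_gt2 = t2 @ g_std
    s_g2t2 = t2 @ g_std**2
    M = np.empty((J, 4, 4))
    M[:, 0, 0] = n
    M[:, 0, 1] = M[:, 1, 0] = s_g
    M[:, 0, 2] = M[:, 2, 0] = s_t
    M[:, 0, 3] = M[:, 3, 0] = s_gt
    M[:, 1, 1] = s_g2
    M[:, 1, 2] = M[:, 2, 1] = s_gt
    M[:, 1, 3] = M[:, 3, 1] = s_g2t
    M[:, 2, 2] = s_t2
    M[:, 2, 3] = M[:, 3, 2] = s_gt2
    M[:, 3, 3] = s_g2t2
    v = np.empty((J, 4))
    v[:, 0] = y.sum()
    v[:, 1] = y @ g_std
    v[:, 2] = (y * t_std).sum()
    v[:, 3] = (y * t_std) @ g_std
    beta = np.linalg.solve(M, v[..., None])[..., 0]
    yy = float(y @ y)
    rss = yy - np.einsum("jk,jk->j", beta, v)
    sigma2 = np.maximum(rss, 0.0) / (n - 4)
    Minv = np.linalg.inv(M)
    se_g = np.sqrt(sigma2 * Minv[:, 1, 1])
    se_i = np.sqrt(sigma2 * Minv[:, 3, 3])
    return pd.DataFrame({
        "beta_G": beta[:, 1], "se_G": se_g,
        "beta_I": beta[:, 3], "se_I": se_i,
    })


def _split_indices(n: int, fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    cut = int(round(fraction * n))
    return np.sort(order[:cut]), np.sort(order[cut:])


def _require_genotypes(data: TrialDataset, method: str):
    if data.genotypes is None:
        raise ValueError(f"{method} requires a genotype matrix")


def _check_arms(t: np.ndarray, what: str):
    if (t == 1).sum() == 0 or (t == 0).sum() == 0:
        raise ValueError(f"{what} contains an empty treatment arm")


def within_gwis_pes(
    data: TrialDataset, split_fraction: float = 0.5, seed: int = 0
) -> BaselineResult:
    """PES built from within-trial SNP-by-treatment estimates.

    The trial is split in two: per-SNP interaction coefficients are
    estimated on the training half, the resulting score
    PES_i = sum_j G_ij * beta_hat_Ij is evaluated on the test half, and the
    PES x T interaction is tested there. With a small trial the per-SNP
    estimates are dominated by noise, which is exactly the regime the
    scaling laws predict to be underpowered.
    """
    _require_genotypes(data, "within_gwis_pes")
    train, test = _split_indices(data.n, split_fraction, seed)
    _check_arms(data.t[train], "training split")
    _check_arms(data.t[test], "test split")
    g_std = data.genotypes.standardized()
    t_std = standardize_treatment(data.t, data.design_p)
    scan = gwis_scan(g_std[train], t_std[train], data.y[train])
    pes = g_std[test] @ scan["beta_I"].to_numpy()
    if pes.std() < 1e-12:
        raise ValueError("within-sample PES has zero variance")
    res = _interaction_ols(
        data.y[test], t_std[test], standardize(pes), "within_gwis",
        extra_details={"n_train": int(train.size), "n_test": int(test.size)},
    )
    return res


_SHRINK_KEEP_FRACTIONS = (1.0, 0.5, 0.2, 0.1, 0.05)


def _threshold_weights(beta: np.ndarray, z: np.ndarray, keep: float) -> np.ndarray:
    if keep >= 1.0:
        return beta
    k = max(1, int(round(keep * beta.size)))
    cutoff = np.partition(np.abs(z), beta.size - k)[beta.size - k]
    out = np.where(np.abs(z) >= cutoff, beta, 0.0)
    return out


def prspgx(
    data: TrialDataset,
    split_fraction: float = 0.5,
    holdout_fraction: float = 0.25,
    seed: int = 0,
) -> BaselineResult:
    """Two-score prognostic/predictive model from within-trial GWIS.

    Per-SNP additive and interaction effects estimated on a training split
    feed a prognostic score (sum G * beta_G) and a predictive score
    (sum G * beta_I). A grid of top-|z| selection thresholds per weight
    vector is tuned on a holdout carved from the training half — prognostic
    weights to predict the outcome, predictive weights to predict the
    inverse-propensity pseudo-outcome (treatment response) — and the final
    model Y ~ 1 + T + ProgScore + T x PredScore is tested on the remaining
    split. (Multiplicative rescaling of a whole weight vector would leave
    the interaction test invariant, so tuning selects SNP subsets instead.)
    """
    _require_genotypes(data, "prspgx")
    seed_split, seed_hold = spawn_seeds(seed, 2)
    train_all, test = _split_indices(data.n, split_fraction, seed_split)
    hold_rel, sub_rel = _split_indices(train_all.size, holdout_fraction, seed_hold)
    holdout, subtrain = train_all[hold_rel], train_all[sub_rel]
    for part, name in ((subtrain, "GWIS split"), (holdout, "holdout split"),
                       (test, "test split")):
        _check_arms(data.t[part], name)
    g_std = data.genotypes.standardized()
    t_std = standardize_treatment(data.t, data.design_p)
    scan = gwis_scan(g_std[subtrain], t_std[subtrain], data.y[subtrain])
    beta_g = scan["beta_G"].to_numpy()
    beta_i = scan["beta_I"].to_numpy()
    z_g = beta_g / scan["se_G"].to_numpy()
    z_i = beta_i / scan["se_I"].to_numpy()

    yh_hold = pseudo_outcome(data.y[holdout], data.t[holdout], data.design_p).values
    best = {"prog": None, "pred": None}
    for target, beta, z, key in (
        (data.y[holdout], beta_g, z_g, "prog"),
        (yh_hold, beta_i, z_i, "pred"),
    ):
        best_score, best_w, best_keep = -np.inf, None, None
        for keep in _SHRINK_KEEP_FRACTIONS:
            w = _threshold_weights(beta, z, keep)
            score = g_std[holdout] @ w
            if score.std() < 1e-12:
                continue
            r = abs(float(np.corrcoef(score, target)[0, 1]))
            if r > best_score:
                best_score, best_w, best_keep = r, w, keep
        if best_w is None:
            raise ValueError("all candidate scores degenerate on the holdout")
        best[key] = (best_w, best_keep)
    prog = g_std[test] @ best["prog"][0]
    pred = g_std[test] @ best["pred"][0]
    if prog.std() < 1e-12 or pred.std() < 1e-12:
        raise ValueError("degenerate prognostic/predictive score on test split")
    return _interaction_ols(
        data.y[test], t_std[test], standardize(pred), "prspgx",
        prognostic=standardize(prog),
        extra_details={
            "n_gwis": int(subtrain.size), "n_holdout": int(holdout.size),
            "n_test": int(test.size),
            "keep_prognostic": best["prog"][1], "keep_predictive": best["pred"][1],
        },
    )


def mlearner_snp(
    data: TrialDataset, learner=None, K: int = 5, seed: int = 0
) -> BaselineResult:
    """Learner pipeline on standardized SNP dosages (no transfer learning)."""
    from .individual import LearnerSpec, run_mlearner_i

    _require_genotypes(data, "mlearner_snp")
    learner = learner or LearnerSpec("linear")
    report = run_mlearner_i(
        data, learner, K=K, q=4, seed=seed,
        features=data.genotypes.standardized(),
    )
    blp = report.per_learner[learner.name]["blp"]
    return BaselineResult(
        method="mlearner_snp", interaction_coef=blp.beta_hat, se=blp.se_beta,
        p_value=blp.p_value,
        details={"n_used": blp.n_used, "K": K, "learner": learner.name},
    )
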