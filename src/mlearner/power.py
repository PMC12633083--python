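"""Analytic power scaling laws for the PES-by-treatment interaction test.

Consider the test regression Y ~ S_hat + T + S_hat*T on N_test independent
individuals, where S_hat is an estimated polygenic efficacy score (PES) with
unit variance and the outcome has unit variance. Under the random-effects
polygenic model, the expected interaction coefficient E[alpha_I] =
Cov(S, S_hat) / Var(S_hat) depends on how S_hat was estimated:

* ``within_gwis``    — per-SNP interaction effects re-estimated inside the
  trial itself: E[alpha_I] = sigma_I^2 / (sigma_I^2 + Me / N_RCT)
* ``single_prs``     — a pre-trained PRS for the trial outcome:
  E[alpha_I] = r_GI * sqrt(sigma_I^2 sigma_G^2) / (sigma_G^2 + Me / N_G)
* ``multi_prs``      — the best linear combination of K pre-trained PRS:
  E[alpha_I] = Sigma_WX' Sigma_XX^{-1} Sigma_WX / sigma_W^2

Here sigma_I^2 is the treatment-response variance explained by G x T,
sigma_G^2 the outcome heritability, r_GI the correlation between the true
PES and the PRS, and Me the effective number of independent SNPs (so Me/N is
the estimation-noise variance of a score trained on N individuals).

The z-statistic of the interaction test is asymptotically normal with mean
(noncentrality) lambda = sqrt(N_test) * Cov(S, S_hat) / sqrt(Var(S_hat))
(outcome variance ~ 1), giving two-sided power

    Power = 1 - Phi(z_{1-a/2} - lambda) + Phi(-z_{1-a/2} - lambda).

The ``transfer_rho`` noncentrality parameterizes S_hat only through its
correlation rho with the true PES: lambda = sqrt(N_test * rho^2 * sigma_I^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PowerParams",
    "MultiPrsCovariance",
    "expected_interaction_coef",
    "noncentrality",
    "power_two_sided",
    "power_curve",
]

COEF_STRATEGIES = ("within_gwis", "single_prs", "multi_prs")
NCP_STRATEGIES = ("within_gwis", "single_prs", "transfer_rho")


@dataclass
class PowerParams:
    """Scaling-law parameters.

    sigma2_I : variance of treatment response explained by G x T (0..1)
    sigma2_G : outcome heritability (0..1)
    r_GI     : correlation between true PES and the single PRS (-1..1)
    Me       : effective number of independent SNPs (> 0)
    N_RCT    : trial sample size used to train a within-sample PES
    N_G      : GWAS sample size behind the pre-trained PRS
    N_test   : independent test sample size for the interaction regression
    alpha    : two-sided type-I error level
    rho      : correlation between true and estimated PES (transfer curve)
    """

    sigma2_I: float = 0.03
    sigma2_G: float = 0.3
    r_GI: float = 0.5
    Me: float = 60_000.0
    N_RCT: int = 2500
    N_G: int = 400_000
    N_test: int = 2500
    alpha: float = 0.05
    rho: float = 0.5

    def __post_init__(self):
        if not (0.0 <= self.sigma2_I <= 1.0 and 0.0 <= self.sigma2_G <= 1.0):
            raise ValueError("variance fractions must lie in [0, 1]")
        if not -1.0 <= self.r_GI <= 1.0:
            raise ValueError("r_GI must lie in [-1, 1]")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if min(self.Me, self.N_RCT, self.N_G, self.N_test) <= 0:
            raise ValueError("Me and sample sizes must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class MultiPrsCovariance:
    """Covariance blocks between the true PES (W) and K PRS (X)."""

    sigma2_W: float
    cov_WX: np.ndarray
    cov_XX: np.ndarray

    def __post_init__(self):
        self.cov_WX = np.atleast_1d(np.asarray(self.cov_WX, dtype=float))
        self.cov_XX = np.atleast_2d(np.asarray(self.cov_XX, dtype=float))
        k = self.cov_WX.shape[0]
        if self.cov_XX.shape != (k, k):
            raise ValueError("cov_XX must be K x K matching cov_WX")
        if not np.allclose(self.cov_XX, self.cov_XX.T):
            raise ValueError("cov_XX must be symmetric")
        if self.sigma2_W <= 0:
            raise ValueError("sigma2_W must be positive")
        eigvals = np.linalg.eigvalsh(self.cov_XX)
        if eigvals.min() <= 0:
            raise np.linalg.LinAlgError("cov_XX is not positive definite")


def expected_interaction_coef(
    strategy: str, params: PowerParams | MultiPrsCovariance
) -> float:
    """Expected PES x T interaction coefficient for one estimation strategy."""
    if strategy == "within_gwis":
        p = params
        return p.sigma2_I / (p.sigma2_I + p.Me / p.N_RCT)
    if strategy == "single_prs":
        p = params
        return (
            p.r_GI * np.sqrt(p.sigma2_I * p.sigma2_G)
            / (p.sigma2_G + p.Me / p.N_G)
        )
    if strategy == "multi_prs":
        if not isinstance(params, MultiPrsCovariance):
            raise TypeError("multi_prs requires MultiPrsCovariance params")
        sol = np.linalg.solve(params.cov_XX, params.cov_WX)
        return float(params.cov_WX @ sol / params.sigma2_W)
    raise ValueError(f"strategy must be one of {COEF_STRATEGIES}, got {strategy!r}")


def noncentrality(strategy: str, params: PowerParams) -> float:
    """Noncentrality lambda of the interaction z-statistic.

    lambda = sqrt(N_test) * Cov(S, S_hat) / sqrt(Var(S_hat)) with the
    outcome and PES scaled to unit variance.
    """
    p = params
    if strategy == "within_gwis":
        return float(
            np.sqrt(p.N_test) * p.sigma2_I / np.sqrt(p.sigma2_I + p.Me / p.N_RCT)
        )
    if strategy == "single_prs":
        return float(
            np.sqrt(p.N_test)
            * p.r_GI * np.sqrt(p.sigma2_I * p.sigma2_G)
            / np.sqrt(p.sigma2_G + p.Me / p.N_G)
        )
    if strategy == "transfer_rho":
        return float(np.sqrt(p.N_test) * p.rho * np.sqrt(p.sigma2_I))
    raise ValueError(f"strategy must be one of {NCP_STRATEGIES}, got {strategy!r}")


def power_two_sided(lmbda: float, alpha: float) -> float:
    """Two-sided power 1 - Phi(z_{1-a/2} - lambda) + Phi(-z_{1-a/2} - lambda)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
    lmbda = float(lmbda)
    return float(stats.norm.sf(zcrit - lmbda) + stats.norm.cdf(-zcrit - lmbda))


_GRID_FIELD = {"within_gwis": "sigma2_I", "single_prs": "r_GI", "transfer_rho": "rho"}


def power_curve(
    strategy: str, params: PowerParams, grid: np.ndarray
) -> pd.DataFrame:
    """Vectorized power curve over a parameter grid.

    The grid varies sigma2_I for ``within_gwis``, r_GI for ``single_prs``
    and rho for ``transfer_rho``; all other parameters are held fixed.
    Returns a table of (grid value, lambda, power).
    """
    field = _GRID_FIELD.get(strategy)
    if field is None:
        raise ValueError(f"strategy must be one of {NCP_STRATEGIES}, got {strategy!r}")
    rows = []
    for v in np.asarray(grid, dtype=float):
        kwargs = {**params.__dict__, field: float(v)}
        lam = noncentrality(strategy, PowerParams(**kwargs))
        rows.append({field: float(v), "lambda": lam,
                     "power": power_two_sided(lam, params.alpha)})
    return pd.DataFrame(rows)
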