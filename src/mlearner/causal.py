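"""Polygenic gene-by-treatment model math.

The outcome model is

    Y_i = sum_j G_ij * beta_Gj + T_i * beta_T + sum_j G_ij * T_i * beta_Ij + eps_i

with standardized genotypes G_ij and the treatment indicator coded
sqrt((1-p)/p) for treated and -sqrt(p/(1-p)) for control. Under this model
the conditional average treatment effect is linear in the polygenic efficacy
score S_i = sum_j G_ij * beta_Ij:

    CATE_i = A + C * S_i,   C = sqrt((1-p)/p) + sqrt(p/(1-p)) = 1/sqrt(p(1-p))

where A = C * beta_T is the average treatment effect. The inverse-propensity
pseudo-outcome Y^H_i = T_i Y_i / e - (1 - T_i) Y_i / (1 - e) satisfies
E[Y^H | G] = CATE(G) and is the regression target of the individual-level
learner pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._utils import check_in_open_unit_interval

__all__ = [
    "PesModel",
    "PseudoOutcome",
    "compute_pes",
    "interaction_scale",
    "cate_from_pes",
    "pseudo_outcome",
    "ate_difference_in_means",
    "PROPENSITY_BOUND",
]

#: positivity bound on the propensity score; values outside
#: [PROPENSITY_BOUND, 1 - PROPENSITY_BOUND] are a hard error.
PROPENSITY_BOUND = 1e-3


@dataclass(frozen=True)
class PesModel:
    """True coefficients of the polygenic G x T model."""

    beta_G: np.ndarray
    beta_I: np.ndarray
    beta_T: float

    def __post_init__(self):
        bg = np.asarray(self.beta_G, dtype=float)
        bi = np.asarray(self.beta_I, dtype=float)
        if bg.shape != bi.shape or bg.ndim != 1:
            raise ValueError("beta_G and beta_I must be 1-D vectors of equal length")
        if not (np.isfinite(bg).all() and np.isfinite(bi).all() and np.isfinite(self.beta_T)):
            raise ValueError("model coefficients must be finite")
        object.__setattr__(self, "beta_G", bg)
        object.__setattr__(self, "beta_I", bi)


@dataclass(frozen=True)
class PseudoOutcome:
    """Inverse-propensity pseudo-outcomes, E[Y^H | G] = CATE(G)."""

    values: np.ndarray
    propensity_used: float

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.isfinite(v).all():
            raise ValueError("pseudo-outcomes must be finite")
        object.__setattr__(self, "values", v)


def compute_pes(g_std: np.ndarray, beta_I: np.ndarray) -> np.ndarray:
    """Polygenic efficacy score S_i = sum_j G_ij * beta_Ij."""
    g_std = np.asarray(g_std, dtype=float)
    beta_I = np.asarray(beta_I, dtype=float)
    if g_std.ndim != 2 or beta_I.ndim != 1 or g_std.shape[1] != beta_I.shape[0]:
        raise ValueError(
            f"dimension mismatch: G is {g_std.shape}, beta_I has length {beta_I.shape}"
        )
    return g_std @ beta_I


def interaction_scale(p: float) -> float:
    """C = sqrt((1-p)/p) + sqrt(p/(1-p)) = 1/sqrt(p(1-p)).

    The gap between the two standardized treatment codes; minimized (C=2) at
    p = 1/2 and symmetric in p <-> 1-p.
    """
    check_in_open_unit_interval(p, "p")
    return 1.0 / np.sqrt(p * (1.0 - p))


def cate_from_pes(s: np.ndarray, ate_A: float, p: float) -> tuple[np.ndarray, float]:
    """CATE_i = A + C * S_i; returns (cate, C)."""
    c = interaction_scale(p)
    return ate_A + c * np.asarray(s, dtype=float), c


def pseudo_outcome(
    y: np.ndarray, t: np.ndarray, e: float | np.ndarray
) -> PseudoOutcome:
    """Y^H_i = T_i * Y_i / e_i - (1 - T_i) * Y_i / (1 - e_i).

    ``e`` is the known randomization probability (scalar) or a per-individual
    propensity vector; positivity is enforced by requiring e within
    [1e-3, 1 - 1e-3].
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    if y.shape != t.shape:
        raise ValueError("y and t must have the same shape")
    if not np.isin(t, (0.0, 1.0)).all():
        raise ValueError("treatment must be coded 0/1")
    e_arr = np.asarray(e, dtype=float)
    if np.any(e_arr < PROPENSITY_BOUND) or np.any(e_arr > 1.0 - PROPENSITY_BOUND):
        raise ValueError(
            "propensity violates positivity: every e must lie in "
            f"[{PROPENSITY_BOUND}, {1 - PROPENSITY_BOUND}]; the pseudo-outcome "
            "requires the treatment probability bounded away from 0 and 1"
        )
    values = t * y / e_arr - (1.0 - t) * y / (1.0 - e_arr)
    return PseudoOutcome(values=values, propensity_used=float(np.mean(e_arr)))


def ate_difference_in_means(y: np.ndarray, t: np.ndarray) -> tuple[float, float]:
    """Difference-in-means ATE with the unpooled (Welch) standard error."""
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    y1, y0 = y[t == 1.0], y[t == 0.0]
    if y1.size == 0 or y0.size == 0:
        raise ValueError(
            f"both arms must be nonempty (treated n={y1.size}, control n={y0.size})"
        )
    est = y1.mean() - y0.mean()
    v1 = y1.var(ddof=1) if y1.size > 1 else 0.0
    v0 = y0.var(ddof=1) if y0.size > 1 else 0.0
    se = float(np.sqrt(v1 / y1.size + v0 / y0.size))
    return float(est), se
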