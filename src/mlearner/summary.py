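"""Summary-statistic HTE pipeline (M-Learner-S).

Inputs are per-SNP z-scores from a genome-wide interaction study (GWIS,
SNP-by-treatment) and from one external GWAS per candidate trait. For each
trait the GWAS z-scores act as PRS weights and are contrasted against the
GWIS interaction z-scores with an inverse-variance inner-product statistic;
the per-trait p-values are aggregated into one global heterogeneity p-value
with the Cauchy combination test, which is robust to dependence among the
per-trait tests. Variants are assumed LD-independent (e.g. pre-pruned);
the caller is responsible for supplying such a panel.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import ScoringFile, SummaryStats, harmonize_variants

logger = logging.getLogger(__name__)

__all__ = [
    "PrsInteractionResult",
    "CauchyResult",
    "prs_treatment_interaction_z",
    "cauchy_combine",
    "run_mlearner_s",
]

#: p-values are clipped into [CLIP, 1-CLIP] before the Cauchy transform,
#: whose tangent diverges at 0 and 1.
CLIP = 1e-15


@dataclass(frozen=True)
class PrsInteractionResult:
    """PRS-by-treatment interaction test for one trait."""

    trait_label: str
    z: float
    p_value: float
    n_variants_used: int


@dataclass
class CauchyResult:
    """Combined heterogeneity evidence across the PRS panel."""

    per_prs: list[PrsInteractionResult]
    t_stat: float
    p_combined: float
    ranking: list[str]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                {
                    "trait": r.trait_label,
                    "z": r.z,
                    "p": r.p_value,
                    "n_variants": r.n_variants_used,
                }
                for r in self.per_prs
            ]
        )
        m = len(df)
        df["p_bonferroni"] = np.minimum(1.0, df["p"] * m)
        df["rank"] = df["p"].rank(method="first").astype(int)
        return df.sort_values("rank", kind="stable").reset_index(drop=True)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "t_stat": self.t_stat,
            "p_combined": self.p_combined,
            "ranking": self.ranking,
            "per_prs": self.to_frame().to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text


def prs_treatment_interaction_z(
    gwis: SummaryStats,
    gwas: SummaryStats | None = None,
    weights: ScoringFile | None = None,
    drop_palindromic: bool = True,
) -> PrsInteractionResult:
    """Weighted inner-product z for one PRS-by-treatment interaction.

    GWAS marginal z-scores (or scoring-file weights) weight the GWIS
    interaction z-scores:

        z = sum_j w_j Z_Ij / sqrt(sum_j w_j^2)

    which is standard normal under the null of no interaction when variants
    are independent. The two inputs are allele-harmonized first. Rescaling
    all weights by a positive constant leaves z unchanged; negating them
    negates z but not the two-sided p-value.
    """
    if (gwas is None) == (weights is None):
        raise ValueError("supply exactly one of gwas or weights")
    if gwas is not None:
        pairs = harmonize_variants(gwis, gwas, drop_palindromic=drop_palindromic)
        z_i = pairs.z_reference
        w = pairs.z_other
        label = gwas.trait_label
    else:
        z_by_id = {r.variant_id: r for r in gwis.records}
        z_i_list, w_list = [], []
        for vid, allele, weight in weights.entries:
            rec = z_by_id.get(vid)
            if rec is None:
                continue
            if allele == rec.allele_effect:
                sign = 1.0
            elif allele == rec.allele_other:
                sign = -1.0
            else:
                continue
            z_i_list.append(rec.z)
            w_list.append(sign * weight)
        if not z_i_list:
            raise ValueError("no scoring variants overlap the GWIS panel")
        z_i, w = np.asarray(z_i_list), np.asarray(w_list)
        label = weights.label
    denom = float(np.sqrt(np.sum(w**2)))
    if denom == 0.0:
        raise ValueError(
            f"all weights are zero for trait {label!r}: statistic undefined"
        )
    z = float(np.sum(w * z_i) / denom)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return PrsInteractionResult(
        trait_label=label, z=z, p_value=p, n_variants_used=int(len(w))
    )


def cauchy_combine(pvals: Sequence[float]) -> tuple[float, float]:
    """Cauchy combination: T = mean(tan((1/2 - p_k) pi)), p = 1/2 - arctan(T)/pi.

    T is standard Cauchy under the global null even for dependent p-values;
    the combined p equals the standard-Cauchy upper tail of T. Strictly
    decreasing in every input p.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("cannot combine an empty p-value list")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    p = np.clip(p, CLIP, 1.0 - CLIP)
    t = float(np.mean(np.tan((0.5 - p) * np.pi)))
    p_comb = float(0.5 - np.arctan(t) / np.pi)
    return t, min(max(p_comb, CLIP), 1.0 - CLIP)


def run_mlearner_s(
    gwis: SummaryStats,
    gwas_list: Sequence[SummaryStats],
    drop_palindromic: bool = True,
) -> CauchyResult:
    """Scan a panel of GWAS against one GWIS and combine the evidence.

    Traits with no harmonizable variants are excluded with a warning; the
    ranking lists traits by ascending interaction p-value.
    """
    if not gwas_list:
        raise ValueError("need at least one GWAS")
    per_prs: list[PrsInteractionResult] = []
    for gwas in gwas_list:
        try:
            res = prs_treatment_interaction_z(
                gwis, gwas=gwas, drop_palindromic=drop_palindromic
            )
        except ValueError as exc:
            logger.warning("excluding trait %r: %s", gwas.trait_label, exc)
            continue
        per_prs.append(res)
    if not per_prs:
        raise ValueError("no GWAS shares harmonizable variants with the GWIS")
    t_stat, p_combined = cauchy_combine([r.p_value for r in per_prs])
    ranking = [r.trait_label for r in sorted(per_prs, key=lambda r: r.p_value)]
    return CauchyResult(
        per_prs=per_prs, t_stat=t_stat, p_combined=p_combined, ranking=ranking
    )
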