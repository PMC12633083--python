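"""Shared fixtures: small deterministic datasets and the two expensive
Monte Carlo studies (null calibration of the full pipeline, and the
linear-scenario method comparison) reused by several tests."""

from __future__ import annotations

import numpy as np
import pytest

from mlearner.individual import LearnerSpec, run_mlearner_i
from mlearner.simulate import SimConfig, run_method_comparison, simulate_trial


@pytest.fixture(scope="session")
def null_pipeline_pvalues() -> np.ndarray:
    """500 global p-values of the individual-level pipeline under the null
    generator (no G x T component, n=1000, 25 estimated PRS, penalized
    linear learner, K=5), replicate r seeded base + r."""
    base = 1000
    cfg = SimConfig(n_rct=1000, pes_mode="null")
    pvals = []
    for r in range(500):
        data = simulate_trial(cfg, seed=base + r)
        report = run_mlearner_i(
            data, LearnerSpec("linear"), K=5, q=4, seed=base + r
        )
        pvals.append(report.p_combined)
    return np.asarray(pvals)


@pytest.fixture(scope="session")
def linear_comparison_table():
    """Rejection rates of the learner pipeline, the single-outcome-PRS test
    and the within-trial GWIS PES in the linear scenario at n=2000
    (100 seeded replicates, desk-scale 2000-SNP panel)."""
    cfg = SimConfig(n_rct=2000, pes_mode="linear", with_genotypes=True)
    return run_method_comparison(
        cfg,
        ["mlearner_i", "single_prs", "within_gwis"],
        replicates=100,
        seed=500,
        keep_pvalues=True,
    )


@pytest.fixture()
def toy_trial() -> "TrialDataset":
    """Small deterministic trial (n=60, 3 PRS) for structural checks."""
    from mlearner.data import TrialDataset

    rng = np.random.default_rng(42)
    n = 60
    prs = rng.standard_normal((n, 3))
    t = np.tile([0.0, 1.0], n // 2)
    y = 0.5 * prs[:, 0] + t * prs[:, 1] + rng.standard_normal(n)
    return TrialDataset(
        ids=[f"i{k:03d}" for k in range(n)],
        y=y,
        t=t,
        design_p=0.5,
        prs=prs,
        prs_labels=["PRS_A", "PRS_B", "PRS_C"],
    )
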