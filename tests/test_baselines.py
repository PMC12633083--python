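"""Comparison baselines: single-PRS modifier test, within-trial GWIS PES,
prognostic/predictive two-score model, SNP-level learner pipeline."""

import numpy as np
import pytest

from mlearner.baselines import (
    gwis_scan,
    mlearner_snp,
    prspgx,
    single_prs_interaction,
    within_gwis_pes,
)
from mlearner.data import GenotypeMatrix, TrialDataset, standardize_treatment
from mlearner.individual import LearnerSpec, run_mlearner_i
from mlearner.simulate import SimConfig, simulate_genotypes, simulate_trial


def geno_trial(n=600, J=200, seed=0, interaction=None):
    """Trial with genotypes; optional per-SNP interaction effect vector."""
    rng = np.random.default_rng(seed)
    gm = simulate_genotypes(n, J, seed=seed)
    g_std = gm.standardized()
    t = rng.binomial(1, 0.5, n).astype(float)
    t_std = standardize_treatment(t, 0.5)
    y = rng.standard_normal(n)
    if interaction is not None:
        y = y + (g_std @ interaction) * t_std
    prs = rng.standard_normal((n, 3))
    return TrialDataset(
        ids=[f"i{k}" for k in range(n)], y=y, t=t, design_p=0.5,
        prs=prs, prs_labels=["a", "b", "c"], genotypes=gm,
    )


class TestGwisScan:
    def test_matches_per_snp_ols(self):
        """Batched normal-equation solve equals column-by-column OLS."""
        data = geno_trial(n=150, J=12, seed=1)
        g_std = data.genotypes.standardized()
        t_std = standardize_treatment(data.t, 0.5)
        scan = gwis_scan(g_std, t_std, data.y)
        for j in range(12):
            x = np.column_stack(
                [np.ones(150), g_std[:, j], t_std, g_std[:, j] * t_std]
            )
            beta, *_ = np.linalg.lstsq(x, data.y, rcond=None)
            resid = data.y - x @ beta
            sigma2 = resid @ resid / (150 - 4)
            cov = sigma2 * np.linalg.inv(x.T @ x)
            assert scan.loc[j, "beta_G"] == pytest.approx(beta[1], abs=1e-8)
            assert scan.loc[j, "beta_I"] == pytest.approx(beta[3], abs=1e-8)
            assert scan.loc[j, "se_I"] == pytest.approx(np.sqrt(cov[3, 3]), abs=1e-8)


class TestSinglePrs:
    def test_model_has_four_coefficients(self):
        data = geno_trial(n=200, seed=2)
        res = single_prs_interaction(data, prs_index=0)
        assert res.details["n_params"] == 4

    def test_null_pvalues_uniform(self):
        """500 null replicates: interaction p-values approximately uniform."""
        from scipy import stats

        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(500):
            n = 300
            prs = rng.standard_normal((n, 1))
            t = rng.binomial(1, 0.5, n).astype(float)
            y = 0.3 * prs[:, 0] + rng.standard_normal(n)
            data = TrialDataset(
                ids=[str(i) for i in range(n)], y=y, t=t, design_p=0.5,
                prs=prs, prs_labels=["p0"],
            )
            pvals.append(single_prs_interaction(data, prs_index=0).p_value)
        ks = stats.ks_1samp(np.asarray(pvals), stats.uniform.cdf)
        assert ks.statistic < 0.08

    def test_correctly_specified_modifier_has_power(self):
        """When the supplied PRS equals the true effect modifier with a
        strong interaction, rejection is near-certain at n=2000."""
        rng = np.random.default_rng(4)
        rejections = 0
        for _ in range(50):
            n = 2000
            s = rng.standard_normal(n)
            t = rng.binomial(1, 0.5, n).astype(float)
            t_std = standardize_treatment(t, 0.5)
            y = np.sqrt(0.1) * s * t_std + rng.standard_normal(n) * np.sqrt(0.9)
            data = TrialDataset(
                ids=[str(i) for i in range(n)], y=y, t=t, design_p=0.5,
                prs=s[:, None], prs_labels=["s"],
            )
            rejections += single_prs_interaction(data, prs_index=0).p_value < 0.05
        assert rejections / 50 > 0.90

    def test_constant_prs_rejected(self):
        data = geno_trial(n=100, seed=5)
        with pytest.raises(ValueError, match="constant"):
            single_prs_interaction(data, prs_values=np.ones(100))


class TestWithinGwis:
    def test_split_disjoint_exhaustive(self):
        from mlearner.baselines import _split_indices

        train, test = _split_indices(101, 0.5, seed=0)
        assert len(np.intersect1d(train, test)) == 0
        assert len(train) + len(test) == 101

    def test_null_calibration(self):
        """200 null replicates: type-I error within 3 binomial SEs of 5%."""
        rejections, reps = 0, 200
        for r in range(reps):
            data = geno_trial(n=400, J=150, seed=30_000 + r)
            rejections += within_gwis_pes(data, seed=r).p_value < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_detects_strong_snp_interactions(self):
        rng = np.random.default_rng(6)
        J = 100
        beta_i = rng.normal(scale=np.sqrt(0.3 / J), size=J)
        rejections = 0
        for r in range(20):
            data = geno_trial(n=2000, J=J, seed=40_000 + r, interaction=beta_i)
            rejections += within_gwis_pes(data, seed=r).p_value < 0.05
        assert rejections >= 15


class TestPrspgx:
    def test_scores_match_loop_oracle(self):
        """Prognostic/predictive scores are G_std @ beta by construction."""
        data = geno_trial(n=60, J=10, seed=7)
        g_std = data.genotypes.standardized()
        t_std = standardize_treatment(data.t, 0.5)
        scan = gwis_scan(g_std, t_std, data.y)
        prog_oracle = np.array(
            [sum(g_std[i, j] * scan.loc[j, "beta_G"] for j in range(10))
             for i in range(60)]
        )
        pred_oracle = np.array(
            [sum(g_std[i, j] * scan.loc[j, "beta_I"] for j in range(10))
             for i in range(60)]
        )
        np.testing.assert_allclose(g_std @ scan["beta_G"], prog_oracle, atol=1e-10)
        np.testing.assert_allclose(g_std @ scan["beta_I"], pred_oracle, atol=1e-10)

    def test_null_calibration(self):
        rejections, reps = 0, 200
        for r in range(reps):
            data = geno_trial(n=400, J=120, seed=50_000 + r)
            rejections += prspgx(data, seed=r).p_value < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_recovers_generative_two_score_model(self):
        """Data generated from the two-score model with dense strong
        weights: the fitted interaction coefficient is positive and highly
        significant, and the details log the three-way split."""
        rng = np.random.default_rng(8)
        n, J = 8000, 60
        gm = simulate_genotypes(n, J, seed=8)
        g_std = gm.standardized()
        w_g = rng.normal(scale=np.sqrt(0.3 / J), size=J)
        w_i = rng.normal(scale=np.sqrt(0.3 / J), size=J)
        prog = g_std @ w_g
        pred = g_std @ w_i
        t = rng.binomial(1, 0.5, n).astype(float)
        t_std = standardize_treatment(t, 0.5)
        y = (0.3 * t_std + prog / prog.std() * 0.5
             + 0.4 * t_std * pred / pred.std()
             + rng.standard_normal(n) * 0.6)
        data = TrialDataset(
            ids=[str(i) for i in range(n)], y=y, t=t, design_p=0.5,
            prs=rng.standard_normal((n, 2)), prs_labels=["x", "y"],
            genotypes=gm,
        )
        res = prspgx(data, seed=1)
        assert res.p_value < 1e-6
        # estimated scores are noisy proxies, so allow attenuation but the
        # coefficient must sit within a few SEs of the generative value
        assert res.interaction_coef > 0.2
        assert abs(res.interaction_coef - 0.4) < 6 * res.se
        assert res.details["n_gwis"] + res.details["n_holdout"] \
            + res.details["n_test"] == n


class TestMlearnerSnp:
    def test_identical_to_prs_pipeline_on_same_features(self):
        """Running the SNP-level variant on a genotype matrix whose
        standardized dosages equal the PRS matrix reproduces the PRS
        pipeline bit-exactly."""
        rng = np.random.default_rng(9)
        n, J = 120, 6
        gm = simulate_genotypes(n, J, seed=9)
        g_std = gm.standardized()
        t = rng.binomial(1, 0.5, n).astype(float)
        y = rng.standard_normal(n)
        data = TrialDataset(
            ids=[f"i{k}" for k in range(n)], y=y, t=t, design_p=0.5,
            prs=g_std, prs_labels=list(gm.variant_ids),
            genotypes=gm, standardize_prs=False,
        )
        spec = LearnerSpec("linear")
        via_snp = mlearner_snp(data, spec, K=4, seed=13)
        via_prs = run_mlearner_i(data, spec, K=4, q=4, seed=13)
        assert via_snp.p_value == via_prs.p_values["linear"]
        assert via_snp.interaction_coef == \
            via_prs.per_learner["linear"]["blp"].beta_hat

    def test_requires_genotypes(self):
        data = geno_trial(n=100, seed=10)
        data.genotypes = None
        with pytest.raises(ValueError, match="genotype"):
            mlearner_snp(data, LearnerSpec("linear"), K=3, seed=0)

    def test_null_calibration(self):
        cfg = SimConfig(n_rct=300, n_snps=50, pes_mode="null",
                        with_genotypes=True)
        rejections, reps = 0, 200
        for r in range(reps):
            data = simulate_trial(cfg, seed=60_000 + r)
            rejections += mlearner_snp(
                data, LearnerSpec("linear"), K=5, seed=r
            ).p_value < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)
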