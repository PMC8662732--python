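"""GRM closed forms and oracle, REML behaviour, mixed-model association."""

import numpy as np
import pandas as pd
import pytest

from awmnet.gwas import (
    GRM,
    build_design,
    build_grm,
    mlm_assoc,
    reml_h2,
    subset_h2_validation,
    _profile_reml,
)
from awmnet.qc import qc_filter

from .conftest import random_genotypes


def grm_bruteforce(x):
    """Literal double-loop GCTA GRM for the oracle check."""
    n, m = x.shape
    p = x.mean(axis=0) / 2
    G = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            acc = 0.0
            for k in range(m):
                denom = 2 * p[k] * (1 - p[k])
                if i == j:
                    acc += (x[i, k] ** 2 - (1 + 2 * p[k]) * x[i, k] + 2 * p[k] ** 2) / denom
                else:
                    acc += (x[i, k] - 2 * p[k]) * (x[j, k] - 2 * p[k]) / denom
            G[i, j] = acc / m + (1.0 if i == j else 0.0)
    return G


class TestGRM:
    def test_single_snp_closed_form(self):
        # one SNP with p=0.5: G_ij = (2-1)(0-1)/(2*0.5*0.5) = -2
        from awmnet.containers import GenotypeMatrix

        meta = pd.DataFrame(
            {"snp": ["s0"], "chrom": ["1"], "pos": [100],
             "allele_counted": "B", "allele_other": "A"}
        )
        g = GenotypeMatrix(np.array([[2.0], [0.0]]), meta, ["a", "b"])
        grm = build_grm(g)
        assert grm.matrix[0, 1] == pytest.approx(-2.0)

    def test_symmetry_and_diagonal_scale(self, clean_panel):
        geno, _ = qc_filter(clean_panel[0])
        grm = build_grm(geno)
        assert np.abs(grm.matrix - grm.matrix.T).max() == 0.0
        assert 0.8 < grm.matrix.diagonal().mean() < 1.2

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        geno = random_genotypes(rng, 50, 500)
        # inject missingness: oracle runs on the mean-imputed matrix
        mask = rng.random(geno.dosage.shape) < 0.02
        geno.dosage[mask] = np.nan
        grm = build_grm(geno)
        oracle = grm_bruteforce(geno.imputed_dosage())
        assert np.abs(grm.matrix - oracle).max() < 1e-10

    def test_monomorphic_rejected(self):
        rng = np.random.default_rng(4)
        geno = random_genotypes(rng, 20, 50)
        geno.dosage[:, 0] = 2.0
        with pytest.raises(ValueError, match="monomorphic"):
            build_grm(geno)


def simulate_polygenic(rng, grm, h2, n):
    d, U = np.linalg.eigh(grm.matrix)
    d = np.maximum(d, 0.0)
    u = U @ (rng.normal(size=n) * np.sqrt(d * h2))
    return u + rng.normal(0.0, np.sqrt(1 - h2), n)


@pytest.fixture(scope="module")
def null_grm():
    rng = np.random.default_rng(5)
    geno = random_genotypes(rng, 600, 2500)
    return build_grm(geno)


class TestREML:
    def test_null_h2_concentrates_near_zero(self, null_grm):
        """sigma_u^2 = 0 truth: estimates sit near the boundary (the REML
        null distribution at n=600 keeps ~90% of its mass below 0.15)."""
        n = null_grm.n
        X = np.ones((n, 1))
        ests = []
        for seed in range(20):
            y = np.random.default_rng(seed).normal(size=n)
            ests.append(reml_h2(y, X, null_grm).h2)
        ests = np.asarray(ests)
        assert np.median(ests) < 0.05
        assert (ests < 0.15).sum() >= 18

    def test_degenerate_trait_raises(self, null_grm):
        n = null_grm.n
        X = np.column_stack([np.ones(n), np.arange(n, dtype=float)])
        y = X @ np.array([1.0, 0.5])  # exactly in the design space
        with pytest.raises(ValueError, match="residual"):
            reml_h2(y, X, null_grm)

    def test_rank_deficient_design_raises(self, null_grm):
        n = null_grm.n
        X = np.column_stack([np.ones(n), np.ones(n)])
        with pytest.raises(ValueError, match="rank"):
            reml_h2(np.random.default_rng(0).normal(size=n), X, null_grm)

    def test_recovery_at_h2_half(self, null_grm):
        rng = np.random.default_rng(17)
        n = null_grm.n
        ests = [
            reml_h2(simulate_polygenic(rng, null_grm, 0.5, n), np.ones((n, 1)), null_grm).h2
            for _ in range(10)
        ]
        assert abs(np.mean(ests) - 0.5) < 0.08

    def test_profile_is_maximised_at_estimate(self, null_grm):
        """loglik(h2 +/- 0.01) <= loglik(h2) on converged fits."""
        rng = np.random.default_rng(23)
        n = null_grm.n
        d, U = np.linalg.eigh(null_grm.matrix)
        d = np.maximum(d, 0.0)
        for _ in range(5):
            y = simulate_polygenic(rng, null_grm, 0.4, n)
            vc = reml_h2(y, np.ones((n, 1)), null_grm)
            yt, Xt = U.T @ y, U.T @ np.ones((n, 1))
            for delta in (-0.01, 0.01):
                h = np.clip(vc.h2 + delta, 1e-6, 1 - 1e-6)
                assert _profile_reml(h, d, yt, Xt)[0] <= vc.loglik + 1e-6

    def test_missing_trait_values_dropped(self, null_grm):
        rng = np.random.default_rng(29)
        n = null_grm.n
        y = simulate_polygenic(rng, null_grm, 0.4, n)
        y[:25] = np.nan
        vc = reml_h2(y, np.ones((n, 1)), null_grm)
        assert 0.0 <= vc.h2 <= 1.0 and np.isfinite(vc.loglik)


class TestMLM:
    def test_identity_grm_zero_h2_equals_ols(self):
        rng = np.random.default_rng(31)
        geno = random_genotypes(rng, 80, 60)
        n = geno.n_individuals
        grm = GRM(np.eye(n), geno.n_snps, geno.sample_ids)
        y = rng.normal(size=n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        from awmnet.gwas import VarianceComponents

        vc = VarianceComponents(0.0, 1.0, 1e-6, 0.0, 0.0)
        res = mlm_assoc(geno, y, X, grm, vc)
        S = geno.imputed_dosage()
        for j in range(geno.n_snps):
            D = np.column_stack([X, S[:, j]])
            beta = np.linalg.lstsq(D, y, rcond=None)[0][-1]
            assert res["beta"].iloc[j] == pytest.approx(beta, abs=1e-8)

    def test_planted_effect_is_detected(self):
        """A causal SNP with a standardised effect of 0.5 at n=600 is
        essentially always genome-wide significant."""
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(300 + seed)
            # large haplotype pool: mild relatedness, so the polygenic term
            # does not absorb the single-SNP signal
            geno = random_genotypes(rng, 600, 300, pool=400)
            grm = build_grm(geno)
            n = geno.n_individuals
            g = geno.dosage[:, 0]
            gz = (g - g.mean()) / g.std()
            y = 0.5 * gz + simulate_polygenic(rng, grm, 0.3, n)
            vc = reml_h2(y, np.ones((n, 1)), grm)
            res = mlm_assoc(geno, y, np.ones((n, 1)), grm, vc)
            hits += res["p"].iloc[0] < 1e-6
        assert hits == 5

    def test_zero_variance_snp_flagged_untestable(self):
        rng = np.random.default_rng(37)
        geno = random_genotypes(rng, 50, 20)
        geno.dosage[:, 3] = 1.0  # constant after imputation
        n = geno.n_individuals
        grm = GRM(np.eye(n), geno.n_snps, geno.sample_ids)
        from awmnet.gwas import VarianceComponents

        vc = VarianceComponents(0.0, 1.0, 1e-6, 0.0, 0.0)
        res = mlm_assoc(geno, rng.normal(size=n), np.ones((n, 1)), grm, vc)
        assert not res["testable"].iloc[3]
        assert np.isnan(res["p"].iloc[3])
        assert res["testable"].drop(index=3).all()

    def test_null_pvalues_uniform_ks(self, null_grm):
        """Pooled null p-values pass a KS uniformity check in most seeds."""
        from scipy import stats

        n = null_grm.n
        passes = 0
        for seed in range(5):
            rng = np.random.default_rng(600 + seed)
            geno = random_genotypes(rng, n, 450)
            y = simulate_polygenic(rng, null_grm, 0.3, n)
            vc = reml_h2(y, np.ones((n, 1)), null_grm)
            res = mlm_assoc(geno, y, np.ones((n, 1)), null_grm, vc)
            p = res["p"].dropna().to_numpy()
            passes += stats.kstest(p, "uniform").pvalue > 0.01
        assert passes >= 3


class TestDesignAndValidation:
    def test_design_uses_trait_specific_batch_factor(self, clean_panel):
        traits = clean_panel[1]
        t = traits.trait_names[0]
        X = build_design(traits, t)
        n_batch = traits.covariates["batch"].nunique()
        assert X.shape[1] == 1 + 1 + (n_batch - 1)
        assert np.linalg.matrix_rank(X) == X.shape[1]

    def test_subset_equal_to_panel_matches_whole(self, clean_panel):
        geno, traits, *_ = clean_panel
        geno, _ = qc_filter(geno)
        ids = list(geno.snp_meta["snp"])
        val = subset_h2_validation(
            geno, traits, ids, n_iter=1, seed=0, trait_names=[traits.trait_names[0]]
        )
        assert val["h2_subset"].iloc[0] == pytest.approx(val["h2_whole"].iloc[0])

    def test_validation_reproducible_and_bounded(self, clean_panel):
        geno, traits, *_ = clean_panel
        geno, _ = qc_filter(geno)
        subset = list(geno.snp_meta["snp"][:200])
        t = [traits.trait_names[0]]
        a = subset_h2_validation(geno, traits, subset, n_iter=2, seed=5, trait_names=t)
        b = subset_h2_validation(geno, traits, subset, n_iter=2, seed=5, trait_names=t)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError, match="not in panel"):
            subset_h2_validation(geno, traits, ["nope"], n_iter=1, trait_names=t)
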