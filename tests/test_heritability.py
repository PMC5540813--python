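"""Kinship algebra, variance-component likelihoods against a dense
multivariate-normal oracle, boundary behavior, and correlation recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats

from subasym import (
    BivariateVarianceComponentModel,
    PedigreeSimConfig,
    VarianceComponentModel,
    cross_ai_correlations,
    fit_bivariate_vc,
    generate_pedigrees,
    kinship_from_pedigree,
)
from subasym.heritability import validate_pedigree


def _ped(rows):
    return pd.DataFrame(rows, columns=["family_id", "individual_id",
                                       "father_id", "mother_id", "sex"])


@pytest.fixture
def three_generations():
    return _ped([
        ("f", "gp1", None, None, "M"),
        ("f", "gm1", None, None, "F"),
        ("f", "dad", "gp1", "gm1", "M"),
        ("f", "unc", "gp1", "gm1", "M"),
        ("f", "mom", None, None, "F"),
        ("f", "mom2", None, None, "F"),
        ("f", "kid1", "dad", "mom", "F"),
        ("f", "kid2", "dad", "mom", "M"),
        ("f", "half", "dad", "mom2", "F"),
    ])


class TestKinship:
    def test_pedigree_algebra(self, three_generations):
        ped = three_generations
        K = kinship_from_pedigree(ped)
        idx = {v: i for i, v in enumerate(ped["individual_id"])}

        def k(a, b):
            return K[idx[a], idx[b]]

        assert k("dad", "kid1") == 0.5          # parent-offspring
        assert k("kid1", "kid2") == 0.5         # full siblings
        assert k("dad", "unc") == 0.5           # full siblings
        assert k("kid1", "half") == 0.25        # half siblings
        assert k("gp1", "kid1") == 0.25         # grandparent-grandchild
        assert k("unc", "kid1") == 0.25         # avuncular
        assert k("mom", "dad") == 0.0           # unrelated founders
        assert np.allclose(np.diag(K), 1.0)     # non-inbred diagonal
        assert np.all(np.linalg.eigvalsh(K) > -1e-10)

    def test_order_independence(self, three_generations):
        shuffled = three_generations.sample(frac=1.0, random_state=1)
        K1 = kinship_from_pedigree(three_generations)
        ids1 = list(three_generations["individual_id"])
        K2 = kinship_from_pedigree(shuffled)
        ids2 = list(shuffled["individual_id"])
        perm = [ids2.index(i) for i in ids1]
        np.testing.assert_allclose(K1, K2[np.ix_(perm, perm)], atol=1e-12)

    def test_cycle_detected(self):
        with pytest.raises(ValueError, match="cycle"):
            validate_pedigree(_ped([
                ("f", "a", "b", "c", "M"),
                ("f", "b", "a", "c", "M"),
                ("f", "c", None, None, "F"),
            ]))

    def test_single_parent_rejected(self):
        with pytest.raises(ValueError, match="one known parent"):
            kinship_from_pedigree(_ped([
                ("f", "a", None, None, "M"),
                ("f", "b", "a", None, "F"),
            ]))


def dense_loglik_uni(y, X, beta, sigma_g2, sigma_e2, K):
    mean = X @ beta
    cov = sigma_g2 * K + sigma_e2 * np.eye(len(y))
    return stats.multivariate_normal.logpdf(y, mean=mean, cov=cov)


class TestUnivariateFit:
    def test_loglik_matches_dense_cholesky(self, small_pedigree):
        ped, phen, K, X = small_pedigree
        n = 200
        y = phen["trait_0"].to_numpy()[:n]
        m = VarianceComponentModel().fit(y, X[:n], kinship=K[:n, :n])
        Xd = np.column_stack([np.ones(n), X[:n]])
        dense = dense_loglik_uni(y, Xd, m.beta_, m.sigma2_g_, m.sigma2_e_,
                                 K[:n, :n])
        assert m.loglik_ == pytest.approx(dense, abs=1e-6)

    def test_profile_optimality(self, small_pedigree):
        ped, phen, K, X = small_pedigree
        y = phen["trait_0"].to_numpy()
        m = VarianceComponentModel().fit(y, X, kinship=K)
        lam, U = np.linalg.eigh(K)
        ytil = U.T @ y
        Xtil = U.T @ np.column_stack([np.ones(len(y)), X])
        for h in (0.0, 0.25, 0.75, 1.0):
            nll_h = VarianceComponentModel._nll(h, ytil, Xtil,
                                                np.clip(lam, 0, None))[0]
            assert m.loglik_ >= -nll_h - 1e-9
        assert m.loglik_ >= m.loglik_null_ - 1e-9

    def test_recovers_heritability(self):
        ests = []
        for seed in range(5):
            ped, phen = generate_pedigrees(
                PedigreeSimConfig(n_pedigrees=71, h2=(0.5,), seed=100 + seed))
            K = kinship_from_pedigree(ped)
            m = VarianceComponentModel().fit(
                phen["trait_0"].to_numpy(), None, kinship=K)
            ests.append(m.h2_)
        mc_se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert np.mean(ests) == pytest.approx(0.5, abs=max(3 * mc_se, 0.05))

    def test_identity_kinship_returns_zero_boundary(self, rng):
        # with K = I the likelihood is flat in h2; the fit resolves to the
        # h2 = 0 boundary with the LRT mixture p-value of 0.5
        m = VarianceComponentModel().fit(
            rng.standard_normal(150), None, kinship=np.eye(150))
        assert m.h2_ == 0.0 and m.at_boundary_
        assert m.p_ == pytest.approx(0.5)

    def test_null_trait_boundary_mass_near_half(self, rng):
        # under a structured kinship but h2 = 0 truth, the MLE lands on the
        # boundary roughly half the time (chi2 mixture behavior)
        boundary = 0
        reps = 30
        for seed in range(reps):
            ped, phen = generate_pedigrees(
                PedigreeSimConfig(n_pedigrees=10, h2=(0.0,), seed=400 + seed))
            K = kinship_from_pedigree(ped)
            m = VarianceComponentModel().fit(
                phen["trait_0"].to_numpy(), None, kinship=K)
            if m.h2_ == 0.0:
                boundary += 1
                assert m.p_ == pytest.approx(0.5)
        assert 6 <= boundary <= 24  # ~Binomial(30, 0.5) range

    def test_noiseless_genetic_trait_hits_upper_boundary(self):
        ped, phen = generate_pedigrees(
            PedigreeSimConfig(n_pedigrees=30, h2=(1.0,), seed=21))
        K = kinship_from_pedigree(ped)
        m = VarianceComponentModel().fit(phen["trait_0"].to_numpy(), None,
                                         kinship=K)
        assert m.h2_ > 0.9

    def test_null_trait_rarely_significant(self, rng):
        ped, phen = generate_pedigrees(
            PedigreeSimConfig(n_pedigrees=40, h2=(0.0,), seed=22))
        K = kinship_from_pedigree(ped)
        m = VarianceComponentModel().fit(phen["trait_0"].to_numpy(), None,
                                         kinship=K)
        assert m.p_ > 0.007

    def test_non_psd_kinship_rejected(self, rng):
        n = 20
        K = -np.eye(n)
        with pytest.raises(ValueError, match="positive semi-definite"):
            VarianceComponentModel().fit(rng.standard_normal(n), None, kinship=K)


def dense_loglik_bi(y1, y2, X, beta, G, E, K):
    n = len(y1)
    mean = np.concatenate([X @ beta[: X.shape[1]], X @ beta[X.shape[1]:]])
    cov = np.block([
        [G[0, 0] * K + E[0, 0] * np.eye(n), G[0, 1] * K + E[0, 1] * np.eye(n)],
        [G[0, 1] * K + E[0, 1] * np.eye(n), G[1, 1] * K + E[1, 1] * np.eye(n)],
    ])
    L = linalg.cholesky(cov, lower=True)
    r = np.concatenate([y1, y2]) - mean
    z = linalg.solve_triangular(L, r, lower=True)
    return -0.5 * (2 * n * np.log(2 * np.pi) + z @ z) - np.sum(np.log(np.diag(L)))


class TestBivariateFit:
    @staticmethod
    @pytest.fixture(scope="class")
    def correlated_fit():
        cfg = PedigreeSimConfig(
            n_pedigrees=12, h2=(0.6, 0.6), rho_g=0.9, rho_e=0.4,
            trait_sd=(1.0, 1.0), trait_mean=(0.0, 0.0), seed=31)
        ped, phen = generate_pedigrees(cfg)
        K = kinship_from_pedigree(ped)
        Y = phen[["trait_0", "trait_1"]].to_numpy()
        m = BivariateVarianceComponentModel().fit(Y, None, kinship=K)
        return m, Y, K

    def test_loglik_matches_dense_cholesky(self, correlated_fit):
        m, Y, K = correlated_fit
        n = len(Y)
        assert n <= 250
        Xd = np.ones((n, 1))
        dense = dense_loglik_bi(Y[:, 0], Y[:, 1], Xd, m.beta_, m.G_, m.E_, K)
        assert m.loglik_ == pytest.approx(dense, abs=1e-6)

    def test_estimates_are_correlations(self, correlated_fit):
        m, _, _ = correlated_fit
        assert -1.0 <= m.rho_g_ <= 1.0
        assert -1.0 <= m.rho_e_ <= 1.0
        assert -1.0 <= m.rho_phen_ <= 1.0
        assert np.all((0.0 <= m.h2_) & (m.h2_ <= 1.0))

    def test_identical_genetic_values_give_rho_one(self):
        ped, phen = generate_pedigrees(PedigreeSimConfig(
            n_pedigrees=40, h2=(0.7, 0.7), rho_g=1.0, rho_e=0.0,
            trait_sd=(1.0, 1.0), trait_mean=(0.0, 0.0), seed=33))
        K = kinship_from_pedigree(ped)
        m = BivariateVarianceComponentModel().fit(
            phen[["trait_0", "trait_1"]].to_numpy(), None, kinship=K)
        assert m.rho_g_ > 0.95
        assert m.p_rho1_ > 0.007  # complete pleiotropy not rejected

    def test_independent_genetic_effects_give_rho_zero(self):
        ped, phen = generate_pedigrees(PedigreeSimConfig(
            n_pedigrees=60, h2=(0.6, 0.6), rho_g=0.0, rho_e=0.0,
            trait_sd=(1.0, 1.0), trait_mean=(0.0, 0.0), seed=34))
        K = kinship_from_pedigree(ped)
        m = BivariateVarianceComponentModel().fit(
            phen[["trait_0", "trait_1"]].to_numpy(), None, kinship=K)
        assert abs(m.rho_g_) < 0.25
        assert m.p_rho0_ > 0.01

    def test_phenotypic_correlation_matches_empirical(self):
        cfg = PedigreeSimConfig(
            n_pedigrees=71, h2=(0.627, 0.627), rho_g=0.899, rho_e=0.58,
            trait_sd=(600.0, 600.0), trait_mean=(5500.0, 5500.0), seed=35)
        ped, phen = generate_pedigrees(cfg)
        K = kinship_from_pedigree(ped)
        Y = phen[["trait_0", "trait_1"]].to_numpy()
        m = BivariateVarianceComponentModel().fit(Y, None, kinship=K)
        emp = np.corrcoef(Y[:, 0], Y[:, 1])[0, 1]
        assert m.rho_phen_ == pytest.approx(emp, abs=0.05)


class TestCrossTraitTable:
    def test_independent_traits_cover_zero(self, rng):
        ped, phen = generate_pedigrees(PedigreeSimConfig(
            n_pedigrees=30, h2=(0.5,), seed=36))
        K = kinship_from_pedigree(ped)
        n = len(phen)
        traits = pd.DataFrame({
            "a": phen["trait_0"],
            "b": rng.standard_normal(n),
            "c": rng.standard_normal(n),
        })
        X = np.column_stack([phen["age_years"],
                             (phen["sex"] == "M").astype(float)])
        table = cross_ai_correlations(traits, X, K)
        assert len(table) == 3
        ok = (table["p_rho0"] > 0.01) | (
            np.abs(table["rho_g"]) < 2.5 * table["rho_g_se"])
        assert ok.all()
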