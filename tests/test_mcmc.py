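"""Gibbs samplers: bookkeeping, oracle equivalence, recovery, reproducibility."""

import numpy as np
import pytest

import boapred as bp
from boapred.mcmc import (
    BoaPriors,
    CovariancePrior,
    McmcSettings,
    VariancePrior,
    heuristic_variances,
)


def _ridge_data(seed, n=120, m=150, s2u=0.01, s2e=1.0):
    rng = np.random.default_rng(seed)
    Z = rng.normal(size=(n, m))
    Z -= Z.mean(axis=0)
    u = rng.normal(0, np.sqrt(s2u), m)
    y = 3.0 + Z @ u + rng.normal(0, np.sqrt(s2e), n)
    return y, Z, s2u, s2e


class TestSettingsAndPriors:
    def test_retained_sample_formula(self):
        assert McmcSettings(100, 20, 10).n_retained == 8
        assert McmcSettings(1000, 100, 7).n_retained == (1000 - 100) // 7

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            McmcSettings(n_cycles=100, burn_in=100)
        with pytest.raises(ValueError):
            McmcSettings(thin=0)

    def test_variance_prior_scale_formula(self):
        # S = old * (df - 2) / df: 0.01 with df 4 -> 0.005
        assert VariancePrior(0.01, df=4).scale == pytest.approx(0.005)
        with pytest.raises(ValueError):
            VariancePrior(0.01, df=2.0)

    def test_covariance_prior_scale_is_twice_old_for_three_breeds(self):
        B_old = np.array([[2.0, 0.5, 0.0], [0.5, 1.0, 0.2], [0.0, 0.2, 1.5]])
        prior = CovariancePrior(B_old, nu=6)
        np.testing.assert_allclose(prior.V, 2.0 * B_old)
        with pytest.raises(ValueError):
            CovariancePrior(B_old, nu=4.0)  # nu must exceed K + 1
        with pytest.raises(ValueError):
            CovariancePrior(np.array([[1.0, 2.0], [2.0, 1.0]]))  # not PD

    def test_tiny_chain_retains_formula_count(self):
        y, Z, s2u, s2e = _ridge_data(0, n=30, m=10)
        st = McmcSettings(200, 50, 7, seed=1)
        fit = bp.fit_within_breed(y, Z, VariancePrior(s2u), VariancePrior(s2e), st)
        assert fit.variance_samples["sigma2_e"].size == st.n_retained
        assert fit.diagnostics["n_retained"] == (200 - 50) // 7


class TestWithinBreed:
    def test_fixed_variance_posterior_mean_solves_ridge(self):
        y, Z, s2u, s2e = _ridge_data(3)
        fit = bp.fit_within_breed(
            y, Z, VariancePrior(s2u), VariancePrior(s2e),
            McmcSettings(8000, 1000, 2, seed=5), update_variances=False,
        )
        lam = s2e / s2u
        direct = np.linalg.solve(Z.T @ Z + lam * np.eye(Z.shape[1]), Z.T @ (y - y.mean()))
        assert np.corrcoef(fit.u_hat, direct)[0, 1] > 0.999
        assert np.polyfit(direct, fit.u_hat, 1)[0] == pytest.approx(1.0, abs=0.02)

    def test_constant_response_gives_null_effects(self):
        rng = np.random.default_rng(1)
        Z = rng.normal(size=(80, 40))
        y = np.full(80, 2.5)
        fit = bp.fit_within_breed(
            y, Z, VariancePrior(0.01), VariancePrior(1.0),
            McmcSettings(4000, 500, 2, seed=2), update_variances=False,
        )
        # Monte-Carlo noise only: posterior sd / sqrt(ESS) scale
        assert np.abs(fit.u_hat).max() < 0.05
        assert fit.mu_hat == pytest.approx(2.5, abs=0.05)

    def test_residual_variance_recovered_within_20_percent(self):
        rng = np.random.default_rng(8)
        n, m = 2000, 250
        Z = rng.binomial(2, rng.uniform(0.1, 0.9, m), size=(n, m)).astype(float)
        Z -= Z.mean(axis=0)
        s2u_true = 1.0 / m
        u = rng.normal(0, np.sqrt(s2u_true), m)
        y = 1.0 + Z @ u + rng.normal(0, 1.0, n)
        s2u0, s2e0 = heuristic_variances(y, Z)
        fit = bp.fit_within_breed(
            y, Z, VariancePrior(s2u0), VariancePrior(s2e0), McmcSettings.desk(seed=3)
        )
        assert fit.variance_samples["sigma2_e"].mean() == pytest.approx(1.0, rel=0.2)

    def test_marker_permutation_equivariance(self):
        y, Z, s2u, s2e = _ridge_data(5, n=100, m=60)
        st = McmcSettings(6000, 1000, 2, seed=4)
        fit = bp.fit_within_breed(
            y, Z, VariancePrior(s2u), VariancePrior(s2e), st, update_variances=False
        )
        perm = np.random.default_rng(0).permutation(60)
        fit_p = bp.fit_within_breed(
            y, Z[:, perm], VariancePrior(s2u), VariancePrior(s2e), st,
            update_variances=False,
        )
        # same posterior up to Monte-Carlo noise, permuted
        assert np.corrcoef(fit.u_hat[perm], fit_p.u_hat)[0, 1] > 0.999

    def test_input_validation(self):
        with pytest.raises(ValueError, match="two records"):
            bp.fit_within_breed(
                np.array([1.0]), np.ones((1, 2)), VariancePrior(0.1),
                VariancePrior(1.0), McmcSettings.desk(),
            )
        with pytest.raises(ValueError, match="finite"):
            bp.fit_within_breed(
                np.array([1.0, np.nan, 2.0]), np.ones((3, 2)), VariancePrior(0.1),
                VariancePrior(1.0), McmcSettings.desk(),
            )


def _boa_toy(seed, n_per=60, n_cross=80, m=80):
    cfg = bp.SimConfig(
        n_markers=m, n_qtl=m, n_purebred_per_breed=n_per, seed=seed,
        crossbred_design=(
            bp.CrossSpec("F1", "CH", "LM", n_cross // 2),
            bp.CrossSpec("X2", "CH", "OT", n_cross // 2),
        ),
    )
    ds = bp.simulate(cfg)
    idx = np.arange(ds.genotypes.n_animals)
    freqs = bp.breed_allele_freqs(ds.genotypes, ds.origins, idx)
    parts = bp.build_partial_genotypes(ds.genotypes, ds.origins, freqs)
    return ds, parts


class TestBoa:
    def test_fixed_diagonal_B_matches_uncorrelated_mode(self):
        ds, parts = _boa_toy(21)
        y = ds.adjusted_phenotypes
        s2u = 2e-3
        priors = BoaPriors(
            snp=[VariancePrior(s2u)] * 3,
            residual=VariancePrior(1.0),
            covariance=CovariancePrior(np.eye(3) * s2u),
        )
        st = McmcSettings(6000, 1000, 2, seed=9)
        unc = bp.fit_boa(y, parts.X, parts, "uncorrelated", priors, st,
                         update_variances=False)
        cor = bp.fit_boa(y, parts.X, parts, "correlated", priors, st,
                         update_B=False, update_variances=False)
        for k in range(3):
            assert np.corrcoef(unc.u_hat[:, k], cor.u_hat[:, k])[0, 1] > 0.99
        np.testing.assert_allclose(unc.b_hat, cor.b_hat, atol=0.08)

    def test_B_draws_stay_symmetric_positive_definite(self):
        ds, parts = _boa_toy(22)
        priors = BoaPriors(
            snp=[VariancePrior(2e-3)] * 3,
            residual=VariancePrior(1.0),
            covariance=CovariancePrior(np.eye(3) * 2e-3),
        )
        fit = bp.fit_boa(
            ds.adjusted_phenotypes, parts.X, parts, "correlated", priors,
            McmcSettings(800, 200, 3, seed=1),
        )
        for B in fit.variance_samples["B"]:
            np.testing.assert_allclose(B, B.T)
            np.linalg.cholesky(B)

    def test_identical_seed_gives_bit_identical_chain(self):
        ds, parts = _boa_toy(23, n_per=30, n_cross=30, m=40)
        priors = BoaPriors(
            snp=[VariancePrior(2e-3)] * 3,
            residual=VariancePrior(1.0),
            covariance=CovariancePrior(np.eye(3) * 2e-3),
        )
        st = McmcSettings(400, 100, 2, seed=77)
        a = bp.fit_boa(ds.adjusted_phenotypes, parts.X, parts, "correlated", priors, st)
        b = bp.fit_boa(ds.adjusted_phenotypes, parts.X, parts, "correlated", priors, st)
        assert np.array_equal(a.u_hat, b.u_hat)
        assert np.array_equal(a.variance_samples["B"], b.variance_samples["B"])

    def test_gbp_rows_must_sum_to_one(self):
        ds, parts = _boa_toy(24, n_per=20, n_cross=20, m=30)
        priors = BoaPriors(snp=[VariancePrior(1e-3)] * 3, residual=VariancePrior(1.0))
        badX = parts.X + 0.2
        with pytest.raises(ValueError, match="sum to 1"):
            bp.fit_boa(ds.adjusted_phenotypes, badX, parts, "uncorrelated",
                       priors, McmcSettings.desk())

    def test_purebred_only_boa_tracks_within_breed_solutions(self):
        # with a purebred-only reference and uncorrelated effects, the
        # multi-breed model is near-equivalent to per-breed ridge fits
        ds, parts = _boa_toy(25, n_per=120, n_cross=60, m=120)
        ped = ds.pedigree
        pos = {a: i for i, a in enumerate(ds.genotypes.animal_ids)}
        y = ds.adjusted_phenotypes
        pure_idx = np.array([pos[a] for a in ped.loc[ped["is_purebred"], "animal"]])
        cross_idx = np.array([pos[a] for a in ped.loc[~ped["is_purebred"], "animal"]])
        freqs_p = bp.breed_allele_freqs(ds.genotypes, ds.origins, pure_idx)
        parts_p = bp.build_partial_genotypes(ds.genotypes, ds.origins, freqs_p)
        priors = BoaPriors(snp=[VariancePrior(2e-3)] * 3, residual=VariancePrior(1.0))
        st = McmcSettings(5000, 1000, 4, seed=3)
        boa = bp.fit_boa(y[pure_idx], parts_p.X[pure_idx],
                         parts_p.subset(pure_idx), "uncorrelated", priors, st)
        within = {}
        for k, label in enumerate(("CH", "LM", "OT")):
            sub = np.array([pos[a] for a in ped.loc[
                ped["is_purebred"] & (ped["breed_label"] == label), "animal"]])
            cg = bp.center_genotypes(ds.genotypes, sub)
            fit = bp.fit_within_breed(
                y[sub], cg.Z[sub], VariancePrior(2e-3), VariancePrior(1.0), st
            )
            fit.centering_freqs = cg.freqs
            within[label] = fit
        ids = [ds.genotypes.animal_ids[i] for i in cross_idx]
        pgm_boa = bp.predict_boa(boa, parts_p.subset(cross_idx), ids)["pgm"]
        pgm_bom = bp.predict_bom(within, parts_p.subset(cross_idx), ids)["pgm"]
        assert np.corrcoef(pgm_boa, pgm_bom)[0, 1] > 0.95


class TestJoint:
    def test_single_breed_collapses_to_within_breed(self):
        y, Z, s2u, s2e = _ridge_data(31, n=90, m=50)
        st = McmcSettings(5000, 1000, 2, seed=6)
        w = bp.fit_within_breed(y, Z, VariancePrior(s2u), VariancePrior(s2e), st,
                                update_variances=False)
        X = np.ones((y.size, 1))
        j = bp.fit_joint(y, X, Z, VariancePrior(s2u), VariancePrior(s2e), st,
                         update_variances=False)
        assert np.corrcoef(w.u_hat, j.u_hat)[0, 1] > 0.999
        assert j.b_hat[0] == pytest.approx(w.mu_hat, abs=0.05)

    def test_retained_count_formula_holds(self):
        y, Z, s2u, s2e = _ridge_data(32, n=40, m=20)
        st = McmcSettings(300, 60, 4, seed=1)
        j = bp.fit_joint(y, np.ones((40, 1)), Z, VariancePrior(s2u),
                         VariancePrior(s2e), st)
        assert j.variance_samples["sigma2_e"].size == st.n_retained


class TestPilot:
    def test_deterministic_given_seed(self):
        ds, parts = _boa_toy(41, n_per=25, n_cross=20, m=30)
        st = McmcSettings(300, 50, 3, seed=12)
        a = bp.pilot_variances(ds.adjusted_phenotypes, parts.X, parts, st)
        b = bp.pilot_variances(ds.adjusted_phenotypes, parts.X, parts, st)
        np.testing.assert_array_equal(a.sigma2_u, b.sigma2_u)
        assert a.sigma2_e == b.sigma2_e

    def test_pilot_seeds_parameterize_priors(self):
        ds, parts = _boa_toy(42, n_per=25, n_cross=20, m=30)
        pv = bp.pilot_variances(
            ds.adjusted_phenotypes, parts.X, parts, McmcSettings(300, 50, 3, seed=1)
        )
        prior = VariancePrior(float(pv.sigma2_u[0]))
        assert prior.scale == pytest.approx(pv.sigma2_u[0] / 2)
        cov = CovariancePrior(pv.B_old)
        np.testing.assert_allclose(cov.V, 2 * pv.B_old)
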