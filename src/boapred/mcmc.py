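"""Gibbs-sampling estimation of SNP effects.

Three model families share the machinery here:

* the within-breed Bayesian ridge  y* = 1 mu + Z u + e, with
  u | s2u ~ N(0, I s2u) and scaled-inverse-chi-square priors on both
  variances (SNP-BLUP with unknown variances),
* the multi-breed BOA model  y* = X b + Z_CH u_CH + Z_LM u_LM +
  Z_OT u_OT + e, with breed-specific SNP variances (uncorrelated mode)
  or a full across-breed covariance matrix B with an inverse-Wishart
  prior (correlated mode), and
* the joint single-component model  y* = X b + Z u + e over the combined
  purebred + crossbred data, ignoring breed-of-origin.

Because the GBP rows of X sum to one, a separate global intercept would
be confounded with the breed means; the implementation therefore absorbs
mu into b and reports the fitted breed means, which is what the
predictors consume.  Within-breed fits use a plain intercept.

All samplers are single-site Gibbs with residual updating; the
correlated mode updates the per-locus breed vector jointly (small
Cholesky solve), which mixes better than scalar-wise updates and is an
equally valid Gibbs scheme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import invwishart

from . import _gibbs
from .breedorigin import CenteredGenotypes, PartialGenotypeSet

logger = logging.getLogger(__name__)

#: How often the residual vector is recomputed from scratch to cancel
#: accumulated floating-point drift of the incremental updates.
_REFRESH_EVERY = 500


@dataclass
class McmcSettings:
    """Chain length bookkeeping.

    The defaults mirror a full production run (100,000 cycles, 20,000
    burn-in, thinning 10, hence 8,000 retained samples per parameter);
    :meth:`desk` returns a scaled-down profile for interactive work.
    """

    n_cycles: int = 100_000
    burn_in: int = 20_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_cycles:
            raise ValueError("burn_in must be smaller than n_cycles")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_cycles - self.burn_in) // self.thin

    @classmethod
    def desk(cls, seed: int = 0) -> "McmcSettings":
        return cls(n_cycles=5_000, burn_in=1_000, thin=5, seed=seed)


@dataclass
class VariancePrior:
    """Scaled-inverse-chi-square prior parameterized by a prior estimate.

    The scale is S = old_variance * (df - 2) / df, which puts the prior
    mode near the earlier estimate; df must exceed 2 for S to be positive.
    """

    old_variance: float
    df: float = 4.0

    def __post_init__(self) -> None:
        if self.df <= 2:
            raise ValueError("df must exceed 2")
        if self.old_variance <= 0:
            raise ValueError("old_variance must be positive")

    @property
    def scale(self) -> float:
        return self.old_variance * (self.df - 2.0) / self.df


@dataclass
class CovariancePrior:
    """Inverse-Wishart prior for the across-breed SNP covariance B.

    The scale matrix is V_B = (nu - K - 1) * B_old for K breeds, so the
    prior mean of B equals the earlier estimate B_old; nu must exceed
    K + 1 for V_B to be positive-definite.
    """

    B_old: np.ndarray
    nu: float = 6.0

    def __post_init__(self) -> None:
        self.B_old = np.asarray(self.B_old, dtype=np.float64)
        K = self.B_old.shape[0]
        if self.B_old.shape != (K, K) or not np.allclose(self.B_old, self.B_old.T):
            raise ValueError("B_old must be symmetric")
        if self.nu <= K + 1:
            raise ValueError("nu must exceed n_breeds + 1")
        np.linalg.cholesky(self.B_old)  # raises if not PD

    @property
    def V(self) -> np.ndarray:
        K = self.B_old.shape[0]
        return (self.nu - K - 1.0) * self.B_old


@dataclass
class BoaPriors:
    """Prior bundle for the multi-breed BOA model."""

    snp: Sequence[VariancePrior]
    residual: VariancePrior
    covariance: CovariancePrior | None = None


@dataclass
class PosteriorFit:
    """Posterior summaries of one Gibbs run.

    ``u_hat`` is (n_markers,) for single-component models and
    (n_markers, n_breeds) for the BOA model.  ``variance_samples`` holds
    the retained draws ('sigma2_e', 'sigma2_u' and, in correlated mode,
    'B' with shape (S, K, K)).
    """

    u_hat: np.ndarray
    b_hat: np.ndarray | None
    mu_hat: float | None
    breeds: tuple[str, ...] | None
    variance_samples: dict[str, np.ndarray]
    settings: McmcSettings
    diagnostics: dict[str, object] = field(default_factory=dict)
    centering_freqs: np.ndarray | None = None

    def snp_effect_correlations(self) -> np.ndarray:
        """Posterior mean of the per-pair correlations implied by B draws."""
        if "B" not in self.variance_samples:
            raise ValueError("no B samples: fit was not run in correlated mode")
        B = self.variance_samples["B"]
        d = np.sqrt(np.einsum("skk->sk", B))
        corr = B / (d[:, :, None] * d[:, None, :])
        return corr.mean(axis=0)


def effective_sample_size(x: np.ndarray) -> float:
    """ESS from the initial-positive-sequence autocorrelation estimator."""
    x = np.asarray(x, dtype=np.float64)
    S = x.size
    if S < 4 or np.var(x) == 0:
        return float(S)
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * S)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:S].real / S
    rho = acov / acov[0]
    # sum consecutive pairs while they stay positive (Geyer)
    tau = 1.0
    for t in range(1, S - 1, 2):
        pair = rho[t] + rho[t + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
    return float(S / tau)


def _as_matrix(Z) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(Z, CenteredGenotypes):
        return np.asarray(Z.Z, dtype=np.float64), Z.freqs
    return np.asarray(Z, dtype=np.float64), None


def _validate_response(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=np.float64)
    if y.size < 2:
        raise ValueError("need at least two records")
    if not np.isfinite(y).all():
        raise ValueError("phenotypes contain non-finite values")
    return y


def _run_single_component(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    snp_prior: VariancePrior,
    residual_prior: VariancePrior,
    settings: McmcSettings,
    update_variances: bool,
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray], dict[str, object]]:
    n, m = Z.shape
    p = X.shape[1]
    Zt = np.ascontiguousarray(Z.T)
    zz = np.einsum("ji,ji->j", Zt, Zt)
    Xt = np.ascontiguousarray(X.T)
    xx = np.einsum("ji,ji->j", Xt, Xt)
    if (xx == 0).any():
        raise ValueError("design matrix has an empty column")
    rng = np.random.default_rng(settings.seed)

    s2u = snp_prior.old_variance
    s2e = residual_prior.old_variance
    u = np.zeros(m)
    b = np.zeros(p)
    e = y.copy()
    S = settings.n_retained
    u_sum = np.zeros(m)
    b_sum = np.zeros(p)
    s2u_draws = np.empty(S)
    s2e_draws = np.empty(S)
    kept = 0
    for cycle in range(1, settings.n_cycles + 1):
        _gibbs.sweep_fixed(Xt, xx, e, b, s2e, rng.standard_normal(p))
        _gibbs.sweep_effects_single(Zt, zz, e, u, s2e / s2u, s2e, rng.standard_normal(m))
        if update_variances:
            s2u = (u @ u + snp_prior.df * snp_prior.scale) / rng.chisquare(snp_prior.df + m)
            s2e = (e @ e + residual_prior.df * residual_prior.scale) / rng.chisquare(residual_prior.df + n)
        if cycle > settings.burn_in and (cycle - settings.burn_in) % settings.thin == 0:
            u_sum += u
            b_sum += b
            s2u_draws[kept] = s2u
            s2e_draws[kept] = s2e
            kept += 1
        if cycle % _REFRESH_EVERY == 0:
            e = y - X @ b - Z @ u
    assert kept == S
    samples = {"sigma2_u": s2u_draws, "sigma2_e": s2e_draws}
    diag = {
        "n_retained": S,
        "ess": {k: effective_sample_size(v) for k, v in samples.items()},
    }
    return u_sum / S, b_sum / S, samples, diag


def fit_within_breed(
    y_star: np.ndarray,
    Z: CenteredGenotypes | np.ndarray,
    snp_prior: VariancePrior,
    residual_prior: VariancePrior,
    settings: McmcSettings,
    update_variances: bool = True,
) -> PosteriorFit:
    """Within-breed Bayesian ridge: y* = 1 mu + Z u + e.

    With ``update_variances=False`` both variances stay fixed at the
    priors' ``old_variance`` values and the posterior mean of u converges
    to the ridge (SNP-BLUP) solution.
    """
    y = _validate_response(y_star)
    Zm, freqs = _as_matrix(Z)
    if Zm.shape[0] != y.size:
        raise ValueError("rows of Z must match the number of records")
    X = np.ones((y.size, 1))
    u_hat, b_hat, samples, diag = _run_single_component(
        y, X, Zm, snp_prior, residual_prior, settings, update_variances
    )
    return PosteriorFit(
        u_hat=u_hat,
        b_hat=None,
        mu_hat=float(b_hat[0]),
        breeds=None,
        variance_samples=samples,
        settings=settings,
        diagnostics=diag,
        centering_freqs=freqs,
    )


def fit_joint(
    y_star: np.ndarray,
    X: np.ndarray,
    Z: CenteredGenotypes | np.ndarray,
    snp_prior: VariancePrior,
    residual_prior: VariancePrior,
    settings: McmcSettings,
    breeds: Sequence[str] | None = None,
    update_variances: bool = True,
) -> PosteriorFit:
    """Joint single-component model over all animals: y* = X b + Z u + e.

    Breed-mean fixed effects are retained through X (GBP rows), but a
    single vector of SNP effects ignores breed-of-origin.
    """
    y = _validate_response(y_star)
    Zm, freqs = _as_matrix(Z)
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] != y.size or Zm.shape[0] != y.size:
        raise ValueError("X and Z must have one row per record")
    u_hat, b_hat, samples, diag = _run_single_component(
        y, X, Zm, snp_prior, residual_prior, settings, update_variances
    )
    return PosteriorFit(
        u_hat=u_hat,
        b_hat=b_hat,
        mu_hat=None,
        breeds=tuple(breeds) if breeds is not None else None,
        variance_samples=samples,
        settings=settings,
        diagnostics=diag,
        centering_freqs=freqs,
    )


def _boa_design(Z_by_breed, breeds):
    if isinstance(Z_by_breed, PartialGenotypeSet):
        return np.asarray(Z_by_breed.Z, dtype=np.float64), Z_by_breed.breeds
    if isinstance(Z_by_breed, Mapping):
        if breeds is None:
            breeds = tuple(Z_by_breed)
        Z = np.stack([np.asarray(Z_by_breed[k], dtype=np.float64) for k in breeds])
        return Z, tuple(breeds)
    Z = np.asarray(Z_by_breed, dtype=np.float64)
    if breeds is None:
        breeds = tuple(f"breed{k}" for k in range(Z.shape[0]))
    return Z, tuple(breeds)


def fit_boa(
    y_star: np.ndarray,
    X: np.ndarray,
    Z_by_breed: PartialGenotypeSet | Mapping[str, np.ndarray] | np.ndarray,
    mode: str,
    priors: BoaPriors,
    settings: McmcSettings,
    breeds: Sequence[str] | None = None,
    update_variances: bool = True,
    update_B: bool = True,
) -> PosteriorFit:
    """Multi-breed BOA model: y* = X b + sum_k Z_k u_k + e.

    ``mode`` is 'uncorrelated' (independent per-breed SNP variances) or
    'correlated' (full across-breed covariance B with an inverse-Wishart
    update).  In correlated mode a non-positive-definite full-conditional
    scale is an error that names the offending cycle, never a silent
    regularization.
    """
    if mode not in ("uncorrelated", "correlated"):
        raise ValueError("mode must be 'uncorrelated' or 'correlated'")
    y = _validate_response(y_star)
    Z, breeds = _boa_design(Z_by_breed, breeds)
    K, n, m = Z.shape
    if n != y.size:
        raise ValueError("Z_by_breed rows must match the number of records")
    X = np.asarray(X, dtype=np.float64)
    if X.shape != (n, K):
        raise ValueError("X must be (n_records, n_breeds)")
    if not np.allclose(X.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("GBP rows of X must sum to 1")
    if len(priors.snp) != K:
        raise ValueError("need one SNP variance prior per breed")
    if mode == "correlated" and priors.covariance is None:
        raise ValueError("correlated mode needs a CovariancePrior")

    Zts = np.ascontiguousarray(Z.transpose(0, 2, 1))  # (K, m, n)
    zz = np.einsum("kji,kji->kj", Zts, Zts)
    Xt = np.ascontiguousarray(X.T)
    xx = np.einsum("ji,ji->j", Xt, Xt)
    rng = np.random.default_rng(settings.seed)

    s2u = np.array([pr.old_variance for pr in priors.snp])
    s2e = priors.residual.old_variance
    res_prior = priors.residual
    correlated = mode == "correlated"
    if correlated:
        W = np.ascontiguousarray(np.einsum("kji,lji->jkl", Zts, Zts))
        B = priors.covariance.B_old.copy()
        Binv = np.linalg.inv(B)
        V_B = priors.covariance.V
        nu = priors.covariance.nu
        work = np.empty((2, K, K))

    U = np.zeros((m, K))
    b = np.zeros(K)
    e = y.copy()
    S = settings.n_retained
    U_sum = np.zeros((m, K))
    b_sum = np.zeros(K)
    s2e_draws = np.empty(S)
    s2u_draws = np.empty((S, K))
    B_draws = np.empty((S, K, K)) if correlated else None
    kept = 0
    for cycle in range(1, settings.n_cycles + 1):
        _gibbs.sweep_fixed(Xt, xx, e, b, s2e, rng.standard_normal(K))
        if correlated:
            bad = _gibbs.sweep_effects_correlated(
                Zts, W, e, U, Binv, s2e, rng.standard_normal((m, K)), work
            )
            if bad >= 0:
                raise RuntimeError(
                    f"non-positive-definite full conditional at cycle {cycle}, locus {bad}"
                )
            if update_B:
                scale = V_B + U.T @ U
                try:
                    np.linalg.cholesky(scale)
                except np.linalg.LinAlgError as exc:
                    raise RuntimeError(
                        f"non-positive-definite inverse-Wishart scale at cycle {cycle}"
                    ) from exc
                B = invwishart.rvs(df=nu + m, scale=scale, random_state=rng)
                Binv = np.linalg.inv(B)
        else:
            for k in range(K):
                _gibbs.sweep_effects_single(
                    Zts[k], zz[k], e, U[:, k], s2e / s2u[k], s2e, rng.standard_normal(m)
                )
            if update_variances:
                for k in range(K):
                    pr = priors.snp[k]
                    s2u[k] = (U[:, k] @ U[:, k] + pr.df * pr.scale) / rng.chisquare(pr.df + m)
        if update_variances:
            s2e = (e @ e + res_prior.df * res_prior.scale) / rng.chisquare(res_prior.df + n)
        if cycle > settings.burn_in and (cycle - settings.burn_in) % settings.thin == 0:
            U_sum += U
            b_sum += b
            s2e_draws[kept] = s2e
            if correlated:
                B_draws[kept] = B
                s2u_draws[kept] = np.diag(B)
            else:
                s2u_draws[kept] = s2u
            kept += 1
        if cycle % _REFRESH_EVERY == 0:
            e = y - X @ b - np.einsum("knm,mk->n", Z, U)
    assert kept == S
    samples = {"sigma2_u": s2u_draws, "sigma2_e": s2e_draws}
    if correlated:
        samples["B"] = B_draws
    diag = {
        "n_retained": S,
        "ess": {
            "sigma2_e": effective_sample_size(s2e_draws),
            "sigma2_u": [effective_sample_size(s2u_draws[:, k]) for k in range(K)],
        },
    }
    return PosteriorFit(
        u_hat=U_sum / S,
        b_hat=b_sum / S,
        mu_hat=None,
        breeds=breeds,
        variance_samples=samples,
        settings=settings,
        diagnostics=diag,
    )


@dataclass
class PilotVariances:
    """Old-variance seeds for the main run's priors."""

    sigma2_u: np.ndarray  # per breed (length 1 for single-component models)
    sigma2_e: float
    B_old: np.ndarray  # diagonal when the pilot was uncorrelated


def heuristic_variances(y: np.ndarray, Z: np.ndarray) -> tuple[float, float]:
    """Variance-partition fallback: half of var(y) to markers, half residual."""
    vy = float(np.var(y))
    if vy == 0:
        vy = 1.0
    col_var = float(np.sum(np.var(Z, axis=0)))
    s2u = 0.5 * vy / max(col_var, 1e-12)
    return s2u, 0.5 * vy


def pilot_variances(
    y_star: np.ndarray,
    X: np.ndarray | None,
    Z,
    short_settings: McmcSettings,
) -> PilotVariances:
    """Short-chain posterior means used to parameterize the main priors.

    With ``X=None`` and a single Z matrix, runs a short within-breed
    chain; otherwise a short uncorrelated BOA chain.  Starting values come
    from the variance-partition heuristic (logged), and the returned
    B_old is diagonal with the per-breed pilot SNP variances.
    """
    y = _validate_response(y_star)
    if X is None:
        Zm, _ = _as_matrix(Z)
        s2u0, s2e0 = heuristic_variances(y, Zm)
        logger.info("pilot start from heuristic: s2u=%.4g s2e=%.4g", s2u0, s2e0)
        fit = fit_within_breed(
            y, Zm, VariancePrior(s2u0), VariancePrior(s2e0), short_settings
        )
        s2u = np.array([fit.variance_samples["sigma2_u"].mean()])
        s2e = float(fit.variance_samples["sigma2_e"].mean())
        return PilotVariances(s2u, s2e, np.diag(s2u))
    Zarr, breeds = _boa_design(Z, None)
    K = Zarr.shape[0]
    starts = []
    for k in range(K):
        s2u0, s2e0 = heuristic_variances(y, Zarr[k])
        starts.append(s2u0 / K)
    _, s2e0 = heuristic_variances(y, Zarr[0])
    logger.info("pilot start from heuristic: s2u=%s s2e=%.4g", starts, s2e0)
    priors = BoaPriors(
        snp=[VariancePrior(s) for s in starts], residual=VariancePrior(s2e0)
    )
    fit = fit_boa(y, X, Zarr, "uncorrelated", priors, short_settings, breeds=breeds)
    s2u = fit.variance_samples["sigma2_u"].mean(axis=0)
    s2e = float(fit.variance_samples["sigma2_e"].mean())
    return PilotVariances(s2u, s2e, np.diag(s2u))
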