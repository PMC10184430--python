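"""Predictors of genetic merit (PGM) for the four method families.

* BPM weights each within-breed SNP solution by the animal's genomic
  breed proportions: PGM_i = sum_k GBP_ik * m_i' u_k + sum_k GBP_ik b_k,
  with m_i centered using breed k's reference frequencies inside the
  breed-k term (which makes the purebred identity with BOM exact).
* BOM applies within-breed solutions to the breed-specific allele
  contents: PGM_i = sum_k z_ik' u_k + sum_k GBP_ik b_k.
* BOA uses the same form with the multi-breed model's solutions and
  fitted breed means.
* The joint model uses a single SNP-effect vector plus X b.

For single-breed fits the "mean effect of breed k" is the fit's
intercept; for the BOA and joint models it is the fitted breed mean.
PGM computation never consults the phenotypes of the target animals.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .breedorigin import PartialGenotypeSet
from .mcmc import PosteriorFit
from .simulate import PhasedGenotypes

#: Canonical method labels.
METHODS = ("BPM", "BOM", "BOA_UNCOR", "BOA_COR", "JOINT")


def pgm_table(animal_ids: Sequence[str], method: str, pgm: np.ndarray) -> pd.DataFrame:
    """One row per animal for one method: (animal_id, method, pgm)."""
    pgm = np.asarray(pgm, dtype=np.float64)
    if not np.isfinite(pgm).all():
        raise ValueError("PGM values must be finite")
    return pd.DataFrame({"animal_id": list(animal_ids), "method": method, "pgm": pgm})


def _check_fits(within_fits: Mapping[str, PosteriorFit], breeds: Sequence[str]) -> None:
    missing = [b for b in breeds if b not in within_fits]
    if missing:
        raise ValueError(f"missing within-breed fits for: {missing}")


def _breed_mean_term(X: np.ndarray, b_by_breed: np.ndarray) -> np.ndarray:
    return X @ b_by_breed


def predict_bpm(
    within_fits: Mapping[str, PosteriorFit],
    genotypes: PhasedGenotypes,
    X: np.ndarray,
    breeds: Sequence[str],
    method: str = "BPM",
) -> pd.DataFrame:
    """Breed-proportion-weighted combination of within-breed solutions.

    Each within-breed fit must carry ``centering_freqs`` (the reference
    frequencies its Z was centered with), so the genotype-content term
    for breed k is (m_i - 2 p_k)' u_k.
    """
    _check_fits(within_fits, breeds)
    X = np.asarray(X, dtype=np.float64)
    dos = genotypes.dosages()
    if X.shape != (dos.shape[0], len(breeds)):
        raise ValueError("X must be (n_animals, n_breeds)")
    pgm = np.zeros(dos.shape[0])
    b_hat = np.empty(len(breeds))
    for k, breed in enumerate(breeds):
        fit = within_fits[breed]
        if fit.centering_freqs is None:
            raise ValueError(f"within-breed fit for {breed!r} lacks centering frequencies")
        centered = dos - 2.0 * fit.centering_freqs
        pgm += X[:, k] * (centered @ fit.u_hat)
        b_hat[k] = fit.mu_hat
    pgm += _breed_mean_term(X, b_hat)
    return pgm_table(genotypes.animal_ids, method, pgm)


def predict_bom(
    within_fits: Mapping[str, PosteriorFit],
    partials: PartialGenotypeSet,
    animal_ids: Sequence[str],
    method: str = "BOM",
) -> pd.DataFrame:
    """Breed-of-origin weighting of within-breed SNP solutions."""
    _check_fits(within_fits, partials.breeds)
    n = partials.Z.shape[1]
    pgm = np.zeros(n)
    b_hat = np.empty(partials.n_breeds)
    for k, breed in enumerate(partials.breeds):
        fit = within_fits[breed]
        pgm += partials.Z[k] @ fit.u_hat
        b_hat[k] = fit.mu_hat
    pgm += _breed_mean_term(partials.X, b_hat)
    return pgm_table(animal_ids, method, pgm)


def predict_boa(
    boa_fit: PosteriorFit,
    partials: PartialGenotypeSet,
    animal_ids: Sequence[str],
    method: str = "BOA_COR",
) -> pd.DataFrame:
    """PGM from the multi-breed BOA fit's solutions and breed means."""
    if boa_fit.breeds is not None and tuple(boa_fit.breeds) != tuple(partials.breeds):
        raise ValueError(
            f"fit breeds {boa_fit.breeds} do not match partial genotypes {partials.breeds}"
        )
    if boa_fit.u_hat.ndim != 2 or boa_fit.u_hat.shape[1] != partials.n_breeds:
        raise ValueError("BOA fit does not carry one SNP-solution vector per breed")
    n = partials.Z.shape[1]
    pgm = np.zeros(n)
    for k in range(partials.n_breeds):
        pgm += partials.Z[k] @ boa_fit.u_hat[:, k]
    pgm += _breed_mean_term(partials.X, boa_fit.b_hat)
    return pgm_table(animal_ids, method, pgm)


def predict_joint(
    joint_fit: PosteriorFit,
    genotypes: PhasedGenotypes,
    X: np.ndarray,
    method: str = "JOINT",
) -> pd.DataFrame:
    """PGM from the joint single-component model: (m_i - 2p)' u + X b."""
    if joint_fit.centering_freqs is None:
        raise ValueError("joint fit lacks centering frequencies")
    dos = genotypes.dosages()
    centered = dos - 2.0 * joint_fit.centering_freqs
    pgm = centered @ joint_fit.u_hat + _breed_mean_term(np.asarray(X, float), joint_fit.b_hat)
    return pgm_table(genotypes.animal_ids, method, pgm)
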