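"""Model inputs derived from phased genotypes and per-allele breed-of-origin.

Given phased haplotypes and a resolved breed-of-origin for every allele,
this module builds the quantities the prediction models consume:

* breed-specific allele frequencies p_jk (reference alleles of breed k at
  locus j over all alleles of breed k),
* partial-genotype ("BOA") matrices Z_k with entries x_jk - m_jk * p_jk,
  where x_jk is the breed-k partial dosage and m_jk the breed-k allele
  count at the locus,
* genomic breed proportions (GBP): the fraction of an animal's alleles
  assigned to each breed, and
* plain centered genotype matrices for single-breed analyses.

Frequencies are always computed on a reference subset and then frozen, so
validation animals are centered with reference frequencies (no leakage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .simulate import BreedOrigins, PhasedGenotypes, UNASSIGNED

logger = logging.getLogger(__name__)


@dataclass
class BreedAlleleFreqs:
    """Breed-specific allele frequencies with the observed allele counts."""

    p: np.ndarray  # (n_markers, n_breeds), in [0, 1]
    observed_allele_counts: np.ndarray  # (n_markers, n_breeds), integer
    n_fallback: int = 0  # (marker, breed) cells that fell back to the pooled frequency

    def __post_init__(self) -> None:
        if not np.isfinite(self.p).all() or (self.p < 0).any() or (self.p > 1).any():
            raise ValueError("frequencies must be finite and in [0, 1]")
        if (self.observed_allele_counts < 0).any():
            raise ValueError("allele counts must be non-negative")


@dataclass
class PartialGenotypeSet:
    """Per-breed centered partial genotypes plus GBP.

    ``Z`` is stacked (n_breeds, n_animals, n_markers); ``M`` holds the
    per-breed allele counts (0/1/2) with the same layout; ``X`` is the GBP
    matrix (n_animals, n_breeds).  Summing M over breeds gives 2 at every
    (animal, marker), and summing Z_k + M_k * p_k recovers the raw dosage.
    """

    Z: np.ndarray
    M: np.ndarray
    X: np.ndarray
    freqs: BreedAlleleFreqs
    breeds: tuple[str, ...]

    def z_for(self, breed: str) -> np.ndarray:
        return self.Z[self.breeds.index(breed)]

    def subset(self, idx) -> "PartialGenotypeSet":
        """Restrict to a subset of animals (frequencies stay frozen)."""
        idx = np.asarray(idx, dtype=int)
        return PartialGenotypeSet(
            Z=self.Z[:, idx, :], M=self.M[:, idx, :], X=self.X[idx],
            freqs=self.freqs, breeds=self.breeds,
        )

    @property
    def n_breeds(self) -> int:
        return self.Z.shape[0]


@dataclass
class CenteredGenotypes:
    """Dosages centered on reference-population allele frequencies."""

    Z: np.ndarray  # (n_animals, n_markers)
    freqs: np.ndarray  # (n_markers,) reference frequencies used


def resolve_unassigned(origins: BreedOrigins, others_index: int) -> BreedOrigins:
    """Fold unassigned alleles into the designated Others breed.

    Every ``UNASSIGNED`` code becomes ``others_index``; nothing else
    changes, so assignment is complete (100%) afterwards.
    """
    if not 0 <= others_index < origins.n_breeds:
        raise ValueError("others_index must designate an existing breed")
    out = origins.copy()
    n = int((out.origins == UNASSIGNED).sum())
    if n:
        logger.info("resolved %d unassigned alleles into breed index %d", n, others_index)
        out.origins[out.origins == UNASSIGNED] = others_index
    return out


def _require_resolved(origins: BreedOrigins) -> None:
    if origins.has_unassigned:
        raise ValueError("origins contain unassigned alleles; run resolve_unassigned first")


def breed_allele_freqs(
    genotypes: PhasedGenotypes,
    origins: BreedOrigins,
    reference_subset: Sequence[int] | np.ndarray,
) -> BreedAlleleFreqs:
    """Breed-specific allele frequencies from a reference subset of animals.

    p_jk = (# reference alleles of breed k at locus j) / (# alleles of
    breed k at locus j), counted over the reference animals only.  Cells
    with zero observed alleles for a breed fall back to the pooled
    (all-breed) frequency so that centering stays defined with zero
    expectation; the number of such cells is logged and recorded.
    """
    idx = np.asarray(reference_subset, dtype=int)
    if idx.size == 0:
        raise ValueError("reference subset is empty")
    _require_resolved(origins)
    al = genotypes.alleles[idx]
    orig = origins.origins[idx]
    K = origins.n_breeds
    m = genotypes.n_markers
    counts = np.empty((m, K), dtype=np.int64)
    ref_counts = np.empty((m, K), dtype=np.int64)
    for k in range(K):
        mask = orig == k
        counts[:, k] = mask.sum(axis=(0, 1))
        ref_counts[:, k] = (al * mask).sum(axis=(0, 1))
    pooled = al.sum(axis=(0, 1)) / (2.0 * idx.size)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = ref_counts / counts
    missing = counts == 0
    n_fallback = int(missing.sum())
    if n_fallback:
        logger.info("%d (marker, breed) cells had no observed alleles; pooled-frequency fallback used", n_fallback)
        p = np.where(missing, pooled[:, None], p)
    return BreedAlleleFreqs(p=p, observed_allele_counts=counts, n_fallback=n_fallback)


def build_partial_genotypes(
    genotypes: PhasedGenotypes,
    origins: BreedOrigins,
    freqs: BreedAlleleFreqs,
    breeds: Sequence[str] = ("CH", "LM", "OT"),
) -> PartialGenotypeSet:
    """Breed-specific centered partial genotype matrices Z_k.

    The entry for animal i, locus j, breed k is x_jk - m_jk * p_jk: zero
    when the animal carries no breed-k allele at the locus, (0 or 1) -
    p_jk with one breed-k allele, and (0, 1 or 2) - 2 p_jk with two.
    """
    _require_resolved(origins)
    K = origins.n_breeds
    if freqs.p.shape != (genotypes.n_markers, K):
        raise ValueError("frequency matrix shape does not match genotypes/origins")
    if len(breeds) != K:
        raise ValueError("breed labels must match n_breeds")
    n, m = genotypes.n_animals, genotypes.n_markers
    Z = np.empty((K, n, m), dtype=np.float64)
    M = np.empty((K, n, m), dtype=np.int8)
    for k in range(K):
        mask = origins.origins == k
        M[k] = mask.sum(axis=1)
        x = (genotypes.alleles * mask).sum(axis=1)
        Z[k] = x - M[k] * freqs.p[:, k]
    X = genomic_breed_proportions(origins)
    return PartialGenotypeSet(Z=Z, M=M, X=X, freqs=freqs, breeds=tuple(breeds))


def genomic_breed_proportions(origins: BreedOrigins) -> np.ndarray:
    """GBP matrix: X[i, k] = (# alleles of breed k in animal i) / (2 m)."""
    _require_resolved(origins)
    n, _, m = origins.origins.shape
    K = origins.n_breeds
    X = np.empty((n, K), dtype=np.float64)
    for k in range(K):
        X[:, k] = (origins.origins == k).sum(axis=(1, 2))
    return X / (2.0 * m)


def center_genotypes(
    genotypes: PhasedGenotypes,
    reference_subset: Sequence[int] | np.ndarray,
) -> CenteredGenotypes:
    """Dosages centered with allele frequencies of the reference subset.

    The returned matrix covers *all* animals, but the frequencies (and
    hence the centering) come from the reference subset only, so columns
    average to ~0 over the reference animals and the identical centering
    applies to validation animals.
    """
    idx = np.asarray(reference_subset, dtype=int)
    if idx.size == 0:
        raise ValueError("reference subset is empty")
    dos = genotypes.dosages()
    freqs = dos[idx].mean(axis=0) / 2.0
    return CenteredGenotypes(Z=dos - 2.0 * freqs, freqs=freqs)
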