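"""Synthetic multi-breed crossbred populations with tracked breed-of-origin.

The generator emulates the data structure of a national multi-breed beef
evaluation: a handful of pure breeds with divergent allele frequencies,
crossbred animals of varying composition produced from those purebreds,
phased haplotypes whose per-allele breed-of-origin is known exactly by
construction, breed-specific (optionally correlated) SNP effects, fixed
breed means and adjusted phenotypes with a Gaussian residual.

Loci are simulated independently given the breed allele frequency (no LD
model): none of the downstream estimators depends on a particular LD
structure, and independence keeps the analytic oracles exact.  Origin
blocks along the genome arise from per-chromosome recombination when
gametes are formed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Sentinel code for an allele whose breed-of-origin is not assigned.
UNASSIGNED = -1

# Mean of p(1-p) for ancestral frequencies ~ Uniform(0.1, 0.9); used to
# translate a target genetic variance into a per-QTL effect variance.
_MEAN_HET = float(np.mean([p * (1 - p) for p in np.linspace(0.1, 0.9, 10001)]))


@dataclass
class PhasedGenotypes:
    """Phased biallelic genotypes: (animal, haplotype, marker) in {0, 1}."""

    alleles: np.ndarray  # uint8, shape (n_animals, 2, n_markers)
    animal_ids: list[str]
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles)
        if self.alleles.ndim != 3 or self.alleles.shape[1] != 2:
            raise ValueError("alleles must have shape (animal, 2, marker)")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("allele codes must be 0 or 1")
        if len(self.animal_ids) != self.alleles.shape[0]:
            raise ValueError("animal_ids length does not match alleles")
        if len(self.marker_ids) != self.alleles.shape[2]:
            raise ValueError("marker_ids length does not match alleles")

    @property
    def n_animals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[2]

    def dosages(self) -> np.ndarray:
        """Allele content m_i per animal and marker (0/1/2)."""
        return self.alleles.sum(axis=1).astype(np.float64)


@dataclass
class BreedOrigins:
    """Per-allele breed-of-origin codes, same shape as the haplotypes.

    Codes are 0..n_breeds-1, or :data:`UNASSIGNED` (-1) before resolution.
    """

    origins: np.ndarray  # int8, shape (n_animals, 2, n_markers)
    n_breeds: int

    def __post_init__(self) -> None:
        self.origins = np.asarray(self.origins)
        if self.origins.ndim != 3 or self.origins.shape[1] != 2:
            raise ValueError("origins must have shape (animal, 2, marker)")
        bad = (self.origins < UNASSIGNED) | (self.origins >= self.n_breeds)
        if bad.any():
            raise ValueError("origin codes must be in {-1, 0..n_breeds-1}")

    def copy(self) -> "BreedOrigins":
        return BreedOrigins(self.origins.copy(), self.n_breeds)

    @property
    def has_unassigned(self) -> bool:
        return bool((self.origins == UNASSIGNED).any())


@dataclass(frozen=True)
class CrossSpec:
    """One crossbred cohort: dam and sire groups, size, optional birth year.

    ``dam`` and ``sire`` name either a pure breed label or a previously
    simulated cross, so backcrosses and multi-way crosses chain naturally.
    """

    name: str
    dam: str
    sire: str
    count: int
    birth_year: int | None = None


def default_true_B(
    n_qtl: int,
    heritability: float = 0.4,
    residual_variance: float = 1.0,
    correlations: Sequence[float] = (0.86, 0.71, 0.49),
) -> np.ndarray:
    """Across-breed SNP-effect covariance matrix for a 3-breed simulation.

    Diagonals are set so that the genetic variance within a breed is about
    ``heritability / (1 - heritability) * residual_variance`` at Hardy-
    Weinberg loci; off-diagonals follow the given correlations ordered as
    (breed0-breed1, breed0-breed2, breed1-breed2).
    """
    var_g = heritability / (1.0 - heritability) * residual_variance
    v = var_g / (n_qtl * 2.0 * _MEAN_HET)
    r01, r02, r12 = correlations
    B = v * np.array([[1.0, r01, r02], [r01, 1.0, r12], [r02, r12, 1.0]])
    return B


def default_design(n_ref: int = 600, n_val: int = 300) -> tuple[CrossSpec, ...]:
    """A crossbred design spanning the four main-breed-proportion groups.

    Reference cohorts are born before the usual validation threshold year
    and validation cohorts after it.  Expected main-breed (CH+LM) content:
    F1 CHxLM and backcross = 1.0, CHxOT = 0.5, (CHxOT)xOT = 0.25 and
    ((CHxOT)xOT)xOT = 0.125, so realized genomic breed proportions cover
    all four grouping intervals.
    """

    def cohort(prefix: str, year: int, n: int) -> tuple[CrossSpec, ...]:
        c = max(1, round(n / 6))
        return (
            CrossSpec(f"{prefix}F1", "CH", "LM", c, year),
            CrossSpec(f"{prefix}CHOT", "CH", "OT", c, year),
            CrossSpec(f"{prefix}LMOT", "LM", "OT", c, year),
            CrossSpec(f"{prefix}BC", f"{prefix}F1", "CH", c, year + 1),
            CrossSpec(f"{prefix}LOW", f"{prefix}CHOT", "OT", c, year + 1),
            CrossSpec(f"{prefix}VLOW", f"{prefix}LOW", "OT", c, year + 1),
        )

    return cohort("R", 2016, n_ref) + cohort("V", 2019, n_val)


@dataclass
class SimConfig:
    """Parameters of the synthetic multi-breed population.

    ``founder_freq_divergence`` is the Balding-Nichols drift parameter F in
    (0, 1): breed allele frequencies are drawn around a shared ancestral
    frequency p with variance F·p·(1-p), so F=0 means identical breeds.
    ``true_B`` is the (n_breeds x n_breeds) SNP-effect covariance across
    breeds; by default it uses correlations (0.86, 0.71, 0.49) and
    diagonals giving heritability ~0.4 within a pure breed.
    """

    n_breeds: int = 3
    breeds: tuple[str, ...] = ("CH", "LM", "OT")
    n_markers: int = 500
    n_qtl: int = 150
    founder_freq_divergence: float = 0.15
    n_purebred_per_breed: int = 350
    crossbred_design: tuple[CrossSpec, ...] = field(default_factory=default_design)
    true_B: np.ndarray | None = None
    breed_means: tuple[float, ...] = (0.0, 0.6, -0.4)
    residual_variance: float = 1.0
    birth_year_range: tuple[int, int] = (2014, 2021)
    n_chromosomes: int = 5
    crossovers_per_chromosome: int = 1
    seed: int = 2024

    def __post_init__(self) -> None:
        if self.n_breeds < 2:
            raise ValueError("need at least two breeds")
        if len(self.breeds) != self.n_breeds:
            raise ValueError("breeds labels must match n_breeds")
        if len(self.breed_means) != self.n_breeds:
            raise ValueError("breed_means must match n_breeds")
        for name, v in (
            ("n_markers", self.n_markers),
            ("n_qtl", self.n_qtl),
            ("n_purebred_per_breed", self.n_purebred_per_breed),
            ("n_chromosomes", self.n_chromosomes),
        ):
            if v < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl cannot exceed n_markers")
        if not 0.0 <= self.founder_freq_divergence < 1.0:
            raise ValueError("founder_freq_divergence must be in [0, 1)")
        if self.residual_variance < 0:
            raise ValueError("residual_variance must be non-negative")
        if self.true_B is None:
            if self.n_breeds != 3:
                raise ValueError("default true_B only defined for 3 breeds")
            self.true_B = default_true_B(self.n_qtl, residual_variance=max(self.residual_variance, 1e-12))
        self.true_B = np.asarray(self.true_B, dtype=np.float64)
        _check_pd(self.true_B, "true_B")

    def rng_streams(self) -> dict[str, np.random.Generator]:
        """Named, independent random streams all derived from ``seed``."""
        names = ("freqs", "founders", "crosses", "effects", "residual")
        seqs = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(s) for n, s in zip(names, seqs)}


def _check_pd(B: np.ndarray, name: str) -> None:
    B = np.asarray(B, dtype=np.float64)
    if B.ndim != 2 or B.shape[0] != B.shape[1]:
        raise ValueError(f"{name} must be a square matrix")
    if not np.allclose(B, B.T):
        raise ValueError(f"{name} must be symmetric")
    try:
        np.linalg.cholesky(B)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{name} is not positive-definite") from exc


@dataclass
class SyntheticDataset:
    """A fully simulated population with ground truth attached."""

    genotypes: PhasedGenotypes
    origins: BreedOrigins
    pedigree: pd.DataFrame  # animal, sire, dam, birth_year, breed_label, is_purebred
    true_snp_effects: np.ndarray  # (n_markers, n_breeds); zero on non-QTL rows
    true_genetic_values: np.ndarray  # (n_animals,)
    adjusted_phenotypes: np.ndarray  # (n_animals,)
    breed_freqs: np.ndarray  # (n_markers, n_breeds) founder frequencies used
    config: SimConfig

    @property
    def breed_mean_terms(self) -> np.ndarray:
        """GBP-weighted breed means per animal (the Xb part of y*)."""
        from .breedorigin import genomic_breed_proportions

        X = genomic_breed_proportions(self.origins)
        return X @ np.asarray(self.config.breed_means)


def draw_breed_frequencies(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Breed-specific founder allele frequencies, (n_markers, n_breeds).

    A Balding-Nichols draw per breed around a shared ancestral frequency:
    p_k ~ Beta(p(1-F)/F, (1-p)(1-F)/F).  The draw uses inverse-CDF on a
    common uniform, so at fixed seed the divergence between two breeds is
    monotone in F locus by locus.  Frequencies are clamped to [0.01, 0.99]
    (degenerate draws are logged).
    """
    F = config.founder_freq_divergence
    ancestral = rng.uniform(0.1, 0.9, size=config.n_markers)
    u = rng.uniform(size=(config.n_markers, config.n_breeds))
    if F == 0.0:
        p = np.repeat(ancestral[:, None], config.n_breeds, axis=1)
    else:
        lam = (1.0 - F) / F
        a = ancestral[:, None] * lam
        b = (1.0 - ancestral)[:, None] * lam
        p = stats.beta.ppf(u, a, b)
    n_clamped = int(((p < 0.01) | (p > 0.99)).sum())
    if n_clamped:
        logger.info("clamped %d breed allele frequencies to [0.01, 0.99]", n_clamped)
    return np.clip(p, 0.01, 0.99)


def simulate_founders(
    config: SimConfig,
    breed_freqs: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[PhasedGenotypes, BreedOrigins, pd.DataFrame]:
    """Purebred founder animals, one block of animals per breed.

    Haplotype alleles are Bernoulli draws at the breed frequency,
    independent across loci; every origin equals the animal's own breed.
    Returns genotypes, origins and a pedigree table (founders have no
    recorded parents and are born in the first year of the range).
    """
    streams = config.rng_streams()
    if breed_freqs is None:
        breed_freqs = draw_breed_frequencies(config, streams["freqs"])
    if rng is None:
        rng = streams["founders"]

    n_per = config.n_purebred_per_breed
    n_total = n_per * config.n_breeds
    alleles = np.empty((n_total, 2, config.n_markers), dtype=np.uint8)
    origins = np.empty((n_total, 2, config.n_markers), dtype=np.int8)
    ids: list[str] = []
    rows = []
    for k, label in enumerate(config.breeds):
        sl = slice(k * n_per, (k + 1) * n_per)
        pk = breed_freqs[:, k]
        alleles[sl] = (rng.uniform(size=(n_per, 2, config.n_markers)) < pk).astype(np.uint8)
        origins[sl] = k
        for i in range(n_per):
            aid = f"{label}{i:05d}"
            ids.append(aid)
            rows.append((aid, "", "", config.birth_year_range[0], label, True))
    markers = [f"m{j:05d}" for j in range(config.n_markers)]
    ped = pd.DataFrame(rows, columns=["animal", "sire", "dam", "birth_year", "breed_label", "is_purebred"])
    genos = PhasedGenotypes(alleles, ids, markers)
    return genos, BreedOrigins(origins, config.n_breeds), ped


def _chromosome_bounds(n_markers: int, n_chromosomes: int) -> list[tuple[int, int]]:
    edges = np.linspace(0, n_markers, n_chromosomes + 1).astype(int)
    return [(int(edges[c]), int(edges[c + 1])) for c in range(n_chromosomes)]


def _make_gamete(
    alleles: np.ndarray,
    origins: np.ndarray,
    bounds: list[tuple[int, int]],
    n_crossovers: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One recombinant gamete (alleles and origins) from a parent."""
    n_markers = alleles.shape[1]
    hap = np.empty(n_markers, dtype=np.int8)
    for lo, hi in bounds:
        length = hi - lo
        current = rng.integers(0, 2)
        if length <= 1 or n_crossovers == 0:
            hap[lo:hi] = current
            continue
        cuts = np.sort(rng.integers(1, length, size=n_crossovers))
        pos = 0
        for cut in cuts:
            hap[lo + pos : lo + cut] = current
            current = 1 - current
            pos = cut
        hap[lo + pos : hi] = current
    idx = np.arange(n_markers)
    return alleles[hap, idx], origins[hap, idx]


def simulate_crosses(
    founders: tuple[PhasedGenotypes, BreedOrigins, pd.DataFrame],
    design: Sequence[CrossSpec],
    seed: int | np.random.Generator,
    n_chromosomes: int = 5,
    crossovers_per_chromosome: int = 1,
    breeds: Sequence[str] = ("CH", "LM", "OT"),
) -> tuple[PhasedGenotypes, BreedOrigins, pd.DataFrame]:
    """Crossbred animals from a design of (dam group x sire group) cohorts.

    Each offspring receives one recombinant gamete per parent; both the
    allele and its origin are copied from the chosen parental haplotype,
    so breed-of-origin is exact by construction.  Birth years increase by
    generation unless a cohort sets one explicitly.  Returns the combined
    (founders + crossbreds) genotypes, origins and pedigree.
    """
    if len(design) == 0:
        raise ValueError("crossbred design is empty")
    geno_f, orig_f, ped_f = founders
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_markers = geno_f.n_markers
    bounds = _chromosome_bounds(n_markers, n_chromosomes)

    all_ids = list(geno_f.animal_ids)
    id_index = {a: i for i, a in enumerate(all_ids)}
    base_year = int(ped_f["birth_year"].min())

    # group name -> (list of animal indices, generation)
    groups: dict[str, tuple[list[int], int]] = {}
    for label in breeds:
        members = [id_index[a] for a, b in zip(ped_f["animal"], ped_f["breed_label"]) if b == label]
        groups[label] = (members, 0)

    rows = list(ped_f.itertuples(index=False, name=None))
    next_index = len(all_ids)
    stacked_alleles = geno_f.alleles.copy()
    stacked_origins = orig_f.origins.copy()

    for spec in design:
        for parent in (spec.dam, spec.sire):
            if parent not in groups:
                raise ValueError(f"cross {spec.name!r} references unknown group {parent!r}")
        dam_pool, gd = groups[spec.dam]
        sire_pool, gs = groups[spec.sire]
        generation = max(gd, gs) + 1
        year = spec.birth_year if spec.birth_year is not None else base_year + generation
        members: list[int] = []
        cohort_alleles = np.empty((spec.count, 2, n_markers), dtype=np.uint8)
        cohort_origins = np.empty((spec.count, 2, n_markers), dtype=np.int8)
        for i in range(spec.count):
            dam = int(rng.choice(dam_pool))
            sire = int(rng.choice(sire_pool))
            for h, parent in enumerate((dam, sire)):
                ga, go = _make_gamete(
                    stacked_alleles[parent], stacked_origins[parent],
                    bounds, crossovers_per_chromosome, rng,
                )
                cohort_alleles[i, h] = ga
                cohort_origins[i, h] = go
            aid = f"{spec.name}{i:05d}"
            rows.append((aid, all_ids[sire], all_ids[dam], year, spec.name, False))
            all_ids.append(aid)
            members.append(next_index)
            next_index += 1
        stacked_alleles = np.concatenate([stacked_alleles, cohort_alleles], axis=0)
        stacked_origins = np.concatenate([stacked_origins, cohort_origins], axis=0)
        groups[spec.name] = (members, generation)

    ped = pd.DataFrame(rows, columns=["animal", "sire", "dam", "birth_year", "breed_label", "is_purebred"])
    genos = PhasedGenotypes(stacked_alleles, all_ids, list(geno_f.marker_ids))
    return genos, BreedOrigins(stacked_origins, orig_f.n_breeds), ped


def simulate_effects_and_phenotypes(
    genotypes: PhasedGenotypes,
    origins: BreedOrigins,
    pedigree: pd.DataFrame,
    config: SimConfig,
    breed_freqs: np.ndarray,
    effects_rng: np.random.Generator | None = None,
    residual_rng: np.random.Generator | None = None,
) -> SyntheticDataset:
    """Draw breed-specific QTL effects and build adjusted phenotypes.

    Per QTL the breed-effect vector is multivariate normal with covariance
    ``config.true_B``; non-QTL markers carry zero effects.  The genetic
    value sums, over loci and haplotypes, the effect of the allele's breed
    of origin times the allele; the adjusted phenotype adds a GBP-weighted
    breed-mean term and a Gaussian residual.
    """
    streams = config.rng_streams()
    effects_rng = effects_rng if effects_rng is not None else streams["effects"]
    residual_rng = residual_rng if residual_rng is not None else streams["residual"]
    _check_pd(config.true_B, "true_B")

    m, K = config.n_markers, config.n_breeds
    qtl = np.sort(effects_rng.choice(m, size=config.n_qtl, replace=False))
    effects = np.zeros((m, K))
    L = np.linalg.cholesky(config.true_B)
    effects[qtl] = effects_rng.standard_normal((config.n_qtl, K)) @ L.T

    g = true_genetic_values(genotypes, origins, effects)

    from .breedorigin import genomic_breed_proportions

    X = genomic_breed_proportions(origins)
    mean_term = X @ np.asarray(config.breed_means)
    resid = residual_rng.normal(0.0, np.sqrt(config.residual_variance), size=genotypes.n_animals)
    y_star = mean_term + g + resid
    return SyntheticDataset(
        genotypes=genotypes,
        origins=origins,
        pedigree=pedigree,
        true_snp_effects=effects,
        true_genetic_values=g,
        adjusted_phenotypes=y_star,
        breed_freqs=breed_freqs,
        config=config,
    )


def true_genetic_values(
    genotypes: PhasedGenotypes, origins: BreedOrigins, effects: np.ndarray
) -> np.ndarray:
    """Sum of breed-of-origin-matched allele effects over both haplotypes."""
    if origins.has_unassigned:
        raise ValueError("origins must be fully assigned to compute genetic values")
    g = np.zeros(genotypes.n_animals)
    for k in range(origins.n_breeds):
        content = (genotypes.alleles * (origins.origins == k)).sum(axis=1)
        g += content @ effects[:, k]
    return g


def simulate(config: SimConfig) -> SyntheticDataset:
    """Full pipeline: founders -> crosses -> effects and phenotypes."""
    streams = config.rng_streams()
    breed_freqs = draw_breed_frequencies(config, streams["freqs"])
    founders = simulate_founders(config, breed_freqs=breed_freqs, rng=streams["founders"])
    genos, origs, ped = simulate_crosses(
        founders,
        config.crossbred_design,
        streams["crosses"],
        n_chromosomes=config.n_chromosomes,
        crossovers_per_chromosome=config.crossovers_per_chromosome,
        breeds=config.breeds,
    )
    return simulate_effects_and_phenotypes(
        genos, origs, ped, config, breed_freqs,
        effects_rng=streams["effects"], residual_rng=streams["residual"],
    )


def corrupt_origins(
    origins: BreedOrigins,
    switch_rate: float,
    seed: int | np.random.Generator,
    to_unassigned: bool = False,
) -> BreedOrigins:
    """Independently reassign each allele's origin with probability ``switch_rate``.

    A switched allele moves to a breed chosen uniformly among the *other*
    breeds, or to :data:`UNASSIGNED` when ``to_unassigned`` is set.  A rate
    of 0 returns an identical copy; a rate of 1 leaves no allele with its
    original assignment.
    """
    if not 0.0 <= switch_rate <= 1.0:
        raise ValueError("switch_rate must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = origins.copy()
    if switch_rate == 0.0:
        return out
    mask = rng.uniform(size=out.origins.shape) < switch_rate
    if to_unassigned:
        out.origins[mask] = UNASSIGNED
        return out
    K = origins.n_breeds
    shift = rng.integers(1, K, size=out.origins.shape)
    switched = (out.origins + shift) % K
    out.origins = np.where(mask, switched, out.origins).astype(np.int8)
    return out
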