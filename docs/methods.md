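# Methods

`boapred` implements and compares three strategies for predicting the
genetic merit of crossbred animals in a multi-breed population, together
with a synthetic-population generator that makes the whole pipeline
testable without any proprietary data.

## Models

All models act on adjusted phenotypes y\* (phenotypes pre-corrected for
environmental fixed and non-genetic random effects) and phased, biallelic
SNP genotypes with a known breed-of-origin for every allele.

**Within-breed Bayesian ridge.** For each pure breed separately,

y\* = 1μ + Z u + e,

with Z the genotype dosages centered on the breed's reference allele
frequencies, u | σ²ᵤ ~ N(0, I σ²ᵤ) and e | σ²ₑ ~ N(0, I σ²ₑ).  Both
variances carry scaled-inverse-chi-square priors with df = 4 and scale
S = σ²₍old₎ (df − 2)/df, where σ²₍old₎ comes from an earlier (pilot)
analysis.  This is SNP-BLUP with unknown, estimated variances.

**Multi-breed BOA model.**  Purebred and crossbred records are analyzed
jointly:

y\* = X b + Z_CH u_CH + Z_LM u_LM + Z_OT u_OT + e,

where X holds genomic breed proportions (GBP: per-animal fractions of
alleles assigned to each breed), b the fixed breed means, and the Z_k are
partial-genotype matrices with entries x_jk − m_jk p_jk (partial dosage
minus allele count times breed-specific allele frequency).  In
*uncorrelated* mode each u_k has its own variance σ²ᵤ,ₖ; in *correlated*
mode the per-locus breed-effect vectors are N(0, B) with B an across-breed
covariance matrix carrying an inverse-Wishart prior IW(ν, V) with ν = 6
and V = (ν − K − 1) B₍old₎ for K breeds, so the prior mean is B₍old₎.
With the three breed components used throughout (CH, LM, OT) this is
V = 2 B₍old₎.

Because GBP rows sum to one, a global intercept is confounded with the
breed means; the implementation drops μ and absorbs it into b.  The
predictors consume b̂ₖ directly, so predictions are invariant to this
choice.

**Joint single-component model.**  The same combined data with a single
effect vector, y\* = X b + Z u + e, ignoring breed-of-origin; it isolates
how much of the BOA model's advantage comes from the extra crossbred
records rather than from breed specificity.

## Samplers

All fits are single-site Gibbs samplers with residual updating.  Scalar
effects are drawn from N(rhs/c, σ²ₑ/c) with c = z′z + σ²ₑ/σ²ᵤ; in
correlated mode the per-locus K-vector is drawn jointly from its
multivariate-normal full conditional (a K×K Cholesky solve), which is an
equally valid Gibbs scheme that mixes better than scalar-wise updates.
B is drawn from IW(ν + m, V + U′U) once per cycle; a non-positive-definite
scale raises an error naming the cycle rather than being silently
regularized.  Fixed effects use flat priors.

Numerical choices: effects start at zero and variances at the pilot
estimates; the residual vector is recomputed from scratch every 500
cycles to cancel incremental floating-point drift; all Gaussian noise is
pre-generated from one seeded generator per chain, so chains are
bit-for-bit reproducible given the seed.  The default chain profile is
100,000 cycles, 20,000 burn-in, thinning 10 (8,000 retained samples per
parameter); `McmcSettings.desk()` (5,000 / 1,000 / 5) is the profile used
by the tests, the scenario driver and the acceptance script.  Effective
sample sizes of the variance draws are logged as advisory diagnostics,
not used as a gate.

Pilot variances come from a short uncorrelated chain started at a
variance-partition heuristic (half of var(y\*) assigned to markers);
B₍old₎ is the diagonal matrix of the pilot per-breed variances.

## Predictors of genetic merit (PGM)

* **BPM** weights within-breed SNP solutions by GBP:
  PGM = Σₖ GBPₖ (m − 2 p_k)′ ûₖ + Σₖ GBPₖ b̂ₖ, with m the dosage vector
  centered by breed k's reference frequencies inside the breed-k term.
* **BOM** applies within-breed solutions to breed-specific allele
  contents: PGM = Σₖ z′ₖ ûₖ + Σₖ GBPₖ b̂ₖ.
* **BOA** uses the same form with the multi-breed model's solutions and
  fitted breed means.

For the single-breed fits the "breed mean" b̂ₖ is the fit's intercept,
which is the only mean those models estimate; with shared centering this
makes BPM and BOM identical for purebred animals to machine precision, a
structural identity the tests assert.  Any fixed centering choice shifts
PGM by an animal-independent constant per breed profile and therefore
leaves correlations unchanged and slopes essentially unchanged.

## Validation

The reference/validation split mimics a forward validation: animals born
after a threshold year (default 2018) start in validation, and for every
sire the whole sire-offspring group is co-assigned — to validation when
strictly more than half of the offspring are late-born, to reference
otherwise.  Crossbred validation animals are grouped by the summed GBP of
the two main breeds into [0, 0.25), [0.25, 0.50), [0.50, 0.85) and
[0.85, 1].

Predictive ability is the Pearson correlation of y\* with PGM; dispersion
is the OLS slope of y\* on PGM (slopes below 1 flag inflated predictions).
The slope is deliberately taken in this direction — it is the one under
which "slope < 1 means overdispersed PGM" is algebraically true.  Method
comparisons use a paired nonparametric bootstrap: one resample of
validation indices per replicate shared across all methods (pairing is
what makes a paired t-test on replicate-level predictive abilities
meaningful), a two-tailed paired t-test over replicates, and Bonferroni
correction over the method pairs within an animal group.  The production
replicate count is 10,000; tests use smaller counts since only the
pairing structure and separation behavior are asserted.

## Synthetic populations

The generator emulates the structure of a national multi-breed beef
dataset: K pure breeds whose allele frequencies diverge by a
Balding–Nichols draw around shared ancestral frequencies (drift parameter
F = `founder_freq_divergence`; the inverse-CDF coupling makes divergence
monotone in F at a fixed seed), crossbred cohorts defined by chained
dam × sire specifications (F1s, backcrosses, three-way and low-main-breed
crosses), per-chromosome recombination that copies allele and origin
together (so breed-of-origin is exact by construction), breed-specific
QTL effects drawn from N(0, B_true), GBP-weighted breed means, and a
Gaussian residual.  An origin-corruption operator reassigns alleles (or
marks them unassigned) at a chosen rate to study sensitivity to
assignment errors; unassigned alleles are folded into the Others group,
mirroring how unassignable alleles are handled in practice.

What the generator does **not** model: linkage disequilibrium within
founder breeds (loci are independent given breed frequencies — none of
the estimators here depends on an LD structure, and independence keeps
the variance oracles analytic), realistic genome maps, mutation,
selection across generations, and non-additive effects.  Passing tests
therefore demonstrate correctness of the estimators and the qualitative
data-addition effects, not performance on LD-structured real genotypes.

Default study conditions: B_true uses across-breed effect correlations
(0.86, 0.71, 0.49) — production-scale estimates adopted as simulation
truth — with diagonals set for a within-breed heritability of about 0.4
at residual variance 1; breed means (0.0, 0.6, −0.4) in residual-SD
units; ancestral frequencies Uniform(0.1, 0.9) with F = 0.15; five
chromosomes with one crossover each.

## Desk-scale study conditions

Production-scale analyses (tens of thousands of animals, 50K markers)
are out of reach on a single CPU, so the package defines two scaled
protocols, used identically by the test suite and `scripts/acceptance.py`:

* **Recovery protocol** — 1,800 purebreds + 1,200 crossbreds in the
  reference (~3,000 records), 1,000 markers all carrying effects, BOA
  correlated mode at the desk chain profile.  It checks that the
  posterior of B recovers the true across-breed correlations and that
  validation slopes are near 1.  At this information level the posterior
  correlation estimates attenuate noticeably toward zero (single
  replicates scatter by up to ~0.17 around truth for the highest
  correlation), so the recovery check averages over three replicate
  seeds, the same seed-averaging the ordering check uses.
* **Ordering protocol** — animal counts at 1/20 of the production
  scenario grid (≈1,020 purebreds; 221 / 412 / 919 crossbreds added in
  nested subsets; ≈630 validation animals), with 750 markers so that
  markers remain of the same order as records — the regime in which
  marker effects are data-limited, as they are at production scale where
  markers outnumber reference animals.  Averaged over five replicate
  seeds, crossbred predictive ability satisfies
  BOA_COR ≥ BOM ≈ BPM and grows with the crossbred reference size.

## Known limitations

* The joint single-component model performs on par with BOA_COR at desk
  scale; the advantage of breed-specific effects for high-main-breed
  crossbreds emerges at production scale and is not asserted by the
  tests here.
* Breed-specific allele frequencies for a breed unobserved at a locus
  fall back to the pooled frequency (logged), keeping centering defined
  with zero expectation; there is no principled frequency estimate in
  that case.
* Origin corruption is independent across alleles; real assignment
  errors cluster along haplotypes and chromosome ends.
* Fixed effects beyond breed means (herd, age, ...) are assumed already
  removed in y\*.
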