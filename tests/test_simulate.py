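"""Generator checks: divergence control, origin tracking, effect draws."""

import numpy as np
import pytest

import boapred as bp
from boapred.simulate import draw_breed_frequencies

from conftest import animal_indices


def _founder_config(**kw):
    defaults = dict(n_markers=200, n_qtl=50, n_purebred_per_breed=100, seed=7)
    defaults.update(kw)
    return bp.SimConfig(**defaults)


class TestFounders:
    def test_zero_divergence_gives_identical_breed_frequencies(self):
        cfg = _founder_config(founder_freq_divergence=0.0)
        p = draw_breed_frequencies(cfg, np.random.default_rng(1))
        assert np.all(p[:, 0] == p[:, 1]) and np.all(p[:, 0] == p[:, 2])

    def test_purebred_origins_equal_own_breed(self):
        cfg = _founder_config()
        genos, origins, ped = bp.simulate_founders(cfg)
        assert genos.n_animals == 300
        for k, label in enumerate(cfg.breeds):
            sel = (ped["breed_label"] == label).to_numpy()
            assert np.all(origins.origins[sel] == k)

    def test_breed_divergence_monotone_in_drift_parameter(self):
        # brute-force per-locus mean absolute frequency difference
        gaps = []
        for F in (0.05, 0.2, 0.5):
            cfg = _founder_config(founder_freq_divergence=F)
            p = draw_breed_frequencies(cfg, np.random.default_rng(11))
            total = 0.0
            for j in range(cfg.n_markers):
                total += abs(p[j, 0] - p[j, 1])
            gaps.append(total / cfg.n_markers)
        assert gaps[0] < gaps[1] < gaps[2]

    def test_frequencies_clamped_into_open_interval(self):
        cfg = _founder_config(founder_freq_divergence=0.9)
        p = draw_breed_frequencies(cfg, np.random.default_rng(3))
        assert p.min() >= 0.01 and p.max() <= 0.99


class TestCrosses:
    def test_f1_carries_one_allele_per_parental_breed(self, small_dataset):
        ds = small_dataset
        f1 = animal_indices(ds, breed_label="RF1")  # CH x LM cohort
        assert f1.size > 0
        orig = ds.origins.origins[f1]
        # exactly one CH-origin and one LM-origin allele at every locus
        assert np.all((orig == 0).sum(axis=1) == 1)
        assert np.all((orig == 1).sum(axis=1) == 1)
        X = bp.genomic_breed_proportions(ds.origins)[f1]
        assert np.array_equal(X, np.tile([0.5, 0.5, 0.0], (f1.size, 1)))

    def test_backcross_breed_proportion_matches_binomial_expectation(self):
        design = (
            bp.CrossSpec("F1", "CH", "LM", 40),
            bp.CrossSpec("BC", "F1", "CH", 100),
        )
        cfg = _founder_config(crossbred_design=design)
        ds = bp.simulate(cfg)
        bc = animal_indices(ds, breed_label="BC")
        gbp_ch = bp.genomic_breed_proportions(ds.origins)[bc, 0]
        se = gbp_ch.std(ddof=1) / np.sqrt(bc.size)
        assert abs(gbp_ch.mean() - 0.75) < 3 * se

    def test_origin_counts_conserved(self, small_dataset):
        ds = small_dataset
        counts = sum(
            (ds.origins.origins == k).sum(axis=(1, 2)) for k in range(3)
        )
        assert np.all(counts == 2 * ds.genotypes.n_markers)

    def test_empty_design_rejected(self):
        cfg = _founder_config()
        founders = bp.simulate_founders(cfg)
        with pytest.raises(ValueError, match="empty"):
            bp.simulate_crosses(founders, (), seed=0)


class TestEffectsAndPhenotypes:
    def test_diagonal_covariance_draws_uncorrelated_effects(self):
        cfg = _founder_config(
            n_markers=900,
            n_qtl=900,
            n_purebred_per_breed=5,
            true_B=np.diag([1e-3, 1e-3, 1e-3]),
            crossbred_design=(bp.CrossSpec("F1", "CH", "LM", 4),),
        )
        ds = bp.simulate(cfg)
        u = ds.true_snp_effects
        r = np.corrcoef(u[:, 0], u[:, 1])[0, 1]
        assert abs(r) < 3 / np.sqrt(cfg.n_qtl)

    def test_noiseless_phenotype_equals_mean_term_plus_genetic_value(self):
        cfg = _founder_config(residual_variance=0.0)
        ds = bp.simulate(cfg)
        np.testing.assert_allclose(
            ds.adjusted_phenotypes, ds.breed_mean_terms + ds.true_genetic_values,
            atol=1e-12,
        )

    def test_correlated_truth_recovered_in_drawn_effects(self):
        # simulation truth uses the production-scale estimates of the
        # across-breed SNP-effect correlations as chosen truth
        cfg = _founder_config(
            n_markers=1000, n_qtl=1000, n_purebred_per_breed=5,
            crossbred_design=(bp.CrossSpec("F1", "CH", "LM", 4),),
        )
        ds = bp.simulate(cfg)
        u = ds.true_snp_effects
        truth = {(0, 1): 0.86, (0, 2): 0.71, (1, 2): 0.49}
        for (a, b), r_true in truth.items():
            r = np.corrcoef(u[:, a], u[:, b])[0, 1]
            assert abs(r - r_true) < 0.1

    def test_non_positive_definite_covariance_rejected_by_name(self):
        bad = np.array([[1.0, 2.0, 0.0], [2.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(ValueError, match="true_B"):
            _founder_config(true_B=bad)

    def test_residual_variance_matches_sample_variance(self):
        cfg = _founder_config(n_purebred_per_breed=400, n_markers=150, n_qtl=100)
        ds = bp.simulate(cfg)
        resid = ds.adjusted_phenotypes - ds.breed_mean_terms - ds.true_genetic_values
        n = resid.size
        assert n >= 1000
        se = np.sqrt(2.0 / n)  # SE of a variance estimate at variance 1
        assert abs(np.var(resid) - cfg.residual_variance) < 3 * se

    def test_implied_heritability_matches_empirical_variance_ratio(self):
        # per-breed genetic variance implied by (frequencies, realized QTL
        # effects) against the empirical variance over 700 purebreds
        ds = bp.simulate(bp.SimConfig(
            n_markers=300, n_qtl=300, n_purebred_per_breed=700, seed=5,
            crossbred_design=(bp.CrossSpec("F1", "CH", "LM", 4),),
        ))
        u = ds.true_snp_effects
        for k, label in enumerate(("CH", "LM", "OT")):
            idx = animal_indices(ds, breed_label=label)
            var_emp = np.var(ds.true_genetic_values[idx], ddof=1)
            p = ds.breed_freqs[:, k]
            var_implied = float(np.sum(2 * p * (1 - p) * u[:, k] ** 2))
            assert abs(var_emp / var_implied - 1) < 0.16


class TestCorruptOrigins:
    def test_zero_rate_is_identity(self, small_dataset):
        out = bp.corrupt_origins(small_dataset.origins, 0.0, seed=1)
        assert np.array_equal(out.origins, small_dataset.origins.origins)

    def test_full_rate_switches_every_allele(self, small_dataset):
        out = bp.corrupt_origins(small_dataset.origins, 1.0, seed=1)
        assert np.all(out.origins != small_dataset.origins.origins)

    def test_switch_fraction_matches_binomial_rate(self):
        orig = bp.BreedOrigins(np.zeros((25, 2, 200), dtype=np.int8), 3)
        out = bp.corrupt_origins(orig, 0.1, seed=2)
        n = orig.origins.size
        assert n == 10_000
        frac = (out.origins != orig.origins).mean()
        assert abs(frac - 0.1) < 3 * np.sqrt(0.1 * 0.9 / n)

    def test_unassigned_outcome_and_resolution(self, small_dataset):
        out = bp.corrupt_origins(small_dataset.origins, 0.2, seed=3, to_unassigned=True)
        assert out.has_unassigned
        resolved = bp.resolve_unassigned(out, others_index=2)
        assert not resolved.has_unassigned
        # untouched alleles keep their origin
        keep = out.origins != bp.UNASSIGNED
        assert np.array_equal(resolved.origins[keep], small_dataset.origins.origins[keep])

    def test_rate_out_of_range_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="switch_rate"):
            bp.corrupt_origins(small_dataset.origins, 1.5, seed=0)


def test_fixed_seed_reproduces_bit_identical_outputs():
    cfg = bp.SimConfig(n_markers=80, n_qtl=20, n_purebred_per_breed=30, seed=9)
    a = bp.simulate(cfg)
    b = bp.simulate(bp.SimConfig(n_markers=80, n_qtl=20, n_purebred_per_breed=30, seed=9))
    assert np.array_equal(a.genotypes.alleles, b.genotypes.alleles)
    assert np.array_equal(a.origins.origins, b.origins.origins)
    assert np.array_equal(a.adjusted_phenotypes, b.adjusted_phenotypes)
    assert a.pedigree.equals(b.pedigree)
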