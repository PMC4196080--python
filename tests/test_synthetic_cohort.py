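"""The cohort generator: HWE, noise model, calibration, ascertainment."""

import numpy as np
import pytest
from scipy import stats

import telogrs as tg
from telogrs.errors import SimulationError, TelogrsError
from telogrs.synthetic_cohort import (
    TARGET_GENETIC_VARIANCE_FRACTION,
    induced_effects,
    residual_sd,
    simulate_genotypes,
    variance_explained,
)


class TestSimulateGenotypes:
    def test_mean_dosage_at_half_maf(self):
        rng = np.random.default_rng(1)
        d = simulate_genotypes(0.5, 100_000, rng=rng)
        assert d.mean() == pytest.approx(1.0, abs=0.01)

    def test_hwe_frequencies_at_published_maf(self):
        """At MAF 0.135 the genotype classes appear in HWE proportions
        (0.748, 0.234, 0.018)."""
        rng = np.random.default_rng(2)
        d = simulate_genotypes(0.135, 100_000, rng=rng)
        freqs = np.array([(d == g).mean() for g in (0, 1, 2)])
        expected = np.array([0.865**2, 2 * 0.135 * 0.865, 0.135**2])
        np.testing.assert_allclose(freqs, expected, atol=0.006)

    def test_noise_controls_info_score(self):
        """With dosage_noise = 0.8 the squared correlation between noisy
        dosage and hard genotype is ~0.8 (the INFO-score analogue)."""
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.25, size=10_000).astype(float)
        from telogrs.synthetic_cohort import _noisy_dosage

        d = _noisy_dosage(g, 0.25, 0.8, rng)
        r2 = np.corrcoef(d, g)[0, 1] ** 2
        assert r2 == pytest.approx(0.8, abs=0.03)
        assert d.min() >= 0.0 and d.max() <= 2.0

    @pytest.mark.parametrize("maf,n", [(0.0, 10), (0.6, 10), (0.2, 0)])
    def test_invalid_parameters(self, maf, n):
        with pytest.raises(TelogrsError):
            simulate_genotypes(maf, n, rng=np.random.default_rng(0))

    def test_invalid_noise(self):
        with pytest.raises(TelogrsError):
            simulate_genotypes(0.2, 10, dosage_noise=0.0, rng=np.random.default_rng(0))

    def test_hwe_chi_square_calibration(self):
        """Under the null the HWE chi-square check at alpha=0.001 passes in
        >= 99% of simulated SNP draws."""
        rng = np.random.default_rng(4)
        n = 4000
        passes = 0
        reps = 400
        for i in range(reps):
            maf = rng.uniform(0.05, 0.5)
            g = rng.binomial(2, maf, size=n)
            counts = np.bincount(g, minlength=3)
            p = counts @ [0, 1, 2] / (2 * n)
            expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
            chi2 = np.sum((counts - expected) ** 2 / expected)
            passes += stats.chi2.sf(chi2, 1) > 0.001
        assert passes / reps >= 0.99


class TestSimulateCohort:
    def test_determinism(self):
        cfg = tg.SimulationConfig(n_cases=200, n_controls=200, n_strata=2, seed=99)
        a = tg.simulate_cohort(cfg)
        b = tg.simulate_cohort(cfg)
        np.testing.assert_array_equal(a[0].values, b[0].values)
        np.testing.assert_array_equal(a[1].status, b[1].status)
        np.testing.assert_array_equal(a[1].measured_telomere, b[1].measured_telomere)

    def test_quotas_and_strata(self, small_cohort):
        cfg, dosages, cohort, _ = small_cohort
        assert cohort.n_cases == cfg.n_cases
        assert cohort.n_controls == cfg.n_controls
        assert len(cohort.strata()) == cfg.n_strata
        assert dosages.values.shape == (cfg.n_cases + cfg.n_controls, 7)

    def test_null_model_maf_equal_in_cases_and_controls(self):
        cfg = tg.SimulationConfig(n_cases=4000, n_controls=4000, n_strata=1,
                                  gamma=0.0, seed=31)
        dosages, cohort, _ = tg.simulate_cohort(cfg)
        case = dosages.values[cohort.status == 1].mean(axis=0) / 2
        ctrl = dosages.values[cohort.status == 0].mean(axis=0) / 2
        se = np.sqrt(case * (1 - case) / (2 * 4000) + ctrl * (1 - ctrl) / (2 * 4000))
        assert np.all(np.abs(case - ctrl) < 4 * se)

    def test_induced_effect_signs_follow_telomere_betas(self):
        """Pure mediation: each SNP's induced disease effect has the sign
        of its telomere-length weight."""
        cfg = tg.SimulationConfig(seed=0)
        truth = tg.simulate_cohort(
            tg.SimulationConfig(n_cases=50, n_controls=50, n_strata=1, seed=0)
        )[2]
        for w in cfg.snps:
            assert np.sign(truth.per_snp_logor[w.rsid]) == np.sign(w.weight)
            assert np.sign(truth.per_snp_logor_marginal[w.rsid]) == np.sign(w.weight)

    def test_genetic_variance_fraction_calibrated(self):
        """The seven default SNPs explain 1.2% +- 0.2% of the latent trait."""
        cfg = tg.SimulationConfig(seed=0)
        pop = tg.simulate_population(cfg, 100_000, np.random.default_rng(55))
        r2 = variance_explained(pop["T"], pop["D"])
        assert r2 == pytest.approx(TARGET_GENETIC_VARIANCE_FRACTION, abs=0.002)

    def test_confounder_marginality(self):
        """Genotypes are assigned before the confounder acts: sample
        correlation |r| < 3/sqrt(n) for every SNP even under strong U."""
        cfg = tg.SimulationConfig(confounder_strength=(0.8, 0.8), seed=0)
        n = 20_000
        pop = tg.simulate_population(cfg, n, np.random.default_rng(66))
        for j in range(pop["G"].shape[1]):
            r = np.corrcoef(pop["G"][:, j], pop["U"])[0, 1]
            assert abs(r) < 3 / np.sqrt(n)

    def test_case_enrichment(self, small_cohort):
        _, dosages, cohort, _ = small_cohort
        sv = tg.compute_score(dosages, tg.default_weights())
        assert sv.values[cohort.status == 1].mean() > sv.values[cohort.status == 0].mean()

    def test_reverse_causation_shifts_measured_trait_only(self):
        base = tg.SimulationConfig(n_cases=500, n_controls=500, n_strata=1, seed=47)
        shifted = tg.SimulationConfig(n_cases=500, n_controls=500, n_strata=1,
                                      seed=47, reverse_causation_delta=0.7)
        d0, c0, _ = tg.simulate_cohort(base)
        d1, c1, _ = tg.simulate_cohort(shifted)
        np.testing.assert_array_equal(d0.values, d1.values)  # genotypes untouched
        cases = c0.status == 1
        np.testing.assert_allclose(
            c1.measured_telomere[cases] - c0.measured_telomere[cases], 0.7, atol=1e-12
        )
        np.testing.assert_allclose(
            c1.measured_telomere[~cases], c0.measured_telomere[~cases], atol=1e-12
        )

    def test_unattainable_quota_raises(self):
        cfg = tg.SimulationConfig(n_cases=500, n_controls=10, n_strata=1,
                                  alpha_by_stratum=(-18.0,), seed=1)
        with pytest.raises(SimulationError, match="quota"):
            tg.simulate_cohort(cfg)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_cases=0),
            dict(dosage_noise=0.0),
            dict(dosage_noise=1.5),
            dict(gamma=np.inf),
            dict(n_strata=3, alpha_by_stratum=(0.0,)),
        ],
    )
    def test_invalid_config(self, kwargs):
        with pytest.raises(TelogrsError):
            tg.SimulationConfig(**kwargs)


class TestInducedEffects:
    def test_null_gamma_gives_zero_effects(self):
        cfg = tg.SimulationConfig(gamma=0.0, seed=0)
        eff = induced_effects(cfg)
        assert eff["score"] == pytest.approx(0.0, abs=1e-10)

    def test_confounder_without_gamma_leaves_genotypes_null(self):
        """Even a strong shared confounder induces no genotype-disease
        effect: the instrument argument in exact form."""
        cfg = tg.SimulationConfig(gamma=0.0, confounder_strength=(0.9, 0.9), seed=0)
        eff = induced_effects(cfg)
        assert abs(eff["score"]) < 1e-10
        assert all(abs(eff[w.rsid]) < 1e-10 for w in cfg.snps)

    def test_marginal_attenuated_vs_conditional(self):
        cfg = tg.SimulationConfig(seed=0)
        truth = tg.simulate_cohort(
            tg.SimulationConfig(n_cases=50, n_controls=50, n_strata=1, seed=0)
        )[2]
        assert 0 < truth.score_logor_marginal < truth.score_logor_conditional

    def test_matches_large_simulation(self):
        """The enumerated estimand agrees with a brute-force fit on a very
        large simulated cohort (independent Monte Carlo oracle)."""
        cfg = tg.SimulationConfig(n_cases=60_000, n_controls=60_000, n_strata=1, seed=1234)
        dosages, cohort, truth = tg.simulate_cohort(cfg)
        sv = tg.compute_score(dosages, list(cfg.snps))
        _, meta = tg.score_association(sv, cohort)
        assert abs(meta.beta - truth.score_logor_marginal) < 3 * meta.se

    def test_residual_sd_closed_form(self, weights):
        vg = sum(w.weight**2 * 2 * w.maf * (1 - w.maf) for w in weights)
        sd = residual_sd(weights)
        assert vg / (vg + sd**2) == pytest.approx(0.012, abs=1e-12)
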