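"""Generators: determinism, domain constraints, and moment recovery."""

import numpy as np
import pandas as pd
import pytest

import stemnsc as sn
from stemnsc.spectra import snv


class TestGenotypes:
    def test_domain_and_shape(self):
        g = sn.simulate_genotypes(2, 5, maf_range=(0.5, 0.5), seed=1)
        assert g.dosages.shape == (2, 5)
        assert np.isin(g.dosages, (0.0, 1.0, 2.0)).all()

    def test_deterministic_given_seed(self):
        a = sn.simulate_genotypes(10, 50, seed=42)
        b = sn.simulate_genotypes(10, 50, seed=42)
        assert np.array_equal(a.dosages, b.dosages)
        assert not np.array_equal(a.dosages, sn.simulate_genotypes(10, 50, seed=43).dosages)

    def test_binomial_mean(self):
        # Binomial(2, 0.2) expectation oracle: mean dosage 0.4, se = sqrt(2pq/n)
        g = sn.simulate_genotypes(10_000, 1, maf_range=(0.2, 0.2), seed=5)
        se = np.sqrt(2 * 0.2 * 0.8 / 10_000)
        assert abs(g.dosages.mean() - 0.4) < 3 * se

    @pytest.mark.parametrize("bad", [(0.0, 0.5), (0.1, 0.6), (-0.1, 0.2), (0.4, 0.2)])
    def test_invalid_maf_range(self, bad):
        with pytest.raises(ValueError):
            sn.simulate_genotypes(5, 5, maf_range=bad)

    def test_allele_freq_invariant(self):
        g = sn.simulate_genotypes(50, 20, seed=9)
        assert np.allclose(g.allele_freqs, g.dosages.mean(axis=0) / 2, atol=1e-12)


class TestPhenotypes:
    def test_zero_genetic_variance_gives_zero_truth(self, small_genotypes):
        cfg = sn.PhenoSimConfig(n_reps=4, var_additive=0.0, var_nonadditive=0.0,
                                var_error=1.0, seed=1)
        sim = sn.simulate_phenotypes(small_genotypes, cfg)
        assert sim.truth["genetic"].abs().max() == 0.0

    def test_perfect_genetic_correlation(self, small_genotypes):
        cfg = sn.PhenoSimConfig(n_reps=3, var_additive=(0.5, 0.8), var_nonadditive=0.0,
                                var_error=0.2, genetic_corr=1.0,
                                traits=("STCH_HD", "SUC_HD"), seed=2)
        sim = sn.simulate_phenotypes(small_genotypes, cfg)
        a1 = sim.trait_truth("STCH_HD")
        a2 = sim.trait_truth("SUC_HD")
        assert np.corrcoef(a1, a2)[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_additive_variance_targets_config(self):
        # Monte-Carlo oracle: across seeds the realised Var(a) averages to 0.6
        geno = sn.simulate_genotypes(200, 300, seed=3)
        vars_ = []
        for seed in range(20):
            cfg = sn.PhenoSimConfig(n_reps=2, var_additive=0.6, var_nonadditive=0.1,
                                    var_error=0.3, seed=seed)
            sim = sn.simulate_phenotypes(geno, cfg)
            vars_.append(sim.trait_truth("DTH").var(ddof=1))
        assert np.mean(vars_) == pytest.approx(0.6, rel=0.15)

    def test_realized_heritability_matches_target(self):
        geno = sn.simulate_genotypes(150, 300, seed=4)
        h2 = []
        for seed in range(20):
            cfg = sn.PhenoSimConfig(n_reps=5, var_additive=0.6, var_nonadditive=0.1,
                                    var_error=0.3, seed=100 + seed)
            sim = sn.simulate_phenotypes(geno, cfg)
            tab = sim.table.pivot_table(index=["line", "replicate"], columns="trait",
                                        values="value")
            va = sim.trait_truth("DTH").var(ddof=1)
            vp = tab["DTH"].var(ddof=1)
            h2.append(va / vp)
        assert np.mean(h2) == pytest.approx(0.6, abs=0.07)

    def test_replicate_error(self, small_genotypes):
        with pytest.raises(ValueError, match="n_reps"):
            sn.simulate_phenotypes(small_genotypes, sn.PhenoSimConfig(n_reps=1))

    def test_genotypes_required_for_additive(self):
        cfg = sn.PhenoSimConfig(n_lines=10, n_reps=3, var_additive=0.5)
        with pytest.raises(ValueError, match="genotypes"):
            sn.simulate_phenotypes(None, cfg)

    def test_deterministic(self, small_genotypes):
        cfg = sn.PhenoSimConfig(n_reps=3, seed=77)
        a = sn.simulate_phenotypes(small_genotypes, cfg)
        b = sn.simulate_phenotypes(small_genotypes, cfg)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_student_t_errors_have_target_variance(self, small_genotypes):
        cfg = sn.PhenoSimConfig(n_reps=400, var_additive=0.0, var_nonadditive=0.0,
                                var_error=0.5, error_family="student_t", t_df=5, seed=8)
        sim = sn.simulate_phenotypes(small_genotypes, cfg)
        assert sim.table["value"].var(ddof=1) == pytest.approx(0.5, rel=0.1)


class TestSpectra:
    def test_zero_concentration_flat_spectrum(self):
        conc = pd.DataFrame({"starch": [0.0], "sucrose": [0.0]}, index=["S1"])
        cfg = sn.SpectraSimConfig(noise_sd=0.0, scatter_log_sd=0.0,
                                  baseline_offset_sd=0.0, baseline_slope_sd=0.0,
                                  matrix_bands=None, wetchem_error_sd=0.0, seed=1)
        sim = sn.simulate_spectra(conc, cfg)
        assert np.all(sim.spectra.absorbance == 0.0)

    def test_linearity_in_concentration(self):
        conc = pd.DataFrame({"starch": [0.1, 0.2], "sucrose": [0.05, 0.1]},
                            index=["A", "B"])
        cfg = sn.SpectraSimConfig(noise_sd=0.0, scatter_log_sd=0.0,
                                  baseline_offset_sd=0.0, baseline_slope_sd=0.0,
                                  matrix_bands=None, wetchem_error_sd=0.0, seed=1)
        sim = sn.simulate_spectra(conc, cfg)
        # doubling every concentration doubles the absorbance everywhere
        assert np.allclose(2 * sim.spectra.absorbance[0], sim.spectra.absorbance[1])

    def test_snv_removes_scatter(self):
        # two samples, identical composition, scatter + offsets on, no noise:
        # after SNV the spectra agree exactly
        conc = pd.DataFrame({"starch": [0.2, 0.2], "sucrose": [0.05, 0.05]},
                            index=["A", "B"])
        cfg = sn.SpectraSimConfig(noise_sd=0.0, baseline_slope_sd=0.0,
                                  scatter_log_sd=0.3, baseline_offset_sd=0.05,
                                  wetchem_error_sd=0.0, seed=4)
        sim = sn.simulate_spectra(conc, cfg)
        assert not np.allclose(sim.spectra.absorbance[0], sim.spectra.absorbance[1])
        corrected = snv(sim.spectra).absorbance
        assert np.allclose(corrected[0], corrected[1], atol=1e-10)

    def test_constituent_mismatch(self):
        conc = pd.DataFrame({"starch": [0.1]}, index=["S1"])
        with pytest.raises(ValueError, match="constituents"):
            sn.simulate_spectra(conc, sn.SpectraSimConfig())

    def test_wetchem_replicates_and_gross_errors(self):
        conc = sn.simulate_nsc_concentrations(20, seed=1)
        cfg = sn.SpectraSimConfig(seed=2, wetchem_reps=3, gross_error_ids=(0, 3),
                                  gross_error_size=0.1)
        sim = sn.simulate_spectra(conc, cfg)
        assert len(sim.wetchem_replicates) == 60
        err = (sim.spectra.constituents - sim.true_concentrations)["starch"]
        assert abs(err.iloc[0]) > 0.05 and abs(err.iloc[3]) > 0.05
        assert err.drop(err.index[[0, 3]]).abs().max() < 0.05

    def test_deterministic(self):
        conc = sn.simulate_nsc_concentrations(5, seed=1)
        a = sn.simulate_spectra(conc, sn.SpectraSimConfig(seed=9))
        b = sn.simulate_spectra(conc, sn.SpectraSimConfig(seed=9))
        assert np.array_equal(a.spectra.absorbance, b.spectra.absorbance)
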