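"""Outlier rule, reference uncertainty, and the calibration workflow."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gamma as gamma_fn

import stemnsc as sn
from stemnsc.calibrate import (CalibrationConfig, detect_outliers, pretreat,
                               reference_uncertainty)


class TestDetectOutliers:
    def test_threshold_arithmetic(self):
        pred = np.array([0.01, 0.05, 0.039])
        ref = np.zeros(3)
        out = detect_outliers(pred, ref, 0.02, sample_ids=["a", "b", "c"])
        assert out == ["b"]  # |0.039| is below the strict 0.04 threshold

    def test_zero_residuals_empty(self):
        y = np.arange(5.0)
        assert detect_outliers(y, y, 0.1) == []

    def test_pls2_either_response_rule(self):
        rng = np.random.default_rng(3)
        pred = rng.normal(size=(30, 2))
        ref = pred + rng.normal(0, 0.5, size=(30, 2))
        thr = np.array([0.6, 0.8])
        flagged = detect_outliers(pred, ref, thr)
        brute = [i for i in range(30)
                 if abs(pred[i, 0] - ref[i, 0]) > 2 * thr[0]
                 or abs(pred[i, 1] - ref[i, 1]) > 2 * thr[1]]
        assert flagged == brute


class TestReferenceUncertainty:
    def test_hand_values(self):
        df = pd.DataFrame({
            "sample_id": ["a"] * 2 + ["b"] * 2,
            "value": [0.0, 0.02 * np.sqrt(2), 1.0, 1.0 + 0.04 * np.sqrt(2)],
        })
        # within-sample SDs are exactly 0.02 and 0.04 -> 2 * mean = 0.06
        assert reference_uncertainty(df) == pytest.approx(0.06)

    def test_identical_replicates_zero(self):
        df = pd.DataFrame({"sample_id": ["a", "a", "b", "b"], "value": [1.0] * 4})
        assert reference_uncertainty(df) == 0.0

    def test_single_replicate_excluded_with_warning(self):
        df = pd.DataFrame({"sample_id": ["a", "a", "b"], "value": [1.0, 2.0, 5.0]})
        with pytest.warns(UserWarning, match="excluding"):
            out = reference_uncertainty(df)
        assert out == pytest.approx(2 * np.std([1.0, 2.0], ddof=1))

    def test_simulation_matches_c4_oracle(self):
        # E[sd of 3 normals] = c4(3) * tau with c4 = sqrt(2/(n-1)) G(n/2)/G((n-1)/2)
        tau, n_rep = 0.01, 3
        rng = np.random.default_rng(9)
        rows = []
        for s in range(150):
            for r in range(n_rep):
                rows.append({"sample_id": f"s{s}", "value": rng.normal(0, tau)})
        c4 = np.sqrt(2 / (n_rep - 1)) * gamma_fn(n_rep / 2) / gamma_fn((n_rep - 1) / 2)
        est = reference_uncertainty(pd.DataFrame(rows))
        assert est == pytest.approx(2 * tau * c4, rel=0.08)


@pytest.fixture(scope="module")
def synthetic_study():
    """Deterministic 434-sample study with planted gross wet-chem errors."""
    conc = sn.simulate_nsc_concentrations(434, seed=5)
    cfg = sn.SpectraSimConfig(seed=6, wetchem_reps=3,
                              gross_error_ids=tuple(range(0, 40, 5)),
                              gross_error_size=0.06)
    return cfg, sn.simulate_spectra(conc, cfg)


class TestCalibrateWorkflow:
    @pytest.fixture(scope="class")
    def report(self, synthetic_study):
        _, sim = synthetic_study
        return sn.calibrate(
            sim.spectra,
            CalibrationConfig(responses=("TNC",), mode="pls1", n_components=3),
            wetchem_replicates=sim.wetchem_replicates,
        )

    def test_bookkeeping(self, report, synthetic_study):
        _, sim = synthetic_study
        assert report.n_calibration + report.n_validation == sim.spectra.n_samples
        assert set(report.outlier_ids) <= set(report.calibration_ids)
        assert len(report.outlier_ids) <= report.n_calibration

    def test_reference_uncertainty_reported(self, report):
        # TNC triplicate error is sqrt(2) * per-constituent error
        assert report.reference_uncertainty["TNC"] == pytest.approx(
            2 * np.sqrt(2) * 6e-3 * 0.8862, rel=0.15)

    def test_table_shape(self, report):
        table = report.table()
        assert "RMSEP validation" in table.index
        assert table.loc["Calibration samples", "TNC"] == 300

    def test_noiseless_validation_r2(self):
        """With every nuisance off (hence no SNV needed) the model class is
        exact: validation R2 > 0.999 at the true component count (two
        constituents)."""
        conc = sn.simulate_nsc_concentrations(60, seed=11)
        cfg = sn.SpectraSimConfig(noise_sd=0.0, scatter_log_sd=0.0,
                                  baseline_offset_sd=0.0, baseline_slope_sd=0.0,
                                  wetchem_error_sd=0.0, seed=12)
        sim = sn.simulate_spectra(conc, cfg)
        rep = sn.calibrate(sim.spectra, CalibrationConfig(
            responses=("TNC",), mode="pls1", n_components=2, cal_size=40,
            apply_snv=False))
        assert rep.r2_validation["TNC"] > 0.999

    def test_validation_leak_free(self, synthetic_study):
        """Permuting validation-set responses changes no fitted parameter."""
        _, sim = synthetic_study
        cfg = CalibrationConfig(responses=("TNC",), mode="pls1", n_components=3,
                                cal_size=300)
        rep_a = sn.calibrate(sim.spectra, cfg)
        scrambled = sim.spectra.constituents.copy()
        val = list(rep_a.validation_ids)
        perm = np.random.default_rng(0).permutation(len(val))
        scrambled.loc[val] = scrambled.loc[val].to_numpy()[perm]
        spectra_b = sn.SpectraSet(sim.spectra.wavenumbers, sim.spectra.absorbance,
                                  sim.spectra.sample_ids, constituents=scrambled)
        rep_b = sn.calibrate(spectra_b, cfg)
        assert np.array_equal(rep_a.model.coef, rep_b.model.coef)
        assert rep_a.outlier_ids == rep_b.outlier_ids
        assert rep_a.rmsec == rep_b.rmsec

    def test_rmsec_not_above_rmsecv(self):
        """Training-error optimism: RMSEC <= RMSECV on nearly all random
        synthetic datasets at matched component count."""
        holds = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(25, 12))
            y = x @ rng.normal(size=12) + rng.normal(0, 0.5, 25)
            m = sn.fit_pls(x, y, 3, mode="pls1")
            fit_rmse = sn.rmse(sn.predict(m, x), y)
            cv = sn.cross_validate(x, y, 3, mode="pls1")
            holds += fit_rmse <= cv.rmsecv[2, 0] + 1e-12
        assert holds >= 19

    def test_pretreat_records_chain(self, synthetic_study):
        _, sim = synthetic_study
        pre = pretreat(sim.spectra, CalibrationConfig())
        assert pre.treatments == ("restrict[4000,9000]", "snv", "savgol[w=25,p=2,d=1]")
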