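"""Noise filtering, charge deconvolution, CE-time calibration,
housekeeping normalization and the sample QC gate."""

import numpy as np
import pandas as pd
import pytest

from uromarker import (
    CalibrationError,
    GroundTruth,
    NormalizationError,
    PROTON_MASS,
    ReferenceSet,
    SimConfig,
    calibrate_migration_time,
    deconvolute_charges,
    filter_signals,
    generate_raw_signals,
    loess_fit,
    normalize_amplitudes,
    qc_sample,
)

from conftest import make_matrix


def sig(mz, z, intensity, spectrum_index, noise=1.0):
    return {"mz": mz, "z": z, "intensity": intensity,
            "spectrum_index": spectrum_index, "noise_level": noise}


def trace(mz, z, intensity, start, n=3, noise=1.0):
    return [sig(mz, z, intensity, start + k, noise) for k in range(n)]


class TestFilterSignals:
    def test_singly_charged_removed(self):
        df = pd.DataFrame(trace(500.0, 1, 100.0, 10))
        assert len(filter_signals(df)) == 0

    def test_two_spectra_removed_three_kept(self):
        short = pd.DataFrame(trace(500.0, 2, 100.0, 5, n=2))
        full = pd.DataFrame(trace(500.0, 2, 100.0, 5, n=3))
        assert len(filter_signals(short)) == 0
        assert len(filter_signals(full)) == 3

    def test_snr_boundary_at_four(self):
        kept = pd.DataFrame(trace(500.0, 2, 8.0, 5, noise=2.0))
        removed = pd.DataFrame(trace(500.0, 2, 7.9, 5, noise=2.0))
        assert len(filter_signals(kept)) == 3
        assert len(filter_signals(removed)) == 0

    def test_gap_breaks_a_run(self):
        rows = trace(500.0, 2, 100.0, 5, n=2) + trace(500.0, 2, 100.0, 9, n=2)
        assert len(filter_signals(pd.DataFrame(rows))) == 0

    def test_empty_input_empty_output(self):
        df = pd.DataFrame(columns=["mz", "z", "intensity", "spectrum_index", "noise_level"])
        assert len(filter_signals(df)) == 0


class TestDeconvolution:
    def test_single_signal_neutral_mass_by_hand(self):
        df = pd.DataFrame([sig(501.00364, 2, 10.0, 400)])
        peaks = deconvolute_charges(df)
        assert len(peaks) == 1
        assert peaks["mass_da"].iloc[0] == pytest.approx(2 * (501.00364 - 1.00728), abs=1e-9)

    def test_conjugate_charge_states_merge_and_sum(self):
        mass = 2000.0
        rows = [
            sig((mass + 2 * PROTON_MASS) / 2, 2, 10.0, 400),
            sig((mass * (1 + 10e-6) + 3 * PROTON_MASS) / 3, 3, 5.0, 401),
        ]
        peaks = deconvolute_charges(pd.DataFrame(rows))
        assert len(peaks) == 1
        assert peaks["amplitude"].iloc[0] == pytest.approx(15.0)

    def test_beyond_tolerance_stays_separate(self):
        rows = [
            sig((2000.0 + 2 * PROTON_MASS) / 2, 2, 10.0, 400),
            sig((2000.0 * (1 + 200e-6) + 2 * PROTON_MASS) / 2, 2, 10.0, 400),
        ]
        assert len(deconvolute_charges(pd.DataFrame(rows))) == 2

    def test_idempotent_on_its_own_output(self):
        rng = np.random.default_rng(0)
        masses = np.sort(rng.uniform(800, 5000, 30))
        rows = [sig((m + 2 * PROTON_MASS) / 2, 2, 10.0, int(25 * 20)) for m in masses]
        peaks = deconvolute_charges(pd.DataFrame(rows))
        again = deconvolute_charges(
            pd.DataFrame(
                {
                    "mz": (peaks["mass_da"] + 2 * PROTON_MASS) / 2,
                    "z": 2,
                    "intensity": peaks["amplitude"],
                    "spectrum_index": (peaks["cetime_min"] * 20).round().astype(int),
                    "noise_level": 1.0,
                }
            )
        )
        assert len(again) == len(peaks)
        assert np.allclose(np.sort(again["mass_da"]), np.sort(peaks["mass_da"]), atol=1e-6)


def _refs(cal_masses, cal_times, hk=None):
    calibrants = pd.DataFrame({"mass_da": cal_masses, "cetime_min": cal_times})
    if hk is None:
        hk = pd.DataFrame({"mass_da": [1500.0], "cetime_min": [30.0], "amplitude": [100.0]})
    return ReferenceSet(calibrants=calibrants, housekeeping=hk)


class TestCalibration:
    def setup_method(self):
        self.canon = np.linspace(20, 44, 8)
        self.masses = np.linspace(900, 4500, 8)

    def _peaks(self, times):
        return pd.DataFrame(
            {"mass_da": self.masses, "cetime_min": times, "amplitude": 100.0}
        )

    def test_constant_offset_recovered(self):
        peaks = self._peaks(self.canon + 1.0)
        out, resid = calibrate_migration_time(peaks, _refs(self.masses, self.canon))
        assert np.allclose(out["cetime_min"], self.canon, atol=1e-6)
        assert resid < 1e-6

    def test_affine_stretch_recovered(self):
        peaks = self._peaks(1.05 * self.canon)
        out, resid = calibrate_migration_time(peaks, _refs(self.masses, self.canon))
        assert resid < 0.01
        assert np.allclose(out["cetime_min"], self.canon, atol=0.01)

    def test_already_calibrated_is_identity(self):
        peaks = self._peaks(self.canon)
        out, resid = calibrate_migration_time(peaks, _refs(self.masses, self.canon))
        assert np.allclose(out["cetime_min"], self.canon, atol=1e-9)
        assert resid < 1e-9

    def test_too_few_calibrant_matches_raises(self):
        peaks = self._peaks(self.canon)
        refs = _refs(self.masses + 500.0, self.canon)  # nothing within tolerance
        with pytest.raises(CalibrationError):
            calibrate_migration_time(peaks, refs)

    def test_sample_offset_recovered_through_raw_pipeline(self):
        # constant +1.0 min instrument shift removed to < 0.05 min
        masses = np.linspace(800, 4000, 40)
        times = np.linspace(20, 44, 40)
        m = make_matrix(masses, times, np.full((40, 1), 100.0))
        truth = GroundTruth(
            peptides=pd.DataFrame(index=m.peptides.index),
            samples=pd.DataFrame(
                {"dilution_log10": [0.0], "time_offset_min": [1.0]},
                index=pd.Index(["s1"], name="sample_id"),
            ),
        )
        cfg = SimConfig(n_peptides=40, n_housekeeping=0, n_calibrants=0,
                        n_differential_type=0, n_age_correlated=0,
                        mass_noise_ppm=0.0, time_noise_min=0.0,
                        n_noise_signals=0, seed=1)
        signals = generate_raw_signals(m, truth, cfg, samples=["s1"])["s1"]
        peaks = deconvolute_charges(filter_signals(signals))
        refs = _refs(masses[::4], times[::4])
        out, resid = calibrate_migration_time(peaks, refs)
        assert resid < 0.05
        matched = out["cetime_min"].to_numpy()
        # systematic shift removed to < 0.05 min; each peak lands within its
        # true time up to the spectrum raster (half-bin = 1/(2*20) min)
        err = matched[:, None] - times[None, :]
        nearest = err[np.arange(len(matched)), np.argmin(np.abs(err), axis=1)]
        assert abs(nearest.mean()) < 0.05
        assert np.abs(nearest).max() < 0.05 + 0.5 / cfg.spectra_per_min


class TestNormalization:
    def _sample(self, scale):
        hk = pd.DataFrame(
            {"mass_da": [1000.0, 2000.0, 3000.0],
             "cetime_min": [22.0, 30.0, 38.0],
             "amplitude": [100.0, 200.0, 50.0]}
        )
        peaks = pd.DataFrame(
            {"mass_da": [1000.0, 2000.0, 3000.0, 4000.0],
             "cetime_min": [22.0, 30.0, 38.0, 41.0],
             "amplitude": [100.0 * scale, 200.0 * scale, 50.0 * scale, 70.0]}
        )
        return peaks, ReferenceSet(calibrants=pd.DataFrame(columns=["mass_da", "cetime_min"]),
                                   housekeeping=hk)

    def test_double_observed_halves_everything(self):
        peaks, refs = self._sample(2.0)
        out = normalize_amplitudes(peaks, refs)
        assert np.allclose(out["amplitude"], [100.0, 200.0, 50.0, 35.0])

    def test_already_canonical_is_identity(self):
        peaks, refs = self._sample(1.0)
        out = normalize_amplitudes(peaks, refs)
        assert np.allclose(out["amplitude"], peaks["amplitude"])

    def test_scale_equivariance(self):
        peaks, refs = self._sample(1.7)
        out1 = normalize_amplitudes(peaks, refs)
        peaks2 = peaks.copy()
        peaks2["amplitude"] *= 13.0
        out2 = normalize_amplitudes(peaks2, refs)
        assert np.allclose(out1["amplitude"], out2["amplitude"])

    def test_missing_housekeeping_raises(self):
        peaks, refs = self._sample(1.0)
        refs.housekeeping["mass_da"] += 500.0
        with pytest.raises(NormalizationError):
            normalize_amplitudes(peaks, refs)

    @pytest.mark.parametrize("mode", ["global_median_ratio", "lowess"])
    def test_dilution_cv_shrinks_across_cohort(self, mode, small_cohort):
        # per-sample dilution SD 0.3 log10: normalizing against housekeeping
        # must strictly reduce the cross-sample CV of housekeeping amplitudes
        cfg, _, matrix, truth = small_cohort
        from uromarker import reference_set_from_truth

        refs = reference_set_from_truth(matrix, truth)
        hk_ids = truth.peptides.index[truth.peptides.is_housekeeping]
        pre = matrix.amplitudes.loc[hk_ids]
        post = {}
        for s in matrix.sample_ids:
            det = matrix.amplitudes[s] > 0
            peaks = pd.DataFrame(
                {"mass_da": matrix.peptides.loc[det, "mass_da"],
                 "cetime_min": matrix.peptides.loc[det, "cetime_min"],
                 "amplitude": matrix.amplitudes.loc[det, s]}
            ).reset_index()
            out = normalize_amplitudes(peaks, refs, mode=mode)
            post[s] = out.set_index("peptide_id")["amplitude"].reindex(hk_ids)
        post = pd.DataFrame(post)
        cv_pre = (pre.std(axis=1, ddof=1) / pre.mean(axis=1)).median()
        cv_post = (post.std(axis=1, ddof=1) / post.mean(axis=1)).median()
        assert cv_post < cv_pre


class TestQC:
    def _peaks(self, n, t0=19.0, t1=45.0):
        return pd.DataFrame(
            {"mass_da": np.linspace(800, 5000, n),
             "cetime_min": np.linspace(t0, t1, n),
             "amplitude": 1.0}
        )

    def test_passing_sample(self):
        rep = qc_sample(self._peaks(950), mean_residual=0.1)
        assert rep.passed and rep.reasons == []

    def test_low_count_fails_with_reason(self):
        rep = qc_sample(self._peaks(949), mean_residual=0.1)
        assert not rep.passed
        assert any("count" in r for r in rep.reasons)

    def test_residual_boundary_is_strict(self):
        rep = qc_sample(self._peaks(950), mean_residual=0.35)
        assert not rep.passed

    def test_narrow_span_fails(self):
        rep = qc_sample(self._peaks(950, 30.0, 35.0), mean_residual=0.1)
        assert not rep.passed
        assert any("span" in r for r in rep.reasons)


def test_loess_reproduces_affine_exactly():
    x = np.linspace(0, 10, 17)
    y = 3.0 * x - 2.0
    out = loess_fit(x, y, np.array([0.5, 5.0, 9.7]))
    assert np.allclose(out, 3.0 * np.array([0.5, 5.0, 9.7]) - 2.0, atol=1e-9)
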