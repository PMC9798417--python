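"""Scan averaging, mass binning, normalization, autoscaling, QC reporting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metafinger import (PeakMatrix, SampleRecord, Spectrum, average_scans,
                        bin_to_matrix, log_autoscale, qc_report, read_matrix,
                        tic_normalize, write_matrix)
from metafinger.peakmatrix import LOG_SCALED, RAW, TIC_NORMALIZED, concat_polarities

from conftest import make_spectrum


class TestSpectrum:
    def test_rejects_unsorted_mz(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            Spectrum([100.0, 99.0], [1.0, 1.0])

    def test_rejects_negative_intensity(self):
        with pytest.raises(ValueError, match="non-negative"):
            Spectrum([100.0], [-1.0])

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            Spectrum([100.0, 101.0], [1.0])


class TestAverageScans:
    def test_identical_scans_are_idempotent(self):
        scan = make_spectrum([100.0, 150.0, 200.0], [5.0, 10.0, 2.0])
        avg = average_scans([scan] * 10)
        np.testing.assert_allclose(avg.mz, scan.mz)
        np.testing.assert_allclose(avg.intensity, scan.intensity)

    def test_absence_counts_as_zero(self):
        # peak present at 8 in one of two scans averages to 4
        a = make_spectrum([100.0, 150.0], [8.0, 2.0])
        b = make_spectrum([150.0], [2.0])
        avg = average_scans([a, b])
        assert avg.intensity[np.argmin(np.abs(avg.mz - 100.0))] == pytest.approx(4.0)

    def test_peaks_within_tolerance_merge(self):
        a = make_spectrum([100.000], [10.0])
        b = make_spectrum([100.004], [30.0])
        avg = average_scans([a, b], tolerance=0.005)
        assert len(avg) == 1
        # intensity-weighted centroid leans toward the stronger peak
        assert avg.mz[0] == pytest.approx((10 * 100.000 + 30 * 100.004) / 40)
        assert avg.intensity[0] == pytest.approx(20.0)

    def test_mixed_polarity_rejected(self):
        a = make_spectrum([100.0], [1.0], "positive")
        b = make_spectrum([100.0], [1.0], "negative")
        with pytest.raises(ValueError, match="polarity"):
            average_scans([a, b])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            average_scans([])


class TestBinning:
    def test_close_peaks_share_a_bin(self):
        spectra = {"a": make_spectrum([100.000], [5.0]),
                   "b": make_spectrum([100.004], [7.0])}
        pm = bin_to_matrix(spectra, tolerance=0.005)
        assert pm.values.shape == (2, 1)
        assert np.all(pm.values > 0)

    def test_gap_beyond_window_splits_bins(self):
        spectra = {"a": make_spectrum([100.000, 100.020], [5.0, 6.0])}
        pm = bin_to_matrix(spectra, tolerance=0.005)
        assert pm.values.shape == (1, 2)

    def test_single_peak_single_sample(self):
        pm = bin_to_matrix({"a": make_spectrum([123.4], [9.0])})
        assert pm.values.shape == (1, 1)
        assert pm.values[0, 0] == 9.0
        assert pm.stage == RAW

    def test_empty_spectrum_gives_zero_row(self):
        spectra = {"a": make_spectrum([100.0], [5.0]),
                   "b": make_spectrum([], [])}
        pm = bin_to_matrix(spectra)
        row_b = pm.values[pm.sample_ids.index("b")]
        assert np.all(row_b == 0)

    def test_no_spectra_is_an_error(self):
        with pytest.raises(ValueError):
            bin_to_matrix({})

    @settings(deadline=None, max_examples=25)
    @given(st.randoms(use_true_random=False))
    def test_sample_order_only_permutes_rows(self, rand):
        base = {f"s{i}": make_spectrum([100.0 + i * 0.001, 150.0], [float(i + 1), 2.0])
                for i in range(5)}
        keys = list(base)
        rand.shuffle(keys)
        pm1 = bin_to_matrix(base)
        pm2 = bin_to_matrix({k: base[k] for k in keys})
        order = [pm2.sample_ids.index(s) for s in pm1.sample_ids]
        np.testing.assert_allclose(pm1.values, pm2.values[order])
        np.testing.assert_allclose(pm1.bin_mz, pm2.bin_mz)


class TestTicNormalize:
    def _pm(self, values):
        values = np.atleast_2d(np.asarray(values, float))
        samples = [SampleRecord(f"s{i}", "serum", "HD", "", i)
                   for i in range(values.shape[0])]
        return PeakMatrix(values, np.arange(values.shape[1]) + 100.0, samples)

    def test_divides_by_row_mean(self):
        out = tic_normalize(self._pm([10.0, 30.0, 60.0]))
        np.testing.assert_allclose(out.values[0], [0.3, 0.9, 1.8])
        assert out.stage == TIC_NORMALIZED

    def test_scale_invariance(self):
        pm = self._pm([[1.0, 2.0, 7.0], [3.0, 6.0, 21.0]])
        out = tic_normalize(pm)
        np.testing.assert_allclose(out.values[0], out.values[1])

    def test_all_zero_row_warns_and_passes_through(self):
        with pytest.warns(UserWarning, match="all-zero"):
            out = tic_normalize(self._pm([[1.0, 2.0], [0.0, 0.0]]))
        np.testing.assert_array_equal(out.values[1], [0.0, 0.0])

    def test_wrong_stage_rejected(self):
        out = tic_normalize(self._pm([1.0, 2.0]))
        with pytest.raises(ValueError, match="raw"):
            tic_normalize(out)


class TestLogAutoscale:
    def _normalized(self, values):
        values = np.asarray(values, float)
        samples = [SampleRecord(f"s{i}", "serum", "HD", "", i)
                   for i in range(values.shape[0])]
        pm = PeakMatrix(values, np.arange(values.shape[1]) + 100.0, samples)
        return tic_normalize(pm)

    def test_columns_standardized(self, rng):
        pm = self._normalized(rng.lognormal(size=(12, 6)))
        out = log_autoscale(pm)
        assert out.stage == LOG_SCALED
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.values.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_constant_column_becomes_zero(self):
        pm = self._normalized([[2.0, 1.0], [2.0, 5.0], [2.0, 9.0]])
        # after TIC normalization column 0 may vary; build directly instead
        pm.values[:, 0] = 1.0
        out = log_autoscale(pm)
        np.testing.assert_array_equal(out.values[:, 0], 0.0)

    def test_e_squared_ratio_maps_to_unit_pair(self):
        # two samples with one bin at v and v*e^2: ln gap 2, centered ±1 after sd scaling
        samples = [SampleRecord("a", "serum", "HD", "", 0),
                   SampleRecord("b", "serum", "HD", "", 1)]
        v = 3.0
        pm = PeakMatrix(np.array([[v], [v * np.e ** 2]]), np.array([100.0]), samples,
                        stage=TIC_NORMALIZED)
        out = log_autoscale(pm, epsilon=0.0)
        np.testing.assert_allclose(out.values[:, 0], [-np.sqrt(0.5), np.sqrt(0.5)])

    def test_negative_values_rejected(self):
        samples = [SampleRecord("a", "serum", "HD", "", 0)]
        pm = PeakMatrix(np.array([[-1.0]]), np.array([100.0]), samples,
                        stage=TIC_NORMALIZED)
        with pytest.raises(ValueError, match="negative"):
            log_autoscale(pm)


class TestQCReport:
    def _pm_with_qc(self, qc_values, run_indices=None):
        qc_values = np.asarray(qc_values, float)
        n = qc_values.shape[0]
        runs = run_indices or list(range(n))
        samples = [SampleRecord(f"q{i}", "qc", "QC", "", runs[i]) for i in range(n)]
        return PeakMatrix(qc_values, np.arange(qc_values.shape[1]) + 100.0, samples)

    def test_identical_qc_rows_have_zero_rsd(self):
        rep = qc_report(self._pm_with_qc([[5.0, 2.0]] * 3))
        np.testing.assert_allclose(rep["table"]["rsd"], 0.0)

    def test_rsd_matches_hand_computation(self):
        rep = qc_report(self._pm_with_qc([[90.0], [100.0], [110.0]]))
        assert rep["table"]["rsd"].iloc[0] == pytest.approx(0.10)

    def test_monotone_bin_has_unit_drift_correlation(self):
        rep = qc_report(self._pm_with_qc([[1.0], [2.0], [5.0]], [0, 10, 20]))
        assert rep["table"]["drift_spearman"].iloc[0] == pytest.approx(1.0)

    def test_requires_two_qc_samples(self):
        with pytest.raises(ValueError, match="QC"):
            qc_report(self._pm_with_qc([[1.0]]))


class TestMatrixIO:
    def test_round_trip_is_bit_identical(self, tmp_path, rng):
        values = rng.lognormal(size=(4, 7))
        samples = [SampleRecord(f"s{i}", "serum", "HD", "", i) for i in range(4)]
        pm = PeakMatrix(values, np.sort(rng.uniform(50, 1000, 7)), samples)
        write_matrix(pm, tmp_path / "m.tsv")
        back = read_matrix(tmp_path / "m.tsv")
        np.testing.assert_array_equal(back.values, pm.values)
        np.testing.assert_array_equal(back.bin_mz, pm.bin_mz)
        assert back.sample_ids == pm.sample_ids
        assert back.stage == pm.stage

    def test_polarity_concat_tags_survive(self):
        samples = [SampleRecord("a", "serum", "HD", "", 0, "positive")]
        pos = PeakMatrix(np.array([[1.0]]), np.array([100.0]), samples)
        neg = PeakMatrix(np.array([[2.0]]), np.array([100.0]),
                         [SampleRecord("a", "serum", "HD", "", 0, "negative")])
        both = concat_polarities(pos, neg)
        assert both.values.shape == (1, 2)
        assert both.bin_ids[0].startswith("pos") and both.bin_ids[1].startswith("neg")
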