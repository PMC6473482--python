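"""Preprocessing-chain contracts: each stage against its analytic oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ramancell as rc
from ramancell.preprocess import (
    BackgroundModel, RamanPreprocessor, asls_baseline, baseline_correct,
    calibrate_axis, despike, normalize_amide1, silicon_shift, smooth, snv,
    stitch_windows, subtract_background, truncate_excise, zero_offset)
from ramancell.spectra import ProcessedSpectrum, RawSpectrum


def gauss_spectrum(center=1000.0, sigma=15.0, amp=1.0,
                   lo=300.0, hi=1800.0, **meta):
    w = np.arange(lo, hi + 1.0)
    return RawSpectrum(w, amp * np.exp(-0.5 * ((w - center) / sigma) ** 2),
                       **meta)


class TestDespike:
    def test_spike_free_noiseless_gaussian_unchanged(self):
        s = gauss_spectrum()
        out, flags = despike(s)
        assert flags == []
        assert np.array_equal(out.intensities, s.intensities)

    def test_constant_spectrum_unchanged(self):
        s = RawSpectrum(np.arange(10.0), np.full(10, 3.0))
        out, flags = despike(s)
        assert flags == []
        assert np.array_equal(out.intensities, s.intensities)

    def test_injected_spikes_flagged_exactly(self):
        """Every truth-record spike flagged, zero false positives."""
        inst = rc.InstrumentModel(cosmic_rate=3.0)
        prof = rc.default_profiles(classes=["SW620"])[0]
        found = 0
        for seed in range(6):
            w1, _, truth = rc.generate_cell_spectrum(
                prof, inst, seed, return_truth=True)
            true_spikes = set(truth["spikes"]["window1"])
            out, flags = despike(w1)
            assert set(flags) == true_spikes
            found += len(true_spikes)
        assert found > 5  # the scenario actually exercised spikes

    def test_non_finite_rejected(self):
        s = RawSpectrum(np.arange(10.0), np.r_[np.ones(9), np.nan])
        with pytest.raises(ValueError):
            despike(s)


class TestCalibration:
    @pytest.mark.parametrize("shift", [3.0, 0.0, -2.2])
    def test_shift_recovered(self, shift):
        si = rc.generate_silicon_spectrum(shift)
        assert silicon_shift(si) == pytest.approx(-shift, abs=0.1)

    def test_cell_axis_corrected(self):
        si = rc.generate_silicon_spectrum(3.0)
        s = gauss_spectrum()
        out = calibrate_axis(s, si)
        np.testing.assert_allclose(
            out.wavenumbers - s.wavenumbers, -3.0, atol=0.1)

    def test_flat_silicon_rejected(self):
        flat = RawSpectrum(np.arange(300.0, 1800.0), np.zeros(1500))
        with pytest.raises(ValueError):
            silicon_shift(flat)


class TestZeroOffset:
    @pytest.mark.parametrize("vals,expect", [
        ([5, 7, 6], [0, 2, 1]),
        ([0, 2, 1], [0, 2, 1]),
        ([-3, -1], [0, 2])])
    def test_examples(self, vals, expect):
        s = RawSpectrum(np.arange(float(len(vals))), np.array(vals, float))
        np.testing.assert_allclose(zero_offset(s).intensities, expect)


class TestBackgroundSubtraction:
    def make_bg(self, amp=2.0):
        w = np.arange(300.0, 1801.0)
        quartz = amp * np.exp(-0.5 * ((w - 480.0) / 45.0) ** 2)
        return BackgroundModel(RawSpectrum(w, quartz))

    def test_known_mixing_factor_recovered(self):
        bg = self.make_bg()
        cell = gauss_spectrum(center=1440, sigma=10)
        mixed = cell.with_intensities(
            cell.intensities + 1.3 * bg.mean_background.intensities)
        out, a, _ = subtract_background(mixed, bg)
        assert a == pytest.approx(1.3, abs=1e-6)
        w = out.wavenumbers
        m = (w >= 430) & (w <= 530)
        assert np.abs(out.intensities[m]).max() < 1e-9

    def test_background_onto_itself(self):
        bg = self.make_bg()
        out, a, _ = subtract_background(bg.mean_background, bg)
        assert a == pytest.approx(1.0, abs=1e-9)
        assert np.abs(out.intensities).max() < 1e-9

    def test_window_outside_range_rejected(self):
        bg = self.make_bg()
        short = RawSpectrum(np.arange(600.0, 1800.0), np.zeros(1200))
        with pytest.raises(ValueError):
            subtract_background(short, bg)

    def test_zero_quartz_keeps_scale_finite(self):
        w = np.arange(300.0, 1801.0)
        base = 0.5 + 1e-4 * (w - 300)
        bg = BackgroundModel(RawSpectrum(w, base))
        cell = RawSpectrum(w, 0.8 * base)
        out, a, _ = subtract_background(cell, bg)
        assert np.isfinite(a)
        # with no quartz feature the background is collinear with the
        # co-fitted local linear term: only the detrended residual is zero
        m = (w >= 430) & (w <= 530)
        resid = out.intensities[m]
        detrended = resid - np.polyval(np.polyfit(w[m], resid, 1), w[m])
        assert np.abs(detrended).max() < 1e-9


class TestSmoothing:
    def test_low_order_polynomial_is_fixed_point(self):
        w = np.arange(300.0, 500.0)
        y = 1.0 + 0.01 * w + 1e-5 * w ** 2 - 1e-8 * w ** 3
        s = RawSpectrum(w, y)
        np.testing.assert_allclose(smooth(s, 11, 3).intensities, y,
                                   atol=1e-9 * np.abs(y).max())

    def test_noise_variance_reduced(self, rng):
        s = RawSpectrum(np.arange(500.0), rng.normal(size=500))
        assert smooth(s).intensities.var() < s.intensities.var()

    def test_gaussian_peak_attenuation_below_1pct(self):
        s = gauss_spectrum(center=1000, sigma=15)
        out = smooth(s, 11, 3)
        i = np.argmax(s.intensities)
        assert abs(out.intensities[i] - 1.0) < 0.01

    def test_window_too_large_rejected(self):
        s = RawSpectrum(np.arange(9.0), np.zeros(9))
        with pytest.raises(ValueError):
            smooth(s, 11, 3)


class TestBaseline:
    def test_pure_polynomial_fully_removed(self):
        w = np.arange(730.0, 3101.0)
        x = (w - 730) / 2370
        y = 2.0 + 1.5 * x - 0.8 * x ** 2 + 0.3 * x ** 3
        s = RawSpectrum(w, y)
        out, z = baseline_correct(s)
        assert np.abs(out.intensities).max() < 0.01 * (y.max() - y.min())

    def test_zero_spectrum_zero_baseline(self):
        s = RawSpectrum(np.arange(100.0), np.zeros(100))
        out, z = baseline_correct(s)
        assert np.allclose(z, 0.0)

    def test_known_baseline_under_bands_recovered(self):
        w = np.arange(730.0, 3101.0)
        x = (w - 730) / 2370
        truth = 1.0 + 0.8 * x - 0.5 * x ** 2
        bands = sum(a * np.exp(-0.5 * ((w - c) / 12) ** 2)
                    for c, a in [(1001, 0.5), (1440, 0.6), (1655, 1.0),
                                 (2930, 2.0)])
        s = RawSpectrum(w, truth + bands)
        _, z = baseline_correct(s)
        free = bands < 0.01
        rms = np.sqrt(np.mean((z[free] - truth[free]) ** 2))
        assert rms < 0.05 * (truth.max() - truth.min())

    def test_baseline_at_or_below_apexes(self):
        w = np.arange(730.0, 3101.0)
        y = 1.0 + np.exp(-0.5 * ((w - 1655) / 12) ** 2)
        z = asls_baseline(y)
        i = np.argmax(y)
        assert z[i] <= y[i] + 1e-6


class TestStitching:
    def test_identical_constant_windows(self):
        w1 = RawSpectrum(np.arange(300.0, 1801.0), np.full(1501, 2.0),
                         cell_id="c")
        w2 = RawSpectrum(np.arange(1800.0, 3201.0), np.full(1401, 2.0),
                         window_id=2, cell_id="c")
        out = stitch_windows(w1, w2)
        assert np.allclose(out.intensities, 2.0)
        assert out.wavenumbers[0] == 300.0 and out.wavenumbers[-1] == 3200.0

    def test_intensity_offset_removed_at_junction(self):
        w1 = RawSpectrum(np.arange(300.0, 1801.0), np.full(1501, 1.0),
                         cell_id="c")
        w2 = RawSpectrum(np.arange(1800.0, 3201.0), np.full(1401, 11.0),
                         window_id=2, cell_id="c")
        out = stitch_windows(w1, w2)
        d = np.abs(np.diff(out.intensities))
        assert d.max() < 1e-9  # continuous across 1800 cm-1

    def test_wide_gap_rejected(self):
        w1 = RawSpectrum(np.arange(300.0, 1751.0), np.zeros(1451),
                         cell_id="c")
        w2 = RawSpectrum(np.arange(1800.0, 3201.0), np.zeros(1401),
                         window_id=2, cell_id="c")
        with pytest.raises(ValueError):
            stitch_windows(w1, w2)


class TestTruncateExcise:
    def test_retained_channel_count(self):
        s = RawSpectrum(np.arange(300.0, 3201.0),
                        np.ones(2901))
        ps = truncate_excise(s)
        assert ps.wavenumbers.size == (1750 - 730 + 1) + (3100 - 2800 + 1)

    def test_endpoint_conventions(self):
        s = RawSpectrum(np.arange(300.0, 3201.0), np.ones(2901))
        ps = truncate_excise(s)
        for kept in (730.0, 1750.0, 2800.0, 3100.0):
            assert kept in ps.wavenumbers
        assert 2000.0 not in ps.wavenumbers
        assert not np.any((ps.wavenumbers > 1750) & (ps.wavenumbers < 2800))

    def test_coverage_gap_rejected(self):
        s = RawSpectrum(np.arange(800.0, 3201.0), np.ones(2401))
        with pytest.raises(ValueError):
            truncate_excise(s)


def processed(w, y):
    keep = (w <= 1750) | (w >= 2800)
    return ProcessedSpectrum(w[keep], y[keep])


class TestNormalisation:
    def test_amide_scaling(self):
        w = np.arange(730.0, 3101.0)
        y = 4.0 * np.exp(-0.5 * ((w - 1655) / 12) ** 2) + 0.4
        ps = processed(w, y)
        out = normalize_amide1(ps)
        m = (out.wavenumbers >= 1600) & (out.wavenumbers <= 1690)
        assert out.intensities[m].max() == pytest.approx(1.0, abs=1e-12)
        out2 = normalize_amide1(out)
        np.testing.assert_allclose(out2.intensities, out.intensities)

    def test_flat_zero_region_rejected(self):
        w = np.arange(730.0, 3101.0)
        ps = processed(w, np.zeros_like(w))
        with pytest.raises(ValueError):
            normalize_amide1(ps)

    def test_snv_example(self):
        ps = ProcessedSpectrum(np.array([730.0, 731, 732]),
                               np.array([1.0, 2, 3]))
        np.testing.assert_allclose(snv(ps).intensities, [-1, 0, 1])

    @settings(max_examples=25, deadline=None)
    @given(scale=st.floats(0.1, 50), offset=st.floats(-10, 10),
           seed=st.integers(0, 10_000))
    def test_snv_affine_invariance(self, scale, offset, seed):
        y = np.random.default_rng(seed).normal(size=64)
        if y.std() == 0:
            return
        w = np.arange(730.0, 794.0)
        a = snv(ProcessedSpectrum(w, y)).intensities
        b = snv(ProcessedSpectrum(w, scale * y + offset)).intensities
        np.testing.assert_allclose(a, b, atol=1e-9)
        assert abs(a.mean()) < 1e-12
        assert a.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_snv_zero_variance_rejected(self):
        ps = ProcessedSpectrum(np.array([730.0, 731]), np.array([2.0, 2.0]))
        with pytest.raises(ValueError):
            snv(ps)


class TestFullChain:
    def test_branches_have_expected_ranges(self, two_class_small):
        _, res = two_class_small
        assert res.band_set.wavenumbers[-1] == 3100.0
        assert res.chemo_set.wavenumbers[-1] == 3000.0
        assert res.band_set.wavenumbers[0] == 730.0

    def test_rerun_is_bit_identical(self, two_class_small):
        ds, res = two_class_small
        res2 = RamanPreprocessor().process(ds)
        assert np.array_equal(res.matrix, res2.matrix)
        assert np.array_equal(res.band_set.matrix(), res2.band_set.matrix())

    def test_adjustment_factor_recovery(self, two_class_small):
        ds, res = two_class_small
        fit = np.array([res.adjustment_factors[c["cell_id"]]
                        for c in ds.cells])
        true = np.array([ds.truth[c["cell_id"]]["background_scale"]
                         for c in ds.cells])
        rel = np.abs(fit - true) / true
        assert rel.mean() < 0.05
        assert np.corrcoef(fit, true)[0, 1] > 0.99

    def test_corrupt_cell_skipped_not_fatal(self, two_class_small):
        ds, _ = two_class_small
        import copy
        bad = copy.deepcopy(ds)
        w1 = bad.cells[0]["w1"]
        y = w1.intensities.copy()
        y[100] = np.nan
        bad.cells[0]["w1"] = w1.with_intensities(y)
        res = RamanPreprocessor().process(bad)
        assert len(res.chemo_set) == len(ds.cells) - 1
        assert len(res.skipped) == 1
        assert res.skipped[0][0] == bad.cells[0]["cell_id"]

    def test_despiking_is_noop_on_clean_data(self, quiet_instrument):
        prof = rc.default_profiles(classes=["SW480", "SW620"])
        cfg = rc.GeneratorConfig(
            profiles=prof, cells_per_class={"SW480": 3, "SW620": 3},
            instrument=quiet_instrument, seed=2)
        # quiet instrument but keep quartz so background fit stays sane
        cfg.instrument.quartz_amplitude = 2.0
        cfg.instrument.cosmic_rate = 0.0
        cfg.instrument.noise_sd = 0.0
        ds = rc.generate_study_dataset(cfg)
        a = RamanPreprocessor(enable_despike=True).process(ds)
        b = RamanPreprocessor(enable_despike=False).process(ds)
        np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-9)
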