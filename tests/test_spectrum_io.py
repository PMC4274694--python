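"""ASCII spectrum I/O, preprocessing, peak picking, synthesis."""

import numpy as np
import pytest

from hdxfine.hdx_theory import M_HDX, required_peak_width
from hdxfine.spectrum_io import (
    PeakList,
    Spectrum,
    SpectrumFormatError,
    fit_line_intensities,
    pick_peaks,
    preprocess,
    read_spectrum,
    shift_mz,
    synthesize_spectrum,
    write_spectrum,
)


class TestReadWrite:
    def test_whitespace_and_comma_equivalent(self, tmp_path):
        a = tmp_path / "a.txt"
        b = tmp_path / "b.txt"
        a.write_text("100.0 5\n101.0 3\n")
        b.write_text("100.0,5\n101.0,3\n")
        sa, sb = read_spectrum(a), read_spectrum(b)
        assert np.array_equal(sa.mz, sb.mz)
        assert np.array_equal(sa.intensity, sb.intensity)
        assert len(sa) == 2

    def test_out_of_order_rows_sorted(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("300.5 1\n100.25 2\n200.125 3\n")
        s = read_spectrum(p)
        assert list(s.mz) == [100.25, 200.125, 300.5]
        assert list(s.intensity) == [2.0, 3.0, 1.0]

    def test_duplicate_mz_summed(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("100.0 1\n100.0 2\n")
        s = read_spectrum(p)
        assert len(s) == 1
        assert s.intensity[0] == 3.0

    @pytest.mark.parametrize(
        "content,lineno",
        [("100.0 1 extra\n", 1), ("mz intensity\n100 1\n", 1), ("100 1\nabc 2\n", 2)],
    )
    def test_malformed_reports_line_number(self, tmp_path, content, lineno):
        p = tmp_path / "bad.txt"
        p.write_text(content)
        with pytest.raises(SpectrumFormatError, match=f":{lineno}:"):
            read_spectrum(p)

    def test_round_trip_preserves_printed_precision(self, tmp_path):
        rng = np.random.default_rng(0)
        mz = np.sort(rng.uniform(100, 1000, 50))
        inten = rng.uniform(0.001, 1e6, 50)
        s = Spectrum(mz, inten)
        p = tmp_path / "rt.txt"
        write_spectrum(s, p)
        s2 = read_spectrum(p)
        assert np.allclose(s2.mz, mz, atol=5e-7)
        assert np.allclose(s2.intensity, inten, rtol=1e-5)


class TestPreprocess:
    def _line_spectrum(self, noise=0.0, baseline=0.0, seed=0):
        lines = PeakList(np.array([500.0]), np.array([1.0]))
        return synthesize_spectrum(
            lines, fwhm=0.001, noise_sigma=noise, baseline_level=baseline, seed=seed
        )

    def test_noop_limit(self):
        s = self._line_spectrum()
        out = preprocess(s, denoise=False, baseline=False)
        assert np.allclose(out.intensity, np.clip(s.intensity, 0, None), atol=1e-9)
        assert np.array_equal(out.mz, s.mz)

    def test_baseline_offset_removed(self):
        c = 0.5
        clean = self._line_spectrum()
        offset = Spectrum(clean.mz, clean.intensity + c)
        out = preprocess(offset, baseline=True, baseline_window=2001)
        # recovered to within c/100 away from the peak
        off_peak = np.abs(out.mz - 500.0) > 0.05
        assert np.abs(out.intensity[off_peak] - clean.intensity[off_peak]).max() < c / 100

    def test_denoise_reduces_rms(self):
        clean = self._line_spectrum()
        noisy = self._line_spectrum(noise=0.05, seed=11)
        den = preprocess(noisy, denoise=True)
        rms_before = np.sqrt(np.mean((np.clip(noisy.intensity, 0, None) - clean.intensity) ** 2))
        rms_after = np.sqrt(np.mean((den.intensity - clean.intensity) ** 2))
        assert rms_after < rms_before

    def test_never_negative_never_resized(self):
        s = self._line_spectrum(noise=0.3, seed=5)
        out = preprocess(s, denoise=True, baseline=True)
        assert len(out) == len(s)
        assert out.intensity.min() >= 0

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            preprocess(Spectrum(np.arange(5.0), np.ones(5)))


class TestShift:
    def test_identity_and_inverse(self):
        s = Spectrum(np.array([100.0, 200.0]), np.array([1.0, 2.0]))
        assert np.array_equal(shift_mz(s, 0.0).mz, s.mz)
        back = shift_mz(shift_mz(s, 0.001), -0.001)
        assert np.allclose(back.mz, s.mz, atol=1e-12)

    def test_ppm_mode(self):
        s = Spectrum(np.array([1000.0]), np.array([1.0]))
        assert shift_mz(s, 5.0, mode="ppm").mz[0] == pytest.approx(1000.005)


class TestPickPeaks:
    def test_single_line_centroid(self):
        lines = PeakList(np.array([500.0]), np.array([1.0]))
        s = synthesize_spectrum(lines, fwhm=0.001)
        peaks = pick_peaks(s)
        assert len(peaks) == 1
        assert abs(peaks.mz[0] - 500.0) < required_peak_width(1) / 10

    def test_flat_spectrum_empty(self):
        s = Spectrum(np.linspace(100, 101, 1000), np.zeros(1000))
        assert len(pick_peaks(s)) == 0

    def test_resolves_lines_at_half_hdx_spacing(self):
        """Two lines m_HDX/2 apart, synthesized at the 50%-valley width for
        z = 2, must appear as two distinct centroids."""
        sep = M_HDX / 2
        lines = PeakList(np.array([500.0, 500.0 + sep]), np.array([1.0, 1.0]))
        s = synthesize_spectrum(lines, fwhm=required_peak_width(2), grid_step=sep / 40)
        peaks = pick_peaks(s)
        assert len(peaks) == 2
        assert np.allclose(peaks.mz, lines.mz, atol=sep / 5)

    def test_min_spacing_merges_keeping_taller(self):
        lines = PeakList(np.array([500.0, 500.0008]), np.array([1.0, 0.4]))
        s = synthesize_spectrum(lines, fwhm=0.001)
        peaks = pick_peaks(s, min_spacing=0.005)
        assert len(peaks) == 1
        assert abs(peaks.mz[0] - 500.0) < 3e-4

    def test_centroided_passthrough(self):
        s = Spectrum(
            np.array([100.0, 200.0]), np.array([1.0, 2.0]), {"centroided": True}
        )
        peaks = pick_peaks(s)
        assert np.array_equal(peaks.mz, s.mz)
        assert np.array_equal(peaks.intensity, s.intensity)


class TestSynthesize:
    def test_apex_and_width(self):
        lines = PeakList(np.array([500.0]), np.array([1.0]))
        s = synthesize_spectrum(lines, fwhm=0.001)
        apex = np.argmax(s.intensity)
        assert s.intensity[apex] == pytest.approx(1.0, abs=0.01)
        above = s.mz[s.intensity >= 0.5]
        assert above.max() - above.min() == pytest.approx(0.001, abs=2 * 0.0002)

    def test_deterministic_for_seed(self):
        lines = PeakList(np.array([500.0]), np.array([1.0]))
        a = synthesize_spectrum(lines, fwhm=0.001, noise_sigma=0.05, seed=7)
        b = synthesize_spectrum(lines, fwhm=0.001, noise_sigma=0.05, seed=7)
        assert np.array_equal(a.intensity, b.intensity)

    def test_grid_too_coarse_rejected(self):
        lines = PeakList(np.array([500.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            synthesize_spectrum(lines, fwhm=0.001, grid_step=0.001)

    def test_pick_round_trip_well_separated_lines(self):
        """Centroid recovery within fwhm/10 for lines >= 2 fwhm apart,
        across 100 seeded random cases."""
        fwhm = 0.002
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = rng.integers(2, 6)
            mz = 400 + np.cumsum(rng.uniform(2 * fwhm, 10 * fwhm, n))
            inten = rng.uniform(0.3, 1.0, n)
            lines = PeakList(mz, inten)
            s = synthesize_spectrum(
                lines, fwhm=fwhm, noise_sigma=0.002, seed=int(rng.integers(2**31))
            )
            peaks = pick_peaks(s)
            assert len(peaks) >= n
            for m in mz:
                assert np.min(np.abs(peaks.mz - m)) < fwhm / 10


class TestFitLineIntensities:
    def test_recovers_sub_threshold_line(self):
        """A line well below the detection threshold still gets an amplitude
        close to truth when its position is supplied."""
        lines = PeakList(np.array([500.0, 500.01]), np.array([1.0, 0.015]))
        s = synthesize_spectrum(lines, fwhm=0.001, noise_sigma=0.02, seed=3)
        picked = pick_peaks(s, min_snr=3.0)
        # the weak line itself is below the detection threshold
        assert np.min(np.abs(picked.mz - 500.01)) > 5e-4
        out = fit_line_intensities(s, np.array([500.0, 500.01]))
        i_weak = np.argmin(np.abs(out.mz - 500.01))
        assert abs(out.mz[i_weak] - 500.01) < 1e-9  # the supplied position
        assert out.intensity[i_weak] == pytest.approx(0.015, abs=0.02)

    def test_matches_pick_peaks_for_strong_lines(self):
        lines = PeakList(np.array([500.0, 500.02]), np.array([1.0, 0.5]))
        s = synthesize_spectrum(lines, fwhm=0.001, noise_sigma=0.005, seed=4)
        picked = pick_peaks(s)
        fitted = fit_line_intensities(s, lines.mz)
        for m in lines.mz:
            a = picked.intensity[np.argmin(np.abs(picked.mz - m))]
            b = fitted.intensity[np.argmin(np.abs(fitted.mz - m))]
            assert b == pytest.approx(a, rel=0.05)
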