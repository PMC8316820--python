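"""Spectrum preprocessing: baseline, smoothing, peak picking, deisotoping,
replicate consensus, blank screening."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import zoomsid as z
from zoomsid.errors import SpectrumError
from zoomsid.preprocess import ISOTOPE_SPACING


def spectrum(lo=1000.0, hi=1400.0, step=0.05, y=None):
    mz = np.arange(lo, hi + step / 2, step)
    inten = np.zeros_like(mz) if y is None else y(mz)
    return z.RawSpectrum(mz, inten, specimen_id="S1")


def gaussian(center, height, sigma):
    return lambda mz: height * np.exp(-0.5 * ((mz - center) / sigma) ** 2)


class TestBaseline:
    def test_constant_trace_maps_to_zero(self):
        s = spectrum(y=lambda mz: np.full_like(mz, 3.7))
        out = z.correct_baseline(s, window=100.0)
        assert np.allclose(out.intensity, 0.0)

    def test_flat_zero_maps_to_itself(self):
        out = z.correct_baseline(spectrum(), window=100.0)
        assert np.allclose(out.intensity, 0.0)

    def test_exponential_baseline_mostly_removed(self):
        s = spectrum(800.0, 3500.0, y=lambda mz: 2.0 * np.exp(-(mz - 800) / 600))
        out = z.correct_baseline(s, window=100.0)
        assert out.intensity.max() < 0.05 * s.intensity.max()

    def test_narrow_peak_height_preserved(self):
        s = spectrum(y=gaussian(1200.0, 5.0, 0.3))
        out = z.correct_baseline(s, window=100.0)
        assert abs(out.intensity.max() - 5.0) < 0.25  # within 5%

    def test_window_larger_than_span_errors(self):
        with pytest.raises(SpectrumError):
            z.correct_baseline(spectrum(1000, 1050), window=100.0)


class TestSmooth:
    def test_constant_unchanged(self):
        s = spectrum(y=lambda mz: np.full_like(mz, 2.0))
        assert np.allclose(z.smooth(s, 5).intensity, 2.0)

    def test_delta_spike_attenuated(self):
        y = np.zeros(201)
        y[100] = 8.0
        s = z.RawSpectrum(np.arange(201) * 0.05 + 1000, y)
        assert z.smooth(s, 5).intensity.max() < 8.0

    def test_gaussian_apex_shift_below_grid_spacing(self):
        s = spectrum(y=gaussian(1200.013, 1.0, 0.3))
        out = z.smooth(s, 5)
        apex = out.mz[np.argmax(out.intensity)]
        raw_apex = s.mz[np.argmax(s.intensity)]
        assert abs(apex - raw_apex) < 0.05

    @pytest.mark.parametrize("bad", [2, 1, -3])
    def test_bad_window_errors(self, bad):
        with pytest.raises(SpectrumError):
            z.smooth(spectrum(), bad)

    def test_window_exceeding_length_errors(self):
        s = z.RawSpectrum(np.arange(5) * 0.05 + 1000, np.zeros(5))
        with pytest.raises(SpectrumError):
            z.smooth(s, 7)


class TestPickPeaks:
    def test_all_zero_trace_empty(self):
        assert len(z.pick_peaks(spectrum())) == 0

    @staticmethod
    def _peak_on_noisy_background(height, center=1200.42, noise_scale=0.1,
                                  seed=42):
        """Clean Gaussian peak over a noisy background: the noise estimate
        comes from the surroundings, so the height/noise ratio is exactly
        the constructed one."""
        mz = np.arange(1000.0, 1400.025, 0.05)
        rng = np.random.default_rng(seed)
        y = np.asarray(rng.normal(0, noise_scale, mz.size))
        win = np.abs(mz - center) < 2.0
        y[win] = gaussian(center, height, 0.3)(mz[win])
        return z.RawSpectrum(mz, y, specimen_id="S1")

    def test_single_clear_peak_found_at_apex(self):
        s = self._peak_on_noisy_background(height=1.0)  # 10x the noise
        peaks = z.pick_peaks(s, snr_threshold=3.5)
        near = peaks.mz[np.abs(peaks.mz - 1200.42) < 1.0]
        assert near.size == 1
        assert abs(near[0] - 1200.42) < 0.05

    def test_below_threshold_peak_rejected(self):
        # 3.0x the noise scale sits below the stated 3.5 cut-off
        s = self._peak_on_noisy_background(height=0.3)
        peaks = z.pick_peaks(s, snr_threshold=3.5)
        assert not np.any(np.abs(peaks.mz - 1200.42) < 1.0)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        y = gaussian(1100.0, 2.0, 0.3)
        s = spectrum(1000, 1400, y=lambda mz: y(mz)
                     + gaussian(1250.0, 0.6, 0.3)(mz))
        noisy = z.RawSpectrum(s.mz,
                              s.intensity + rng.normal(0, 0.1, s.mz.size))
        sm = z.smooth(noisy, 5)
        lo = z.pick_peaks(sm, snr_threshold=2.0)
        hi = z.pick_peaks(sm, snr_threshold=5.0)
        assert set(np.round(hi.mz, 6)) <= set(np.round(lo.mz, 6))

    def test_zero_length_errors(self):
        with pytest.raises(SpectrumError):
            z.RawSpectrum(np.array([]), np.array([]))


class TestDeisotope:
    def test_envelope_collapses_to_monoisotopic(self, make_peaklist):
        p = make_peaklist([1105.0, 1105.0 + ISOTOPE_SPACING,
                           1105.0 + 2 * ISOTOPE_SPACING],
                          intensities=[100.0, 55.0, 18.0])
        out = z.deisotope(p, tol=0.15)
        assert list(out.mz) == [1105.0]
        assert out.intensity[0] == 100.0

    def test_heavy_peptide_envelope_with_larger_satellite(self, make_peaklist):
        # above ~1800 Da the +1 isotope exceeds the monoisotopic peak
        base = 3033.0
        p = make_peaklist([base + k * ISOTOPE_SPACING for k in range(4)],
                          intensities=[50.0, 84.0, 71.0, 40.0])
        out = z.deisotope(p, tol=0.15)
        assert list(out.mz) == [base]

    def test_isolated_peak_unchanged(self, make_peaklist):
        out = z.deisotope(make_peaklist([2131.0]))
        assert list(out.mz) == [2131.0]

    def test_unrelated_peaks_retained(self, make_peaklist):
        out = z.deisotope(make_peaklist([1105.0, 1154.0]))
        assert list(out.mz) == [1105.0, 1154.0]

    def test_bad_tolerance_errors(self, make_peaklist):
        with pytest.raises(SpectrumError):
            z.deisotope(make_peaklist([1105.0]), tol=0.6)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=800, max_value=3400), min_size=0,
                    max_size=25),
           st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_idempotent_and_mass_conserving(self, masses, seed):
        rng = np.random.default_rng(seed)
        m = np.asarray(sorted(set(np.round(masses, 3))))
        p = z.PeakList(m, rng.uniform(1, 100, m.size),
                       np.full(m.size, 10.0), specimen_id="S1")
        once = z.deisotope(p)
        twice = z.deisotope(once)
        assert np.array_equal(once.mz, twice.mz)
        assert set(once.mz) <= set(p.mz)  # no peaks invented


class TestMergeReplicates:
    def test_three_identical_lists(self, make_peaklist):
        pls = [make_peaklist([1105.0, 1580.0]) for _ in range(3)]
        out = z.merge_replicates(pls)
        assert list(out.mz) == [1105.0, 1580.0]
        assert list(out.n_replicates_present) == [3, 3]

    def test_minority_peak_dropped(self, make_peaklist):
        pls = [make_peaklist([1105.0, 1580.0]), make_peaklist([1105.0]),
               make_peaklist([1105.0])]
        out = z.merge_replicates(pls, min_presence=2)
        assert list(out.mz) == [1105.0]

    def test_weighted_mean_within_cluster_range(self, make_peaklist):
        pls = [make_peaklist([1580.00]), make_peaklist([1580.10]),
               make_peaklist([1580.05])]
        out = z.merge_replicates(pls, tol=0.3)
        assert len(out) == 1
        assert 1580.00 <= out.mz[0] <= 1580.10

    def test_specimen_mismatch_errors(self, make_peaklist):
        with pytest.raises(SpectrumError):
            z.merge_replicates([make_peaklist([1105.0], specimen_id="A"),
                                make_peaklist([1105.0], specimen_id="B")])

    def test_empty_input_errors(self):
        with pytest.raises(SpectrumError):
            z.merge_replicates([])


class TestCheckBlanks:
    def test_empty_blanks_pass(self, panel, make_peaklist):
        rep = z.check_blanks([make_peaklist([], specimen_id="B1")], panel)
        assert rep.passed

    def test_marker_mass_in_blank_fails_naming_marker(self, panel,
                                                      make_peaklist):
        rep = z.check_blanks([make_peaklist([1105.1], specimen_id="B1")],
                             panel, tol=0.5)
        assert not rep.passed
        assert rep.flagged[0][2] == "COL1a1 507-518"

    def test_non_marker_peak_passes_with_warning(self, panel, make_peaklist):
        rep = z.check_blanks([make_peaklist([950.0], specimen_id="B1")],
                             panel, tol=0.5)
        assert rep.passed
        assert any("950" in w for w in rep.warnings)
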