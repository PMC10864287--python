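"""Spectrogram and measurement correctness against analytic oracles."""

import datetime as dt

import numpy as np
import pytest

from finsong.audio_annotations import Recording, Selection
from finsong.note_measures import (SpectrogramGrid, bandwidth90,
                                   center_frequency, center_time,
                                   inband_power, measure_notes, note_snr,
                                   peak_frequency, spectrogram)
from finsong.songsynth import CANONICAL_NOTE, NoiseSpec, make_noise, make_note

FS = 2000
BIN = FS / 1024  # 1.953125 Hz


def _rec(x, fs=FS, id="r"):
    return Recording(id=id, start=dt.datetime(2017, 9, 5), fs=fs,
                     samples=np.asarray(x, float))


def _tone(freq, duration=60.0, amplitude=0.5, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return amplitude * np.sin(2 * np.pi * freq * t)


def synthetic_grid(per_bin_energy: dict[int, float],
                   n_frames: int = 20) -> SpectrogramGrid:
    """Hand-built grid with prescribed per-bin energy, uniform over frames."""
    bins = np.arange(513) * BIN
    psd = np.zeros((n_frames, 513))
    for k, e in per_bin_energy.items():
        psd[:, k] = e / n_frames
    hop = 102
    times = (512 + hop * np.arange(n_frames)) / FS
    return SpectrogramGrid(psd=psd, frame_times=times, bin_freqs=bins,
                           fs=FS, nfft=1024, hop=hop)


WIDE = Selection(1, "r", 0.0, 10.0, 0.0, 1000.0)


class TestSpectrogramGrid:
    def test_resolution_constants(self, tone20_grid):
        _, g = tone20_grid
        assert g.bin_width == pytest.approx(1.953125)
        assert g.hop == 102
        assert g.hop_seconds == pytest.approx(0.051)
        assert np.allclose(np.diff(g.bin_freqs), g.bin_width)

    def test_pure_tone_energy_concentrates_at_its_bin(self, tone20_grid):
        # an exactly-on-bin tone: the Hann window spreads a line over its
        # bin +/- 1 (amplitude 0.5/1/0.5), so bin 10 is the maximum and
        # bins 9-11 hold essentially all energy; leakage beyond is < 5%
        rec2 = _rec(_tone(10 * BIN))
        g2 = spectrogram(rec2)
        per_bin = g2.psd.sum(axis=0)
        assert int(np.argmax(per_bin)) == 10
        assert per_bin[9:12].sum() / per_bin.sum() > 0.95

    def test_parseval_energy_conservation(self):
        x = make_noise(FS * 60, NoiseSpec(), FS, np.random.default_rng(0))
        g = spectrogram(_rec(x))
        assert g.psd.sum() == pytest.approx(np.sum(x ** 2), rel=0.01)

    def test_too_short_recording_raises(self):
        with pytest.raises(ValueError, match="shorter than one"):
            spectrogram(_rec(np.zeros(500)))


class TestInbandPower:
    def test_doubling_amplitude_adds_6dB(self):
        g1 = spectrogram(_rec(_tone(10 * BIN, amplitude=0.2)))
        g2 = spectrogram(_rec(_tone(10 * BIN, amplitude=0.4)))
        sel = Selection(1, "r", 1.0, 59.0, 15.0, 25.0)
        assert (inband_power(g2, sel) - inband_power(g1, sel)
                == pytest.approx(6.02, abs=0.01))

    def test_silent_band_of_noiseless_tone(self):
        g = spectrogram(_rec(_tone(10 * BIN)))
        sel = Selection(1, "r", 1.0, 59.0, 200.0, 400.0)  # far from the tone
        assert inband_power(g, sel) <= -80.0

    def test_tone_inband_power_matches_time_domain_energy(self):
        x = _tone(10 * BIN, duration=120.0)
        g = spectrogram(_rec(x))
        sel = Selection(1, "r", 0.0, 120.0, 10.0, 30.0)
        lin = 10 ** (inband_power(g, sel) / 10)
        assert lin == pytest.approx(np.sum(x ** 2), rel=0.01)

    def test_empty_intersection_raises(self):
        g = spectrogram(_rec(_tone(20)))
        with pytest.raises(ValueError, match="does not intersect"):
            inband_power(g, Selection(1, "r", 100.0, 101.0, 15.0, 25.0))


class TestFrequencyMeasures:
    def test_peak_frequency_is_bin_quantized(self):
        g20 = spectrogram(_rec(_tone(20.0)))
        g50 = spectrogram(_rec(_tone(50.0)))
        sel = Selection(1, "r", 1.0, 59.0, 0.0, 1000.0)
        assert peak_frequency(g20, sel) == pytest.approx(19.53125)  # bin 10
        assert peak_frequency(g50, sel) == pytest.approx(50.78125)  # bin 26

    def test_single_bin_tone_center_equals_peak_and_zero_bandwidth(self):
        g = synthetic_grid({10: 1.0})
        assert center_frequency(g, WIDE) == pytest.approx(10 * BIN)
        assert bandwidth90(g, WIDE) == 0.0

    def test_center_frequency_uniform_bins_first_reaching_half(self):
        g = synthetic_grid({9: 1.0, 10: 1.0, 11: 1.0, 12: 1.0})
        # cumulative hits 50% exactly at the second occupied bin
        assert center_frequency(g, WIDE) == pytest.approx(10 * BIN)

    def test_bandwidth90_uniform_ten_bins(self):
        g = synthetic_grid({k: 1.0 for k in range(10, 20)})
        bw = bandwidth90(g, WIDE)
        # discrete rule: f5 = first bin (5% inside bin 10), f95 = bin 19
        assert bw == pytest.approx(9 * BIN)
        assert abs(bw - 9 * BIN * 0.9) <= BIN  # within one bin of continuum

    def test_all_frequencies_multiples_of_bin_width(self, canonical_grid,
                                                    canonical_selection):
        for f in (peak_frequency(canonical_grid, canonical_selection),
                  center_frequency(canonical_grid, canonical_selection),
                  bandwidth90(canonical_grid, canonical_selection)):
            assert f % BIN == pytest.approx(0.0, abs=1e-9)


class TestCenterTime:
    @pytest.mark.parametrize("begin,end,expect",
                             [(2.0, 3.0, 2.5), (0.0, 0.9, 0.45)])
    def test_midpoint(self, begin, end, expect):
        assert center_time(Selection(1, "r", begin, end, 15, 25)) == expect


class TestNoteSnr:
    @staticmethod
    def _grid_with_levels(s_lin, n_lin):
        """Grid where the note box holds s_lin energy and noise box n_lin."""
        bins = np.arange(513) * BIN
        n_frames = 400
        hop = 102
        times = (512 + hop * np.arange(n_frames)) / FS
        psd = np.zeros((n_frames, 513))
        note_frames = (times >= 10.0) & (times <= 11.0)
        noise_frames = (times >= 4.0) & (times <= 5.0)
        psd[note_frames, 10] = s_lin / note_frames.sum()
        psd[noise_frames, 10] = n_lin / noise_frames.sum()
        return SpectrogramGrid(psd=psd, frame_times=times, bin_freqs=bins,
                               fs=FS, nfft=1024, hop=hop)

    def test_closed_forms(self):
        sel = Selection(1, "r", 10.0, 11.0, 15.0, 25.0)
        g = self._grid_with_levels(2.0, 1.0)     # S = 2N -> 0 dB
        snr, window, flags = note_snr(g, sel)
        assert snr == pytest.approx(0.0, abs=1e-9)
        assert window == (4.0, 5.0)
        g = self._grid_with_levels(11.0, 1.0)    # S = 11N -> 10 dB boundary
        snr, _, _ = note_snr(g, sel)
        assert snr == pytest.approx(10.0, abs=1e-9)

    def test_s_below_n_flagged_undefined(self):
        sel = Selection(1, "r", 10.0, 11.0, 15.0, 25.0)
        g = self._grid_with_levels(0.5, 1.0)
        snr, _, flags = note_snr(g, sel)
        assert np.isnan(snr) and "snr_undefined" in flags

    def test_noise_window_out_of_bounds_flagged(self):
        g = self._grid_with_levels(2.0, 1.0)
        sel = Selection(1, "r", 3.0, 4.0, 15.0, 25.0)  # noise would start at -2
        snr, _, flags = note_snr(g, sel)
        assert np.isnan(snr) and "noise_window_out_of_bounds" in flags

    def test_mean_snr_within_1db_of_analytic_for_note_over_white_noise(self):
        # closed-form energy ratio: note energy over the expected white-noise
        # energy inside the quantized selection box; a single noise window
        # has sampling scatter, so compare the mean over independent seeds
        note = make_note(CANONICAL_NOTE, FS)
        sel = Selection(1, "r", 15.0, 15.9, 15.0, 25.0)
        snrs = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            x = make_noise(FS * 30, NoiseSpec(level=-40, spectral_slope=0.0),
                           FS, rng)
            x[FS * 15:FS * 15 + note.size] += note
            snr, _, _ = note_snr(spectrogram(_rec(x)), sel)
            snrs.append(snr)
        e_note = np.sum(note ** 2)
        n_bins_in_box = 5                       # bins 8..12 lie in [15, 25] Hz
        e_noise = (10 ** (-40 / 10)) * 0.9 * FS * (n_bins_in_box / 512)
        expect = 10 * np.log10(e_note / e_noise)
        assert np.mean(snrs) == pytest.approx(expect, abs=1.0)

    def test_snr_strictly_increasing_in_note_amplitude(self):
        rng = np.random.default_rng(8)
        noise = make_noise(FS * 30, NoiseSpec(level=-35), FS, rng)
        from dataclasses import replace
        snrs = []
        for amp in (0.05, 0.1, 0.2, 0.4):
            note = make_note(replace(CANONICAL_NOTE, amplitude=amp), FS)
            x = noise.copy()
            x[FS * 15:FS * 15 + note.size] += note
            g = spectrogram(_rec(x))
            snr, _, _ = note_snr(g, Selection(1, "r", 15.0, 15.9, 15.0, 25.0))
            snrs.append(snr)
        assert all(b > a for a, b in zip(snrs, snrs[1:]))


class TestMeasureNotes:
    def test_zero_selections_empty_table(self, canonical_recording):
        out = measure_notes(canonical_recording, [])
        assert out.empty

    def test_deterministic_repeat(self, canonical_recording,
                                  canonical_selection):
        a = measure_notes(canonical_recording, [canonical_selection])
        b = measure_notes(canonical_recording, [canonical_selection])
        assert a.equals(b)

    def test_short_ini_noise_window_overlap_flagged(self):
        # two notes 5 s apart: the second note's noise window overlaps the first
        note = make_note(CANONICAL_NOTE, FS)
        x = np.zeros(FS * 30)
        # second note at 15.5 s: its noise window [9.6, 10.5] overlaps the
        # first note [10.0, 10.9]
        for onset in (10.0, 15.5):
            i0 = int(onset * FS)
            x[i0:i0 + note.size] += note
        rec = _rec(x)
        sels = [Selection(i + 1, "r", o, o + 0.9, 15.0, 25.0)
                for i, o in enumerate((10.0, 15.5))]
        out = measure_notes(rec, sels)
        assert "noise_overlaps_note" in out["Flags"].iloc[1]
        assert np.isfinite(out["SNR NIST Quick (dB)"].iloc[1])
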